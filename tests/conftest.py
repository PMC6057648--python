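import numpy as np
import pandas as pd
import pytest

from mitolineage import (
    MitoFeature,
    MitoGenome,
    PresenceMatrix,
    SampleMeta,
    mouse_scaffold,
    toy_genome,
)
from mitolineage.origins import TISSUES


@pytest.fixture(scope="session")
def mouse():
    return mouse_scaffold(seed=0)


@pytest.fixture(scope="session")
def toy():
    return toy_genome(seed=0)


def animal_meta(animal_id="a1", n_clones=3, genotype="wt", age_group="old",
                clone_level="sf_clone"):
    """Metadata for a 7-bulk-tissue + n skin-clone animal."""
    metas = {}
    for t in TISSUES:
        m = SampleMeta(f"{animal_id}_{t}", animal_id, genotype, 20.0,
                       age_group, t, "bulk")
        metas[m.sample_id] = m
    for c in range(1, n_clones + 1):
        m = SampleMeta(f"{animal_id}_c{c}", animal_id, genotype, 20.0,
                       age_group, "skin", clone_level, clone_id=f"c{c}")
        metas[m.sample_id] = m
    return metas


def make_matrix(detections, meta, animal_id="a1"):
    """PresenceMatrix from {variant_key: {sample_id: het}}."""
    samples = sorted(meta)
    idx = pd.MultiIndex.from_tuples(sorted(detections),
                                    names=["pos", "ref", "alt"])
    mat = pd.DataFrame(np.nan, index=idx, columns=samples)
    for key, dets in detections.items():
        for sid, het in dets.items():
            mat.loc[key, sid] = het
    return PresenceMatrix(animal_id=animal_id, matrix=mat, meta=meta)


@pytest.fixture
def make_animal_matrix():
    def _make(detections, n_clones=3, **kw):
        meta = animal_meta(n_clones=n_clones, **kw)
        return make_matrix(detections, meta)
    return _make
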