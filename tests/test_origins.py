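"""Origin classification from sharing patterns; pedigree logic; partitions."""

import numpy as np
import pandas as pd
import pytest

from mitolineage import (
    SampleMeta,
    build_presence,
    classify_all,
    classify_origin,
    classify_pedigree,
    read_manifest,
    shared_unique_partition,
    write_manifest,
)
from conftest import animal_meta, make_matrix

KEY = (100, "G", "A")


def mat(detections, **kw):
    return make_matrix(detections, animal_meta(**kw))


class TestClassifyOrigin:
    def test_multi_organ_bulk_is_germline(self):
        m = mat({KEY: {"a1_brain": 5.0, "a1_heart": 8.0, "a1_kidney": 3.0}})
        o = classify_origin(m, KEY)
        assert o.origin == "germline"
        assert o.n_organs == 3 and o.n_clones == 0

    def test_skin_bulk_plus_clones_is_early_embryonic(self):
        m = mat({KEY: {"a1_skin": 10.0, "a1_c1": 20.0, "a1_c2": 15.0,
                       "a1_c3": 30.0}})
        assert classify_origin(m, KEY).origin == "early_embryonic"

    def test_single_clone_only_is_somatic(self):
        m = mat({KEY: {"a1_c2": 40.0}}, n_clones=10)
        o = classify_origin(m, KEY)
        assert o.origin == "somatic"
        assert o.n_clones == 1

    def test_single_bulk_organ_is_early_embryonic(self):
        # interpretation: one-organ confinement marks embryonic origin for any
        # organ, not just skin/spleen
        m = mat({KEY: {"a1_liver": 4.0}})
        assert classify_origin(m, KEY).origin == "early_embryonic"

    def test_two_clones_no_bulk_is_early_embryonic(self):
        m = mat({KEY: {"a1_c1": 5.0, "a1_c2": 9.0}})
        assert classify_origin(m, KEY).origin == "early_embryonic"

    def test_clone_plus_other_organ_bulk_is_germline(self):
        # the clone counts toward its source organ (skin), so skin+liver = 2 organs
        m = mat({KEY: {"a1_c1": 5.0, "a1_liver": 3.0}})
        assert classify_origin(m, KEY).origin == "germline"

    def test_absent_variant_raises(self):
        m = mat({KEY: {"a1_brain": 5.0}})
        with pytest.raises(KeyError):
            classify_origin(m, (200, "C", "T"))

    def test_labels_partition_and_monotone_toward_germline(self):
        """Every pattern gets exactly one label; adding a new-organ detection
        never moves a variant toward somatic."""
        meta = animal_meta(n_clones=1)
        samples = sorted(meta)
        rank = {"somatic": 0, "early_embryonic": 1, "germline": 2}
        for bits in range(1, 2 ** len(samples)):
            dets = {s: 10.0 for i, s in enumerate(samples) if bits >> i & 1}
            m = make_matrix({KEY: dets}, meta)
            o = classify_origin(m, KEY)
            assert o.origin in rank
            organs = {meta[s].tissue for s in dets}
            for s in samples:
                if s in dets or meta[s].tissue in organs:
                    continue
                bigger = make_matrix({KEY: {**dets, s: 10.0}}, meta)
                assert rank[classify_origin(bigger, KEY).origin] >= rank[o.origin]


class TestSharedUniquePartition:
    def test_all_clones_identical_no_unique(self):
        dets = {
            (p, "G", "A"): {"a1_c1": 5.0, "a1_c2": 5.0, "a1_c3": 5.0}
            for p in (10, 20, 30)
        }
        n_total, n_shared, n_unique = shared_unique_partition(mat(dets))
        assert (n_total, n_shared, n_unique) == (9, 9, 0)

    def test_disjoint_clones_all_unique(self):
        dets = {(10 * c, "G", "A"): {f"a1_c{c}": 5.0} for c in (1, 2, 3)}
        n_total, n_shared, n_unique = shared_unique_partition(mat(dets))
        assert (n_total, n_shared, n_unique) == (3, 0, 3)

    def test_bulk_detection_makes_clone_occurrence_shared(self):
        dets = {KEY: {"a1_c1": 5.0, "a1_brain": 3.0}}
        assert shared_unique_partition(mat(dets)) == (1, 1, 0)

    def test_no_clone_samples_raises(self):
        m = mat({KEY: {"a1_brain": 5.0}}, n_clones=0)
        with pytest.raises(ValueError):
            shared_unique_partition(m)

    def test_totals_conserved_on_random_matrices(self):
        rng = np.random.default_rng(5)
        meta = animal_meta(n_clones=5)
        samples = sorted(meta)
        for _ in range(30):
            dets = {}
            for p in range(1, rng.integers(2, 40)):
                carriers = [s for s in samples if rng.random() < 0.3]
                if carriers:
                    dets[(p, "G", "A")] = {s: 5.0 for s in carriers}
            if not dets:
                continue
            n_total, n_shared, n_unique = shared_unique_partition(
                make_matrix(dets, meta)
            )
            assert n_shared + n_unique == n_total
            som = sum(
                1 for k in dets
                if classify_origin(make_matrix(dets, meta), k).origin == "somatic"
            )
            assert som == n_unique  # unique occurrences are the somatic calls


class TestPedigree:
    @staticmethod
    def _family():
        mother_meta = animal_meta("mom", n_clones=0)
        pups = {p: animal_meta(p, n_clones=0) for p in ("pup1", "pup2", "pup3")}
        return mother_meta, pups

    def test_maternal_detection_is_recurring(self):
        mother_meta, pups = self._family()
        key = (15104, "C", "T")
        mother = make_matrix({key: {"mom_skin": 6.0}}, mother_meta, "mom")
        pup1 = make_matrix(
            {key: {f"pup1_{t}": 13.0 for t in
                   ("brain", "heart", "kidney", "liver", "lung", "spleen", "skin")}},
            pups["pup1"], "pup1",
        )
        assert classify_pedigree(mother, [pup1], key) == "recurring"

    def test_sibling_sharing_is_recurring_without_mother(self):
        mother_meta, pups = self._family()
        key = (6612, "C", "T")
        mother = make_matrix({}, mother_meta, "mom")
        pup2 = make_matrix(
            {key: {f"pup2_{t}": 20.0 for t in
                   ("brain", "heart", "kidney", "liver", "lung", "spleen", "skin")}},
            pups["pup2"], "pup2",
        )
        pup3 = make_matrix(
            {key: {"pup3_kidney": 5.0, "pup3_lung": 6.0}}, pups["pup3"], "pup3"
        )
        assert classify_pedigree(mother, [pup2, pup3], key) == "recurring"

    def test_single_pup_private_variant_is_de_novo(self):
        mother_meta, pups = self._family()
        key = (9056, "C", "T")
        mother = make_matrix({}, mother_meta, "mom")
        pup1 = make_matrix({key: {"pup1_lung": 3.0}}, pups["pup1"], "pup1")
        pup2 = make_matrix({}, pups["pup2"], "pup2")
        assert classify_pedigree(mother, [pup1, pup2], key) == "de_novo"

    def test_absent_everywhere_raises(self):
        mother_meta, pups = self._family()
        mother = make_matrix({}, mother_meta, "mom")
        pup1 = make_matrix({}, pups["pup1"], "pup1")
        with pytest.raises(ValueError):
            classify_pedigree(mother, [pup1], (1, "A", "G"))


class TestMetaAndManifest:
    def test_clone_id_required_iff_clone(self):
        with pytest.raises(ValueError):
            SampleMeta("s", "a", "wt", 2.0, "young", "skin", "sf_clone")
        with pytest.raises(ValueError):
            SampleMeta("s", "a", "wt", 2.0, "young", "skin", "bulk",
                       clone_id="c1")

    def test_tissue_panel_enforced(self):
        with pytest.raises(ValueError):
            SampleMeta("s", "a", "wt", 2.0, "young", "tail", "bulk")

    def test_manifest_round_trip(self, tmp_path):
        meta = animal_meta(n_clones=2)
        p = tmp_path / "manifest.tsv"
        write_manifest(meta, p)
        again = read_manifest(p)
        assert again == meta

    def test_build_presence_groups_by_animal(self):
        meta = {**animal_meta("a1", 1), **animal_meta("a2", 1)}
        calls = pd.DataFrame(
            [("a1_brain", 100, "G", "A", 5.0), ("a2_brain", 100, "G", "A", 7.0),
             ("a1_heart", 100, "G", "A", 6.0)],
            columns=["sample_id", "pos", "ref", "alt", "heteroplasmy"],
        )
        mats = build_presence(calls, meta)
        assert set(mats) == {"a1", "a2"}
        assert classify_origin(mats["a1"], (100, "G", "A")).origin == "germline"
        assert classify_origin(mats["a2"], (100, "G", "A")).origin == \
            "early_embryonic"
        assert len(classify_all(mats["a1"])) == 1
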