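"""Developmental-origin classification of mtDNA variants within an animal.

The sharing pattern of a variant across an animal's bulk tissues and
single-cell-derived clones determines its origin:

* **germline** — detected in >= 2 distinct organs. A mutation inherited via
  the oocyte is distributed to most or all organs; detection in a clone
  counts toward the clone's source organ, but a variant seen only in clones
  of one organ is never germline.
* **somatic** — detected in exactly one clone and in no bulk sample: a
  late-arising mutation private to a single cell lineage.
* **early_embryonic** — everything else: confined to a single organ but
  present in its bulk sample and/or shared by >= 2 of its clones, the
  signature of a mutation arising in an embryonic progenitor of that lineage.

Across a pedigree, a germline variant of a pup is **recurring** if it is also
detected in any maternal sample or in >= 2 siblings, and **de_novo**
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPES = ("wt", "polg_homozygous", "polg_heterozygous")
AGE_GROUPS = ("young", "old")
TISSUES = ("brain", "heart", "kidney", "liver", "lung", "spleen", "skin")
LEVELS = ("bulk", "sf_clone", "ipsc_clone")
CLONE_LEVELS = ("sf_clone", "ipsc_clone")
ORIGINS = ("germline", "early_embryonic", "somatic")

MANIFEST_COLUMNS = [
    "sample_id", "animal_id", "genotype", "age_months", "age_group",
    "tissue", "level", "clone_id", "mother_id",
]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    genotype: str
    age_months: float
    age_group: str
    tissue: str
    level: str
    clone_id: str | None = None
    mother_id: str | None = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue {self.tissue!r} not in study panel")
        if self.level not in LEVELS:
            raise ValueError(f"unknown sample level {self.level!r}")
        if (self.clone_id is not None) != (self.level in CLONE_LEVELS):
            raise ValueError(
                f"{self.sample_id}: clone_id must be present iff level is a clone"
            )

    @property
    def is_clone(self) -> bool:
        return self.level in CLONE_LEVELS


@dataclass
class PresenceMatrix:
    """Variants x samples heteroplasmy matrix for one animal.

    ``matrix`` has a (pos, ref, alt) MultiIndex over variants and one column
    per sample; NaN means the variant was not detected (below the detection
    threshold) in that sample. Every recorded value is a passing call.
    """

    animal_id: str
    matrix: pd.DataFrame
    meta: dict[str, SampleMeta]

    def __post_init__(self):
        for sid in self.matrix.columns:
            if sid not in self.meta:
                raise ValueError(f"sample {sid} missing from metadata")
            if self.meta[sid].animal_id != self.animal_id:
                raise ValueError(
                    f"sample {sid} belongs to {self.meta[sid].animal_id}, "
                    f"not {self.animal_id}"
                )

    @property
    def variants(self) -> list[tuple[int, str, str]]:
        return list(self.matrix.index)

    def detecting_samples(self, key) -> list[str]:
        row = self.matrix.loc[[key]].iloc[0]
        return [sid for sid in self.matrix.columns if pd.notna(row[sid])]

    def mean_heteroplasmy(self, key) -> float:
        """Per-animal heteroplasmy of a variant: mean across detecting samples."""
        row = self.matrix.loc[[key]].iloc[0]
        return float(row.dropna().mean())


@dataclass(frozen=True)
class OriginCall:
    animal_id: str
    key: tuple[int, str, str]
    origin: str
    n_organs: int
    n_clones: int
    samples: tuple[str, ...]


def build_presence(
    calls: Iterable, manifest: Mapping[str, SampleMeta]
) -> dict[str, PresenceMatrix]:
    """Group passing calls into one PresenceMatrix per animal.

    ``calls`` may be HeteroplasmyCall objects or any records with sample_id,
    position (or pos), ref, alt and heteroplasmy attributes; a calls DataFrame
    from the vectorised caller is accepted too.
    """
    if isinstance(calls, pd.DataFrame):
        records = calls[["sample_id", "pos", "ref", "alt", "heteroplasmy"]].itertuples(
            index=False
        )
        rows = [(r.sample_id, (int(r.pos), r.ref, r.alt), r.heteroplasmy)
                for r in records]
    else:
        rows = [
            (c.sample_id, (int(getattr(c, "position", getattr(c, "pos", None))),
                           c.ref, c.alt), c.heteroplasmy)
            for c in calls
        ]
    by_animal: dict[str, dict] = {}
    for sid, key, het in rows:
        meta = manifest[sid]
        by_animal.setdefault(meta.animal_id, {}).setdefault(key, {})[sid] = het
    out = {}
    for animal_id, data in by_animal.items():
        samples = sorted(
            s for s, m in manifest.items() if m.animal_id == animal_id
        )
        idx = pd.MultiIndex.from_tuples(sorted(data), names=["pos", "ref", "alt"])
        mat = pd.DataFrame(np.nan, index=idx, columns=samples)
        for key, dets in data.items():
            for sid, het in dets.items():
                mat.loc[key, sid] = het
        out[animal_id] = PresenceMatrix(
            animal_id=animal_id,
            matrix=mat,
            meta={s: manifest[s] for s in samples},
        )
    return out


def classify_origin(matrix: PresenceMatrix, key) -> OriginCall:
    """Assign germline / early_embryonic / somatic to one variant."""
    detecting = matrix.detecting_samples(key)
    if not detecting:
        raise ValueError(f"variant {key} not detected in any sample")
    metas = [matrix.meta[s] for s in detecting]
    organs = {m.tissue for m in metas}  # clones count toward their source organ
    clones = [m for m in metas if m.is_clone]
    bulks = [m for m in metas if not m.is_clone]
    if len(organs) >= 2:
        origin = "germline"
    elif len(clones) == 1 and not bulks and len(detecting) == 1:
        origin = "somatic"
    else:
        origin = "early_embryonic"
    return OriginCall(
        animal_id=matrix.animal_id,
        key=key,
        origin=origin,
        n_organs=len(organs),
        n_clones=len(clones),
        samples=tuple(detecting),
    )


def classify_all(matrix: PresenceMatrix) -> list[OriginCall]:
    return [classify_origin(matrix, key) for key in matrix.variants]


def shared_unique_partition(
    matrix: PresenceMatrix, clone_level: str | tuple[str, ...] = "sf_clone"
) -> tuple[int, int, int]:
    """Partition clone variant occurrences into shared vs clonally unique.

    Occurrences are variant x clone detections at the requested clone level.
    An occurrence is *unique* (somatic-type) when its variant is detected in
    exactly one sample of the animal overall — that single clone; it is
    *shared* when the variant is also seen in another clone or in any bulk
    tissue. Returns (n_total, n_shared, n_unique).
    """
    levels = (clone_level,) if isinstance(clone_level, str) else tuple(clone_level)
    clone_samples = [s for s, m in matrix.meta.items() if m.level in levels]
    if not clone_samples:
        raise ValueError(f"no {levels} samples for animal {matrix.animal_id}")
    n_total = n_shared = 0
    for key in matrix.variants:
        detecting = matrix.detecting_samples(key)
        in_clones = [s for s in detecting if s in clone_samples]
        n_total += len(in_clones)
        if len(detecting) > 1:
            n_shared += len(in_clones)
    return n_total, n_shared, n_total - n_shared


def classify_pedigree(
    mother: PresenceMatrix | None,
    offspring: list[PresenceMatrix],
    key,
) -> str:
    """de_novo | recurring for a variant carried by at least one pup.

    Recurring means maternal transmission (detected in any maternal sample)
    or sharing between >= 2 siblings; anything else is a de novo germline
    event in a single oocyte.
    """
    if not offspring:
        raise ValueError("no offspring matrices supplied")
    carriers = [
        m for m in offspring
        if key in set(m.variants) and m.detecting_samples(key)
    ]
    if not carriers:
        raise ValueError(f"variant {key} not detected in any offspring")
    if mother is not None and key in set(mother.variants):
        if mother.detecting_samples(key):
            return "recurring"
    return "recurring" if len(carriers) >= 2 else "de_novo"


# ---------------------------------------------------------------------------
# manifest I/O

def read_manifest(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        def opt(v):
            return None if (not isinstance(v, str) or v in (".", "")) else v
        meta = SampleMeta(
            sample_id=row.sample_id,
            animal_id=row.animal_id,
            genotype=row.genotype,
            age_months=float(row.age_months),
            age_group=row.age_group,
            tissue=row.tissue,
            level=row.level,
            clone_id=opt(row.clone_id),
            mother_id=opt(row.mother_id),
        )
        out[meta.sample_id] = meta
    return out


def write_manifest(manifest: Mapping[str, SampleMeta], path) -> None:
    rows = [
        (m.sample_id, m.animal_id, m.genotype, m.age_months, m.age_group,
         m.tissue, m.level, m.clone_id or ".", m.mother_id or ".")
        for m in manifest.values()
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def origin_calls_frame(origin_calls: list[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.animal_id, o.key[0], o.key[1], o.key[2], o.origin,
             o.n_organs, o.n_clones, ",".join(o.samples))
            for o in origin_calls
        ],
        columns=["animal_id", "pos", "ref", "alt", "origin",
                 "n_organs", "n_clones", "samples"],
    )
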