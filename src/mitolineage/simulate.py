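"""Synthetic multi-tissue / multi-clone mtDNA cohort generator.

The generator seeds three kinds of variants per animal and turns the true
per-sample heteroplasmies into stranded allele-count tables with sequencing
noise, so the whole calling -> annotation -> origin-classification pipeline is
testable without any sequencing data.

Generative model
----------------
* **germline** variants (Poisson per animal) are seeded in the zygote at a low
  founder heteroplasmy and drift independently in every tissue/clone by
  neutral Wright-Fisher resampling of ``n_seg`` segregating mtDNA units for
  ``gens_per_month * age_months`` rounds. Young animals therefore often carry
  germline variants below the 2% detection threshold — non-detection in the
  young is emergent, and clonal expansion with age raises detected
  heteroplasmy.
* **early-embryonic** variants (Poisson per animal) are confined to one organ
  lineage: present in that organ's bulk sample and in clones derived from it,
  again with per-sample drift.
* **somatic** variants (Poisson per clone, genotype- and age-dependent rate)
  are private to a single clone, at a heteroplasmy drawn uniformly from a
  configurable range (default 15-100%; within-clone expansion is not modelled
  mechanistically).

Variant keys (pos, alt) are drawn distinct within an animal: independent
mutational events hitting the same base with the same substitution are
vanishingly rare on a 16.3-kb genome and coincidental sharing would corrupt
the sharing-based truth labels.

Read counts at every site are Multinomial(coverage, allele frequencies) after
applying a uniform per-base error rate (each read miscalled to one of the
other three bases with probability ``error_rate``); forward/reverse counts
split Binomial(n, 1/2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as refmod
from .caller import BASES, COUNTS_COLUMNS
from .origins import SampleMeta, TISSUES, read_manifest, write_manifest
from .reference import MitoGenome

GroupKey = tuple[str, str]  # (genotype, age_group)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Study-design and rate parameters of the synthetic cohort.

    Defaults mirror the study conditions: 7-tissue panel, 10 SF clones per
    animal, >= 1000x coverage (5000x simulated), 0.2% per-base error, an 80%
    transition spectrum, no somatic mutations in wild-type animals and
    mutator-genotype somatic rates of 59.2 (young) and 95.4 (old) per clone.
    """

    n_animals: dict[GroupKey, int] = field(default_factory=lambda: {
        ("wt", "young"): 5,
        ("wt", "old"): 8,
        ("polg_homozygous", "young"): 3,
        ("polg_homozygous", "old"): 3,
    })
    age_months: dict[GroupKey, float] = field(default_factory=lambda: {
        ("wt", "young"): 8.0,
        ("wt", "old"): 26.0,
        ("polg_homozygous", "young"): 2.0,
        ("polg_homozygous", "old"): 9.0,
    })
    tissues: tuple[str, ...] = TISSUES
    sf_clones: int = 10
    ipsc_clones: int = 0
    clone_tissue: str = "skin"
    # mutation rates
    lambda_germline: dict[str, float] = field(default_factory=lambda: {
        "wt": 1.5, "polg_homozygous": 5.0, "polg_heterozygous": 5.0,
    })
    lambda_embryonic: dict[str, float] = field(default_factory=lambda: {
        "wt": 0.8, "polg_homozygous": 20.0, "polg_heterozygous": 20.0,
    })
    lambda_somatic: dict[GroupKey, float] = field(default_factory=lambda: {
        ("wt", "young"): 0.0,
        ("wt", "old"): 0.0,
        ("polg_homozygous", "young"): 59.2,
        ("polg_homozygous", "old"): 95.4,
    })
    # heteroplasmy distributions (fractions, 0..1); germline founders sit
    # below the 2% detection threshold so young-animal non-detection and the
    # age-driven rise in detected counts both emerge from drift
    germline_founder_range: tuple[float, float] = (0.005, 0.02)
    embryonic_founder_range: tuple[float, float] = (0.02, 0.30)
    somatic_het_range: tuple[float, float] = (0.15, 1.0)
    # drift: effective segregating units and resampling rounds per month,
    # calibrated once so detection probability is still in its rising phase
    # over a mouse lifespan (absorption timescale n_seg >> lifetime rounds)
    n_seg: int = 5000
    gens_per_month: float = 1.0
    # spectrum & sequencing
    transition_fraction: float = 0.8
    coverage: int = 5000
    error_rate: float = 0.002

    def __post_init__(self):
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError("transition_fraction must be in [0, 1]")
        for lam in list(self.lambda_germline.values()) + list(
            self.lambda_embryonic.values()
        ) + list(self.lambda_somatic.values()):
            if lam < 0:
                raise ValueError("mutation rates must be >= 0")
        if self.n_seg < 1:
            raise ValueError("n_seg must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    animal_id: str
    position: int
    ref: str
    alt: str
    origin: str
    founder_heteroplasmy: float  # fraction
    sample_heteroplasmy: dict[str, float] = field(default_factory=dict, compare=False)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass
class SimulatedCohort:
    manifest: dict[str, SampleMeta]
    counts: dict[str, pd.DataFrame]  # sample_id -> counts table
    truth: list[TruthRecord]
    genome: MitoGenome


def drift_heteroplasmy(
    h0: float, generations: int, n_seg: int, rng: np.random.Generator
) -> float:
    """Neutral Wright-Fisher drift of a heteroplasmic fraction.

    ``generations`` rounds of Binomial(n_seg, h)/n_seg resampling; 0 and 1 are
    absorbing.
    """
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"heteroplasmy fraction {h0} outside [0, 1]")
    h = h0
    for _ in range(int(generations)):
        if h in (0.0, 1.0):
            break
        h = rng.binomial(n_seg, h) / n_seg
    return h


def _draw_variant(
    genome: MitoGenome, used: set, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, str, str]:
    """A (pos, ref, alt) SNV not yet used in this animal."""
    while True:
        pos = int(rng.integers(1, genome.genome_length + 1))
        ref = genome.base_at(pos)
        if rng.random() < config.transition_fraction:
            alt = _TRANSITION[ref]
        else:
            alt = str(rng.choice(sorted(set("ACGT") - {ref, _TRANSITION[ref]})))
        if (pos, alt) not in used:
            used.add((pos, alt))
            return pos, ref, alt


def _counts_table(
    sample_id: str,
    genome: MitoGenome,
    site_het: dict[int, list[tuple[str, float]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Stranded base counts for one sample over every genome position."""
    L = genome.genome_length
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.fromiter(
        (base_idx[b] for b in genome.sequence), dtype=np.int64, count=L
    )
    p = np.zeros((L, 4))
    p[np.arange(L), ref_idx] = 1.0
    for pos, alleles in site_het.items():
        total = sum(h for _, h in alleles)
        p[pos - 1, ref_idx[pos - 1]] = max(1.0 - total, 0.0)
        for alt, h in alleles:
            p[pos - 1, base_idx[alt]] += h
    e = config.error_rate
    p = p * (1.0 - e) + (1.0 - p) * (e / 3.0)
    p /= p.sum(axis=1, keepdims=True)
    totals = rng.multinomial(config.coverage, p)  # (L, 4)
    fwd = rng.binomial(totals, 0.5)
    rev = totals - fwd
    data = {"sample_id": sample_id, "pos": np.arange(1, L + 1),
            "ref": list(genome.sequence)}
    for b in BASES:
        data[f"{b}_f"] = fwd[:, base_idx[b]]
        data[f"{b}_r"] = rev[:, base_idx[b]]
    data["indel_allele"] = "."
    data["indel_f"] = 0
    data["indel_r"] = 0
    return pd.DataFrame(data, columns=COUNTS_COLUMNS)


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    genome: MitoGenome | None = None,
) -> SimulatedCohort:
    """Simulate a full cohort; deterministic given (config, seed, genome).

    Per-animal RNG substreams are derived from the seed and a running animal
    counter, so one animal's draws do not shift another's when group sizes
    are edited.
    """
    config = config or SimulationConfig()
    genome = genome or refmod.mouse_scaffold()
    manifest: dict[str, SampleMeta] = {}
    counts: dict[str, pd.DataFrame] = {}
    truth: list[TruthRecord] = []
    animal_counter = 0
    for (genotype, age_group), n in sorted(config.n_animals.items()):
        age = config.age_months[(genotype, age_group)]
        gens = int(round(config.gens_per_month * age))
        for i in range(n):
            animal_counter += 1
            rng = np.random.default_rng([seed, animal_counter])
            animal_id = f"{genotype}_{age_group}_{i + 1}"
            metas = _animal_manifest(animal_id, genotype, age, age_group, config)
            for m in metas:
                manifest[m.sample_id] = m
            records = _seed_animal_variants(
                genome, metas, genotype, age_group, gens, config, rng
            )
            truth.extend(records)
            site_het_by_sample: dict[str, dict[int, list]] = {
                m.sample_id: {} for m in metas
            }
            for rec in records:
                for sid, h in rec.sample_heteroplasmy.items():
                    if h > 0:
                        site_het_by_sample[sid].setdefault(
                            rec.position, []
                        ).append((rec.alt, h))
            for m in metas:
                counts[m.sample_id] = _counts_table(
                    m.sample_id, genome, site_het_by_sample[m.sample_id],
                    config, rng,
                )
    return SimulatedCohort(manifest=manifest, counts=counts, truth=truth,
                           genome=genome)


def _animal_manifest(animal_id, genotype, age, age_group, config):
    metas = [
        SampleMeta(
            sample_id=f"{animal_id}_{t}", animal_id=animal_id,
            genotype=genotype, age_months=age, age_group=age_group,
            tissue=t, level="bulk",
        )
        for t in config.tissues
    ]
    for level, n in (("sf_clone", config.sf_clones),
                     ("ipsc_clone", config.ipsc_clones)):
        for c in range(1, n + 1):
            cid = f"{'sf' if level == 'sf_clone' else 'ips'}{c}"
            metas.append(SampleMeta(
                sample_id=f"{animal_id}_{cid}", animal_id=animal_id,
                genotype=genotype, age_months=age, age_group=age_group,
                tissue=config.clone_tissue, level=level, clone_id=cid,
            ))
    return metas


def _seed_animal_variants(genome, metas, genotype, age_group, gens, config, rng):
    used: set = set()
    records: list[TruthRecord] = []
    animal_id = metas[0].animal_id
    bulks = [m for m in metas if m.level == "bulk"]
    clones = [m for m in metas if m.is_clone]
    lo, hi = config.germline_founder_range
    for _ in range(rng.poisson(config.lambda_germline[genotype])):
        pos, ref, alt = _draw_variant(genome, used, config, rng)
        h0 = rng.uniform(lo, hi)
        per_sample = {
            m.sample_id: drift_heteroplasmy(h0, gens, config.n_seg, rng)
            for m in metas
        }
        records.append(TruthRecord(animal_id, pos, ref, alt, "germline",
                                   h0, per_sample))
    lo_e, hi_e = config.embryonic_founder_range
    for _ in range(rng.poisson(config.lambda_embryonic[genotype])):
        pos, ref, alt = _draw_variant(genome, used, config, rng)
        h0 = rng.uniform(lo_e, hi_e)
        organ = config.tissues[int(rng.integers(len(config.tissues)))]
        carriers = [m for m in metas
                    if m.tissue == organ and (m.level == "bulk" or m.is_clone)]
        per_sample = {
            m.sample_id: drift_heteroplasmy(h0, gens, config.n_seg, rng)
            for m in carriers
        }
        records.append(TruthRecord(animal_id, pos, ref, alt,
                                   "early_embryonic", h0, per_sample))
    lam_s = config.lambda_somatic.get((genotype, age_group), 0.0)
    lo_s, hi_s = config.somatic_het_range
    for m in clones:
        for _ in range(rng.poisson(lam_s)):
            pos, ref, alt = _draw_variant(genome, used, config, rng)
            h = rng.uniform(lo_s, hi_s)
            records.append(TruthRecord(animal_id, pos, ref, alt, "somatic",
                                       h, {m.sample_id: h}))
    return records


# ---------------------------------------------------------------------------
# fixture emission / reload

TRUTH_COLUMNS = ["animal_id", "pos", "ref", "alt", "origin",
                 "founder_heteroplasmy", "sample_heteroplasmy"]


def emit_fixtures(cohort: SimulatedCohort, out_dir) -> None:
    """Write ref.fasta, manifest.tsv, truth.tsv and counts/<sample>.tsv."""
    os.makedirs(os.path.join(out_dir, "counts"), exist_ok=True)
    refmod.write_fasta(cohort.genome, os.path.join(out_dir, "ref.fasta"))
    refmod.write_feature_table(
        cohort.genome.features, os.path.join(out_dir, "features.tsv")
    )
    write_manifest(cohort.manifest, os.path.join(out_dir, "manifest.tsv"))
    rows = [
        (t.animal_id, t.position, t.ref, t.alt, t.origin,
         t.founder_heteroplasmy,
         ";".join(f"{s}={h:.6g}" for s, h in sorted(t.sample_heteroplasmy.items())))
        for t in cohort.truth
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        os.path.join(out_dir, "truth.tsv"), sep="\t", index=False
    )
    for sid, df in cohort.counts.items():
        df.to_csv(os.path.join(out_dir, "counts", f"{sid}.tsv"),
                  sep="\t", index=False)


def load_fixtures(out_dir) -> SimulatedCohort:
    genome = refmod.load_reference(
        os.path.join(out_dir, "ref.fasta"), os.path.join(out_dir, "features.tsv")
    )
    manifest = read_manifest(os.path.join(out_dir, "manifest.tsv"))
    truth_df = pd.read_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
    truth = []
    for row in truth_df.itertuples(index=False):
        per_sample = {}
        if isinstance(row.sample_heteroplasmy, str) and row.sample_heteroplasmy:
            for part in row.sample_heteroplasmy.split(";"):
                s, h = part.rsplit("=", 1)
                per_sample[s] = float(h)
        truth.append(TruthRecord(
            row.animal_id, int(row.pos), row.ref, row.alt, row.origin,
            float(row.founder_heteroplasmy), per_sample,
        ))
    counts = {}
    cdir = os.path.join(out_dir, "counts")
    for fn in sorted(os.listdir(cdir)):
        sid = fn[:-4]
        counts[sid] = pd.read_csv(os.path.join(cdir, fn), sep="\t",
                                  dtype={"indel_allele": str})
    return SimulatedCohort(manifest=manifest, counts=counts, truth=truth,
                           genome=genome)


def single_animal_config(
    genotype: str = "polg_homozygous",
    age_group: str = "young",
    **overrides,
) -> SimulationConfig:
    """Convenience: a one-animal cohort of the given group."""
    cfg = SimulationConfig(
        n_animals={(genotype, age_group): 1},
        **overrides,
    )
    return cfg
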