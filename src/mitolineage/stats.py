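"""Cohort-level summaries: mutation-count grids, heteroplasmy means,
spectrum/complex distributions, and Student's t-tests.

Conventions
-----------
* germline counts are reported per bulk tissue sample; early-embryonic counts
  per bulk tissue or single SF clone; somatic counts per clone (SF or iPSC) —
  each unit contributes the number of variants of that origin detected in it.
* SEM uses the sample standard deviation (n-1 denominator) over sqrt(n); it is
  undefined (NaN) for n = 1.
* the t-test is the classical pooled-variance Student's t with
  df = n_a + n_b - 2 (a Welch option is exposed); two-sided p-values.
* printed percentages round half away from zero (84.6 -> 85, 66.7 -> 67).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import VariantAnnotation
from .caller import PipelineConfig
from .origins import (
    CLONE_LEVELS,
    OriginCall,
    PresenceMatrix,
    SampleMeta,
)


def percent_rounded(numerator: int, denominator: int) -> int:
    """Integer percent, rounding halves away from zero (reporting style)."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mean_sem(values) -> tuple[float, float]:
    """(mean, standard error of the mean); SEM is NaN for n = 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem of an empty list")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool


def two_sample_t(a, b, alpha: float = 0.05, welch: bool = False) -> TTestResult:
    """Two-sided Student's t-test (pooled variance by default).

    Degenerate inputs with zero pooled variance give t = 0, p = 1 when the
    means are equal and t = +/-inf, p = 0 otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TTestResult(
            float(res.statistic), float(res.df), float(res.pvalue),
            bool(res.pvalue < alpha),
        )
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, False)
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(t, df, 0.0, True)
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), bool(p < alpha))


def is_functional(annotation: VariantAnnotation) -> bool:
    """True for variants expected to perturb gene products: non-synonymous
    substitutions and indels in protein genes, and any variant in an RNA gene.
    Synonymous, NCR and intergenic variants are not functional (NCR variants
    are tracked in their own summary)."""
    if annotation.effect == "non_synonymous":
        return True
    if annotation.effect == "RNA":
        return True
    return False


# ---------------------------------------------------------------------------
# cohort summary

@dataclass
class CohortSummary:
    """Summary surfaces of a classified, annotated cohort.

    counts          per-(genotype, age_group, origin) mean/SEM/n mutation counts
    heteroplasmy    per-(genotype, age_group, origin) mean/SEM heteroplasmy of
                    functional variants (per-animal variant means)
    spectrum        per-group transition/transversion/indel fractions
    complex_dist    per-group distribution of functional germline variants over
                    OXPHOS complexes / RNA genes
    somatic_strata  per-group counts of functional somatic variants at >= 15%
                    and >= 80% heteroplasmy
    ncr             per-group NCR variant count and mean heteroplasmy
    tests           named TTestResult contrasts (young vs old, per genotype)
    """

    counts: pd.DataFrame
    heteroplasmy: pd.DataFrame
    spectrum: pd.DataFrame
    complex_dist: pd.DataFrame
    somatic_strata: pd.DataFrame
    ncr: pd.DataFrame
    tests: dict[str, TTestResult] = field(default_factory=dict)


def _count_units(origin: str, meta: SampleMeta) -> bool:
    """Is this sample a denominator unit for the given origin's count grid?

    The early-embryonic denominator mixes bulk tissues and single SF clones
    (the reporting convention); pure per-tissue and per-clone variants of the
    same statistic are emitted alongside because the mixed denominator is
    ambiguous to interpret.
    """
    if origin == "germline" or origin == "early_embryonic_per_tissue":
        return meta.level == "bulk"
    if origin == "early_embryonic":
        return meta.level in ("bulk", "sf_clone")
    if origin == "early_embryonic_per_clone":
        return meta.level == "sf_clone"
    return meta.level in CLONE_LEVELS  # somatic: per clone (SF or iPSC)


def per_unit_counts(
    matrices: dict[str, PresenceMatrix],
    origin_calls: list[OriginCall],
    manifest: dict[str, SampleMeta],
    origin: str,
) -> dict[str, int]:
    """Number of variants of ``origin`` detected in each denominator unit."""
    base = "early_embryonic" if origin.startswith("early_embryonic") else origin
    origin_keys = {
        (o.animal_id, o.key) for o in origin_calls if o.origin == base
    }
    units = {
        sid: 0 for sid, m in manifest.items() if _count_units(origin, m)
    }
    for animal_id, pm in matrices.items():
        for key in pm.variants:
            if (animal_id, key) not in origin_keys:
                continue
            for sid in pm.detecting_samples(key):
                if sid in units:
                    units[sid] += 1
    return units


def summarize_cohort(
    matrices: dict[str, PresenceMatrix],
    origin_calls: list[OriginCall],
    annotations: dict[tuple[int, str, str], VariantAnnotation],
    manifest: dict[str, SampleMeta],
    config: PipelineConfig | None = None,
) -> CohortSummary:
    config = config or PipelineConfig()
    groups = sorted({(m.genotype, m.age_group) for m in manifest.values()})
    animal_group = {}
    for m in manifest.values():
        animal_group[m.animal_id] = (m.genotype, m.age_group)

    # ---- count grids -----------------------------------------------------
    count_rows = []
    per_unit_by_origin = {}
    for origin in ("germline", "early_embryonic", "early_embryonic_per_tissue",
                   "early_embryonic_per_clone", "somatic"):
        units = per_unit_counts(matrices, origin_calls, manifest, origin)
        per_unit_by_origin[origin] = units
        for g in groups:
            vals = [
                n for sid, n in units.items()
                if (manifest[sid].genotype, manifest[sid].age_group) == g
            ]
            if not vals:
                continue
            mean, sem = mean_sem(vals) if len(vals) > 1 else (float(vals[0]), float("nan"))
            count_rows.append(g + (origin, mean, sem, len(vals)))
    counts = pd.DataFrame(
        count_rows,
        columns=["genotype", "age_group", "origin", "mean", "sem", "n"],
    )

    # ---- per-(animal, variant) table ------------------------------------
    var_rows = []
    for o in origin_calls:
        pm = matrices[o.animal_id]
        ann = annotations.get(o.key)
        if ann is None:
            continue
        var_rows.append(
            animal_group[o.animal_id]
            + (o.animal_id, o.key, o.origin, ann.effect, ann.oxphos_complex,
               ann.feature_class, ann.substitution_class, is_functional(ann),
               pm.mean_heteroplasmy(o.key))
        )
    variants = pd.DataFrame(
        var_rows,
        columns=["genotype", "age_group", "animal_id", "key", "origin",
                 "effect", "oxphos_complex", "feature_class",
                 "substitution_class", "functional", "heteroplasmy"],
    )

    # ---- heteroplasmy of functional variants by origin -------------------
    het_rows = []
    if not variants.empty:
        func = variants[variants["functional"]]
        for (g, a, origin), sub in func.groupby(["genotype", "age_group", "origin"]):
            vals = sub["heteroplasmy"].to_numpy()
            mean, sem = mean_sem(vals) if len(vals) > 1 else (float(vals[0]), float("nan"))
            het_rows.append((g, a, origin, mean, sem, len(vals)))
    heteroplasmy = pd.DataFrame(
        het_rows,
        columns=["genotype", "age_group", "origin", "mean", "sem", "n"],
    )

    # ---- substitution spectrum -------------------------------------------
    spec_rows = []
    if not variants.empty:
        for (g, a), sub in variants.groupby(["genotype", "age_group"]):
            n = len(sub)
            for cls in ("transition", "transversion", "indel"):
                k = int((sub["substitution_class"] == cls).sum())
                spec_rows.append((g, a, cls, k, k / n))
    spectrum = pd.DataFrame(
        spec_rows,
        columns=["genotype", "age_group", "class", "count", "fraction"],
    )

    # ---- complex / RNA distribution of functional germline variants ------
    cx_rows = []
    if not variants.empty:
        germ = variants[(variants["origin"] == "germline") & variants["functional"]]
        for (g, a), sub in germ.groupby(["genotype", "age_group"]):
            n = len(sub)
            labels = np.where(
                sub["feature_class"].isin(["tRNA", "rRNA"]),
                sub["feature_class"],
                sub["oxphos_complex"],
            )
            for lab in sorted(set(labels)):
                k = int((labels == lab).sum())
                cx_rows.append((g, a, lab, k, k / n))
    complex_dist = pd.DataFrame(
        cx_rows, columns=["genotype", "age_group", "group", "count", "fraction"]
    )

    # ---- somatic heteroplasmy strata --------------------------------------
    strata_rows = []
    if not variants.empty:
        som = variants[(variants["origin"] == "somatic") & variants["functional"]]
        for (g, a), sub in som.groupby(["genotype", "age_group"]):
            strata_rows.append(
                (g, a, len(sub),
                 int((sub["heteroplasmy"] >= config.functional_het_threshold_pct).sum()),
                 int((sub["heteroplasmy"] >= config.high_het_threshold_pct).sum()))
            )
    somatic_strata = pd.DataFrame(
        strata_rows,
        columns=["genotype", "age_group", "n_functional_somatic",
                 "n_ge_15pct", "n_ge_80pct"],
    )

    # ---- NCR sub-summary ---------------------------------------------------
    ncr_rows = []
    if not variants.empty:
        ncr_v = variants[variants["effect"] == "NCR"]
        for (g, a), sub in ncr_v.groupby(["genotype", "age_group"]):
            ncr_rows.append((g, a, len(sub), float(sub["heteroplasmy"].mean())))
    ncr = pd.DataFrame(
        ncr_rows, columns=["genotype", "age_group", "n", "mean_heteroplasmy"]
    )

    # ---- young vs old contrasts -------------------------------------------
    tests: dict[str, TTestResult] = {}
    for genotype in sorted({g for g, _ in groups}):
        for origin in ("germline", "somatic"):
            units = per_unit_by_origin[origin]
            young = [
                n for sid, n in units.items()
                if manifest[sid].genotype == genotype
                and manifest[sid].age_group == "young"
            ]
            old = [
                n for sid, n in units.items()
                if manifest[sid].genotype == genotype
                and manifest[sid].age_group == "old"
            ]
            if len(young) >= 2 and len(old) >= 2:
                tests[f"{genotype}_{origin}_young_vs_old"] = two_sample_t(
                    young, old, alpha=config.alpha
                )

    return CohortSummary(
        counts=counts,
        heteroplasmy=heteroplasmy,
        spectrum=spectrum,
        complex_dist=complex_dist,
        somatic_strata=somatic_strata,
        ncr=ncr,
        tests=tests,
    )
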