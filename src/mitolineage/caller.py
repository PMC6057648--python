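"""Heteroplasmy computation and threshold variant calling from allele counts.

Heteroplasmy of an allele at a site is defined as

    100 * (alt forward + alt reverse) / (A+C+G+T forward+reverse)

i.e. the mutant allele fraction over the total base coverage; for indel
alleles the denominator is unchanged (base coverage). A variant is called
when its heteroplasmy is >= the detection threshold (default 2%, inclusive)
and the site's base coverage is >= the minimum (default 1000x). Homoplasmy is
represented as heteroplasmy = 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import MitoGenome

BASES = ("A", "C", "G", "T")

COUNTS_COLUMNS = [
    "sample_id", "pos", "ref",
    "A_f", "A_r", "C_f", "C_r", "G_f", "G_r", "T_f", "T_r",
    "indel_allele", "indel_f", "indel_r",
]


@dataclass
class PipelineConfig:
    """Detection thresholds of the calling/summary pipeline.

    detection_threshold_pct
        Minimum heteroplasmy (percent, inclusive) for a call. The default 2.0
        is conservative; heteroplasmies above ~1.6% are likely biological
        rather than technical, and that looser bound may be configured here.
    min_coverage
        Minimum total base coverage at the site (default 1000x).
    sanger_note_threshold_pct
        Report-only marker: calls above this level (8%) would historically be
        confirmed by Sanger sequencing.
    functional_het_threshold_pct / high_het_threshold_pct
        Strata bounds (15% / 80%) used in cohort summaries of somatic load.
    alpha
        Two-sided significance level for cohort t-tests.
    """

    detection_threshold_pct: float = 2.0
    min_coverage: int = 1000
    sanger_note_threshold_pct: float = 8.0
    functional_het_threshold_pct: float = 15.0
    high_het_threshold_pct: float = 80.0
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.detection_threshold_pct < 100:
            raise ValueError("detection_threshold_pct must be in (0, 100)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class SiteAlleleCounts:
    """Stranded base counts (and indel evidence) at one site of one sample.

    ``counts`` maps base -> (forward, reverse). ``indel_counts`` maps an indel
    allele key -> (forward, reverse); indel keys are ``ins:<seq>`` (insertion
    of <seq> after the site) or ``del:<n>`` (deletion of <n> bases after the
    site).
    """

    sample_id: str
    position: int
    ref_base: str
    counts: dict[str, tuple[int, int]]
    indel_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for b in BASES:
            self.counts.setdefault(b, (0, 0))
        for allele, (f, r) in list(self.counts.items()) + list(
            self.indel_counts.items()
        ):
            if f < 0 or r < 0:
                raise ValueError(f"negative count for {allele} at {self.position}")

    @property
    def coverage(self) -> int:
        """Total base coverage: A+C+G+T, forward plus reverse."""
        return sum(f + r for f, r in (self.counts[b] for b in BASES))


@dataclass
class HeteroplasmyCall:
    """One called variant in one sample."""

    sample_id: str
    position: int
    ref: str
    alt: str
    heteroplasmy: float  # percent, 0..100
    coverage: int
    passed: bool = True

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def heteroplasmy_percent(site: SiteAlleleCounts, alt: str) -> float:
    """Mutant allele frequency of ``alt`` at ``site``, in percent."""
    cov = site.coverage
    if cov == 0:
        raise ValueError(f"zero coverage at position {site.position}")
    if alt in BASES:
        f, r = site.counts[alt]
    elif alt in site.indel_counts:
        f, r = site.indel_counts[alt]
    else:
        raise KeyError(f"unknown allele {alt!r} at position {site.position}")
    return 100.0 * (f + r) / cov


def indel_ref_alt(genome: MitoGenome, position: int, allele: str) -> tuple[str, str]:
    """Expand an indel allele key into anchored VCF-style (ref, alt) strings."""
    anchor = genome.base_at(position)
    if allele.startswith("ins:"):
        return anchor, anchor + allele[4:]
    if allele.startswith("del:"):
        n = int(allele[4:])
        if position + n > genome.genome_length:
            raise ValueError(f"deletion at {position} runs past genome end")
        return anchor + genome.sequence[position : position + n], anchor
    raise ValueError(f"malformed indel allele {allele!r}")


def call_sample(
    sites: list[SiteAlleleCounts],
    genome: MitoGenome,
    config: PipelineConfig | None = None,
) -> list[HeteroplasmyCall]:
    """Emit passing calls (one per non-reference allele) for one sample.

    A site whose recorded reference base disagrees with the genome raises a
    warning and the genome base is trusted.
    """
    config = config or PipelineConfig()
    calls: list[HeteroplasmyCall] = []
    for site in sites:
        ref = genome.base_at(site.position)
        if site.ref_base != ref:
            warnings.warn(
                f"{site.sample_id} pos {site.position}: counts table ref "
                f"{site.ref_base} != genome {ref}; trusting genome",
                stacklevel=2,
            )
        cov = site.coverage
        if cov == 0 or cov < config.min_coverage:
            continue
        alleles = [b for b in BASES if b != ref and sum(site.counts[b]) > 0]
        alleles += list(site.indel_counts)
        for allele in alleles:
            het = heteroplasmy_percent(site, allele)
            if het < config.detection_threshold_pct:
                continue
            if allele in BASES:
                r, a = ref, allele
            else:
                r, a = indel_ref_alt(genome, site.position, allele)
            calls.append(
                HeteroplasmyCall(
                    sample_id=site.sample_id,
                    position=site.position,
                    ref=r,
                    alt=a,
                    heteroplasmy=het,
                    coverage=cov,
                )
            )
    return calls


def call_frame(
    counts: pd.DataFrame,
    genome: MitoGenome,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Vectorised SNV calling over a counts table in the standard schema.

    Equivalent to :func:`call_sample` for base alleles (indel columns are
    ignored here; use the object path for indels). Returns a frame with
    columns sample_id, pos, ref, alt, heteroplasmy, coverage.
    """
    config = config or PipelineConfig()
    if counts.empty:
        return pd.DataFrame(
            columns=["sample_id", "pos", "ref", "alt", "heteroplasmy", "coverage"]
        )
    pos = counts["pos"].to_numpy()
    ref = np.array([genome.base_at(int(p)) for p in pos])
    totals = {b: (counts[f"{b}_f"] + counts[f"{b}_r"]).to_numpy() for b in BASES}
    cov = sum(totals.values())
    out = []
    for b in BASES:
        n = totals[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            het = np.where(cov > 0, 100.0 * n / np.maximum(cov, 1), 0.0)
        mask = (
            (ref != b)
            & (het >= config.detection_threshold_pct)
            & (cov >= config.min_coverage)
        )
        if mask.any():
            out.append(
                pd.DataFrame(
                    {
                        "sample_id": counts["sample_id"].to_numpy()[mask],
                        "pos": pos[mask],
                        "ref": ref[mask],
                        "alt": b,
                        "heteroplasmy": het[mask],
                        "coverage": cov[mask],
                    }
                )
            )
    if not out:
        return pd.DataFrame(
            columns=["sample_id", "pos", "ref", "alt", "heteroplasmy", "coverage"]
        )
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["sample_id", "pos", "alt"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# counts TSV I/O

def read_counts_tsv(path) -> list[SiteAlleleCounts]:
    """Read per-site allele counts; rows with the same (sample, pos) merge
    their indel alleles onto one site record."""
    df = pd.read_csv(path, sep="\t", dtype={"indel_allele": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    sites: dict[tuple[str, int], SiteAlleleCounts] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, int(row.pos))
        if key not in sites:
            sites[key] = SiteAlleleCounts(
                sample_id=row.sample_id,
                position=int(row.pos),
                ref_base=row.ref,
                counts={
                    b: (int(getattr(row, f"{b}_f")), int(getattr(row, f"{b}_r")))
                    for b in BASES
                },
            )
        allele = row.indel_allele
        if isinstance(allele, str) and allele not in (".", ""):
            sites[key].indel_counts[allele] = (int(row.indel_f), int(row.indel_r))
    return [sites[k] for k in sorted(sites)]


def write_counts_tsv(sites: list[SiteAlleleCounts], path) -> None:
    rows = []
    for s in sites:
        indels = list(s.indel_counts.items()) or [(".", (0, 0))]
        for allele, (f, r) in indels:
            rows.append(
                (s.sample_id, s.position, s.ref_base)
                + tuple(x for b in BASES for x in s.counts[b])
                + (allele, f, r)
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def counts_frame(sites: list[SiteAlleleCounts]) -> pd.DataFrame:
    """Base-count columns of a list of sites, in the standard schema order."""
    rows = [
        (s.sample_id, s.position, s.ref_base)
        + tuple(x for b in BASES for x in s.counts[b])
        + (".", 0, 0)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


# ---------------------------------------------------------------------------
# VCF export

def write_vcf(
    calls: list[HeteroplasmyCall],
    genome: MitoGenome,
    path,
    annotations: dict | None = None,
    origins: dict | None = None,
) -> None:
    """Write calls as VCF 4.2 (one sample column) via pysam.

    INFO carries HET (heteroplasmy percent) and DP (base coverage); when
    annotations/origin maps keyed by (pos, ref, alt) are supplied, GENE,
    EFFECT, COMPLEX, SUBCLASS and ORIGIN INFO fields are added.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.contigs.add("chrM", length=genome.genome_length)
    header.info.add("HET", 1, "Float", "Heteroplasmy percent (mutant allele frequency)")
    header.info.add("DP", 1, "Integer", "Total base coverage at site")
    if annotations is not None:
        header.info.add("GENE", 1, "String", "Primary gene")
        header.info.add("EFFECT", 1, "String", "Functional category")
        header.info.add("COMPLEX", 1, "String", "OXPHOS complex")
        header.info.add("SUBCLASS", 1, "String", "transition/transversion/indel")
    if origins is not None:
        header.info.add("ORIGIN", 1, "String", "Developmental origin")
    sample = calls[0].sample_id if calls else "SAMPLE"
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            rec = vcf.new_record(
                contig="chrM",
                start=c.position - 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["HET"] = float(c.heteroplasmy)
            rec.info["DP"] = int(c.coverage)
            if annotations is not None and c.key in annotations:
                a = annotations[c.key]
                rec.info["GENE"] = a.gene or "."
                rec.info["EFFECT"] = a.effect
                rec.info["COMPLEX"] = a.oxphos_complex
                rec.info["SUBCLASS"] = a.substitution_class
            if origins is not None and c.key in origins:
                rec.info["ORIGIN"] = origins[c.key]
            rec.samples[sample]["GT"] = (1, 1) if c.heteroplasmy >= 100 else (0, 1)
            vcf.write(rec)
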