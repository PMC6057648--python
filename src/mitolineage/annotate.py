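"""Functional annotation of called mtDNA variants.

Each variant gets a primary gene (first overlapping feature in genome order),
a functional effect, an OXPHOS complex and a substitution class:

* effect ``non_synonymous`` / ``synonymous`` — SNVs in protein genes, decided
  by codon retranslation under the vertebrate mitochondrial code (table 2).
  A variant overlapping several protein genes is non-synonymous if it is
  non-synonymous in any of them.
* effect ``RNA`` — variants whose primary feature is a tRNA or rRNA gene.
* effect ``NCR`` — variants inside the non-coding control region (including
  its ETAS/CSB sub-regions).
* effect ``intergenic`` — positions covered by no feature.

Indels in protein genes are non_synonymous and tagged frameshift (or
inframe_indel when the length change is a multiple of 3); mtDNA encodes no
complex II subunits, so COMII never appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .reference import (
    HEAVY,
    MITO_TABLE,
    MitoFeature,
    MitoGenome,
    codon_context,
    features_at,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

EFFECTS = ("non_synonymous", "synonymous", "RNA", "NCR", "intergenic")


@dataclass(frozen=True)
class VariantAnnotation:
    position: int
    ref: str
    alt: str
    gene: str | None
    feature_class: str | None
    effect: str
    aa_change: str | None
    oxphos_complex: str
    substitution_class: str
    overlapping: tuple[str, ...] = field(default_factory=tuple)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


def substitution_class(ref: str, alt: str) -> str:
    """transition | transversion | indel for a ref>alt pair."""
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if len(ref) != len(alt) or len(ref) != 1:
        return "indel"
    if (ref in PURINES) == (alt in PURINES):
        return "transition"
    return "transversion"


def complex_of(genome: MitoGenome, gene: str) -> str:
    """OXPHOS complex of a gene's product (``none`` for RNA/NCR features)."""
    return genome.feature_by_name(gene).oxphos_complex


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


def _protein_effect(
    genome: MitoGenome, feature: MitoFeature, position: int, ref: str, alt: str
) -> tuple[bool, str]:
    """(synonymous?, amino-acid change tag) of an SNV within one protein gene."""
    codon, offset, coding_ref = codon_context(genome, feature, position)
    coding_alt = alt if feature.strand == HEAVY else alt.translate(_COMPLEMENT)
    if codon[offset] != coding_ref:
        raise AssertionError("codon context inconsistent with genome base")
    mutated = codon[:offset] + coding_alt + codon[offset + 1 :]
    if feature.strand == HEAVY:
        codon_index = (position - feature.start) // 3
    else:
        codon_index = (feature.end - position) // 3
    if codon_index == 0 and codon in MITO_TABLE.start_codons:
        # initiator codon: any valid start translates to Met, so swapping one
        # start codon for another is synonymous; losing start status is not
        if mutated in MITO_TABLE.start_codons:
            return True, "M1M"
        return False, f"start_lost:{codon}>{mutated}"
    aa0, aa1 = _translate(codon), _translate(mutated)
    tag = f"{aa0}{codon_index + 1}{aa1}"
    return aa0 == aa1, tag


def annotate_variant(call, genome: MitoGenome) -> VariantAnnotation:
    """Annotate one call (or any object with position/ref/alt attributes).

    A pure function of (variant, genome): identical inputs give identical
    annotations.
    """
    pos, ref, alt = call.position, call.ref, call.alt
    sub = substitution_class(ref, alt)
    feats = features_at(genome, pos)
    overlapping = tuple(f.name for f in feats)
    if not feats:
        return VariantAnnotation(
            pos, ref, alt, None, None, "intergenic", None, "none", sub, overlapping
        )
    primary = feats[0]
    if primary.feature_class == "protein":
        if sub == "indel":
            shift = abs(len(ref) - len(alt)) % 3
            tag = "frameshift" if shift else "inframe_indel"
            return VariantAnnotation(
                pos, ref, alt, primary.name, "protein", "non_synonymous",
                tag, primary.oxphos_complex, sub, overlapping,
            )
        synonymous = True
        tag = None
        for f in feats:
            if f.feature_class != "protein":
                continue
            syn_f, tag_f = _protein_effect(genome, f, pos, ref, alt)
            if tag is None:
                tag = tag_f
            if not syn_f:
                synonymous, tag = False, tag_f
        effect = "synonymous" if synonymous else "non_synonymous"
        return VariantAnnotation(
            pos, ref, alt, primary.name, "protein", effect, tag,
            primary.oxphos_complex, sub, overlapping,
        )
    if primary.feature_class in ("tRNA", "rRNA"):
        return VariantAnnotation(
            pos, ref, alt, primary.name, primary.feature_class, "RNA",
            None, "none", sub, overlapping,
        )
    # NCR and its ETAS/CSB sub-regions
    return VariantAnnotation(
        pos, ref, alt, primary.name, primary.feature_class, "NCR",
        None, "none", sub, overlapping,
    )


def annotate_calls(
    calls, genome: MitoGenome
) -> dict[tuple[int, str, str], VariantAnnotation]:
    """Annotation map keyed by (pos, ref, alt), deduplicated across samples."""
    out: dict[tuple[int, str, str], VariantAnnotation] = {}
    for c in calls:
        if c.key not in out:
            out[c.key] = annotate_variant(c, genome)
    return out
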