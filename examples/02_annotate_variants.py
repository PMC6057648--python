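"""Annotate variants against the mouse mitochondrial feature map.

Positions carry their real NC_005089 gene assignments (the scaffold sequence
itself is synthetic, so amino-acid changes are illustrative).
"""

from dataclasses import dataclass

from mitolineage import annotate_variant, mouse_scaffold


@dataclass(frozen=True)
class Var:
    position: int
    ref: str
    alt: str


genome = mouse_scaffold()

for pos in (3366, 2080, 13029, 15800, 15450):
    ref = genome.base_at(pos)
    alt = "A" if ref != "A" else "G"
    a = annotate_variant(Var(pos, ref, alt), genome)
    print(f"mt{pos} {ref}>{alt}: gene={a.gene or 'intergenic'}"
          f" effect={a.effect} complex={a.oxphos_complex}"
          f" class={a.substitution_class}")

# a frameshift deletion inside mt-Nd5
ref2 = genome.sequence[13052:13054]
a = annotate_variant(Var(13053, ref2, ref2[0]), genome)
print(f"mt13053 del: gene={a.gene} effect={a.effect} tag={a.aa_change}")
# 3366 falls in mt-Nd1 (complex I), 2080 in the 16S rRNA (RNA effect),
# 13029 in mt-Nd5, 15800/15450 in the non-coding control region (NCR).
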