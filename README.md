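# mitolineage

Tools for studying how mitochondrial DNA (mtDNA) mutations accumulate during
mouse aging. The package calls heteroplasmic variants from per-site allele
counts, annotates them against the mouse mitochondrial genome, classifies each
variant's developmental origin — germline, early-embryonic or somatic — from
its sharing pattern across an animal's tissues and single-cell-derived clones,
and summarizes whole cohorts. A synthetic-cohort simulator generates
multi-tissue, multi-clone datasets with known ground truth, so the entire
pipeline is testable without sequencing data.

It is aimed at researchers analysing deep whole-mtDNA sequencing of bulk
tissues and clonally expanded single cells (skin-fibroblast or iPSC clones) in
wild-type and mtDNA-mutator (*Polg* proofreading-deficient) mice.

## The model

**Heteroplasmy.** At each site, the heteroplasmy of an allele is its mutant
allele frequency over total base coverage:

    het% = 100 · (alt_forward + alt_reverse) / Σ_{b∈{A,C,G,T}} (b_forward + b_reverse)

A variant is called when het ≥ 2% (inclusive) and coverage ≥ 1000×. At a
per-base error rate of 0.2% the probability that sequencing error alone
reaches the 2% threshold at 1000× is P(Binomial(1000, 0.002) ≥ 20) < 10⁻⁶,
so an error-only genome yields essentially no false calls.

**Origin classification.** Within one animal, a variant detected in ≥ 2
distinct organs is *germline* (oocyte-inherited mutations distribute to most
or all organs; a clone counts toward its source organ). A variant confined to
a single organ but present in its bulk sample and/or shared by ≥ 2 of its
clones is *early-embryonic*. A variant private to exactly one clone with no
bulk detection is *somatic*. Across a pedigree, a pup's germline variant also
seen in the mother or in ≥ 2 siblings is *recurring*, otherwise *de novo*.

**Annotation.** Effects are computed with the vertebrate mitochondrial
genetic code (transl_table 2): non-synonymous vs synonymous for protein-gene
SNVs (frameshift/in-frame tags for indels), RNA for tRNA/rRNA genes, NCR for
the non-coding control region (positions 15423–16299, with ETAS/CSB
sub-regions), plus transition/transversion/indel classes and OXPHOS complex
assignments (ND genes → complex I, CYTB → III, COX → IV, ATP6/8 → V; mtDNA
encodes no complex II subunits).

**Simulator.** Germline variants start below the detection threshold
(founder heteroplasmy 0.5–2%) and drift by neutral Wright–Fisher resampling
of 5000 segregating units per month of age, so the age-dependent rise of
detected germline mutations is an emergent property. Somatic variants are
Poisson per clone (0/clone in wild type; 59.2 and 95.4 per clone in young/old
mutator animals), and read counts are Multinomial(coverage, allele
frequencies) with uniform sequencing error.

The shipped mouse feature table carries the real NC_005089 coordinates for
all 37 genes and the control region; the bundled genome *sequence* is a
synthetic scaffold with valid coding structure (see `docs/methods.md`).

## Worked example

`examples/03_classify_origins.py` builds one animal with 7 bulk tissues and
3 skin-fibroblast clones and three archetypal sharing patterns:

```
mt2080 G>A: early_embryonic (organs=1, clones=3, mean het=90.0%)
mt3366 G>A: germline (organs=4, clones=0, mean het=25.0%)
mt9056 C>T: somatic (organs=1, clones=1, mean het=40.0%)
```

mt3366 is seen in four organs, so it must have entered through the oocyte;
mt2080 is confined to the skin lineage but shared by its bulk sample and all
clones, placing its origin in an embryonic skin progenitor; mt9056 is private
to a single clone — a late somatic event. `examples/05_simulate_and_summarize.py`
runs the full pipeline on a simulated cohort and prints the per-tissue/per-
clone mutation-count grid, the substitution spectrum and the shared-vs-unique
clone accounting; the other examples cover calling thresholds, annotation and
pedigree logic.

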