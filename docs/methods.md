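# Methods

## Scope and data model

The package analyses deep whole-mtDNA sequencing of mouse cohorts sampled at
two levels: bulk tissues (brain, heart, kidney, liver, lung, spleen, skin) and
single-cell-derived clones (clonally expanded skin fibroblasts, SF, or iPSC
lines derived from them), which act as proxies for single-cell genotyping.
Inputs are per-site stranded allele-count tables (TSV) plus a sample manifest;
outputs are calls (TSV/VCF 4.2 via pysam), per-variant annotations, per-
(animal, variant) origin labels and cohort summary tables. Coordinates are
1-based inclusive throughout; VCF export converts as required.

## Reference model

The mouse mitochondrial genome is represented as a linear 16,299-bp sequence
with a feature map of the 37 genes, the non-coding control region
(NCR, 15423–16299) and its ETAS/CSB sub-regions. Because the NCR abuts the
end of the sequence, no origin-wrapping features are supported. The feature
coordinates are transcribed from the public NC_005089 annotation; ETAS/CSB
bounds are approximate literature intervals (only the NCR bounds are used by
downstream category logic). The packaged genome *sequence* is a synthetic
scaffold: network-independent, generated in code with a start codon, sense
codons and a (possibly incomplete) stop for every protein gene. Where genes
overlap, the later gene in genome order wins, so an upstream gene may carry
internal stops inside the overlap — harmless for codon-context queries, which
never validate open reading frames. Analyses that depend on real codon
content at real positions therefore require a user-supplied FASTA
(`load_reference`); gene identity, OXPHOS complex and NCR lookups are faithful
to the real annotation either way.

Genes whose genomic length is not divisible by 3 (mt-Co3, mt-Nd4, mt-Cytb)
are flagged as incomplete-stop genes; their trailing partial codon is padded
with A, mirroring polyadenylation of the mRNA.

## Variant calling

Heteroplasmy is the mutant allele frequency over total base coverage,
`100·(alt_f+alt_r)/Σ_b(b_f+b_r)`; indel alleles use the same base-coverage
denominator. A call requires heteroplasmy ≥ `detection_threshold_pct`
(default 2.0, inclusive) and coverage ≥ `min_coverage` (default 1000). The
2% default is conservative — heteroplasmies above ~1.6% are generally of
biological rather than technical origin, and that looser threshold can be
configured. The threshold applies to combined forward+reverse counts; no
per-strand filter is applied, because the defining formula uses combined
counts only. Homoplasmy is represented as 100% heteroplasmy. Multi-allelic
sites produce one call per alternate allele. Instead of re-implementing a
proprietary read-level error-correction step, the caller's false-positive
behaviour is certified analytically: with a per-base error rate of 0.2% and
1000× coverage, P(an erroneous allele reaches 2%) = P(Binomial(1000, 0.002) ≥
20) < 10⁻⁶ per site, and an error-only genome-wide sample yields zero calls
in the seeded test.

A vectorised path (`call_frame`) reproduces the object-path caller for SNVs
over whole-genome count tables; equivalence is asserted in the tests.

## Annotation

Effect categories: `non_synonymous` / `synonymous` for protein-gene SNVs,
`RNA` for tRNA/rRNA genes, `NCR` for the control region, `intergenic`
otherwise. The primary feature at a position is the first overlapping feature
in genome order (deterministic and stable for the mtDNA ATP8/ATP6-type
overlaps); effect follows the primary feature's class, and a protein-gene SNV
is non-synonymous if it is non-synonymous in *any* overlapping protein gene
(conservative for functional tallies). Translation uses NCBI transl_table 2.
Initiator codons: any valid start decodes to Met, so start→start substitutions
are synonymous and loss of start status is non-synonymous; stop-loss and
stop-gain are non-synonymous. Protein-gene indels are non-synonymous with a
`frameshift` tag (`inframe_indel` when the length change is a multiple of 3);
RNA-gene indels keep effect `RNA` with substitution class `indel`.
Transitions are purine↔purine / pyrimidine↔pyrimidine; everything else
length-preserving is a transversion.

`is_functional` pools non-synonymous substitutions, protein/RNA-gene indels
and RNA-gene variants; synonymous, NCR and intergenic variants are excluded
(NCR variants get their own summary).

## Origin classification

For each (animal, variant), with detection = a passing call in a sample (no
rescue of sub-threshold signal elsewhere):

* **germline** — detected in ≥ 2 distinct organs. "Multiple organs" is read
  as ≥ 2; clones attribute to their source organ, but a variant seen only in
  clones of one organ can never be germline.
* **somatic** — detected in exactly one clone and no bulk sample.
* **early_embryonic** — everything else (single-organ confinement with bulk
  detection and/or ≥ 2 clones). A variant confined to one bulk organ of any
  kind is early-embryonic; the label is an interpretation for organs beyond
  the skin/spleen archetypes.

The three labels are exhaustive and mutually exclusive, verified against a
brute-force rule table over all 2¹⁰ presence patterns of a 7-tissue +
3-clone animal. iPSC clones are treated identically to SF clones; a variant
present in ≥ 2 SF clones but lost in iPSCs (reprogramming bottleneck) is
still early-embryonic.

The shared/unique clone partition counts variant×clone occurrences (one per
clone carrying the variant, matching per-clone mean accounting): an
occurrence is unique exactly when its variant is detected in no other sample
of the animal, which makes unique occurrences coincide with somatic calls —
an identity asserted in the tests. Per-animal heteroplasmy of a variant is
summarized as the mean over detecting samples.

Pedigree logic: a pup-carried variant is `recurring` if detected in any
maternal sample or in ≥ 2 siblings, else `de_novo`.

## Cohort summaries

Count grids report mean ± SEM per denominator unit: germline per bulk tissue
sample, early-embryonic per bulk tissue or single SF clone, somatic per clone
(SF or iPSC). The early-embryonic denominator mixes tissues and SF clones by
design (matching the reporting convention of per-tissue-or-clone means).
SEM = sd(n−1)/√n, undefined for n = 1. Heteroplasmy summaries are restricted
to functional variants and pool per-animal variant means. Contrasts use the
classical pooled-variance Student's t (df = n₁+n₂−2, two-sided, α = 0.05;
Welch optional); zero pooled variance with equal means yields t = 0, p = 1.
Printed percentages round half away from zero. No multiple-testing correction
is applied.

## Synthetic cohorts

The generator's defaults are the study conditions: group sizes 5/8/3/3
(wt young/old, mutator young/old) at ages 8/26/2/9 months, 7 bulk tissues,
10 SF clones per animal, 5000× coverage, 0.2% per-base error, 80% transition
spectrum, somatic rates 0 (wt), 59.2 (young mutator) and 95.4 (old mutator)
per clone with heteroplasmy uniform on [15%, 100%] (within-clone expansion is
not modelled mechanistically; the 15% floor mirrors the functional-stratum
convention). Germline and embryonic rates per animal (wt 1.5/0.8, mutator
5/20) are realistic scales chosen once for the respective genotypes, since
published per-tissue means depend on detection and do not fix the seeding
rates.

Heteroplasmy dynamics are neutral Wright–Fisher: per sample, the founder
fraction is resampled Binomial(N, h)/N for `gens_per_month · age` rounds with
N = `n_seg`; 0 and 1 are absorbing; selection is out of scope. Calibration
(done once, via a Monte-Carlo probe of P(h ≥ 2%)): `n_seg = 5000`,
`gens_per_month = 1`, germline founders uniform on [0.5%, 2%]. Founders sit
below the detection threshold so young-animal non-detection and the
age-dependent rise of detected germline counts are emergent; the absorption
timescale (≈ n_seg rounds) far exceeds a mouse lifespan, keeping detection in
its rising phase at all study ages.

Variant keys are drawn distinct within an animal (independent mutational
events recurring at the same base with the same substitution are vanishingly
rare on 16.3 kb, and coincidental collisions would corrupt sharing-based
truth labels). The generator emits SNVs only — the modelled spectrum is a
transition/transversion mixture — while the caller and annotator additionally
handle indels supplied in counts tables. Read counts are
Multinomial(coverage, p) after uniform error mixing
(p′ = p(1−e) + (1−p)e/3), with forward/reverse split Binomial(n, ½); counts
always sum to the configured coverage at every site.

What the simulator does *not* emulate: read-level artefacts (PCR bias,
strand-specific error, alignment error), mtDNA deletions/rearrangements,
selection on heteroplasmy, coverage variation along the genome, and indel
generation. Passing recovery tests therefore certify the calling/
classification logic under the stated statistical model, not robustness to
those real-data failure modes.

## Numerical and scale choices

Problem sizes in the test suite and the acceptance script are chosen for
desk-scale runs: the end-to-end recovery experiment uses one mutator animal
(7 tissues + 10 clones, ≈ 600 variants, full 16,299-site count tables at
5000×) with error rate 0 and drift off, where ≥ 99% origin-label recovery is
the designed behaviour; spectra and rates are checked within 3σ binomial/
Poisson bands; unit tests use a 900-bp toy genome with one feature of each
class. All randomness flows through explicit seeds; cohort simulation derives
per-animal substreams from (seed, animal counter) so edits to one group do
not shift another group's draws.

## Known limitations

* The bundled scaffold sequence is synthetic; amino-acid-level results at
  real mouse positions require a user-supplied reference FASTA.
* Origin classification is rule-based, not probabilistic; borderline sharing
  patterns (e.g. one clone + its organ's bulk) follow the fixed rules above.
* An intergenic category is reported for completeness but maps to no
  functional class.
* Heteroplasmy aggregation across samples uses unweighted means over
  detecting samples.
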