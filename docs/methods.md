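# Methods

## Data model

The pipeline operates on a cells × variants matrix of ref/alt read counts
from a targeted single-cell amplicon panel. Each variant site doubles as an
amplicon: total depth `ref + alt` per (cell, site) is the per-amplicon read
count used for CNV. Sites carry a role: `somatic_marker` (clone-defining
mutation), `germline_marker` (donor/recipient polymorphism) or
`amplicon_only` (depth-only CNV target, simulated and treated as
reference-homozygous).

## Genotype calling

Per (cell, variant), with depth d and VAF = alt/d:

* d < `min_depth` (default 10) → NOCALL;
* VAF·100 < 5 → WT; 35 ≤ VAF·100 < 95 → HET; ≥ 95 → HOM; the 5–35% band is
  ambiguous → NOCALL. Intervals are half-open (≥ lower, < upper).
* Genotype quality is the phred-scaled gap between the best and second-best
  binomial likelihood of the alt count at expected alt fractions ε, 0.5,
  1−ε with ε = 0.01; calls with GQ < `min_gq` (default 30) are demoted to
  NOCALL. GQ is monotone in depth; a consequence of the 10/30 defaults is
  that an all-reference cell at depth exactly 10 has GQ ≈ 29.7 and is
  NOCALL — calls effectively need depth ≥ 11 for WT.
* VAF at depth 0 is undefined → NOCALL.

Variant-level QC masks variants genotyped (non-NOCALL) in fewer than 50% of
cells; the boundary is inclusive.

## Clones and tracking

A clone is the set of cells sharing an identical called-genotype vector over
the chosen marker variants. Cells with any NOCALL among the markers are
excluded from the denominator and reported separately, so percentages are
over reliably genotyped cells and reproducible. Clone keys (e.g. `HET/WT`)
are canonical; human labels are user-supplied aliases, never inferred.
Across timepoints clones are matched by genotype vector; absent clones get
fraction 0 and clones absent at the first timepoint are flagged emergent.
The long-format (timepoint, clone_key, fraction) table feeds fish-plot
tools directly.

Cell clustering uses Hamming distance over called states with
pairwise-complete normalization (NOCALL entries excluded pair by pair;
cell pairs with no shared call get distance 1), average linkage, ties
resolved by scipy's deterministic ordering. The 2-D embedding encodes
states numerically (WT 0, HET 1, HOM 2; NOCALL imputed to the variant
mean), reduces to 5 principal components, then UMAP with a fixed
`random_state`. The embedding is a reporting aid; no quantitative
conclusions are drawn from it.

## ADO model and chimerism correction

Dropout is modelled per allele copy: each physical copy at a site is lost
independently with probability a. A heterozygous cell keeps both copies
with (1−a)², appears homozygous for the survivor with 2a(1−a) (a(1−a) per
direction), and loses both with a², emitting only stray error reads (the
caller sees near-zero depth → NOCALL). Note the distinction between this
per-copy parameter and the *observed* per-SNV ADO rate ≈ 2a(1−a): an
observed 4–5% per-SNV rate corresponds to per-copy a ≈ 0.022–0.026.

Directional rates are estimated on an anchor population whose true genotype
at the measured variant is HET, identified *without* that variant — in the
dual-marker setting, cells called HET at the other marker. Wilson 95%
intervals quantify the rate uncertainty.

Origin classification at the marker pair (donor het/het, recipient
hom-alt/hom-alt): het/het → donor, hom/hom → recipient, wt/wt →
`ado_ref_ref` (both alt alleles dropped; no real cell has this genotype),
any other fully-called pattern → mixed zygosity, any NOCALL → nocall.
Categories partition the cell set.

Two corrections for ADO-driven false recipients are reported side by side:

* **parametric product**: E[false] = N_donor·a₁·a₂ with a₁, a₂ the
  het→hom-alt rates (the direction that creates false recipients);
* **empirical symmetric**: E[false] = the wt/wt count, the mirror event
  under symmetric per-allele dropout.

`corrected = max(0, observed − E[false])`, clamped at zero with a flag
(counts cannot be negative). Fractions use the cells genotyped at both
markers as denominator; a seeded parametric bootstrap over the binomial
category and rate counts (default 1 000 replicates) gives the 95% CI.
The total (non-directional) ADO rate can be substituted deliberately for a
more conservative correction.

MRD is the fraction of cells carrying the somatic mutation (HET or HOM by
default) among cells genotyped at that variant, reported as a proportion
and as a percentage rounded to two decimals.

## CNV / relative ploidy

Depth normalization is two-factor: each cell's amplicon counts are divided
by the cell total (library size), then each amplicon by its median over
reference cells (capture efficiency); amplicons with zero reference median
are masked. Ploidy of group g at an amplicon is
2·mean(g)/mean(reference), so the reference group (donor cells, assumed
diploid) is identically 2. Gene ploidy is the unweighted mean over the
gene's amplicons; a loss is flagged below 1.5 (the 1-vs-2 midpoint). Only
depth-based copy loss is reported; allele-ratio LOH is out of scope.

The library-size factor is compositional: if a clone loses k of m amplicon
copies, every other amplicon inflates by ~2m/(2m−k). With panels of dozens
to hundreds of amplicons and focal lesions the distortion is 1–5%;
simulation tests therefore use panels of ~25–70 amplicons, matching
realistic targeted panels where chromosome-7 targets are a small minority.

## Synthetic-data generator

The generator emulates Tapestri-style data: cells drawn i.i.d. from clone
fractions; per-variant allele copies set by clone genotype and an optional
copy-number map (copy number scales both the allele copies and expected
depth by cn/2; HET with fewer than two copies is rejected as
contradictory); per-copy dropout as above; total depth negative-binomial;
read allele identities binomial over the surviving copies with a per-read
miscall probability. Everything is driven by one seeded generator, so
identical configs give bit-identical outputs.

Defaults: mean depth 60 reads/cell/amplicon (sequencing-run depth figures
of "60–80X" do not pin down the per-cell per-amplicon value, so depth is a
free parameter; 60 with negative-binomial dispersion 10, CV ≈ 0.35, is a
realistic middle ground), per-read error 0.002 (consensus amplicon reads),
dropout 0 unless specified.

Not emulated: doublets and barcode collisions, read-level artifacts
(FASTQ/alignment), per-amplicon GC or primer efficiency biases (the
normalization removes a static efficiency factor, which is exercised in
tests by scaling an amplicon's counts), and cell-to-cell amplification
covariance. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real instruments.

## Known limitations and open choices

* **Clone tables under dropout.** Exact-genotype-vector clone assignment is
  biased by ADO: a heterozygous marker is miscalled homozygous in ~a(1−a)
  of cells per direction, which moves cells *between* clone keys (e.g. a
  het/het cell into `HOM/HET`), not merely into NOCALL. At an observed
  per-SNV ADO of 4–5% this depresses a 88% het clone's apparent fraction by
  several percentage points and inflates minor clones — a systematic bias,
  not sampling noise, so no multinomial error band covers it. One recovery
  test asserts clone fractions under per-copy dropout 0.045 within
  3σ multinomial of the nominal mixture and is expected to fail; it is kept
  as an honest record of this bias. Recovery is exact (within multinomial
  error) at zero dropout, and the flip rates themselves match the closed
  form. For the same reason, published clone percentages are treated as
  post-dropout observations: the acceptance script simulates the clone-table
  mixture at the observed fractions without re-applying marker dropout.
* **GQ definition.** Platform genotype quality is vendor-defined; the
  binomial-likelihood phred gap used here is standard, reproducible, and
  monotone in depth, but not numerically identical to any vendor's.
* **Parametric vs empirical correction.** The parametric product uses the
  observed donor-category count (slightly below the true donor count, which
  partially offsets the anchor's slight rate overestimate); the empirical
  wt/wt count is unbiased under symmetric dropout but has higher variance
  at small counts. Both are printed in reports.
* **Whole-sample extrapolation.** All fractions are over genotyped cells;
  extrapolation to the full marrow is left to the user, labelled as such.
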