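# scamplicon

Single-cell targeted-amplicon DNA analysis for transplant and leukemia
monitoring: per-cell genotype calling, genotype-defined clone tracking,
allelic-dropout (ADO) corrected chimerism and minimal-residual-disease (MRD)
quantification, and read-depth CNV/ploidy estimation — with a synthetic-data
generator that provides ground truth for every stage.

## The problem

Droplet single-cell DNA platforms (Tapestri-style) genotype thousands of
cells at a targeted amplicon panel, yielding per-cell ref/alt read counts at
each variant site. Downstream questions in the post-transplant myeloid
setting are:

* **Clonal structure** — which genotype vectors (e.g. *PTPN11*<sup>het</sup>/
  *SETBP1*<sup>het</sup>) define clones, and how do their fractions change
  across timepoints?
* **Chimerism** — which cells are donor vs recipient? With a germline marker
  pair V1/V2 heterozygous in the donor and homozygous in the recipient, a
  cell called het/het is donor and hom/hom is recipient. ADO corrupts this:
  a donor cell that loses the ref allele at a marker appears homozygous
  there, with probability *a* ≈ 4–5% per SNV.
* **MRD** — how many cells still carry the leukemia-defining somatic
  mutation (sensitivity down to a few cells in thousands, ~0.05%)?
* **CNV** — does a clone carry a depth-visible lesion such as monosomy 7,
  relative to donor cells assumed diploid?

The analytical core is the dual-marker ADO correction. Requiring the
recipient genotype at **two** independent markers multiplies the per-marker
dropout probabilities: the false-recipient rate per donor cell falls from
*a* to *a*₁·*a*₂ ≈ *a*², a ≥ 20-fold gain for *a* ≤ 5%. The residual leak is
then removed explicitly, either parametrically,

    E[false recipients] = N_donor · a₁ · a₂,
    corrected = max(0, observed_hom/hom − E[false recipients]),

with the directional (het → hom-alt) rates *a*ᵢ measured on an anchor
population known to be heterozygous, or empirically: alt-allele dropout at
both markers is the mirror event of the ref-allele dropout that creates
false recipients, and it produces wt/wt cells — a genotype no real donor or
recipient cell has — so the observed wt/wt count estimates the
false-recipient count directly.

Genotype calls follow amplicon-platform convention: minimum depth 10,
minimum phred genotype quality 30 (binomial likelihoods at expected alt
fractions 0.01 / 0.5 / 0.99), VAF bands <5% → WT, 35–95% → HET, ≥95% → HOM,
5–35% → no call, and variants genotyped in fewer than 50% of cells are
masked.

## Worked example

A post-transplant marrow of 4 000 cells, 0.5% residual recipient (tumour)
cells, per-allele dropout 0.045 at both *FLT3* germline markers:

```python
import scamplicon as sc

V1 = sc.VariantSite("chr13:28592546:T/C", "FLT3", "germline_marker")
V2 = sc.VariantSite("chr13:28602226:AAGAG/A", "FLT3", "germline_marker")
KRAS = sc.VariantSite("chr12:25398281:C/T", "KRAS", "somatic_marker")

clones = [
    sc.CloneSpec("donor", {V1.id: "HET", V2.id: "HET", KRAS.id: "WT"},
                 0.995, origin="donor"),
    sc.CloneSpec("residual_tumor",
                 {V1.id: "HOM", V2.id: "HOM", KRAS.id: "HET"}, 0.005),
]
config = sc.SimConfig(sites=[V1, V2, KRAS], clones=clones, n_cells=4000,
                      ado={V1.id: 0.045, V2.id: 0.045, KRAS.id: 0.045},
                      seed=42)
counts, truth = sc.simulate_dataset(config)

genotypes = sc.apply_variant_qc(sc.call_genotypes(counts))
est = sc.ChimerismEstimator(pair=sc.MarkerPair(V1.id, V2.id),
                            random_state=0).fit(genotypes)
r = est.result_
print(r.counts, r.expected_false_recipient, r.corrected_recipient_count)

mrd = sc.mrd_fraction(genotypes, KRAS.id)
print(mrd.carriers, mrd.genotyped, mrd.percent)
```

Output:

```
category counts       : {'donor': 3179, 'recipient': 32, 'ado_ref_ref': 6, 'mixed_zygosity': 626, 'nocall': 157}
per-marker ADO (het->hom-alt): 0.0399, 0.0450
expected false recipients    : 5.71
corrected recipient count    : 26.3  (0.68% of 3843 genotyped cells)
95% bootstrap CI             : 0.41%-0.97%
true recipient cells         : 23
MRD: 21/3990 cells carry the KRAS mutation -> 0.53%
```

Of the 32 cells with the recipient hom/hom genotype, ~5.7 are predicted to
be donor cells with combined dropout; the corrected count 26.3 is close to
the 23 truly recipient cells the generator drew, while the raw count
overstates them by ~40%. The MRD readout (0.53%) matches the simulated
tumour fraction.

The same analyses run from the shell:

```bash
scamplicon simulate  --config sim.yaml --out-prefix ds
scamplicon genotype  --counts ds.counts.tsv --manifest ds.manifest.tsv --out calls.tsv
scamplicon clones    --counts ds.counts.tsv --manifest ds.manifest.tsv \
                     --markers chr12:25398281:C/T --out clones.tsv
scamplicon chimerism --counts ds.counts.tsv --manifest ds.manifest.tsv \
                     --v1 chr13:28592546:T/C --v2 chr13:28602226:AAGAG/A \
                     --out chimerism.tsv
scamplicon run       --config run.yaml        # full pipeline + report bundle
```

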