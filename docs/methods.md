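# Methods

## Problem and model

`cfemerge` monitors the emergence of TP53 resistance mutations in plasma
cell-free DNA (cfDNA) from patients treated with an HDM2 antagonist. In
MDM2-amplified, TP53-wild-type tumours (the de-differentiated liposarcoma
setting), reactivating p53 creates selective pressure for TP53-mutant
subclones; their mutations become visible in cfDNA as rising variant
allele frequencies (VAFs). The analysis has four stages.

**Strand-bias QC.** For each variant, ALT_RATIO is the fraction of
alt-supporting reads on the less-abundant read direction:
`min(f, r) / (f + r)`, with `f`/`r` the alt reads on the forward/reverse
strand. 0.5 means balanced (no bias); values near 0 are typical of
sequencing artefacts. ALT_RATIO refers to read orientation of the
alt-supporting reads only, independent of gene strand (TP53 is on the
minus strand, but read orientation is a property of the library, not the
gene). The default advisory cutoff is 0.25; the flag never removes a
variant by itself — the hard filter is the VAF threshold, which is what
the calibration justifies.

**VAF-threshold calibration.** Two empirical anchors: (i) a healthy-donor
plasma panel, where every call is noise — these calls are strand-biased
and stay below ~0.5% VAF; (ii) matched tumour/plasma pairs, where a
cfDNA variant is *concordant* if the identical allele
(contig, pos, ref, alt) is present in the matched tumour at any VAF.
Splitting cfDNA variants at a candidate threshold and tabulating
concordance above/below motivates the conservative 1% calling threshold:
above-threshold variants are overwhelmingly tumour-confirmed, while
below-threshold ones are mostly noise. "Above" is strict (`VAF > t`);
a variant exactly at the threshold falls below. Concordance requires
exact allele identity, not just position, so independent variants
altering the same residue stay distinct.

**Filtering, detection and burden.** A variant passes when it is coding
and non-silent, is not the common germline P72R polymorphism, and has
VAF strictly above the threshold. A plasma sample is *detected* when at
least one variant passes. Per patient and week, the mutation (allele)
burden is the sum of passing-variant VAFs, expressed in percent. Coding
indels pass the filter but are excluded from the substitution spectrum.

**Statistics.**

* *Posterior predictive emergence test.* Let P be the probability that a
  TP53 mutation is called from one normal cfDNA sample. With a uniform
  Beta(1,1) prior and zero detections among nine normal samples, the
  posterior is Beta(1,10). The predictive probability of k detections in
  n future samples is beta-binomial,
  `C(n,k) B(a+k, b+n−k) / B(a,b)`, evaluated in log space via `betaln`.
  With this posterior the probability of the baseline outcome (0 of 14
  samples) is 10/24 ≈ 41.7%, while 12 of 25 on-treatment samples has
  predictive probability ≈ 0.27% (exact k) or ≈ 0.62% (upper tail
  P(X ≥ 12)) — about a 150-fold difference either way. Because "k or
  more" versus "exactly k" is a genuine modelling choice, both variants
  are always reported, as are both fold changes.
* *Transversion-spectrum test.* Chemotherapy-exposed haematopoietic
  clones show transversion fractions near 50%; tumour-derived TP53
  mutations here do not. The test is the exact binomial lower tail
  P(X ≤ k | n, p = 1/2), computed as the rational Σ C(n,i) / 2ⁿ in
  big-integer arithmetic and converted to float at the end, so printed
  values (e.g. 3 of 15 → 576/32768 = 0.017578125) are exact. For p ≠ 1/2
  the tail is accumulated from exact `Fraction` powers.
* *Burden–tumour-size link.* Ordinary least squares of the percent
  change in tumour size on CT imaging against log10 of the burden (in
  percent), restricted to detected samples (log of zero burden is
  undefined and no imputation rule is assumed; an optional pseudo-burden
  switch exists but is off by default). The fit reports the slope t-test
  and the overall F-test — identical for a single predictor
  (F = t²) — and the convention for "significant" is that both are.
  A Pearson test on the same pairs is reported alongside; its r² equals
  the regression R².
* *Pearson test.* r with the t statistic `r sqrt((n−2)/(1−r²))` on n−2
  degrees of freedom and an asymptotic 95% CI from the Fisher
  Z-transform, `tanh(atanh r ± 1.96/sqrt(n−3))`.
* *Two-sample comparisons* (pharmacokinetics, tumour volume) use a
  two-sided Welch t-test by default (the equal-variance variant is a
  flag), reporting group means ± s.d.
* *MDM2 copy number.* ΔCt = mean(target Ct) − mean(reference Ct) over
  triplicates; ΔΔCt subtracts a normal diploid calibrator's ΔCt; copy
  number = 2·2^(−ΔΔCt); *amplified* means strictly more than 5 copies.

## Synthetic cohort generator

No public cohort accompanies this analysis, so a seeded generator
produces data with the statistical structure the pipeline assumes. Its
defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 20 | expansion-cohort scale |
| `sampling_weeks` | 0, 6, 12, 18, 24 | ~6-weekly imaging/plasma cadence |
| `mean_depth` | 8000 | mean exonic coverage of the cfDNA assay |
| `artefact_rate` | 8 per sample | several low-VAF calls per normal sample |
| `artefact_vaf_scale` / truncation | 0.1% / 1% | artefact VAFs concentrate below 0.5% |
| `artefact_strand_skew` | 0.9 | artefacts are strongly strand-biased |
| `clone_prob` | 0.25 | ~5 of 21 patients develop resistant clones |
| clones per affected patient | 1 + Poisson(3) | ~26 mutations across 5 patients |
| `transversion_prob` | 0.2 | observed transversion fraction |
| `emergence_weeks` | {6, 12, 18} | mutations appear from week 6 onward |
| carrying VAF / growth rate | U(0.05, 0.5) / U(0.2, 0.6) wk⁻¹ | heterozygous clones cap at 50% VAF; growth rates are free parameters (none are published), so recovery of *configured* values is what tests assert |
| `ct_link` (a, b, σ) | (10, 30, 10) | tumour-size change = a + b·log10(burden%) + ε |
| `baseline_ct_noise` | σ = 10 | size change for patients with zero burden |
| `germline_p72r_prob` | 0.5 | common polymorphism; exercises the germline filter |

Clone VAFs follow a logistic curve from `init_vaf` (0.5%) at the
emergence week toward the carrying VAF; an optional decay-after-peak
switch reproduces the occasional non-monotone trajectory. Baseline
(week 0) samples never carry true clones. Read counts are binomial at a
Poisson-distributed per-site depth — balanced strands for true variants,
skewed for artefacts. The tumour-size link is applied only to samples
with positive true burden; others get baseline noise, mirroring the
regression's restriction to detected samples. Mutation identities come
from a packaged table of DNA-binding-domain missense hotspots (including
two independent Y220 variants); coordinates live in a self-consistent
toy space, not hg19. One `numpy` Generator is seeded per call and
sub-draws occur in a fixed documented order, so identical seed + config
give bit-identical output.

What the generator does **not** model: read-level effects (no FASTQ/BAM),
FFPE deamination damage, PCR duplicates, clonal haematopoiesis
interference, overlapping clones at one locus, or inter-site coverage
structure. Passing tests therefore demonstrate that the procedures are
correct and well calibrated under the stated generative assumptions, not
that the thresholds are optimal for any particular real assay.

## Numerical and design choices

* Beta-binomial probabilities via `gammaln`/`betaln`; normalisation
  holds to < 1e−12 for n ≤ 200.
* Exact rational arithmetic for the p = 1/2 binomial tail (see above).
* Tie-breaks are strict everywhere: `VAF > t` for calling, ALT_RATIO
  `< cutoff` for the advisory flag, copy number `> 5` for amplification.
* VAF uses total depth at the site as denominator (a ref+alt toggle
  exists; with a single-gene substitution panel the two coincide except
  at multi-allelic sites, which are split into one call per alt allele).
* Spectrum deduplication counts unique
  (patient, contig, pos, ref, alt) events by default — a mutation seen at
  several timepoints is one event; a cohort-wide mode (unique allele
  regardless of patient) is a flag, since either convention is defensible
  when several patients share a hotspot.
* Degenerate fits are defined rather than errors where a meaningful
  value exists: constant response → slope 0, R² 0, p 1; perfect fit →
  t = ±∞, p = 0; constant input to the Pearson test is an error.
* The healthy-donor posterior is parameterised by sample count; the
  source data are ambiguous between nine and ten donors (the posterior
  arithmetic uses nine), so nothing is hard-coded.

## Problem sizes used by the test suite

Type-I calibration uses 5000 null simulations per test (n = 20 per
group); parameter recovery uses 100 cohorts of 200 patients; the noise
ceiling uses 1000 ten-sample panels; the matched-pair checks use 50
seeds of 30 pairs. These sizes give Monte-Carlo error comfortably inside
the asserted bounds while keeping the default suite fast.

## Known limitations

* Effects and protein changes are consumed annotations; no annotation
  engine or caller is included, and no alignment/pileup is performed.
* No multiple-testing correction machinery (the analysis applies none)
  and no survival analysis.
* The treatment-arm predictive probability is reported in both exact-k
  and tail form rather than as a single number, and the fold change
  follows from the package's own exact values.
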