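# Methods

`deadstab` re-implements, as one tested toolkit, the family of analyses used
to characterize a loss of mRNA deadenylation in pancreatic β cells: an
exon/intron split analysis of mRNA stability built on a negative-binomial
differential-expression engine, Ca²⁺-trace β-cell connectivity, actinomycin-D
decay kinetics, ∆∆CT/RIP quantification, bulk poly(A) densitometry, and
gene-set enrichment. This note records the models, the defaults and why they
were chosen, and what the synthetic-data generators do and do not emulate.

## Differential expression engine (`deadstab.de`)

Counts for gene *g* in sample *s* are modelled as negative binomial with mean
μ_gs and dispersion φ_g, parameterized as var = μ + φμ² (φ = 0 is the
Poisson limit; √φ is the biological coefficient of variation).

* **Filtering.** A gene is kept when its CPM (computed on raw library sizes)
  reaches `cpm_min` (default 1) in at least `min_samples` (default 3)
  samples. Filtering precedes normalization, matching the wording of the
  rule it implements.
* **Normalization.** Weighted trimmed mean of M-values (TMM): gene-wise log
  ratios against a reference sample are double-trimmed (30% of the M
  distribution and 5% of the A distribution, each side) and averaged with
  inverse asymptotic-variance weights; factors are rescaled to geometric
  mean 1. The reference is the sample whose upper-quartile CPM is closest
  to the across-sample mean. TMM assumes most genes are unchanged and that
  differential expression is not extremely one-sided; under a strongly
  asymmetric mixture (e.g. 10–20% of genes all upregulated at high φ) the
  trimmed mean retains a composition bias of ~0.1–0.2 log2 that any
  trimmed-mean normalization shares. The stability stage is built so this
  bias cancels (below).
* **Dispersion.** Per gene, a pooled within-group method-of-moments
  estimate (s² − x̄)/x̄² on counts scaled to a common library size. A
  mean–dispersion trend is fit as binned means of the *un-floored*
  estimates versus log mean (flooring first would bias the trend up; a
  median-based trend would bias it down, since the sampling distribution of
  the moment estimator is right-skewed). Each gene is shrunk toward the
  trend with prior weight `prior_df` (default 20) against its residual df,
  then floored at 0.
* **Test.** Exact-style conditional test on group sums. Counts are scaled
  to pseudo-counts at the geometric-mean effective library size; group sums
  of n i.i.d. NB(μ, φ) draws are NB(nμ, φ/n); conditioning on the total S
  gives a distribution over splits whose two tails at the observed split
  are computed exactly, the smaller doubled and capped at 1. At φ = 0 the
  conditional distribution is exactly Binomial(S, n₁/(n₁+n₂)). Pseudo-count
  group sums are rounded only for the integer conditional support; fold
  changes use the continuous values with a prior count of 0.125 per
  library, so log fold changes are invariant to rescaling all counts.
* **Multiplicity.** Benjamini–Hochberg step-up (`bh_fdr`), NaN-rejecting.

The engine is an exact-test/two-group specialization — no GLMs, covariates
or multi-factor designs — because every comparison it serves is
control-vs-knockout.

## Stability: the ∆exon–∆intron statistic (`deadstab.stability`)

Exonic reads track steady-state mRNA; intronic reads track transcription
(pre-mRNA). The per-gene statistic

    delta = exon_log2FC − intron_log2FC

estimates the log2 change in mRNA half-life between genotypes: a
transcription change moves both terms equally and cancels; a stability
change moves the exonic term only.

**Shared normalization.** A sample's exonic and intronic reads come from
one sequencing library, so both feature classes are normalized with shared
per-sample effective library sizes (TMM on the stacked exon+intron matrix).
Any residual composition error in the normalization then enters both log
fold changes identically and cancels in delta — which restores the
statistic's defining invariance to per-sample scaling.

**Significance.** The hypothesis "exon and intron fold changes are equal"
is the interaction term of an NB log-linear model with per-sample
intercepts, a feature-class effect and a feature-class × genotype
interaction. Profiling out the per-sample intercepts by conditioning on
each sample's exon+intron total reduces the model exactly to binomial
logistic regression of the exon count against genotype: the log odds
equals the within-sample exon/intron log ratio, so the group coefficient is
delta (in ln units) and the per-sample intercepts absorb library size *and*
any sample-level fluctuation shared by the two read classes of a gene.
The test is a Wald z on the aggregated (Haldane-corrected) binomial,
BH-corrected across genes. This pairing matters: treating exon and intron
counts as independent NB observations would add twice the biological
dispersion (4φ/n on the ln scale) to the variance of delta, which at φ =
0.1 and n = 3 per group would leave a detectable-effect floor of ~1.5 log2
and make moderate stability changes untestable. An optional
`ratio_dispersion` term adds extra-binomial variance for protocols where
the two read classes are not strictly paired.

**Classification.** With FDR threshold α (default 0.05):
*stabilized* = delta > 0 and interaction FDR < α; *stabilized_up*
additionally requires exonic upregulation (exon FDR < α, logFC > 0);
significant negative delta = *destabilized*; exon-DE without a stability
call = *transcription_driven*; otherwise *unchanged*. Genes lacking intron
signal after filtering are excluded rather than classified — their delta is
undefined. `OverlapSummary` reports the stabilized/upregulated overlap
(the fraction-of-stabilized-also-up readout), and
`overlap_with_reference` intersects target lists with external
(case-normalized) gene lists such as published diabetic-islet
upregulation sets.

## Ca²⁺ connectivity (`deadstab.calcium`)

Traces are smoothed by a centered rolling average (default window 5
samples; the window must be odd so the center is unambiguous) and
normalized per cell to the minimum fluorescence within the basal 3 mM
glucose epoch (F/F_min), making them invariant to per-cell gain. All cell
pairs are scored by Pearson R, excluding the autocorrelation diagonal.

Significance per pair uses a circular time-shift permutation null: one
trace of the pair is rotated by a shift drawn uniformly from
[`min_shift`, T − `min_shift`] (default minimum 10 samples), which
preserves each trace's autocorrelation while destroying the pairing —
the appropriate null for dependent time series. All circular-lag
correlations come from one FFT cross-correlation per pair, so the observed
R is the lag-0 entry of the same transform that supplies the null. The
empirical two-sided p is (1 + #{|R_null| ≥ |R_obs|})/(n_perm + 1), BH
across pairs at α (default 0.05); `pct_connected` per cell is 100 ×
significant partners/(n_cells − 1). Edges are binned for line maps with
the conventional color ramp (R 0.10–0.25 blue, 0.26–0.50 green, 0.51–0.75
yellow, 0.76–1.00 red; implemented as contiguous half-open intervals).

Epoch responses are summarized as the trapezoidal AUC of the islet-mean
normalized trace minus a *group-specific* scalar baseline (e.g. 0.95
control vs 1.03 knockout at high glucose); negative excursions are kept
unless clamping is requested, so the AUC is linear in the baseline.

## Decay kinetics and qPCR (`deadstab.kinetics`)

* **∆∆CT.** ∆CT = Ct_target − Ct_reference per sample; ∆∆CT subtracts the
  calibrator-group mean; expression = E^(−∆∆CT) with amplification
  efficiency E fixed at 2.0 (an efficiency-corrected variant is exposed but
  off by default). Invariant to uniform Ct shifts.
* **Decay normalization.** Each replicate's series is divided by its own
  0 h value × 100, removing per-replicate gain.
* **Half-life fit.** log2(abundance/100) is regressed on time through the
  origin. The 0 h points are identically zero after normalization and are
  excluded from the fit; more importantly, normalizing by the 0 h value
  correlates a replicate's residuals (they share the −log y₀ term), so the
  slope's standard error is taken from the spread of independent
  *per-replicate* slopes, with a t-interval on n_reps − 1 df (the pooled
  point estimate equals the mean of per-replicate slopes for a shared time
  design). Without replicate labels the residual-based SE is used.
  t½ = −1/slope; k = ln2/t½ exactly; a non-negative slope is flagged
  stable with unbounded t½. The fit is exact to machine precision on
  noiseless exponentials.
* **Genotype comparison.** The genotype × time interaction is tested as a
  pooled two-sample t on per-replicate slopes; direction is "stabilized"
  when the knockout slope is shallower.
* **RIP.** The input Ct is adjusted by −log2(1/input_fraction) cycles to
  represent 100% of the material; %input = 100 × 2^(Ct_input,adj − Ct_IP);
  fold = %input(antibody)/%input(IgG).
* **Morphometry.** β-cell mass = (insulin⁺ area/total area) × pancreatic
  weight (mg).

## Poly(A) densitometry (`deadstab.polya`)

Marker anchors (length in nt, migration position) define a piecewise
log-linear calibration — log(length) linear in position, longer tails
migrating less far; queries outside the anchor range are answered by linear
extension of the edge segments and flagged as extrapolated. The summary
statistic is the fraction of total lane intensity at tail lengths above a
threshold (default 50 nt), computed by trapezoidal integration with the
grid split exactly at the threshold's migration position; it is invariant
to intensity rescaling and non-increasing in the threshold. An optional
rolling-minimum baseline subtraction handles gel background; it assumes
bands are narrow relative to the window.

## Enrichment and omics integration (`deadstab.enrich`)

The enrichment score is the signed maximum deviation of the
Kolmogorov–Smirnov running sum over the ranked list: set members increment
by |metric|^w normalized to the set total (w = 0 gives the classic
unweighted statistic; w = 1, the default, weights hits by the metric),
non-members decrement 1/(N − n_set). The leading edge is the set members
up to the extremum. Significance uses a gene-permutation null (random
same-size sets) with the +1-corrected two-sided p — the natural scheme
when only a single ranked list, not per-sample phenotype labels, reaches
this stage. The default ranking metric is the DE log fold change with ties
broken by p-value then gene id, giving a deterministic total order.
Transcriptome–proteome agreement is the Pearson correlation of matched
log fold changes (≥3 pairs required), with an optional gene↔protein id map.

## Synthetic data (`deadstab.synthio`)

Generators are seeded and record their ground truth (`SimTruth`), so every
stage can be scored against what was planted.

* **Exon/intron counts.** Per gene, a control-side exonic mean is drawn
  uniformly from `mu_range` (default 100–1000 expected reads/sample) and
  the intronic mean is a fixed fraction of it (default 0.1, reflecting the
  much lower intronic coverage of poly(A)-selected libraries; the true
  ratio varies by protocol and this default is declared, not inferred).
  Knockout means multiply by 2^tx for introns and 2^(tx+stab) for exons.
  Counts are Gamma–Poisson: a per-(gene, sample) multiplier
  G ~ Gamma(1/φ, φ) (unit mean, variance φ) times the cell mean, then
  Poisson sampling — marginally exactly NB(μ, φ). The multiplier is shared
  between a gene's exonic and intronic counts within a sample
  (`shared_sample_effect`), encoding that both read classes are measured
  from one library; set it False for fully independent noise. Effect
  defaults: 10% of genes stabilized at +1.5 log2, 10%
  transcription-changed at 1.5 log2 (assigned independently, so intron
  fold changes carry no information about stability truth), φ = 0.1.
  `frac_tx_down` optionally flips a fraction of transcription effects to
  −tx_logfc; calibration checks of the DE engine use a balanced (half up,
  half down) mixture, both because trimmed-mean normalization assumes
  non-extreme asymmetry and because real islet DE sets are bidirectional.
* **Ca²⁺ traces.** Unit-variance AR(1) (coefficient 0.8) latent signals:
  block members load √ρ on a shared signal plus √(1−ρ) independent noise,
  so expected within-block pairwise Pearson is ρ and cross-block pairs are
  independent; truth adjacency records co-membership. Deterministic
  additive steps raise epoch means (defaults: 3G 0–180 s at baseline, 17G
  180–600 s at +50% of basal, KCl 600–720 s at +100%; 1 Hz sampling — all
  declared defaults). Per-cell gains are random so the traces genuinely
  need F/F_min normalization. Not modelled: photobleaching, oscillatory
  glucose dynamics, spatial PSF mixing between neighboring cells.
* **Decay courses.** Expected relative abundance 100 × 2^(−t/t½) at 0, 4,
  8 h with multiplicative lognormal noise of unit mean and the stated CV
  (default 5%), so ensemble means stay on the decay curve.
* **Densitograms.** Gaussian bands in tail-length space mapped through the
  marker calibration with the Jacobian |d length/d position|, so each
  band's area equals its mixture weight; the lane is normalized to unit
  area before optional additive noise, and the position grid extends 60%
  beyond the marker range so edge bands keep their mass.

What passing tests on these generators shows — and does not show: recovery
and calibration results demonstrate the estimators are correct *under the
stated generative model* (NB counts with paired exon/intron libraries,
AR(1) traces, exponential decay, Gaussian bands). Real data add
complications the generators deliberately omit (gene-length and GC effects,
zero inflation, intron retention, non-exponential decay, gel smile), so
the suite validates the statistics, not the upstream measurement process.

## Numerical choices and degenerate inputs

Exact-test tails are accumulated in log space (logsumexp). Zero-variance
cells are excluded from correlation summaries with a warning rather than
propagating NaN. Haldane's +0.5 protects the interaction logit for genes
with a zero exon or intron group sum. BH ties share adjusted values via a
stable sort. Genes absent from one feature class, cells in no planted
block, and empty gene-set intersections are handled as explicit logged
exclusions or errors, never silent drops. Reported problem sizes
(2,000-gene stability recovery, 10,000-gene calibration, 1,000-timepoint
traces with 1,000 permutations, 500 decay simulations) were chosen so each
Monte-Carlo check pins its quantity well inside the asserted band.

## Known limitations

* The exact test covers two-group designs only; no covariates or batch
  terms.
* TMM composition bias under extremely one-sided DE is inherited from the
  trimmed-mean idea; the stability stage cancels it, the plain DE stage
  does not.
* delta's mean absolute error is floored by intronic counting noise
  (≈0.15 log2 at the default 10% intron coverage and 3v3 design); it is a
  precision limit, not a bias.
* The permutation null assumes stationarity within the analyzed window;
  strong trends (e.g. spanning a stimulus transition) should be analyzed
  per epoch (`TraceSet.slice_epoch`).
* GSEA reports a single set per call — no cross-set NES normalization or
  set-collection FDR.
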