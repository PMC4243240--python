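# Methods

## Pre-processing model

A probe's observed signal is the log2 ratio of background-subtracted tumour
over reference intensity, median-centred per array. The generative model the
pipeline assumes is an admixture of tumour cells at fraction *p* (the
tumour-cell percentage read from histology) with diploid normal cells: a
segment of true integer copy number *c* yields a linear ratio

    p · c/2 + (1 − p)

so that single-copy losses at 70% purity appear around −0.58 rather than −1.
Superimposed are a slowly varying per-chromosome "wave" artefact — a known
aCGH nuisance correlated across arrays — and i.i.d. Gaussian probe noise.

The stage order is fixed: dewave → median-normalize → segment →
mode-normalize → purity-correct → call.

* **Dewaving** regresses each chromosome's ratios on a wave reference profile
  (least squares, slope subtracted), leaving residuals with zero correlation
  to the reference. The reference is supplied externally; the synthetic
  generator emits the mean wave of the simulated cohort for this purpose.
  Zero-variance references are skipped with a log message. This is a
  deliberate simplification of calibration-set dewaving methods: those need a
  panel of normal hybridizations that the pipeline does not assume.
* **Segmentation** is circular binary segmentation, re-implemented: an
  exhaustive search over all arcs `[i, j)` for the maximal t-like statistic
  between arc and complement, a within-segment permutation test for split
  acceptance (default 1,000 permutations, alpha 0.01, minimum arc width 2),
  recursion until no split is accepted. There is no "undo" pruning step. The
  permutation loop early-stops once rejection has become impossible, which
  changes nothing about the decision. Because a permutation preserves the
  value multiset, the segment standard deviation cancels from all
  comparisons. The defaults are exposed in `CbsParams`; they follow common
  aCGH practice since the upstream description delegates segmentation to a
  reference implementation without parameters.
* **Mode normalization** re-centres the profile so its dominant copy-number
  state sits at log2 ratio 0, under the assumption that the modal state is
  diploid. The mode is found on a Gaussian KDE of segment means weighted by
  probe counts. Silverman's rule is applied with the *probe* count as the
  effective sample size — segments are mass points of very different weight,
  and the segment count would give absurdly wide bandwidths for profiles with
  few segments. Near-ties resolve toward the candidate with more probe mass,
  then toward the smaller shift. The known failure mode — a genome so
  aberrant that the modal state is not diploid — is inherent to the
  assumption, not the estimator.
* **Purity correction** inverts the admixture law per segment mean:
  `corrected = log2(max((2^m − (1 − p))/p, ε))` with ε = 2⁻¹⁰. Values driven
  below the floor (deep losses at modest purity) are clipped and logged.
* **QC** is the unscaled median absolute deviation of probes around their
  segment means; profiles with MAD > 0.4 are excluded (boundary inclusive:
  0.40 is kept). Residual-based MAD is insensitive to how aberrant the
  genome is, which a raw-ratio MAD is not. No 1.4826 normality factor is
  applied; the 0.4 threshold is calibrated on the same unscaled convention.
* **Calling** fits a per-sample one-dimensional Gaussian mixture over
  probe-weighted segment means: four components (loss, normal, gain,
  amplification), shared variance, initial means (−0.45, 0, 0.3, 0.9), EM to
  log-likelihood tolerance 1e-8 or 500 iterations, components kept ordered by
  mean. Segment means are winsorized into [−2.5, 3.0] for fitting only —
  floor-clipped deep losses would otherwise inflate the shared variance and
  swallow single-copy changes; classification uses the raw means, whose
  extreme tails fall to the correct outer component anyway. Components whose
  mass collapses, or near-duplicates parked on one cluster, are dropped with
  their mass folded into the retained slot. A state is called only when its
  posterior reaches 0.5, otherwise the segment is called normal; an
  amplification call whose genomic span exceeds 3 Mb is downgraded to gain
  (3 Mb exactly stays an amplification). Per-sample fitting keeps samples
  independent; a cohort-pooled mixture was the plausible alternative and is
  not what this implementation does.

## Region reduction

Subregions are maximal probe runs whose per-sample call signature is constant
across the cohort up to a tolerance (default 0.01): a greedy left-to-right
scan extends the current subregion while the fraction of samples whose call
differs from the running consensus (per-sample modal call over member probes,
ties resolved toward the standing consensus) stays within tolerance.
Subregions never span chromosomes, partition the probes exactly, and at
tolerance 0 the reduction is lossless. This greedy pass replaces the cited
information-loss-minimising reduction, whose parameters the source does not
state; the lossless-at-zero property anchors its correctness. Chromosome arms
come from a user-supplied centromere table; synthetic genomes default to the
chromosome midpoint. Amplification (+2) counts as gain when deriving carrier
status, and loss carriers are calls ≤ −1.

## Survival association

Eligibility follows the trial rule: at least three treatment cycles, or two
when the patient died of rapidly progressive disease; microsatellite-instable
tumours are excluded (they carry few copy-number aberrations and cluster
apart). Kaplan–Meier curves use the product-limit estimator with the
exponential-Greenwood (log(−log)) confidence interval; the median is the
smallest time with S(t) ≤ 0.5 and is reported NA when never reached.

The two-group log-rank statistic is the chi-square form `U²/V` with
`U = Σ (O₁ − E₁)` and hypergeometric variances summed over distinct event
times; censored observations at a tied time remain at risk for the events at
that time. Significance comes from permuting carrier labels (default 10,000
permutations) with the plus-one convention `p = (1 + #{perm ≥ obs})/(B + 1)`,
so p ≥ 1/(B+1) and p = 1 for degenerate labels. The implementation evaluates
a whole matrix of permuted label vectors at once (suffix-sum at-risk counts,
`reduceat` over event-time blocks), which is what makes a genome-wide
10,000-permutation scan affordable.

The genome-wide scan runs per arm over every region × {gain, loss} with at
least 5 carriers and 5 non-carriers (the source states no floor; 5 is
config-exposed and small enough to admit the 7-carrier regions the original
analysis reported). One set of sample permutations is shared across regions
within an arm, so each permutation replicate yields a full genome-scan
p-vector; the permutation FDR at threshold *t* is the mean number of permuted
p ≤ t divided by the observed count (1 when there are no discoveries).
Two significance tiers are flagged: p < 0.005 in any arm, and p < 0.05 in at
least two arms, each on per-arm permutation p-values without cross-arm
correction, mirroring the uncorrected usage upstream. Between-arm
comparisons are pairwise asymptotic log-rank tests within carrier and
non-carrier strata separately; the permutation machinery is reserved for the
genome-wide scan. Unsupervised clustering is Ward linkage on the mean
absolute difference of ordinal calls (a hard-call simplification of
soft-call clustering; the upstream clustering result was itself negative for
PFS), with cluster enrichment tested by Pearson chi-square.

## Integration

Candidate genes are those overlapping (≥ 1 bp, half-open) a tier-flagged
region whose copy number correlates positively with expression in an
independent paired dataset: one-sided Spearman (Pearson available as an
option), α = 0.05, genes with constant copy number reported untested rather
than retained. The upstream description almost certainly inverted an
inequality when stating its significance rule ("≥ 0.05"); ≤ is implemented.
Amplicons are maximal runs of +2 calls per sample; recurrent loci are
connected components of the ≥ 1 bp overlap graph (single linkage), reported
at frequency ≥ 4 distinct samples with the intersection span (union, flagged,
when chained overlaps empty the intersection). Cell lines are classified
aberrant for a region when any segment in the tested state (copy > 2 gain,
< 2 loss) overlaps it; per region, log-IC50 distributions of aberrant versus
normal lines are compared with a hand-implemented Kruskal–Wallis test
(midranks, tie correction, chi-square p), uncorrected for multiplicity since
the region set is small and pre-declared.

## Synthetic data

The generator is the package's stand-in for the trial, the external paired
expression cohort and the cell-line panel. Defaults encode the study
conditions: arms CAP/CAPIRI/CAPOX-B with 105/111/133 samples; ~17 kb probe
spacing; purity uniform on [0.7, 1.0] (the ≥ 70% tumour-cell inclusion
criterion); MSI fraction 21/349 with background aberration rate scaled by
0.02 ("silent" genomes, never driver carriers); probe noise SD 0.25, which
reproduces the cohort-average residual MAD of ≈ 0.17; arm baseline median
PFS 200/260/390 days, the approximate non-carrier medians printed for the
three arms; censoring 10%, reflecting near-universal progression under
first-line palliative treatment. The genome is scaled down (4 chromosomes ×
250 probes by default) — chromosome count and per-arm aberration frequencies
are free parameters the source does not constrain. Survival is exponential
with multiplicative driver hazards (median = ln 2/λ gives exact checks), and
the censoring rate is tuned analytically via `c/(λᵢ + c)` bisection.
Paired expression gives a chosen fraction of genes expression `a·CN + noise`
calibrated to a target population correlation; cell lines get random
copy-number segments and a log-IC50 shift where aberrant. Integer truth
copies are restricted to {0, 1, 2, 3, 5}, mapping cleanly onto the four call
states.

What the generator does **not** emulate: probe-level spatial autocorrelation
beyond the wave, FFPE-specific artefacts, stratification factors
(performance status, LDH), non-exponential hazards, subclonality, and
correlated background aberrations between samples (each genome's background
events are independent). Passing recovery tests therefore demonstrates the
statistical machinery under the assumed model, not robustness to everything
real arrays do. One visible consequence: on the compressed demo genome
(2 chromosomes), independent background events frequently co-occur at the
planted driver locus, so observed-status carrier groups are diluted and the
demo pipeline will often *not* flag the planted driver — the demo is a
completeness and reproducibility exercise; driver recovery is measured on
ground-truth status in the validation experiments.

## Validation experiment sizes

The experiments in `cnsurv.benchmarks` (run by `scripts/acceptance.py` and
the acceptance tests) use: the 4-patient worked log-rank example and n = 8
exhaustive enumeration; null calibration over 3 arms × 200 regions × 100
samples at 1,000 permutations; 20 planted-driver replicates at 100
samples/arm and 10,000 permutations; 100 noisy step profiles (jump/σ = 10)
and 20 brute-force oracle instances of ≤ 30 probes; 20 random call matrices
for reduction properties; 20 cell-line replicates of 300 lines; a 141-sample
paired-expression cohort with 100 dosage and 100 null genes; and the demo
pipeline (3 arms × 40 samples, 2 × 200 probes, 500 permutations) run twice
for byte-level reproducibility. These sizes keep the whole battery to a few
minutes on one CPU while leaving each check comfortably powered.

## Known limitations

* Mode normalization assumes a diploid modal state; near-triploid genomes
  will be mis-centred by one state.
* The per-sample four-state mixture can merge states in samples lacking
  them (handled by component dropping) and has no explicit double-deletion
  state.
* Permutations are unstratified; whether the original analysis stratified
  (e.g. by trial) is unstated upstream.
* The greedy subregion reduction is order-dependent for tolerance > 0 and
  only approximately bounds the cohort-level reconstruction error.
* Coordinate lift-over between genome builds is out of scope: all inputs
  must share one build.
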