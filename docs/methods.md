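# Methods

## Generative model

Observed counts arise from a two-stage technical process applied to the true
molecule content of each cell. For cell *c* with capture efficiency θ_c and
sequencing efficiency γ_c, an entity with m molecules yields

    z | m ~ Binomial(m, θ_c),      x | z ~ Poisson(z · γ_c).

θ_c ∈ (0, 1] is the probability that an input molecule survives
lysis-to-library conversion; γ_c > 0 is the expected number of observed
counts per captured molecule. γ is Poisson rather than binomial so the same
model covers read counts (γ can exceed 1 after amplification) and UMI counts
(γ < 1, where Poisson and binomial thinning are practically identical).
Efficiencies are i.i.d. across cells and mutually independent; the model
cannot see losses upstream of spike-in addition (e.g. incomplete lysis),
since spike-ins enter at the lysis buffer.

The law of total variance gives, for an entity with cross-cell abundance
moments (E[m], Var m):

    E[x]   = E[m]·μ_η,             μ_η = μ_θ μ_γ
    Var(x) = E[m]·A + E[m]²·B + Var(m)·r²_θ r²_γ

with r²_θ = E[θ²], r²_γ = E[γ²], A = μ_θμ_γ + (μ_θ − r²_θ)r²_γ and
B = r²_θ r²_γ − μ_η². The identity r²_θ r²_γ = B + μ_η² holds algebraically
and is asserted for every fitted model. Spike-ins have constant m = n_s, so
their variance curve n_s·A + n_s²·B identifies the technical parameters;
genes then yield a biological variance estimate

    var_bio = (var_obs − mu_hat·A − mu_hat²·B) / (r²_θ r²_γ),
    mu_hat  = mean(x) / μ_η,

clamped at zero (with a flag) when the moment subtraction goes negative —
which it does for about half of genes under a purely technical null, and
routinely for lowly expressed genes; that noisiness is the substantive point
of the decomposition and the reason low-expression variability should not be
over-read.

## Parameter estimation

Per cell we compute three summaries of the spike-in block:

- η̂_c = Σ_s x_sc / Σ_s n_s — combined efficiency (precise; relative error a
  few percent at realistic designs);
- ŵ_c — the zero-intercept regression slope of squared residuals
  (x_sc − n_s η̂_c)² on n_s, an estimate of the within-cell variance slope
  η(1 + γ − η). The denominator uses the exact correction
  Σ n²(1 − n/Σn) for the fitted mean;
- d̂_c — the cell's dropout rate θ(1 − e^{−γ}), by maximum likelihood on the
  cell's zero pattern, P(x_s = 0) = q^m averaged over the stochastic
  rounding of fractional n_s (Fisher variance retained per cell).

The per-cell split into (θ̂_c, γ̂_c) uses the exact identities
γ = w/η − 1 + η and d/η = (1 − e^{−γ})/γ (dropout route preferred when the
cell has informative zeros; the overdispersion route otherwise; floored at
`gamma_floor`, default 0.01, and flagged degenerate when neither route is
informative, e.g. noise-free synthetic input). A small-θ approximation is
deliberately avoided: it biases γ downward by a factor (1 − θ), which is
material at 10–40% capture.

Per-cell split estimates are unavoidably noisy (an individual cell's zeros
and overdispersion contain limited information about its γ), so the four
population moments are *not* the sample moments of per-cell estimates — that
would inflate the variance parameters by roughly an order of magnitude.
Instead the default fit (`fit_method="matching"`) matches bias-corrected
pooled statistics to their exact expectations under moment-parametrized
Beta (θ) and Gamma (γ) population laws, computed by 24-node Gauss–Legendre
quadrature in quantile space (robust for any shape parameters):

- the per-spike zero-fraction curve (down-weighted to ~8 effective
  observations, since zeros of one cell share its efficiencies),
- mean and variance of η̂_c (the predicted variance includes the exact
  within-cell sampling contribution),
- mean of ŵ_c (predicted with the same finite-sample corrections),
- mean, variance and η̂-covariance of d̂_c, with the dropout MLE's own bias
  and sampling variance calibrated by a small parametric bootstrap (60
  cells × 24 replicates, seeded by `random_state`, so the fit is
  deterministic given the data).

The weighted least-squares objective is minimized by Nelder–Mead in
log-parameter space, initialized at cleaned per-cell sample moments, with a
fallback to plain sample moments for degenerate inputs. The Beta/Gamma forms
are smoothing devices; the estimands are the first two moments of each
efficiency.

Identifiability is asymmetric: the two means (and μ_η, A, B, hence
everything the decomposition and the ASE test consume) are estimated to a
few percent at the canonical design below, but the population *variances* of
θ and γ are weakly identified — the information about a single cell's γ is
bounded by its zero pattern and overdispersion, and deconvolving a
population SD of ~0.2 from ~200 cells with per-cell noise SD ~0.3 leaves a
relative standard error of several tens of percent on σ²_γ (see the
recovery figures the acceptance script computes). This limitation affects
only the realism of parametric efficiency simulation, not the variance
decomposition or the ASE test, which depend on (μ_η, A, B) and the per-cell
(θ̂, γ̂) pairs.

## Normalization

Two DESeq-style median-of-ratios size factors are computed per cell — a
technical factor from spike-ins and a biological factor from endogenous
genes — using only genes nonzero in every cell (the geometric-mean reference
degenerates at zero). When cells were processed in batches, the per-batch
mean efficiency E[η] (zero-intercept regression of observed on expected
spike counts, pooled over the batch; ratio-of-sums offered as an option —
the two differ only in spike weighting) is divided out of all counts, after
which the expected spike count equals n_s in every batch. Model fitting and
ASE testing use batch-normalized counts when several batches are declared,
raw counts otherwise.

## Quality control

Cells are discarded on the first violated criterion, in order: fewer than
500 spike-in transcripts; fewer than 10,000 endogenous transcripts; exon
evidence insufficient (kept if exon-mapped reads ≥ 500,000 *or* exon
fraction ≥ 50% — the parenthetical alternative is read as either condition
sufficing); mitochondrial read fraction strictly above 10% (cell rupture);
failed visual inspection of the capture site. Boundaries are literal:
exactly 500 spike-in transcripts is kept, mitochondrial fraction exactly 10%
is kept. SNPs are removed if not PASS in the VCF FILTER column, if four or
more other SNPs fall within ± read length (inclusive window, multi-allelic
positions counted once, the site itself excluded), if any indel falls in
that window, or if they lie on chromosome X (male sample). Reason labels are
stable strings so filter summaries diff cleanly.

## Simulation

Mode "T" (technical only) gives every pseudo cell the same true count:
fractional means are realized as floor(μ) + Bernoulli(frac), the
mean-preserving minimal-variance rounding. Poisson-distributed input would
itself be biological variability under the technical/biological dichotomy,
so the technical null must exclude it. Mode "T+B" draws true counts from a
Gamma–Poisson (negative binomial) with the requested mean and variance; a
Gamma–Poisson cannot be underdispersed, so var_bio < μ falls back to
Poisson. Only the first two moments of the biological law are treated as
meaningful.

Pseudo-cell efficiencies default to `empirical_resample`: (θ̂_c, γ̂_c) pairs
are resampled with replacement from the fitted cells, preserving their joint
structure and in particular the per-cell combined efficiencies exactly, so
simulated first and second moments are calibrated even though individual
γ̂_c are noisy. A `parametric` source (independent moment-matched
Beta/Gamma) is available.

The synthetic-experiment generator emulates: a 92-species log-spaced
spike-in dilution series (0.5–1000 molecules per cell by default; the
acceptance studies use 1–1000), capture moments (0.1, 0.001) and sequencing
moments (0.8, 0.04) matching reported single-cell capture rates; a gene grid
crossing mean expression {1, 5, 20, 100, 500} with biological CV
{0, 0.5, 1}; 300 background genes at mean 600 and CV 0.5 carrying realistic
per-cell totals; allele units of three classes (balanced null,
imprinted-like 90/10 means, stochastic cell-exclusive choice); and a
read-QC table with realistic exon/mitochondrial fractions. It does not
emulate: gene length or GC effects, UMI collision, allelic mapping bias,
doublets, cell-cycle or subpopulation structure, or correlated efficiencies
between spike-ins and genes. Passing tests therefore demonstrate internal
statistical correctness of the method under its own generative assumptions,
not robustness to those unmodelled features of real data.

## Stochastic-ASE test

Per unit (by default the most expressed SNP of each gene — summing SNPs
would double-count reads spanning several SNPs), the allelic ratio of a cell
is max(maternal, paternal)/total, undefined when both are zero; the
statistic is its mean over informative cells. Allelic means are estimated
separately per allele (controlling for imprinting-like mean differences) as
mean(counts) divided by the mean fitted per-cell efficiency — the divisor
must match the effective efficiency of the resampling simulator, or every
null would be anchored at a slightly wrong expression level. The null
simulates n_sim (default 10,000) replicates of n_cells pseudo cells in mode
"T" with independent alleles; replicates with no informative cell are
redrawn (capped at 10× n_sim). The p-value is add-one: (1 + #{null ≥
observed}) / (1 + n_sim), never zero; calls use p < 0.001 by default, with a
Benjamini–Hochberg column emitted for convenience but no correction applied
to the calls.

Plug-in estimation of the allelic means makes the naive comparison mildly
conservative (the observed statistic and the estimated means are correlated
across datasets). By default the test therefore prepivots: the null
statistic is regressed on each replicate's own re-estimated nuisance
features — log total expression and relative allelic imbalance — and the
fitted dependence is subtracted from both sides before comparison. This
restores null uniformity of the p-values (the acceptance suite checks the
rejection rate and a Kolmogorov–Smirnov uniformity test on 1000 null units);
`adjust_nuisance=False` gives the plain plug-in comparison.

The correlated-allelic-expression test uses the Spearman correlation of the
two alleles' counts over informative cells (≥ 5 required) against a "T+B"
null with independent alleles at the estimated per-allele means and
biological variances; one-tailed for positive correlation, i.e. shared
extrinsic regulation beyond independent expression.

## Study designs used by tests and the acceptance script

Technical-model recovery: 20 experiments of 200 cells × 92 spikes
(n_s ∈ [1, 1000]). Decomposition: 500 genes at mean 100 molecules and
biological CV 0.5; 1000 technical-only genes for the clamp rate. Variance
oracle: 10⁶ draws at μ ∈ {1, 10, 50, 500}. ASE null calibration: 1000
balanced units with per-allele means log-uniform in [10, 100] molecules
(the moderately expressed regime where calls are made), 54 cells,
n_sim = 2000. Power: 100 cell-exclusive units at 30 molecules. Ratio
profiles: equal allelic means at totals {0.5, 1, 10, 100, 1000}, "T+B" with
biological CV 1 per allele, efficiencies paired between modes. These sizes
were chosen to make Monte-Carlo error small relative to the assertions.

## Numerical choices and edge cases

- All clamping (negative variances, θ ≤ 1, γ floor) flags rather than
  errors; degenerate inputs (all-zero cells, empty bins, constant allele
  vectors) are skipped with stable reason strings.
- Ties between null and observed statistics count as "at least as extreme"
  (conservative); their mass is negligible at the tested designs.
- Random state: every stochastic routine takes an explicit seed or
  `random_state`; the pipeline fans one global seed out to stages by fixed
  offsets, and a manifest re-runs byte-identically.

## Known limitations

- σ²_θ and σ²_γ are weakly identified at a 92-spike design (see above);
  treat them as order-of-magnitude estimates.
- The test's null conditions on the fitted technical model; uncertainty in
  (μ_η, A, B) is not propagated into the ASE p-values.
- Spike-in input is treated as fixed at n_s, not Poisson-distributed; at
  n_s ≥ a few molecules the distinction is within estimation error.
- Gene-level ASE uses one SNP per gene; evidence from additional SNPs is
  discarded rather than combined.
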