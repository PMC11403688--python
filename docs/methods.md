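# Methods

This note documents the statistical models, algorithms and design choices
behind `gliomanet`, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Preprocessing

**Nonparanormal transform** (`preprocess.npn_transform`). The graphical
lasso assumes multivariate-normal data. Each gene column is mapped through
the truncated empirical CDF: average-ranks/n are winsorized to
[δₙ, 1 − δₙ] with δₙ = 1/(4 n^{1/4} √(π log n)), pushed through the
standard normal quantile function, and rescaled to unit sample standard
deviation. The truncation constant is the canonical published choice for
this estimator; it controls the tails where the empirical CDF is
unreliable. The map depends only on ranks, so any monotone marginal
distortion is removed exactly and the transform is idempotent. Ties take
average ranks (deterministic). A constant column has no defined ranks and
raises an error naming the gene.

**Normality filter** (`preprocess.filter_normal`). Genes are retained iff
the Jarque–Bera statistic (n/6)(skew² + (kurt−3)²/4), referred to a χ²(2)
distribution, has p > α. Default α = 0.05, the package's significance
convention throughout. The default order is gaussianize-then-filter
(`npn_first=True`); the swap is exposed for sensitivity analysis. After
the rank-based transform nearly all genes pass, so the filter mainly
guards heavy-tail/tie pathologies that ranks cannot fix.

## Network step

**Empirical covariance** uses population normalization S = XcᵀXc/n
(degenerate-safe, the maximum-likelihood plug-in of the Gaussian
log-likelihood).

**Graphical lasso** (`network.glasso_fit`) maximizes
log det Θ − tr(SΘ) − ρ‖Θ‖₁. The ℓ1 norm covers **all** entries by
default, the literal reading of the objective; since θᵢᵢ > 0 this only
shifts the working covariance diagonal by ρ (wᵢᵢ = sᵢᵢ + ρ) and does not
change which off-diagonals are zero, so selection is unaffected.
`penalize_diagonal=False` gives the off-diagonal-only convention of most
library defaults and is cross-checked against scikit-learn in the tests.
The solver is the classical block coordinate descent over columns: each
column update is a lasso subproblem solved by cyclic coordinate descent
with soft-thresholding. Convergence is declared when the maximum absolute
change of Θ̂ per sweep falls below 1e-5 · mean(|diag S|) (cap 500 sweeps;
non-convergence raises). Exact zeros come from soft-thresholding; the edge
tolerance |θᵢⱼ| > 1e-8 only guards round-off. Stationarity is verifiable
via `network.kkt_residual` (max-norm violation of Θ⁻¹ − S = ρ·∂‖Θ‖₁);
fitted instances in the tests sit at residuals ≤ 1e-6.

**Selection, hub scoring** Connected genes (≥ 1 nonzero off-diagonal) form
the selected set. Weight (Σⱼ≠ᵢ|θᵢⱼ|) and count (number of partners)
measures are computed over selected genes only — ranking the disconnected
zero-measure genes would flatten the percentile scale. "Distributing the
measures uniformly in [0, 100]" is operationalized as rank-based spacing:
ascending average-ranks r ∈ {1..K} map to 100(r−1)/(K−1) (a single value
maps to 100). Hubs are the union of {pʷ > t} and {pᶜ > t}, default t = 60.
Cross-scheme rank checks band the combined percentile at thirds
(top ≥ 66.7, middle, low < 33.3); the cutoffs are a presentation choice,
not a statistical one.

**Penalty choice.** ρ = 0.9 is the `glasso_fit` default, appropriate for
real expression cohorts where co-regulated genes correlate at |r| > 0.9.
On the synthetic cohorts all columns have unit variance and within-block
correlations ≈ 0.31, so the pipeline's default RunConfig uses ρ = 0.25:
with n = 150 per type, the sampling noise of a covariance entry is
≈ 1/√150 ≈ 0.08, so ρ = 0.25 puts false edges ≈ 3 noise SDs away while
true edges (0.31) remain detectable. Both defaults are overridable; no
data-driven ρ tuning is attempted (out of scope by design).

## Survival step

**Penalized Cox model.** The Breslow partial log-likelihood (events with
tied times share a risk-set denominator) is maximized minus λ‖β‖₁, on the
full-likelihood scale. Features are centered and scaled to unit variance
before fitting (penalization fairness across genes); coefficients are
returned on the original scale. The solver is a proximal Newton scheme:
an outer quadratic (IRLS) approximation of the partial likelihood with
diagonal Hessian weights, an inner cyclic coordinate descent with
soft-thresholding and glmnet-style active-set iteration, warm-started
along a descending λ path (default 100 log-spaced points from λmax, the
smallest penalty with an all-zero solution computed from the null-model
gradient, down to 0.01·λmax). Outer convergence at max|Δβ| < 1e-7. In the
tests the fits match an independent bound-constrained convex solver to
1e-6 in objective and an unpenalized reference fit to 1e-4 in
coefficients.

**Model-size cap.** pmax = ⌈events/10⌉ (the 10-events-per-variable rule of
thumb against overfitting); `select_model` returns the densest path model
whose active set respects the cap, i.e. the smallest admissible λ.
pmax = 0 degenerates to the null model with a warning.

**Risk stratification.** PI = Xβ̂. The HR/LR threshold is the local
minimum of a Gaussian KDE between the two main PI modes: bandwidth
0.9·min(sd, IQR/1.34)·n^{−1/5} (the classic rule of thumb used by standard
density routines), 512-point grid spanning the data ± 3 bandwidths. Local
maxima must reach ≥ 5% of the global density maximum to count as modes;
without this screen a single outlying sample creates a negligible tail
bump that can masquerade as the "second peak" and push the threshold into
the tail (observed on unimodal samples during development). With ≥ 2
qualifying modes the threshold is the density argmin between the two
highest; otherwise it falls back to the median — the default convention of
the stratification routine this emulates. Ties at the boundary go to LR
(PI ≤ threshold ⇒ LR). Kaplan–Meier estimation and the log-rank test are
delegated to lifelines behind the module surface; both are verified
against hand-computed product-limit and O/E/V oracles in the tests.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
with ground truth:

- **Expression.** Zero-mean multivariate normal per type, covariance the
  inverse of a block-sparse precision matrix: diagonal 1, within-block
  off-diagonals +partial_corr (equicorrelated blocks; positive
  definiteness checked at construction). The three types share block
  positions but differ in which blocks are active, cycling the patterns
  [all types, type 1 only, type 2 only, type 3 only], so shared and
  exclusive selections are both nontrivial. A seeded fraction of gene
  columns is passed through exp(·) — monotone, hence reversible by the
  nonparanormal transform, which lets tests separate the JB-filter path
  from the gaussianization path.
- **Labels.** Each sample carries molecular flags. The 2021-style label is
  deterministic: IDH-mutant + 1p/19q codeletion → oligodendroglioma;
  IDH-mutant without codeletion → astrocytoma; IDH-wildtype → GBM. The
  2016-style label equals it except for a seeded discordant fraction that
  follows the histology flag instead (histology disagrees with the
  molecular type for ~30% of samples, emulating histology-driven calls).
- **Survival.** Event times are exponential with rate
  baseline_rate·exp(xβ_true) (the simplest proportional-hazards-compatible
  baseline; the baseline cancels in the partial likelihood regardless).
  Censoring times are uniform on [0, c] with c solved by root-finding so
  the expected censoring fraction, mean over samples of (1 − e^{−rc})/(rc),
  hits the target. β_true has exactly n_prognostic nonzeros of magnitude
  effect_size with random signs, drawn among block-member genes so the
  diagnostic selection step can in principle retain them.

**Default conditions** (one desk-scale cohort, fixed once): 150 samples
per type, 120 genes, 16 fully connected blocks of 3 (48 block genes, 72
conditionally isolated), partial_corr = 0.45 (within-block marginal
correlation ≈ 0.31 — equicorrelated precision blocks of size k cannot
exceed 1/(k−1) in marginal correlation, so small blocks with strong
entries are used), 5 prognostic genes at effect size 0.5, baseline rate
0.1, 30% censoring, 20% distorted marginals, 15% label discordance.
Recovery experiments use the larger settings stated in their tests
(n = 800, p = 60, blocks of 5 at 0.35 for network support; n = 600,
p = 120 for prognostic-gene recovery).

**What the generator does not emulate.** RNA-Seq count noise,
library-size/batch effects, mean shifts between types (all types are
zero-mean; only the covariance differs). Consequently the PI distribution
of synthetic cohorts is typically unimodal and the KDE threshold takes its
median fallback end-to-end; the bimodal branch is exercised on explicit
Gaussian mixtures. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated conditions — not performance
on real TCGA-scale cohorts (p ≈ 16,000 genes), which desk-scale
simulations do not attempt to emulate.

## Numerical edge cases

- Constant expression columns: error (named gene) in the nonparanormal
  transform; zero-variance vectors: error in Jarque–Bera.
- Covariance with n < 2, non-symmetric S, ρ < 0: errors.
- p = 1 precision: closed form 1/(s + ρ).
- No events: Cox fitting and pmax refuse; single-sample risk sets give a
  zero partial likelihood.
- Constant PI: threshold undefined, error; < 10 samples: error.
- Empty case gene sets (e.g. hub threshold 100): stage-named error with
  the offending case.

## Pipeline determinism

All randomness flows from the run seed (sub-seeds are fixed offsets);
rerunning a config reproduces bit-identical artifacts, which the tests
assert on the summary JSON.
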