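# Methods

## Model and objectives

The data are n i.i.d. p-vectors; the fitted model is an unconstrained
K-component Gaussian mixture f(x;θ) = Σ_k π_k 𝒩(x; μ_k, Σ_k) with full,
component-specific covariances. Two objectives are maximized:

* the log-likelihood ℒ(θ) = Σ_i log f(x_i; θ);
* the penalized objective ℳ(θ) = ℒ(θ) − w₁·KLF(θ) − w₂·KLB(θ), where KLF
  and KLB sum the directed Gaussian KL divergences over ordered component
  pairs (k₁<k₂ forward, k₂<k₁ backward) and w₁, w₂ ≥ 0.

ℒ here is the **total** (not per-point) log-likelihood. The penalty weights
on the default grid (≤ 1.25) are calibrated to that scale: typical
penalized solutions trade tens of nats of total likelihood against
divergence sums in the tens-to-hundreds. A `scale="mean"` switch divides ℒ
by n for users who prefer the empirical-expectation convention; weights
must then be rescaled by 1/n to describe the same trade-off.

Each pairwise divergence decomposes as 0.5(A+B+C): A = log|Σ₂|−log|Σ₁|
(volume), B = tr(Σ₂⁻¹Σ₁)−p (orientation/shape), C = Mahalanobis distance
between means under Σ₂. C ≥ 0 and A+B ≥ 0 (LogDet divergence), so every
pairwise term is non-negative; A cancels between the forward and backward
sums when w₁ = w₂. If one covariance collapses onto a data point, ℒ grows
without bound but B explodes as 1/ε, so ℳ is bounded above and penalized
fitting cannot choose degenerate solutions. The collapse probe in the test
suite exhibits this on a fixed dataset: p = 100 so that the likelihood gain
over ε ∈ [10⁻¹, 10⁻¹²] exceeds 10³ nats ((p/2)·ln 10¹¹), and data variance
10⁻³ per coordinate, which places the interior maximum of ℳ near
ε ≈ Var(x) — inside, not at the edge of, the sweep.

## Parameterization for gradient ascent

Gradient ascent runs on an unconstrained chart: weights as log-proportions
α_k mapped by softmax (gauge fixed by mean(α) = 0), covariances as
log-Cholesky factors (lower-triangular C with free off-diagonal and
log-parameterized diagonal, Σ = CCᵀ). The chart is smooth, bijective onto
valid parameters, and makes plain ascent respect the simplex and positive-
definiteness constraints by construction.

Gradients of ℳ are closed-form: the likelihood part via responsibilities
(∂ℒ/∂α_k = N_k − nπ_k, the usual mean and scatter forms for μ_k and Σ_k)
and the penalty part via the standard matrix-calculus derivatives of
log-determinant, trace and quadratic terms; symmetric covariance gradients
D are chained onto the factor as 2DC with the diagonal scaled by C_jj.
Every formula is pinned against central finite differences over the full
packed parameter vector in the test suite. All density work is done in log
space through Cholesky solves; no covariance is ever inverted explicitly,
and no ridge is added by default (an optional eigenvalue floor exists for
unpenalized baselines but is off — degeneracy is meant to be observable).

## Fitting algorithms

**EM** (`em_fit`): textbook E/M steps for the unconstrained model. Stops
when the total log-likelihood improves by < tol (default 10⁻⁶, default cap
500 iterations). A non-positive-definite M-step covariance or a component
losing all responsibility ends the run with `degenerate=True`, diagnostics
naming the component, and the last valid parameters — collapse is reported,
not silently repaired.

**Gradient ascent** (`adgd_fit`): full-batch Adam-style ascent (β₁ = 0.9,
β₂ = 0.999) of ℳ on the unconstrained chart. Step size 0.05 by default,
halved after 200 iterations without improvement and once more on a
non-finite rescue; convergence requires the relative objective change to
stay below tol (default 10⁻⁷) for 30 consecutive iterations — a single
small adaptive step is not convergence, and treating it as such truncates
ascents through flat regions of ℳ by orders of magnitude. The returned
parameters are the best iterate seen, so the final objective never falls
below the initial one. The run is deterministic given data and init.

**SIA** (`sia_fit`): Step I fits the unpenalized model (EM by default,
gradient ascent optional) from a K-Means initialization; Step II runs
penalized ascent warm-started at Step I independently for each w on the
grid {0, 0.25, 0.5, 1, 1.25} (w₁ = w₂); the selected fit minimizes MPKL,
ties broken toward the smaller weight (the solution closest to Step I).
Grid points may fail individually without failing the run.

**Initialization.** `kmeans_init` converts a K-Means partition (10
internal restarts, best inertia — a poorly converged K-Means is otherwise
itself a frequent bad local optimum that EM inherits) into weights/means/
within-cluster covariances, eigenvalue-floored when a cluster is
degenerate. `random_init` (random distinct points as means, randomly
shrunk global covariance) exists for landscape exploration: K-Means starts
are too stable to expose the diversity of likelihood local maxima that the
multi-restart experiments study.

One master seed fans out to K-Means, simulators and dataset replicates via
`numpy.random.SeedSequence` spawning; all derived seeds stay below 2³¹.

## Model selection and evaluation

AIC = 2k − 2ℒ and BIC = k·log n − 2ℒ use the unconstrained parameter count
k = (K−1) + Kp + Kp(p+1)/2 and the total log-likelihood. `select_k` scans
K ∈ [2, L], fits each (SIA or EM) and returns the K minimizing MPKL.
`group_by_aic` summarizes multi-restart solution sets by AIC range (counts,
AIC and ARI moments, weights, covariance determinants sorted by determinant
for cross-restart comparability — the component indexing of independent
restarts is otherwise arbitrary).

ARI/RI are pair-counting agreement indices (scikit-learn backed; validated
against an exhaustive pair-counting oracle in the tests). The benchmark
harness simulates n_datasets per design cell, fits each requested method
with one K-Means initialization per dataset, and reports per-cell mean/SD
ARI; per-dataset failures are excluded from the mean and counted.

## Univariate asymmetry theory

For the contaminated truth G* = π𝒩(−μ,σ²) + π𝒩(μ,σ²) + (1−2π)𝒩(μ,b²σ²)
(0 < π ≤ 0.5) fitted by a 2-component GMM, the asymmetry coefficient
τ = π̄·erf(μ̄₂/(√2σ̄₂)) + (1−π̄)·erf(μ̄₁/(√2σ̄₁)) of the KL projection obeys
−√(2C₂)+2C_w ≤ τ ≤ √(2C₂)+2C_w with
C₂ = (1−2π)(−log b + 0.5b² − 0.5) + 2πμ²/σ² and
C_w = 0.5(1−2π)·erf(−μ/(√2σ)). The weight symbol inside C_w is taken to be
π — the only weight in the truth, and the reading under which the
symmetric case π = 0.5 gives C_w = 0 as the theory requires. C₂ ≥ 0 for
every b > 0, and the upper bound is minimized at b = 1 (no
misspecification). `bound_sweep` approximates the KL projection by EM fits
at large n (default 5000 per dataset; the MLE converges to the projection),
takes the maximum fitted τ (literally of τ, not |τ|) over datasets per b,
and tabulates it against the bounds.

## Synthetic designs

* **Pinwheel** (p = 2, K arms): z ~ 𝒩((1,0), diag(r², t²)) rotated by
  angle 2πk/K + s·exp(z_radial). r is the radial and t the tangential
  standard deviation; the rate s controls the warp, hence the degree of
  misspecification. s = 0 with r = t gives K isotropic Gaussians
  equidistant on the unit circle. Default 100 points per arm.
* **Cubed separation** (K = 3): means 0.5λ·1_p, 0, −0.5λ·1_p, identity
  covariances, 100·p points per component, every coordinate cubed — the
  components become skewed and heavy-tailed (central component: mean 0,
  per-coordinate variance E[Z⁶] = 15, kurtosis ≫ 3). λ controls
  separation.
* **Unbalanced random-covariance** (K = 2): means ±0.5·1_p, Σ_k = RRᵀ with
  square-root factors R of i.i.d. standard normal entries (positive
  definite almost surely; resampled in the measure-zero singular case),
  100·p points in cluster 1 and {20, 50, 100}·p in cluster 2, coordinates
  cubed.
* **Contaminated mixtures**: a base GMM with an exact fraction (default
  0.1) of points replaced by Student's-t noise (default 3 degrees of
  freedom, scaled to the mixture's marginal spread) or uniform noise over
  the data bounding box expanded ×1.5; contaminant points are labeled −1.
* **Univariate truth G***: a plain mixture draw of the three components.

Generators are pure functions of (config, seed); labeled designs use exact
stratified per-component counts, not multinomial draws.

What these designs emulate is *structured misspecification with known
ground truth*: smooth warps, polynomial marginal transforms, random
covariance geometry, heavy-tail contamination. What they do not emulate:
discrete or mixed-type features, missing data, cluster overlap that is
ambiguous in the ground truth itself, and high-dimension/low-sample
regimes (p ≥ n). Passing benchmarks here shows the penalty corrects
likelihood-favored asymmetric solutions under these controlled departures
from Gaussianity — not that SIA wins on arbitrary real data.

## Problem sizes and reproduction notes

The shipped benchmark reproduction (`scripts/acceptance.py`) uses 50
simulated datasets per cell at p ∈ {3, 5} and 10 at p ∈ {10, 20}, with the
design's native sample sizes (300·p points per dataset). The asymmetry
certification sweeps 12 values of b spanning [0.1, 6] with 50 datasets of
n = 5000 per value. The multi-restart landscape experiment uses 60 random
initializations on one pinwheel realization.

Two reproduction caveats, observed and deliberate:

* With a properly converged K-Means start, EM rarely lands in the very bad
  local optima that depress reference mean-ARI figures for EM-family
  methods at low p; mean ARIs for SIA at p ∈ {3, 5} therefore come out a
  few hundredths *above* the corresponding reference values. (With a
  single-start K-Means the opposite happens, and by a larger margin: the
  penalized refinement cannot rescue solutions whose MPKL is already low.)
* At p = 20 the K-Means partition of the cubed design is already almost
  perfect (ARI ≈ 0.998) and every EM iteration slightly *degrades* it (the
  heavy cubed tails are absorbed by wide Gaussians), plateauing near 0.98.
  An EM run genuinely to convergence therefore cannot reproduce a value
  halfway between the init and the plateau; the implementation runs to
  convergence rather than stopping early.

## Known limitations

* The penalty couples all component pairs; per-evaluation cost is
  O(K²p³). Large K is untested territory.
* MPKL selection assumes asymmetric directed divergences signal poor
  structure; for genuinely unequal-volume true clusters it can prefer an
  over-symmetrized fit (the selected weight then trades real structure for
  symmetry).
* The gradient-ascent stopping rule is heuristic (relative-change
  patience); pathological plateaus longer than the patience window would
  stop early.
* `bound_sweep` certifies the bound against EM approximations of the KL
  projection; EM local optima at moderate n can sit below the projection's
  τ, so the check is one-sided by nature.
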