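"""Seeded synthetic-data generators for misspecified-GMM experiments.

Every generator is a pure function of (config, seed): same inputs, same
dataset.  Per-component counts are exact (stratified sampling) except for
the univariate contaminated mixture, which is an unlabeled mixture draw.

Regimes
-------
* :func:`pinwheel` — warped GMM: K arms equidistant on the unit circle,
  Gaussian (radial, tangential) scatter, angle warped by a rate parameter.
  Misspecification severity is controlled by (r, t, s).
* :func:`cubed_separation` — 3 spherical Gaussians at -0.5*lam*1, 0,
  +0.5*lam*1 with every coordinate cubed afterwards (heavy-tailed, skewed).
* :func:`cubed_random_cov` — 2 components at +/-0.5*1 with random
  square-root covariance factors and unbalanced sizes, coordinates cubed.
* :func:`contaminated` — a base GMM with a fraction of points replaced by
  Student's-t or uniform box noise (contaminant labeled -1).
* :func:`sample_univariate_truth` — the contaminated univariate mixture
  G* = pi N(-mu, s^2) + pi N(mu, s^2) + (1-2 pi) N(mu, b^2 s^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Dataset, GMMParams

__all__ = [
    "PinwheelConfig",
    "SeparationConfig",
    "UnbalancedConfig",
    "ContaminationConfig",
    "UnivariateTruth",
    "pinwheel",
    "cubed_separation",
    "cubed_random_cov",
    "contaminated",
    "sample_univariate_truth",
]


@dataclass(frozen=True)
class PinwheelConfig:
    """Warped-GMM pinwheel: K arms, radial std r, tangential std t, rate s."""

    n_per_class: int = 100
    K: int = 3
    r: float = 0.3
    t: float = 0.05
    s: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.r <= 0 or self.t <= 0:
            raise ValueError("radial and tangential stds must be positive")


@dataclass(frozen=True)
class SeparationConfig:
    """Cubed 3-component design: means 0.5*lam*1_p, 0, -0.5*lam*1_p, I_p."""

    p: int
    lam: float
    seed: int = 0

    @property
    def n_per_component(self) -> int:
        return 100 * self.p


@dataclass(frozen=True)
class UnbalancedConfig:
    """Cubed 2-component design with random covariance factors.

    Cluster 1 has 100*p points; cluster 2 has N2_per*p points,
    N2_per in {20, 50, 100}.
    """

    p: int
    N2_per: int
    N1_per: int = 100
    seed: int = 0


@dataclass(frozen=True)
class ContaminationConfig:
    """Base GMM plus a contaminant: Student's-t or uniform box noise."""

    base: GMMParams
    n: int = 500
    kind: str = "student_t"  # or "uniform_noise"
    fraction: float = 0.1
    t_df: float = 3.0
    box_expand: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fraction < 1:
            raise ValueError("contamination fraction must be in [0, 1)")
        if self.kind not in ("student_t", "uniform_noise"):
            raise ValueError("kind must be 'student_t' or 'uniform_noise'")


@dataclass(frozen=True)
class UnivariateTruth:
    """True contaminated univariate mixture G*(pi, mu, sigma, b)."""

    pi: float
    mu: float
    sigma: float
    b: float

    def __post_init__(self):
        if not 0 < self.pi <= 0.5:
            raise ValueError("pi must be in (0, 0.5]")
        if self.mu <= 0 or self.sigma <= 0 or self.b <= 0:
            raise ValueError("mu, sigma, b must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.pi, self.pi, 1.0 - 2.0 * self.pi])

    @property
    def component_means(self) -> np.ndarray:
        return np.array([-self.mu, self.mu, self.mu])

    @property
    def component_sds(self) -> np.ndarray:
        return np.array([self.sigma, self.sigma, self.b * self.sigma])


def pinwheel(cfg: PinwheelConfig) -> Dataset:
    """Sample a pinwheel (warped GMM) dataset with arm labels.

    Per arm k: draw z ~ N((1, 0), diag(r^2, t^2)); the point is z rotated
    by angle 2*pi*k/K + s*exp(z_radial).  With s = 0 and r = t the arms are
    isotropic Gaussians centered equidistantly on the unit circle.
    """
    rng = np.random.default_rng(cfg.seed)
    base_angles = 2.0 * np.pi * np.arange(cfg.K) / cfg.K
    labels = np.repeat(np.arange(cfg.K), cfg.n_per_class)
    z = rng.standard_normal((cfg.K * cfg.n_per_class, 2)) * np.array([cfg.r, cfg.t])
    z[:, 0] += 1.0
    angles = base_angles[labels] + cfg.s * np.exp(z[:, 0])
    ca, sa = np.cos(angles), np.sin(angles)
    X = np.column_stack([z[:, 0] * ca - z[:, 1] * sa, z[:, 0] * sa + z[:, 1] * ca])
    return Dataset(X, labels)


def cubed_separation(cfg: SeparationConfig) -> Dataset:
    """Cubed 3-component separation design; 100*p points per component."""
    if cfg.lam <= 0:
        raise ValueError("lam must be positive")
    rng = np.random.default_rng(cfg.seed)
    m = 0.5 * cfg.lam * np.ones(cfg.p)
    means = np.stack([m, np.zeros(cfg.p), -m])
    npc = cfg.n_per_component
    X = rng.standard_normal((3 * npc, cfg.p)) + np.repeat(means, npc, axis=0)
    labels = np.repeat(np.arange(3), npc)
    return Dataset(X**3, labels)


def cubed_random_cov(cfg: UnbalancedConfig) -> Dataset:
    """Cubed unbalanced 2-component design with random covariance factors.

    Square-root factors have i.i.d. standard normal entries; the implied
    covariance factor^T factor is positive definite almost surely (resampled
    in the measure-zero singular case).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = (cfg.N1_per * cfg.p, cfg.N2_per * cfg.p)
    means = np.stack([-0.5 * np.ones(cfg.p), 0.5 * np.ones(cfg.p)])
    parts, labels = [], []
    for k in range(2):
        for _ in range(100):
            root = rng.standard_normal((cfg.p, cfg.p))
            if np.linalg.matrix_rank(root) == cfg.p:
                break
        Z = rng.standard_normal((counts[k], cfg.p))
        parts.append(Z @ root.T + means[k])
        labels.append(np.full(counts[k], k))
    X = np.vstack(parts)
    return Dataset(X**3, np.concatenate(labels))


def contaminated(cfg: ContaminationConfig) -> Dataset:
    """Base-GMM sample with a contaminated fraction labeled -1."""
    rng = np.random.default_rng(cfg.seed)
    base = cfg.base
    base.validate()
    n_noise = round(cfg.fraction * cfg.n)
    n_clean = cfg.n - n_noise
    counts = _stratified_counts(base.weights, n_clean)
    parts, labels = [], []
    for k in range(base.K):
        C = np.linalg.cholesky(base.covariances[k])
        Z = rng.standard_normal((counts[k], base.p))
        parts.append(Z @ C.T + base.means[k])
        labels.append(np.full(counts[k], k))
    clean = np.vstack(parts) if parts else np.empty((0, base.p))
    if n_noise:
        if cfg.kind == "student_t":
            center = base.weights @ base.means
            spread = np.sqrt(np.einsum("k,kjj->j", base.weights, base.covariances))
            noise = rng.standard_t(cfg.t_df, size=(n_noise, base.p)) * spread + center
        else:
            lo, hi = clean.min(axis=0), clean.max(axis=0)
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * cfg.box_expand
            noise = rng.uniform(mid - half, mid + half, size=(n_noise, base.p))
        X = np.vstack([clean, noise])
        lab = np.concatenate(labels + [np.full(n_noise, -1)])
    else:
        X, lab = clean, np.concatenate(labels)
    return Dataset(X, lab)


def _stratified_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Exact per-component counts: floor(n*w) plus largest remainders."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def sample_univariate_truth(truth: UnivariateTruth, n: int, seed: int = 0) -> Dataset:
    """Draw n points from the contaminated univariate mixture G*."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=truth.weights)
    x = rng.standard_normal(n) * truth.component_sds[comp] + truth.component_means[comp]
    return Dataset(x[:, None])
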