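"""Direction of Selection and gamma-DFE inference from paired site-frequency spectra.

The DFE model follows the standard Poisson random-field setup with shared
per-frequency-class distortion multipliers r_i absorbing demography and
ascertainment: neutral class means are theta_neu * r_i / i and selected class
means are theta_sel * r_i * Hbar_i, where Hbar_i mixes the deterministic
sojourn-time expectation over a gamma distribution of scaled selection
strengths S = 4*Ne*s acting against the derived allele.  Only polymorphism
enters the fit; the divergence contrast is carried by DoS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.integrate
import scipy.optimize
import scipy.stats
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# Direction of Selection
# ---------------------------------------------------------------------------


def dos(Dn: float, Ds: float, Pn: float, Ps: float) -> float:
    """Dn/(Dn+Ds) - Pn/(Pn+Ps); negative values mean excess non-synonymous
    polymorphism relative to divergence."""
    if Dn + Ds <= 0:
        raise ValueError("Dn + Ds must be positive")
    if Pn + Ps <= 0:
        raise ValueError("Pn + Ps must be positive")
    return Dn / (Dn + Ds) - Pn / (Pn + Ps)


def dos_standard_error(Dn: float, Ds: float, Pn: float, Ps: float) -> float:
    """Delta-method SE treating the two proportions as independent binomials."""
    pd_ = Dn / (Dn + Ds)
    pp = Pn / (Pn + Ps)
    return float(np.sqrt(pd_ * (1 - pd_) / (Dn + Ds) + pp * (1 - pp) / (Pn + Ps)))


# ---------------------------------------------------------------------------
# expected SFS under directional selection
# ---------------------------------------------------------------------------

_NEUTRAL_EPS = 1e-8


def _log_expm1(y: float) -> float:
    """log(exp(y) - 1), overflow-safe for large y."""
    if y > 30.0:
        return y + np.log1p(-np.exp(-y))
    return np.log(np.expm1(y))


def expected_sfs(S: float, n: int) -> np.ndarray:
    """Expected relative class sizes i = 1..n-1 under scaled selection S >= 0
    acting *against* the derived allele.

    E_i(S) = integral_0^1 (exp(S(1-x)) - 1) / ((exp(S) - 1) x (1-x))
             * C(n,i) x^i (1-x)^(n-i) dx,
    normalised so that E_i(0) = 1/i (the neutral limit, returned analytically).
    Evaluated in log space, numerically stable for S up to >= 1e4.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if S < 0:
        raise ValueError("S must be >= 0 (strength against the derived allele)")
    idx = np.arange(1, n)
    if S < _NEUTRAL_EPS:
        return 1.0 / idx

    log_denom = _log_expm1(S)
    out = np.empty(n - 1)
    # the integrand concentrates near x = 0 with width ~1/S for large S
    points = None
    if S > 50:
        points = sorted({min(1.0 - 1e-12, 1.0 / S), min(1.0 - 1e-12, 20.0 / S)})
    for k, i in enumerate(idx):
        log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        ei = int(i) - 1
        en = int(n - i) - 1

        def integrand(x: float, ei=ei, en=en, log_c=log_c) -> float:
            if x <= 0.0 or x >= 1.0:
                return 0.0
            log_val = log_c + _log_expm1(S * (1.0 - x)) - log_denom
            if ei:
                log_val += ei * np.log(x)
            if en:
                log_val += en * np.log1p(-x)
            return np.exp(log_val)

        val, _ = scipy.integrate.quad(
            integrand, 0.0, 1.0, limit=200, points=points
        )
        out[k] = val
    return out


def fold_spectrum(v: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded class vector (length n-1) to minor-allele classes."""
    v = np.asarray(v, dtype=float)
    if v.shape != (n - 1,):
        raise ValueError(f"expected length {n - 1}, got {v.shape}")
    half = n // 2
    folded = np.empty(half)
    for j in range(1, half + 1):
        if j < n - j:
            folded[j - 1] = v[j - 1] + v[n - j - 1]
        else:  # j == n - j, the central class of an even sample
            folded[j - 1] = v[j - 1]
    return folded


def n_classes(n: int, folded: bool) -> int:
    return n // 2 if folded else n - 1


@dataclass(frozen=True)
class SFSPair:
    """Paired neutral/selected site-frequency spectra from the same sample."""

    n: int
    folded: bool
    neutral_counts: np.ndarray
    selected_counts: np.ndarray

    def __post_init__(self) -> None:
        k = n_classes(self.n, self.folded)
        neu = np.asarray(self.neutral_counts, dtype=float)
        sel = np.asarray(self.selected_counts, dtype=float)
        if neu.shape != (k,) or sel.shape != (k,):
            raise ValueError(f"spectra must have {k} classes for n={self.n}, folded={self.folded}")
        if (neu < 0).any() or (sel < 0).any():
            raise ValueError("spectrum counts must be non-negative")
        object.__setattr__(self, "neutral_counts", neu)
        object.__setattr__(self, "selected_counts", sel)

    def fold(self) -> "SFSPair":
        if self.folded:
            return self
        return SFSPair(
            n=self.n,
            folded=True,
            neutral_counts=fold_spectrum(self.neutral_counts, self.n),
            selected_counts=fold_spectrum(self.selected_counts, self.n),
        )


# ---------------------------------------------------------------------------
# gamma mixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed-node Gauss-Legendre grid on log S with analytic tail handling."""

    n: int
    n_nodes: int = 64
    s_lo: float = 1e-4
    s_hi: float = 1e6

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        x, w = np.polynomial.legendre.leggauss(self.n_nodes)
        lo, hi = np.log(self.s_lo), np.log(self.s_hi)
        u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        wu = 0.5 * (hi - lo) * w
        return np.exp(u), wu


_E_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grid_matrices(grid: QuadratureGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S nodes, log-space weights, E matrix of shape (n_nodes, n-1))."""
    key = (grid.n, grid.n_nodes, grid.s_lo, grid.s_hi)
    if key not in _E_CACHE:
        s_nodes, w = grid.nodes()
        mat = np.vstack([expected_sfs(s, grid.n) for s in s_nodes])
        _E_CACHE[key] = (s_nodes, w, mat)
    return _E_CACHE[key]


def gamma_mixed_sfs(beta: float, s_mean: float, grid: QuadratureGrid) -> np.ndarray:
    """Hbar_i = E over S ~ Gamma(shape=beta, mean=s_mean) of expected_sfs(S)_i.

    Mass below the lower grid bound is treated as neutral (1/i); mass above
    the upper bound uses the boundary value.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if s_mean < 0:
        raise ValueError("s_mean must be >= 0")
    idx = np.arange(1, grid.n)
    if s_mean == 0:
        return 1.0 / idx
    s_nodes, w, mat = _grid_matrices(grid)
    dist = scipy.stats.gamma(a=beta, scale=s_mean / beta)
    dens = dist.pdf(s_nodes) * s_nodes  # Jacobian of u = log S
    hbar = (w * dens) @ mat
    lo_mass = dist.cdf(grid.s_lo)
    hi_mass = dist.sf(grid.s_hi)
    hbar += lo_mass / idx + hi_mass * mat[-1]
    return hbar


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------


def _class_shapes(
    beta: float, s_mean: float, grid: QuadratureGrid, folded: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class neutral and selected shape vectors (before theta and r)."""
    idx = np.arange(1, grid.n)
    neu = 1.0 / idx
    sel = gamma_mixed_sfs(beta, s_mean, grid)
    if folded:
        neu = fold_spectrum(neu, grid.n)
        sel = fold_spectrum(sel, grid.n)
    return neu, sel


def _poisson_loglik(counts: np.ndarray, means: np.ndarray) -> float:
    means = np.asarray(means, dtype=float)
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite Poisson mean in likelihood")
    return float(scipy.stats.poisson.logpmf(np.round(counts).astype(int), means).sum())


def dfe_loglik(
    beta: float,
    s_mean: float,
    theta_sel: float,
    theta_neu: float,
    r: Sequence[float],
    sfs_pair: SFSPair,
    grid: QuadratureGrid | None = None,
) -> float:
    """Poisson log-likelihood of the paired spectra under the gamma-DFE model.

    ``r`` has one multiplier per observed class (folded or not); r[0] is the
    reference class and conventionally fixed at 1 when fitting.
    """
    grid = grid or QuadratureGrid(n=sfs_pair.n)
    if grid.n != sfs_pair.n:
        raise ValueError("grid sample size does not match the SFS pair")
    r = np.asarray(r, dtype=float)
    k = n_classes(sfs_pair.n, sfs_pair.folded)
    if r.shape != (k,):
        raise ValueError(f"r must have {k} entries")
    if (r < 0).any():
        raise ValueError("r must be non-negative")
    neu_shape, sel_shape = _class_shapes(beta, s_mean, grid, sfs_pair.folded)
    ll = _poisson_loglik(sfs_pair.neutral_counts, theta_neu * r * neu_shape)
    ll += _poisson_loglik(sfs_pair.selected_counts, theta_sel * r * sel_shape)
    return ll


@dataclass(frozen=True)
class DFEFitConfig:
    n_gamma_nodes: int = 64
    s_lo: float = 1e-4
    s_hi: float = 1e6
    beta_bounds: tuple[float, float] = (0.01, 10.0)
    s_mean_bounds: tuple[float, float] = (1e-3, 1e5)
    beta_starts: tuple[float, ...] = (0.1, 0.3, 1.0)
    s_mean_starts: tuple[float, ...] = (1.0, 50.0, 2000.0)
    fit_distortions: bool = True
    n_bootstrap: int = 0
    seed: int = 0

    def grid(self, n: int) -> QuadratureGrid:
        return QuadratureGrid(n=n, n_nodes=self.n_gamma_nodes, s_lo=self.s_lo, s_hi=self.s_hi)


@dataclass(frozen=True)
class DFEFit:
    beta: float
    s_mean: float
    theta_sel: float
    theta_neu: float
    r: tuple[float, ...]
    log_likelihood: float
    converged: bool
    n: int
    folded: bool
    category_proportions: tuple[float, float, float, float]
    category_se: tuple[float, float, float, float] | None = None
    n_bootstrap: int = 0

    def to_json_dict(self) -> dict:
        d = {
            "beta": self.beta,
            "s_mean": self.s_mean,
            "theta_sel": self.theta_sel,
            "theta_neu": self.theta_neu,
            "r": list(self.r),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n": self.n,
            "folded": self.folded,
            "category_proportions": list(self.category_proportions),
            "n_bootstrap": self.n_bootstrap,
        }
        if self.category_se is not None:
            d["category_se"] = list(self.category_se)
        return d


def _profiled_r(
    neu_counts: np.ndarray,
    sel_counts: np.ndarray,
    theta_neu: float,
    theta_sel: float,
    neu_shape: np.ndarray,
    sel_shape: np.ndarray,
) -> np.ndarray:
    """Closed-form MLE of the distortions r_2..r_K given the other parameters."""
    denom = theta_neu * neu_shape + theta_sel * sel_shape
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (neu_counts + sel_counts) / denom, 0.0)
    r[0] = 1.0
    return r


def _negloglik(
    logp: np.ndarray,
    sfs_pair: SFSPair,
    grid: QuadratureGrid,
    fit_distortions: bool,
) -> float:
    beta, s_mean, theta_sel, theta_neu = np.exp(logp)
    try:
        neu_shape, sel_shape = _class_shapes(beta, s_mean, grid, sfs_pair.folded)
        if fit_distortions:
            r = _profiled_r(
                sfs_pair.neutral_counts,
                sfs_pair.selected_counts,
                theta_neu,
                theta_sel,
                neu_shape,
                sel_shape,
            )
        else:
            r = np.ones_like(neu_shape)
        ll = _poisson_loglik(sfs_pair.neutral_counts, theta_neu * r * neu_shape)
        ll += _poisson_loglik(sfs_pair.selected_counts, theta_sel * r * sel_shape)
    except (ValueError, FloatingPointError):
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_dfe(sfs_pair: SFSPair, config: DFEFitConfig | None = None) -> DFEFit:
    """Maximum-likelihood gamma-DFE fit from multiple deterministic starts.

    The per-class distortions r_2..r_K are profiled out analytically at every
    objective evaluation; the optimizer runs over (beta, s_mean, theta_sel,
    theta_neu) on the log scale.  Non-convergence yields a flagged result,
    not an exception.
    """
    config = config or DFEFitConfig()
    if np.count_nonzero(sfs_pair.neutral_counts + sfs_pair.selected_counts) < 4:
        raise ValueError("need at least 4 frequency classes with data")
    grid = config.grid(sfs_pair.n)

    idx_sum_neu = _class_shapes(1.0, 0.0, grid, sfs_pair.folded)[0].sum()
    theta_neu0 = max(sfs_pair.neutral_counts.sum() / idx_sum_neu, 1e-6)
    theta_sel0 = max(sfs_pair.selected_counts.sum() / idx_sum_neu, 1e-6)

    bounds = [
        tuple(np.log(config.beta_bounds)),
        tuple(np.log(config.s_mean_bounds)),
        (np.log(theta_sel0) - 8.0, np.log(theta_sel0) + 8.0),
        (np.log(theta_neu0) - 8.0, np.log(theta_neu0) + 8.0),
    ]

    best = None
    for beta0 in config.beta_starts:
        for s0 in config.s_mean_starts:
            x0 = np.log([beta0, s0, theta_sel0, theta_neu0])
            res = scipy.optimize.minimize(
                _negloglik,
                x0,
                args=(sfs_pair, grid, config.fit_distortions),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res

    beta, s_mean, theta_sel, theta_neu = np.exp(best.x)
    neu_shape, sel_shape = _class_shapes(beta, s_mean, grid, sfs_pair.folded)
    if config.fit_distortions:
        r = _profiled_r(
            sfs_pair.neutral_counts,
            sfs_pair.selected_counts,
            theta_neu,
            theta_sel,
            neu_shape,
            sel_shape,
        )
    else:
        r = np.ones_like(neu_shape)

    props = category_proportions(beta, s_mean)
    ses = None
    if config.n_bootstrap > 0:
        ses = _bootstrap_category_se(
            beta, s_mean, theta_sel, theta_neu, r, sfs_pair, config, best.x
        )
    return DFEFit(
        beta=float(beta),
        s_mean=float(s_mean),
        theta_sel=float(theta_sel),
        theta_neu=float(theta_neu),
        r=tuple(float(x) for x in r),
        log_likelihood=float(-best.fun),
        converged=bool(best.success),
        n=sfs_pair.n,
        folded=sfs_pair.folded,
        category_proportions=props,
        category_se=ses,
        n_bootstrap=config.n_bootstrap,
    )


def _bootstrap_category_se(
    beta: float,
    s_mean: float,
    theta_sel: float,
    theta_neu: float,
    r: np.ndarray,
    sfs_pair: SFSPair,
    config: DFEFitConfig,
    x_hat: np.ndarray,
) -> tuple[float, float, float, float]:
    """Parametric-bootstrap SEs for the |S| category proportions (refit from
    the MLE as the single start)."""
    grid = config.grid(sfs_pair.n)
    neu_shape, sel_shape = _class_shapes(beta, s_mean, grid, sfs_pair.folded)
    mean_neu = theta_neu * r * neu_shape
    mean_sel = theta_sel * r * sel_shape
    rng = np.random.default_rng(config.seed)
    props = []
    bounds = [
        tuple(np.log(config.beta_bounds)),
        tuple(np.log(config.s_mean_bounds)),
        (x_hat[2] - 8.0, x_hat[2] + 8.0),
        (x_hat[3] - 8.0, x_hat[3] + 8.0),
    ]
    for _ in range(config.n_bootstrap):
        rep = SFSPair(
            n=sfs_pair.n,
            folded=sfs_pair.folded,
            neutral_counts=rng.poisson(mean_neu).astype(float),
            selected_counts=rng.poisson(mean_sel).astype(float),
        )
        res = scipy.optimize.minimize(
            _negloglik,
            x_hat,
            args=(rep, grid, config.fit_distortions),
            method="L-BFGS-B",
            bounds=bounds,
        )
        b, s = np.exp(res.x[:2])
        props.append(category_proportions(b, s))
    arr = np.array(props)
    return tuple(float(x) for x in arr.std(axis=0, ddof=1))


def category_proportions(
    beta: float, s_mean: float, breaks: Sequence[float] = (1.0, 10.0, 100.0)
) -> tuple[float, ...]:
    """Gamma-DFE mass over |S| in [0,1), [1,10), [10,100), [100,inf)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if s_mean < 0:
        raise ValueError("s_mean must be >= 0")
    if s_mean == 0:
        return tuple([1.0] + [0.0] * len(breaks))
    dist = scipy.stats.gamma(a=beta, scale=s_mean / beta)
    edges = [0.0, *breaks, np.inf]
    props = [float(dist.cdf(hi) - dist.cdf(lo)) for lo, hi in zip(edges[:-1], edges[1:])]
    return tuple(props)
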