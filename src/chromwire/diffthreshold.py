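"""Data-driven thresholds for differential-signal calling.

Two threshold rules are implemented. The fold-change rule fits the observed
log2 fold-change distribution with a three-component Gaussian mixture — a
central null component flanked by down- and up-regulated components — and
places the thresholds at the crossover points where the weighted component
densities intersect: beyond a crossover, the flanking component is the more
likely explanation of the observation. The FDR rule locates the inflection
point of the curve counting differential regions as a function of the FDR
cutoff.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MixtureFit",
    "ThresholdPair",
    "fit_three_gaussians",
    "crossover_points",
    "fdr_inflection",
]


@dataclasses.dataclass
class MixtureFit:
    """A fitted 3-component Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("means must be sorted ascending")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    def component_density(self, k: int, x: np.ndarray | float) -> np.ndarray | float:
        """Weighted density w_k * phi_k(x)."""
        return self.weights[k] * stats.norm.pdf(x, loc=self.means[k], scale=self.sds[k])


@dataclasses.dataclass(frozen=True)
class ThresholdPair:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")


class ComponentCollapseError(RuntimeError):
    """A mixture component collapsed onto too few points repeatedly."""


def _em(values: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray,
        max_iter: int, tol: float, sd_floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n = values.size
    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities in log space for stability
        logp = np.stack([
            np.log(w[k]) + stats.norm.logpdf(values, mu[k], sd[k]) for k in range(3)
        ])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            raise ComponentCollapseError("component responsibility vanished")
        w = nk / n
        mu = (resp @ values) / nk
        var = (resp @ (values**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, 0.0))
        if np.any(sd < sd_floor):
            raise ComponentCollapseError("component sd fell below floor")
        if (ll - prev_ll) / n < tol and it > 1:
            converged = True
            break
        prev_ll = ll
    return w, mu, sd, ll, it, converged


def fit_three_gaussians(
    values,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    sd_floor: float = 1e-3,
) -> MixtureFit:
    """Fit a 3-component Gaussian mixture to 1-D values by EM.

    Convergence is declared when the mean per-observation log-likelihood
    improves by less than ``tol`` in one iteration. Initialization is
    deterministic: component means at the 10th/50th/90th percentiles, equal
    weights, common sd from the data. The seed only
    drives the perturbed restarts taken when a component collapses below
    ``sd_floor``; after 5 failed restarts the degenerate input is reported.
    The log-likelihood is non-decreasing across EM iterations.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError("need at least 30 values for a 3-component fit")
    rng = np.random.default_rng(seed)
    mu0 = np.percentile(values, [10, 50, 90]).astype(float)
    sd0 = np.full(3, max(values.std() / 2, sd_floor * 10))
    w0 = np.full(3, 1 / 3)
    last_err: Exception | None = None
    for attempt in range(6):
        mu = mu0 if attempt == 0 else mu0 + rng.normal(0, values.std() / 4 + sd_floor, 3)
        try:
            w, m, s, ll, it, conv = _em(values, w0.copy(), np.sort(mu), sd0.copy(),
                                        max_iter, tol, sd_floor)
        except ComponentCollapseError as err:
            last_err = err
            continue
        order = np.argsort(m)
        return MixtureFit(weights=w[order], means=m[order], sds=s[order],
                          loglik=ll, n_iter=it, converged=conv)
    raise ComponentCollapseError(
        f"mixture fit failed after 5 perturbed restarts: {last_err}")


def _weighted_log_diff(fit: MixtureFit, i: int, j: int, weighted: bool):
    wi = np.log(fit.weights[i]) if weighted else 0.0
    wj = np.log(fit.weights[j]) if weighted else 0.0

    def f(x: float) -> float:
        return (wi + stats.norm.logpdf(x, fit.means[i], fit.sds[i])
                - wj - stats.norm.logpdf(x, fit.means[j], fit.sds[j]))

    return f


def _bracketed_root(f, lo: float, hi: float, label: str) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise ValueError(
            f"no crossover between components {label}: one weighted density "
            "dominates over the whole bracket")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def crossover_points(fit: MixtureFit, weighted: bool = True) -> ThresholdPair:
    """Thresholds at the intersections of adjacent mixture components.

    lower solves w1*phi1(x) = w2*phi2(x) between means 1 and 2; upper solves
    w2*phi2(x) = w3*phi3(x) between means 2 and 3. With ``weighted=False``
    the raw component densities are intersected instead. Roots are found by
    bracketed search on the log-density difference. Exactly equivariant
    under shifting and scaling of the fitted values.
    """
    if not fit.converged:
        warnings.warn("crossovers computed from a non-converged fit")
    if np.any(np.diff(fit.means) <= 0):
        raise ValueError("component means must be distinct")
    lower = _bracketed_root(_weighted_log_diff(fit, 0, 1, weighted),
                            fit.means[0], fit.means[1], "1-2")
    upper = _bracketed_root(_weighted_log_diff(fit, 1, 2, weighted),
                            fit.means[1], fit.means[2], "2-3")
    return ThresholdPair(lower=lower, upper=upper)


def fdr_inflection(qvalues, grid_points: int = 200, smooth_frac: float = 0.05) -> float:
    """FDR cutoff at the inflection of the discovery-count curve.

    Builds N(t) = #{q <= t} on a uniform grid over (0, max q], smooths it
    with a fixed-width moving average (width = smooth_frac * grid_points),
    and returns the grid point of maximum discrete curvature (absolute
    second difference) — where the count curve bends from the steep
    signal-dominated regime into the flat noise-dominated one. Degenerate
    inputs: a single distinct q-value is its own threshold; a near-linear
    curve (uniform q) has no bend and the upper grid boundary is returned
    with a warning.
    """
    q = np.asarray(qvalues, dtype=float)
    if q.size == 0:
        raise ValueError("no q-values")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q-values must lie in [0, 1]")
    distinct = np.unique(q)
    if distinct.size == 1:
        return float(distinct[0])
    if distinct.size < grid_points / 10:
        raise ValueError(
            f"only {distinct.size} distinct q-values for a {grid_points}-point grid; "
            "choose a threshold directly")
    from scipy.ndimage import uniform_filter1d

    grid = np.linspace(q.max() / grid_points, q.max(), grid_points)
    counts = np.searchsorted(np.sort(q), grid, side="right").astype(float)
    width = max(int(round(smooth_frac * grid_points)), 1)
    smooth = uniform_filter1d(counts, size=width, mode="nearest")
    curv = np.abs(np.diff(smooth, n=2))
    # a real bend towers over the sampling-noise curvature of a linear curve
    if curv.max() <= 10 * curv.mean():
        warnings.warn("no clear inflection (near-uniform q-values); returning grid boundary")
        return float(grid[-1])
    # interior index k of diff(n=2) corresponds to grid index k+1
    return float(grid[int(np.argmax(curv)) + 1])
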