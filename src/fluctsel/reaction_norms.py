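"""Selection reaction norms and their moments under Gaussian environments.

A selection reaction norm maps the environment (salinity deviation E from
2.4 M) to a per-day selection coefficient for the focal strain. The
univariate norm is quadratic,

    s(E) = a + b E + c E^2,

so that under a Gaussian environment E ~ N(mu, sigma^2) the selection
coefficient has closed-form mean and variance, and (for c != 0) a
displaced, scaled noncentral chi-square distribution with one degree of
freedom. The bivariate norm adds terms in the previous environment and
its interaction with the current one, capturing a one-transfer memory of
past salinity:

    s(E_prev, E_cur) = a' + b' E_cur + c' E_cur^2 + d E_prev + e E_prev^2
                       + f E_cur E_prev  (+ density and frequency terms).

A transfer schedule in which the environment is redrawn once per transfer
and held constant within it inflates the variance of cumulative
log-frequency change relative to daily redraws by sum(d_i^2)/sum(d_i);
for the alternating 3/4-day week this factor is 25/7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .environment import REFERENCE_SALINITY, SalinitySeries


@dataclass(frozen=True)
class ReactionNormUni:
    """Quadratic selection reaction norm s(E) = a + b E + c E^2 (per day)."""

    a: float
    b: float
    c: float

    def __call__(self, E):
        return selection_at(self, E)

    @property
    def breadth(self) -> float:
        """Breadth of the selective hump, 1/sqrt(-c) (requires c < 0).

        The curvature c has units of per day per M^2, so the quantity with
        units of salinity (M) is 1/sqrt(-c).
        """
        if self.c >= 0:
            raise ValueError("breadth defined only for concave norms (c < 0)")
        return 1.0 / np.sqrt(-self.c)


@dataclass(frozen=True)
class ReactionNormBi:
    """Bivariate selection reaction norm in current and previous environment.

    Optional ``g_density`` (per log10 cells/mL) and ``g_freq`` (per unit
    logit frequency) add density- and frequency-dependent selection terms.
    """

    a: float
    b: float
    c: float
    d: float = 0.0
    e: float = 0.0
    f: float = 0.0
    g_density: float = 0.0
    g_freq: float = 0.0

    def as_univariate(self) -> ReactionNormUni:
        if any(x != 0 for x in (self.d, self.e, self.f)):
            raise ValueError("norm has past-environment terms; no univariate reduction")
        return ReactionNormUni(self.a, self.b, self.c)


@dataclass
class ToleranceCurvePair:
    """Per-strain growth rates (per day) as functions of salinity (M).

    ``growth_C`` is the focal strain, ``growth_A`` the reference; the
    selection coefficient for C at salinity x is growth_C(x) - growth_A(x)
    under density- and frequency-independent selection.
    """

    growth_C: Callable[[np.ndarray], np.ndarray]
    growth_A: Callable[[np.ndarray], np.ndarray]


def selection_at(rn: ReactionNormUni, E):
    """Selection coefficient (per day) at environmental deviation E."""
    E = np.asarray(E, dtype=float)
    out = rn.a + rn.b * E + rn.c * E * E
    return out.item() if out.ndim == 0 else out


def optimum_and_max(rn: ReactionNormUni):
    """Optimal salinity (M) and maximal selection of a concave norm.

    The optimum deviation is E* = -b/(2c); returns
    ``(2.4 + E*, a - b^2/(4c))``.
    """
    if rn.c >= 0:
        raise ValueError("no interior maximum: c must be < 0")
    e_star = -rn.b / (2 * rn.c)
    s_max = rn.a - rn.b**2 / (4 * rn.c)
    return REFERENCE_SALINITY + e_star, s_max


def mean_selection_gaussian(rn: ReactionNormUni, mu: float, sigma2: float) -> float:
    """Mean selection under E ~ N(mu, sigma2): a + b mu + c (mu^2 + sigma2).

    With c < 0 the environmental variance *reduces* mean selection by
    c*sigma2 (Jensen's inequality on a concave norm), independently of mu.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    return rn.a + rn.b * mu + rn.c * (mu * mu + sigma2)


def var_selection_gaussian(rn: ReactionNormUni, mu: float, sigma2: float) -> float:
    """Variance of selection under E ~ N(mu, sigma2).

    Exact Gaussian moment identity:

        var(bE + cE^2) = sigma2 * (b^2 + 4 b c mu + 2 c^2 (sigma2 + 2 mu^2)).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    b, c = rn.b, rn.c
    return sigma2 * (b * b + 4 * b * c * mu + 2 * c * c * (sigma2 + 2 * mu * mu))


class SelectionDistribution:
    """Distribution of s = a + bE + cE^2 for E ~ N(mu, sigma2).

    For c = 0 this is normal. For c != 0, completing the square gives

        s = s_max + c * sigma2 * W,   W ~ chi2_1(lambda),

    with ``s_max = a - b^2/(4c)`` and noncentrality
    ``lambda = (mu + b/(2c))^2 / sigma2`` — a displaced, scaled (possibly
    negatively, when c < 0, hence left-skewed) noncentral chi-square with
    one degree of freedom.
    """

    def __init__(self, rn: ReactionNormUni, mu: float, sigma2: float):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be > 0 (point mass otherwise)")
        self.rn = rn
        self.mu = float(mu)
        self.sigma2 = float(sigma2)
        if rn.c == 0:
            self.kind = "normal"
            self._dist = stats.norm(rn.a + rn.b * mu, np.sqrt(rn.b**2 * sigma2))
            self.location = rn.a + rn.b * mu
            self.scale = np.sqrt(rn.b**2 * sigma2)
            self.noncentrality = None
        else:
            self.kind = "displaced-noncentral-chi-square"
            self.location = rn.a - rn.b**2 / (4 * rn.c)  # s at the optimum
            self.scale = rn.c * sigma2  # signed scale of the chi-square part
            self.noncentrality = (mu + rn.b / (2 * rn.c)) ** 2 / sigma2
            self._dist = stats.ncx2(df=1, nc=self.noncentrality)

    @property
    def mean(self) -> float:
        return mean_selection_gaussian(self.rn, self.mu, self.sigma2)

    @property
    def variance(self) -> float:
        return var_selection_gaussian(self.rn, self.mu, self.sigma2)

    def _w(self, s):
        return (np.asarray(s, dtype=float) - self.location) / self.scale

    def pdf(self, s):
        if self.kind == "normal":
            return self._dist.pdf(s)
        return self._dist.pdf(self._w(s)) / abs(self.scale)

    def cdf(self, s):
        if self.kind == "normal":
            return self._dist.cdf(s)
        if self.scale > 0:
            return self._dist.cdf(self._w(s))
        return self._dist.sf(self._w(s))

    def rvs(self, size, seed=None):
        rng = np.random.default_rng(seed)
        E = self.mu + np.sqrt(self.sigma2) * rng.standard_normal(size)
        return selection_at(self.rn, E)


def selection_distribution(rn: ReactionNormUni, mu: float, sigma2: float) -> SelectionDistribution:
    """Closed-form distribution of selection coefficients under a Gaussian environment."""
    return SelectionDistribution(rn, mu, sigma2)


def bivariate_selection_at(
    rnb: ReactionNormBi,
    E_prev,
    E_cur,
    log10_density: Optional[float] = None,
    logit_freq: Optional[float] = None,
):
    """Evaluate the bivariate norm, optionally with density/frequency terms."""
    E_prev = np.asarray(E_prev, dtype=float)
    E_cur = np.asarray(E_cur, dtype=float)
    s = (
        rnb.a
        + rnb.b * E_cur
        + rnb.c * E_cur**2
        + rnb.d * E_prev
        + rnb.e * E_prev**2
        + rnb.f * E_cur * E_prev
    )
    if log10_density is not None:
        s = s + rnb.g_density * np.asarray(log10_density, dtype=float)
    if logit_freq is not None:
        s = s + rnb.g_freq * np.asarray(logit_freq, dtype=float)
    return s.item() if np.ndim(s) == 0 else s


def bivariate_mean_selection(rnb: ReactionNormBi, mu: float, sigma2: float, rho: float) -> float:
    """Mean of the bivariate norm under binormal (E_prev, E_cur).

    Both margins are N(mu, sigma2) with correlation rho (the environment's
    lag-1 autocorrelation). The result,

        a' + (b'+d) mu + (c'+e)(mu^2 + sigma2) + f (mu^2 + rho sigma2),

    is affine in rho with slope f*sigma2: only the interaction term makes
    mean selection respond to environmental autocorrelation.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    m2 = mu * mu
    return (
        rnb.a
        + (rnb.b + rnb.d) * mu
        + (rnb.c + rnb.e) * (m2 + sigma2)
        + rnb.f * (m2 + rho * sigma2)
    )


def bivariate_var_selection_exact(rnb: ReactionNormBi, mu: float, sigma2: float, rho: float) -> float:
    """Exact variance of the bivariate norm under the binormal law.

    Gaussian moment expansion (Isserlis): with centred x = E_cur - mu,
    y = E_prev - mu, the linear and quadratic parts are uncorrelated and

        var = B^2 s2 + D^2 s2 + 2 B D rho s2
              + 2 c'^2 s4 + 2 e^2 s4 + f^2 s4 (1 + rho^2)
              + 4 c' e rho^2 s4 + 4 (c' + e) f rho s4,

    with B = b' + (2c'+f) mu, D = d + (2e+f) mu, s2 = sigma2, s4 = sigma2^2.
    """
    b, c, d, e, f = rnb.b, rnb.c, rnb.d, rnb.e, rnb.f
    s2 = sigma2
    s4 = sigma2 * sigma2
    B = b + (2 * c + f) * mu
    D = d + (2 * e + f) * mu
    lin = B * B * s2 + D * D * s2 + 2 * B * D * rho * s2
    quad = (
        2 * c * c * s4
        + 2 * e * e * s4
        + f * f * s4 * (1 + rho * rho)
        + 4 * c * e * rho * rho * s4
        + 4 * (c + e) * f * rho * s4
    )
    return lin + quad


def bivariate_var_selection(
    rnb: ReactionNormBi,
    mu: float,
    sigma2: float,
    rho: float,
    method: str = "monte-carlo",
    n_draws: int = 1_000_000,
    seed: int = 2024,
) -> float:
    """Variance of the bivariate norm under the binormal law.

    Default is seeded Monte Carlo over ``n_draws`` binormal pairs; the
    exact Gaussian moment expansion is available as ``method='exact'``
    and serves as the independent cross-check.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if method == "exact":
        return bivariate_var_selection_exact(rnb, mu, sigma2, rho)
    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(sigma2)
    z1 = rng.standard_normal(n_draws)
    z2 = rng.standard_normal(n_draws)
    e_prev = mu + sd * z1
    e_cur = mu + sd * (rho * z1 + np.sqrt(1 - rho * rho) * z2)
    s = bivariate_selection_at(rnb, e_prev, e_cur)
    return float(np.var(s))


def variance_inflation_factor(durations_in_cycle) -> float:
    """Variance inflation from block-constant selection within transfers.

    If the selection coefficient is redrawn independently once per transfer
    and held constant for its d_i days, the cumulative logit change over a
    cycle has variance sum(d_i^2) * var(s); under daily redraws it would be
    sum(d_i) * var(s). The ratio sum(d_i^2)/sum(d_i) is 25/7 for the
    alternating 3/4-day week.
    """
    d = np.asarray(durations_in_cycle, dtype=float)
    if d.size == 0:
        raise ValueError("durations_in_cycle must be non-empty")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(np.sum(d * d) / np.sum(d))


def selection_from_tolerance(
    pair: ToleranceCurvePair,
    E_grid=None,
) -> ReactionNormUni:
    """Predict the selection reaction norm from a pair of tolerance curves.

    Evaluates s(x) = growth_C(x) - growth_A(x) on a salinity grid
    (default 0 to 4.8 M, step 0.1) and least-squares fits a quadratic in
    the deviation E = x - 2.4, returning its (a, b, c). Strains with equal
    tolerance breadths give c ~ 0 and hence a Gaussian distribution of
    selection under a Gaussian environment.
    """
    if E_grid is None:
        grid_M = np.arange(0.0, 4.8 + 1e-9, 0.1)
        E_grid = grid_M - REFERENCE_SALINITY
    E_grid = np.asarray(E_grid, dtype=float)
    if E_grid.size < 3:
        raise ValueError("need at least 3 grid points to fit a quadratic")
    x = E_grid + REFERENCE_SALINITY
    s = np.asarray(pair.growth_C(x), dtype=float) - np.asarray(pair.growth_A(x), dtype=float)
    # polyfit returns highest degree first
    c, b, a = np.polyfit(E_grid, s, 2)
    return ReactionNormUni(float(a), float(b), float(c))


def predict_trajectory(rn, series: SalinitySeries, psi0: float) -> np.ndarray:
    """Mean logit-frequency at the end of each transfer.

    psi(day of transfer k) = psi0 + sum_{j<=k} duration_j * s_j, where s_j
    uses the salinity applied during interval j. For a bivariate norm the
    previous interval's salinity is used as E_prev (the first interval
    reuses its own salinity). Within a transfer the trajectory is linear
    in time.
    """
    E = series.deviations
    d = series.durations
    if isinstance(rn, ReactionNormBi):
        E_prev = np.concatenate([[E[0]], E[:-1]])
        s = bivariate_selection_at(rn, E_prev, E)
    else:
        s = selection_at(rn, E)
    return psi0 + np.cumsum(np.asarray(s) * d)


def predicted_trajectory_frame(rn, series_list, psi0: float):
    """Long-format table of predicted mean logits: line_id, transfer, day, psi_mean."""
    import pandas as pd

    rows = []
    for series in series_list:
        traj = predict_trajectory(rn, series, psi0)
        for k, psi in enumerate(traj):
            rows.append((series.line_id, k + 1, series.start_days[k], psi))
    return pd.DataFrame(rows, columns=["line_id", "transfer", "day", "psi_mean"])
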