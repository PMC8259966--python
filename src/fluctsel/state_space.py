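"""Latent-Gaussian state-space logistic regression of strain frequency.

The true logit frequency psi of the focal strain in each experimental
line is modelled as a Gaussian process over time (days), with drift given
by the mean selection coefficient — a linear function of the line's
environmental covariates (mean mu_E, squared mean, variance sigma2_E and
predictability rho_E^2 of salinity) — and Brownian-type variance growth:

    E[psi(t)]            = psi0_mean + s_bar * t
    cov[psi(t1), psi(t2)] = V(psi0) + (25/7) * sigma_s^2 * min(t1, t2)

with sigma_s^2 = sigma0^2 in constant treatments and sigma1^2 in
fluctuating ones. The 25/7 factor corrects for selection being redrawn
once per transfer and held constant within the alternating 3/4-day
intervals. Observations are read counts at two loci, conditionally
independent binomials given psi: the chloroplast success probability is
logit^-1(psi), the ITS2 one alpha + beta * logit^-1(psi) (shared
haplotype calibration). The latent vector of each line is integrated out
by a Laplace approximation (inner Newton ascent to the joint mode plus a
Gaussian curvature correction), and the marginal likelihood is maximised
over fixed effects and log-variance components by quasi-Newton descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .barcode import DEFAULT_ITS2_CALIBRATION, CalibrationMap
from .reaction_norms import variance_inflation_factor

#: Variance inflation for the alternating 3/4-day transfer schedule.
DEFAULT_VIF = variance_inflation_factor([3, 4])

_TERM_FUNCS = {
    "intercept": lambda mu, s2, rho: 1.0,
    "mu": lambda mu, s2, rho: mu,
    "mu2": lambda mu, s2, rho: mu * mu,
    "sigma2": lambda mu, s2, rho: s2,
    "rho2": lambda mu, s2, rho: rho * rho,
    "rho": lambda mu, s2, rho: rho,
}

_LOG_VARIANCE_FLOOR = -25.0  # log-scale lower bound; effectively zero variance


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects and variance components are free.

    ``mean_terms`` lists the covariate terms of the mean selection
    coefficient; ``variance_structure`` is one of

    - ``"by_fluctuation"``: sigma0^2 for constant, sigma1^2 for
      fluctuating treatments (the selected model),
    - ``"pooled"``: a single selection variance,
    - ``"by_autocorrelation"``: sigma1^2 + theta6 * rho_E in fluctuating
      treatments (the variant that failed to converge on the real data;
      non-convergence is a reportable outcome, not an exception).
    """

    mean_terms: Tuple[str, ...] = ("intercept", "mu", "mu2", "sigma2", "rho2")
    variance_structure: str = "by_fluctuation"
    estimate_calibration: bool = False

    def __post_init__(self):
        for t in self.mean_terms:
            if t not in _TERM_FUNCS:
                raise ValueError(f"unknown mean term {t!r}")
        if self.variance_structure not in ("by_fluctuation", "pooled", "by_autocorrelation"):
            raise ValueError(f"unknown variance structure {self.variance_structure!r}")

    @property
    def param_names(self) -> List[str]:
        names = [f"theta_{t}" for t in self.mean_terms] + ["psi0_mean", "v_psi0"]
        if self.variance_structure == "pooled":
            names += ["sigma_sq"]
        else:
            names += ["sigma0_sq", "sigma1_sq"]
            if self.variance_structure == "by_autocorrelation":
                names += ["theta6"]
        if self.estimate_calibration:
            names += ["alpha", "beta"]
        return names

    def n_free(self) -> int:
        return len(self.param_names)


#: The model selected on the real data (Eq-1 analogue).
SELECTED_MODEL = ModelSpec()
#: The full model that also includes an unsquared-autocorrelation effect.
FULL_MODEL = ModelSpec(mean_terms=("intercept", "mu", "mu2", "sigma2", "rho2", "rho"))


@dataclass
class LineObs:
    """Observed read counts of one line at its sequenced days.

    Arrays are aligned over timepoints: ``n/N`` chloroplast C and total
    reads, ``m/M`` the ITS2 ones. ``mu`` is the treatment mean salinity as
    deviation from 2.4 M; ``sigma2`` and ``rho`` its variance and
    autocorrelation.
    """

    line_id: str
    days: np.ndarray
    n: np.ndarray
    N: np.ndarray
    m: np.ndarray
    M: np.ndarray
    mu: float
    sigma2: float
    rho: float

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        for name in ("n", "N", "m", "M"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        keep = (self.N > 0) | (self.M > 0)
        if not np.all(keep):  # zero-depth timepoints carry no information
            for name in ("days", "n", "N", "m", "M"):
                setattr(self, name, getattr(self, name)[keep])
        if np.any(self.n > self.N) or np.any(self.m > self.M):
            raise ValueError(f"line {self.line_id}: allele counts exceed depth")

    @property
    def n_obs(self) -> int:
        return len(self.days)

    @property
    def is_fluctuating(self) -> bool:
        return self.sigma2 != 0


def lines_from_frames(counts: pd.DataFrame, treatments: pd.DataFrame) -> List[LineObs]:
    """Build per-line observations from long counts and treatment tables.

    ``counts`` columns: line_id, transfer, day, locus (``chloroplast`` or
    ``its2``), n_C, N_total. ``treatments`` columns: line_id, mean
    (salinity in M), variance, autocorrelation.
    """
    treat = treatments.set_index("line_id")
    lines = []
    for line_id, sub in counts.groupby("line_id", sort=True):
        wide = {}
        for _, row in sub.iterrows():
            rec = wide.setdefault(float(row["day"]), [0.0, 0.0, 0.0, 0.0])
            if row["locus"] == "chloroplast":
                rec[0], rec[1] = row["n_C"], row["N_total"]
            elif row["locus"] == "its2":
                rec[2], rec[3] = row["n_C"], row["N_total"]
            else:
                raise ValueError(f"unknown locus {row['locus']!r}")
        days = np.array(sorted(wide))
        arr = np.array([wide[d] for d in days])
        trow = treat.loc[line_id]
        lines.append(
            LineObs(
                str(line_id),
                days,
                arr[:, 0],
                arr[:, 1],
                arr[:, 2],
                arr[:, 3],
                mu=float(trow["mean"]) - 2.4,
                sigma2=float(trow["variance"]),
                rho=float(trow["autocorrelation"]),
            )
        )
    return [ln for ln in lines if ln.n_obs > 0]


# ---------------------------------------------------------------------------
# observation model


def _obs_loglik(psi, n, N, m, M, alpha, beta):
    """Binomial log-likelihood of both loci given latent logits psi."""
    ll = n * special.log_expit(psi) + (N - n) * special.log_expit(-psi)
    p = special.expit(psi)
    q = np.clip(alpha + beta * p, 1e-12, 1 - 1e-12)
    ll = ll + m * np.log(q) + (M - m) * np.log1p(-q)
    return ll


def _obs_derivs(psi, n, N, m, M, alpha, beta):
    """Gradient, (negative) true curvature and Fisher curvature per element."""
    p = special.expit(psi)
    v = p * (1 - p)
    q = np.clip(alpha + beta * p, 1e-12, 1 - 1e-12)
    g_chl = n - N * p
    w_chl = N * v  # -d2, also the Fisher information
    r = m / q - (M - m) / (1 - q)
    qprime = beta * v
    g_its = r * qprime
    h_its_true = (-m / q**2 - (M - m) / (1 - q) ** 2) * qprime**2 + r * beta * v * (1 - 2 * p)
    w_its_fisher = M * qprime**2 / (q * (1 - q))
    grad = g_chl + g_its
    w_true = w_chl - h_its_true
    w_fisher = w_chl + w_its_fisher
    return grad, w_true, w_fisher


# ---------------------------------------------------------------------------
# Laplace machinery


class _Group:
    """Lines sharing one sequencing-day pattern and one treatment."""

    def __init__(self, days: np.ndarray, lines: List[LineObs]):
        self.days = days
        self.k = len(days)
        self.lines = lines
        self.n = np.stack([ln.n for ln in lines])
        self.N = np.stack([ln.N for ln in lines])
        self.m = np.stack([ln.m for ln in lines])
        self.M = np.stack([ln.M for ln in lines])
        self.mu = lines[0].mu
        self.sigma2 = lines[0].sigma2
        self.rho = lines[0].rho
        self.min_days = np.minimum.outer(days, days)
        # warm start at the empirical chloroplast logit (ITS2 fallback)
        p_hat = np.where(
            self.N > 0,
            (self.n + 0.5) / (self.N + 1.0),
            np.clip(((self.m + 0.5) / (self.M + 1.0) - 0.19) / 0.79, 0.02, 0.98),
        )
        self.psi_warm = special.logit(np.clip(p_hat, 1e-4, 1 - 1e-4))


def _build_groups(lines: Sequence[LineObs]) -> List[_Group]:
    buckets: Dict[tuple, List[LineObs]] = {}
    for ln in lines:
        key = (tuple(ln.days), ln.mu, ln.sigma2, ln.rho)
        buckets.setdefault(key, []).append(ln)
    return [_Group(np.array(key[0]), lns) for key, lns in buckets.items()]


def _group_laplace(
    group: _Group,
    mean_vec: np.ndarray,
    v_psi0: float,
    sigma_sq: float,
    alpha: float,
    beta: float,
    vif: float = DEFAULT_VIF,
    max_iter: int = 100,
    grad_tol: float = 1e-6,
):
    """Laplace-approximated marginal log-likelihood of every line in a group.

    Returns ``(loglik_per_line, posterior_modes)``; updates the group's
    warm start in place.
    """
    k = group.k
    Sigma = v_psi0 + vif * sigma_sq * group.min_days
    Sigma = Sigma + 1e-10 * np.eye(k)  # floor for degenerate (zero-noise) fits
    L = np.linalg.cholesky(Sigma)
    logdet_Sigma = 2.0 * np.sum(np.log(np.diag(L)))
    Sigma_inv = np.linalg.inv(Sigma)

    psi = group.psi_warm.copy()

    def objective(psi_mat):
        resid = psi_mat - mean_vec
        quad = np.einsum("li,ij,lj->l", resid, Sigma_inv, resid)
        obs = _obs_loglik(psi_mat, group.n, group.N, group.m, group.M, alpha, beta).sum(axis=1)
        return obs - 0.5 * quad

    f = objective(psi)
    for _ in range(max_iter):
        g_obs, _, w_fish = _obs_derivs(psi, group.n, group.N, group.m, group.M, alpha, beta)
        grad = g_obs - (psi - mean_vec) @ Sigma_inv
        if np.max(np.abs(grad)) < grad_tol:
            break
        A = Sigma_inv[None, :, :] + w_fish[:, :, None] * np.eye(k)[None, :, :]
        step = np.linalg.solve(A, grad[:, :, None])[:, :, 0]
        # backtracking: Fisher metric guarantees an ascent direction; the
        # acceptance slack avoids spinning on rounding noise near the mode
        scale = np.ones(len(psi))
        slack = 1e-9 * (1.0 + np.abs(f))
        for _ in range(15):
            f_new = objective(psi + scale[:, None] * step)
            bad = f_new < f - slack
            if not np.any(bad):
                break
            scale[bad] *= 0.5
        psi = psi + scale[:, None] * step
        f = f_new

    group.psi_warm = psi
    _, w_true, w_fish = _obs_derivs(psi, group.n, group.N, group.m, group.M, alpha, beta)
    # curvature at the mode; fall back to Fisher curvature if non-PD
    w = w_true
    A = Sigma_inv[None, :, :] + w[:, :, None] * np.eye(k)[None, :, :]
    sign, logdet_A = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        bad = sign <= 0
        w = np.where(bad[:, None], w_fish, w_true)
        A = Sigma_inv[None, :, :] + w[:, :, None] * np.eye(k)[None, :, :]
        sign, logdet_A = np.linalg.slogdet(A)
    ll = f - 0.5 * logdet_Sigma - 0.5 * logdet_A
    return ll, psi


def _variance_for(group: _Group, params: Dict[str, float], spec: ModelSpec) -> float:
    if spec.variance_structure == "pooled":
        return params["sigma_sq"]
    if group.sigma2 == 0:
        return params["sigma0_sq"]
    s = params["sigma1_sq"]
    if spec.variance_structure == "by_autocorrelation":
        s = s + params["theta6"] * group.rho
    return s


def _mean_selection(group_or_line, params: Dict[str, float], spec: ModelSpec) -> float:
    return sum(
        params[f"theta_{t}"] * _TERM_FUNCS[t](group_or_line.mu, group_or_line.sigma2, group_or_line.rho)
        for t in spec.mean_terms
    )


def marginal_loglik(
    params: Dict[str, float],
    lines: Sequence[LineObs],
    model: ModelSpec = SELECTED_MODEL,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
    vif: float = DEFAULT_VIF,
    groups: Optional[List[_Group]] = None,
    return_latents: bool = False,
):
    """Total Laplace-approximated marginal log-likelihood over lines.

    ``params`` maps parameter names (see :meth:`ModelSpec.param_names`)
    to values, variances on the natural scale. Lines with no positive
    depth contribute zero. Returns the scalar log-likelihood, or
    ``(loglik, latents)`` with per-line posterior modes when
    ``return_latents`` is true.
    """
    if groups is None:
        groups = _build_groups(lines)
    alpha = params.get("alpha", calibration.alpha)
    beta = params.get("beta", calibration.beta)
    if not (0 <= alpha and alpha + beta <= 1 + 1e-9 and beta > 0):
        raise ValueError(f"invalid calibration alpha={alpha}, beta={beta}")
    total = 0.0
    latents = []
    for g in groups:
        sigma_sq = _variance_for(g, params, model)
        if sigma_sq < 0 or params["v_psi0"] < 0:
            return (-np.inf, None) if return_latents else -np.inf
        s_bar = _mean_selection(g, params, model)
        mean_vec = params["psi0_mean"] + s_bar * g.days
        ll, psi = _group_laplace(g, mean_vec, params["v_psi0"], sigma_sq, alpha, beta, vif)
        if not np.all(np.isfinite(ll)):
            return (-np.inf, None) if return_latents else -np.inf
        total += float(np.sum(ll))
        if return_latents:
            for i, ln in enumerate(g.lines):
                latents.append((ln.line_id, g.days, psi[i]))
    if return_latents:
        return total, latents
    return total


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-marginal-likelihood fit of the state-space model."""

    model: ModelSpec
    params: Dict[str, float]
    se: Dict[str, float]
    cov: pd.DataFrame
    loglik: float
    converged: bool
    message: str
    n_lines: int
    n_obs: int
    latents: pd.DataFrame
    calibration: CalibrationMap

    @property
    def n_free(self) -> int:
        return self.model.n_free()

    def summary(self) -> pd.DataFrame:
        """Parameter table: term, estimate, SE, Wald p-value."""
        rows = []
        for name in self.model.param_names:
            est = self.params[name]
            se = self.se.get(name, np.nan)
            if np.isfinite(se) and se > 0:
                p = 2 * stats.norm.sf(abs(est) / se)
            else:
                p = np.nan
            rows.append((name, est, se, p))
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "p_value"])


def _pack(params: Dict[str, float], spec: ModelSpec) -> np.ndarray:
    x = []
    for name in spec.param_names:
        v = params[name]
        if name in ("v_psi0", "sigma_sq", "sigma0_sq", "sigma1_sq"):
            v = np.log(max(v, np.exp(_LOG_VARIANCE_FLOOR)))
        x.append(v)
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, spec: ModelSpec) -> Dict[str, float]:
    params = {}
    for name, v in zip(spec.param_names, x):
        if name in ("v_psi0", "sigma_sq", "sigma0_sq", "sigma1_sq"):
            v = np.exp(v)
        params[name] = float(v)
    return params


def default_start(lines: Sequence[LineObs], model: ModelSpec) -> Dict[str, float]:
    """Start values from an ordinary regression on empirical logits."""
    rows, y = [], []
    for ln in lines:
        with np.errstate(divide="ignore"):
            p_hat = np.where(ln.N > 0, (ln.n + 0.5) / (ln.N + 1.0), np.nan)
        for t, p in zip(ln.days, p_hat):
            if not np.isfinite(p):
                continue
            x = [1.0] + [t * _TERM_FUNCS[term](ln.mu, ln.sigma2, ln.rho) for term in model.mean_terms]
            rows.append(x)
            y.append(special.logit(np.clip(p, 1e-4, 1 - 1e-4)))
    X = np.array(rows)
    y = np.array(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    params = {"psi0_mean": float(beta[0])}
    for j, term in enumerate(model.mean_terms):
        params[f"theta_{term}"] = float(beta[j + 1])
    resid = y - X @ beta
    # crude per-day residual variance as a variance-component seed
    t_all = X[:, 1] if "intercept" in model.mean_terms else np.ones(len(y))
    denom = DEFAULT_VIF * np.clip(np.abs(t_all), 1.0, None)
    v_seed = float(np.clip(np.mean(resid**2 / denom), 1e-3, 1.0))
    params["v_psi0"] = 0.01
    if model.variance_structure == "pooled":
        params["sigma_sq"] = v_seed
    else:
        params["sigma0_sq"] = v_seed / 2
        params["sigma1_sq"] = v_seed
        if model.variance_structure == "by_autocorrelation":
            params["theta6"] = 0.0
    if model.estimate_calibration:
        params["alpha"] = DEFAULT_ITS2_CALIBRATION.alpha
        params["beta"] = DEFAULT_ITS2_CALIBRATION.beta
    return params


def fit(
    lines: Sequence[LineObs],
    model: ModelSpec = SELECTED_MODEL,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
    start: Optional[Dict[str, float]] = None,
    vif: float = DEFAULT_VIF,
    compute_cov: bool = True,
    maxiter: int = 500,
    ftol: float = 1e-14,
    restarts: int = 4,
) -> FitResult:
    """Maximise the Laplace marginal likelihood over the model's parameters.

    Variance components are optimised on the log scale (bounded below at
    an effectively-zero floor, so boundary estimates like V(psi0) ~ 0 are
    representable); the covariance matrix comes from the inverse numerical
    Hessian, delta-transformed back to natural scale. Non-convergence is
    reported through ``converged``/``message``, not raised.
    """
    lines = [ln for ln in lines if ln.n_obs > 0]
    if not lines:
        raise ValueError("no lines with data")
    groups = _build_groups(lines)
    if start is None:
        start = default_start(lines, model)
    x0 = _pack(start, model)
    names = model.param_names
    is_logvar = np.array([n in ("v_psi0", "sigma_sq", "sigma0_sq", "sigma1_sq") for n in names])

    def negll(x):
        try:
            ll = marginal_loglik(_unpack(x, model), lines, model, calibration, vif, groups)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def negll_grad(x):
        # central differences with parameter-relative steps: parameter scales
        # span several orders of magnitude (per-day rates vs log variances)
        g = np.zeros_like(x)
        for i in range(len(x)):
            h = 1e-5 * max(1.0, abs(x[i]))
            xp = x.copy()
            xp[i] += h
            xm = x.copy()
            xm[i] -= h
            g[i] = (negll(xp) - negll(xm)) / (2 * h)
        return g

    bounds = [
        (_LOG_VARIANCE_FLOOR, 5.0) if lv else (None, None) for lv in is_logvar
    ]
    if model.estimate_calibration:
        for i, n in enumerate(names):
            if n == "alpha":
                bounds[i] = (0.0, 0.6)
            elif n == "beta":
                bounds[i] = (0.05, 1.0)
    # quasi-Newton with restarts: restarting clears the L-BFGS curvature
    # memory, which helps when stiff (theta) and flat (boundary variance)
    # directions coexist
    x, f_prev = x0, np.inf
    for _ in range(max(restarts, 1)):
        res = optimize.minimize(
            negll,
            x,
            jac=negll_grad,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-5},
        )
        x = res.x
        if f_prev - res.fun < 1e-4:
            break
        f_prev = res.fun
    params = _unpack(res.x, model)
    loglik, latents = marginal_loglik(
        params, lines, model, calibration, vif, groups, return_latents=True
    )

    se = {n: np.nan for n in names}
    cov_nat = np.full((len(names), len(names)), np.nan)
    if compute_cov:
        try:
            # Hessian as the Jacobian of the central-difference gradient,
            # with parameter-relative steps; symmetrised, pseudo-inverted
            # (variance components pinned at the floor have ~zero curvature)
            nn = len(res.x)
            H = np.zeros((nn, nn))
            for i in range(nn):
                h = 1e-3 * max(1.0, abs(res.x[i]))
                xp = res.x.copy()
                xp[i] += h
                xm = res.x.copy()
                xm[i] -= h
                H[:, i] = (negll_grad(xp) - negll_grad(xm)) / (2 * h)
            H = 0.5 * (H + H.T)
            # invert on the well-conditioned eigenspace only: a variance
            # component resting on its floor leaves a flat (numerically
            # even slightly negative) direction that must not leak into
            # the other parameters' standard errors
            ev, V = np.linalg.eigh(H)
            keep = ev > ev.max() * 1e-8
            cov_log = (V[:, keep] / ev[keep]) @ V[:, keep].T
            dropped_weight = (V[:, ~keep] ** 2).sum(axis=1) if np.any(~keep) else np.zeros(nn)
            jac = np.array([params[n] if lv else 1.0 for n, lv in zip(names, is_logvar)])
            cov_nat = cov_log * np.outer(jac, jac)
            for i, n in enumerate(names):
                if dropped_weight[i] > 0.5:
                    continue  # parameter lies in the unidentified subspace
                if np.isfinite(cov_nat[i, i]) and cov_nat[i, i] >= 0:
                    se[n] = float(np.sqrt(cov_nat[i, i]))
        except (np.linalg.LinAlgError, ValueError):
            pass

    lat_rows = []
    for line_id, days, psi in latents or []:
        for d, v in zip(days, psi):
            lat_rows.append((line_id, d, v))
    lat_df = pd.DataFrame(lat_rows, columns=["line_id", "day", "psi_mode"])

    grad_ok = res.success or "CONVERGENCE" in str(res.message).upper()
    cal = CalibrationMap(params.get("alpha", calibration.alpha), params.get("beta", calibration.beta))
    return FitResult(
        model=model,
        params=params,
        se=se,
        cov=pd.DataFrame(cov_nat, index=names, columns=names),
        loglik=float(loglik),
        converged=bool(grad_ok and np.isfinite(loglik)),
        message=str(res.message),
        n_lines=len(lines),
        n_obs=int(sum(ln.n_obs for ln in lines)),
        latents=lat_df,
        calibration=cal,
    )


# ---------------------------------------------------------------------------
# tests, intervals, bootstrap


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    kind: str


def wald_test(
    fit_result: FitResult,
    parameter,
    value: float = 0.0,
) -> TestResult:
    """Two-sided Wald test of a parameter (or linear contrast) against a value.

    ``parameter`` is a name, or a dict name -> weight defining a contrast
    sum(w_i * param_i) tested against ``value``.
    """
    if isinstance(parameter, str):
        parameter = {parameter: 1.0}
    names = list(parameter)
    w = np.array([parameter[n] for n in names])
    est = float(sum(parameter[n] * fit_result.params[n] for n in names))
    sub = fit_result.cov.loc[names, names].to_numpy()
    var = float(w @ sub @ w)
    if not np.isfinite(var) or var <= 0:
        raise ValueError("contrast has zero or undefined standard error")
    z = (est - value) / np.sqrt(var)
    return TestResult(float(z), 1, float(2 * stats.norm.sf(abs(z))), "Wald")


def lr_test(fit_full: FitResult, fit_reduced: FitResult, tol: float = 0.05) -> TestResult:
    """Likelihood-ratio test of nested Laplace fits (chi-square reference).

    Negative statistics within ``tol`` log-likelihood units (optimizer
    termination noise, far below any chi-square critical value) are
    clamped to zero; larger ones indicate an optimization failure.
    """
    df = fit_full.n_free - fit_reduced.n_free
    if df <= 0:
        raise ValueError("full model must have more free parameters")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -tol:
        raise RuntimeError(
            f"full model log-likelihood below reduced ({stat/2:.4g}); optimization failure"
        )
    stat = max(stat, 0.0)
    return TestResult(float(stat), df, float(stats.chi2.sf(stat, df)), "LR")


def mean_selection_ci(fit_result: FitResult, rho: float, level: float = 0.95):
    """Delta-method CI for mean selection in a fluctuating treatment.

    s_bar(rho) = theta_intercept + theta_sigma2 + theta_rho2 * rho^2 at
    mu_E = 0, sigma_E^2 = 1. Returns ``(estimate, lower, upper)``.
    """
    contrast = {"theta_intercept": 1.0, "theta_sigma2": 1.0, "theta_rho2": rho * rho}
    names = list(contrast)
    w = np.array([contrast[n] for n in names])
    est = float(sum(contrast[n] * fit_result.params[n] for n in names))
    var = float(w @ fit_result.cov.loc[names, names].to_numpy() @ w)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return est, est - half, est + half


def bootstrap_latent_sd(
    latents: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    subtract_mean: bool = False,
    group_labels: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Nonparametric bootstrap of per-timepoint spread of latent logits.

    Resamples lines with replacement ``B`` times and averages, per day,
    the mean and SD of the (optionally group-mean-centred) psi modes.
    ``group_labels`` maps line_id -> treatment label; with
    ``subtract_mean`` the per-day mean of a line's group is removed
    first, so between-treatment spread does not inflate the SD. Days with
    fewer than 2 lines get a missing SD.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    df = latents.copy()
    if subtract_mean:
        if group_labels is None:
            df["group"] = "all"
        else:
            df["group"] = df["line_id"].map(group_labels)
        centers = df.groupby(["group", "day"])["psi_mode"].transform("mean")
        df["psi_mode"] = df["psi_mode"] - centers
    line_ids = df["line_id"].unique()
    by_line = {lid: sub for lid, sub in df.groupby("line_id")}
    days = np.sort(df["day"].unique())
    mean_acc = {d: [] for d in days}
    sd_acc = {d: [] for d in days}
    for _ in range(B):
        chosen = rng.choice(line_ids, size=len(line_ids), replace=True)
        sample = pd.concat([by_line[lid] for lid in chosen], ignore_index=True)
        g = sample.groupby("day")["psi_mode"]
        means, sds, counts = g.mean(), g.std(ddof=1), g.count()
        for d in days:
            if d in means.index:
                mean_acc[d].append(means[d])
                if counts[d] >= 2:
                    sd_acc[d].append(sds[d])
    rows = []
    for d in days:
        sd = float(np.mean(sd_acc[d])) if sd_acc[d] else np.nan
        rows.append((d, float(np.mean(mean_acc[d])), sd))
    return pd.DataFrame(rows, columns=["day", "psi_mean", "psi_sd"])


# ---------------------------------------------------------------------------
# quadrature oracle for single-latent instances


def quadrature_marginal_loglik(
    n: float,
    N: float,
    m: float,
    M: float,
    prior_mean: float,
    prior_var: float,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
    n_nodes: int = 41,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood for one latent logit.

    Centres the quadrature at the Laplace mode with scale from the
    curvature there; with 41 nodes this is accurate enough to serve as an
    independent reference for the Laplace approximation on scalar
    integrals.
    """
    alpha, beta = calibration.alpha, calibration.beta
    n_a, N_a, m_a, M_a = (np.array([v], dtype=float) for v in (n, N, m, M))

    def f(psi):
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        obs = _obs_loglik(psi, n_a, N_a, m_a, M_a, alpha, beta)
        return obs - 0.5 * (psi - prior_mean) ** 2 / prior_var - 0.5 * np.log(
            2 * np.pi * prior_var
        )

    # mode by 1-d Newton (same scheme as the batched solver)
    psi = np.array([prior_mean])
    for _ in range(200):
        g_obs, _, w_fish = _obs_derivs(psi, n_a, N_a, m_a, M_a, alpha, beta)
        grad = g_obs - (psi - prior_mean) / prior_var
        if abs(grad[0]) < 1e-11:
            break
        psi = psi + grad / (w_fish + 1.0 / prior_var)
    _, w_true, w_fish = _obs_derivs(psi, n_a, N_a, m_a, M_a, alpha, beta)
    curv = w_true[0] + 1.0 / prior_var
    if curv <= 0:
        curv = w_fish[0] + 1.0 / prior_var
    sd = 1.0 / np.sqrt(curv)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    x = psi[0] + sd * nodes
    logvals = f(x) + np.log(weights) + 0.5 * nodes**2 + np.log(sd)
    return float(special.logsumexp(logvals))


def laplace_marginal_loglik_single(
    n: float,
    N: float,
    m: float,
    M: float,
    prior_mean: float,
    prior_var: float,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
) -> float:
    """Laplace marginal log-likelihood for one latent logit (scalar case)."""
    line = LineObs("single", [1.0], [n], [N], [m], [M], 0.0, 1.0, 0.0)
    g = _Group(np.array([1.0]), [line])
    ll, _ = _group_laplace(
        g,
        np.array([prior_mean]),
        v_psi0=prior_var,
        sigma_sq=0.0,
        alpha=calibration.alpha,
        beta=calibration.beta,
    )
    return float(ll[0])
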