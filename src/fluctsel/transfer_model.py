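"""Short-term selection over single transfers with known salinities.

Where the macroscopic model aggregates selection over the whole
experiment through treatment-level covariates, this model looks at pairs
of consecutively sequenced transfers, for which the salinities before and
after the transfer are known. The logit frequencies psi_prev and psi_cur
on either side of a transfer of duration t (3 or 4 days) are latent, each
observed through the dual-locus binomial model, and linked by

    psi_cur | psi_prev ~ N(psi_prev + t * s(E_prev, E_cur), t^2 * sigma_s^2)

with s the bivariate selection reaction norm (optionally with density and
frequency covariates). The prior on psi_prev is flat, so only relative
likelihoods are meaningful — which is all the nested LR tests need. Each
latent pair is integrated out by a bivariate Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .barcode import DEFAULT_ITS2_CALIBRATION, CalibrationMap
from .reaction_norms import ReactionNormBi
from .state_space import TestResult, _obs_derivs, _obs_loglik

#: Design columns of the bivariate reaction norm, in a fixed order.
TRANSFER_TERMS = (
    "intercept",
    "E_cur",
    "E_cur2",
    "E_prev",
    "E_prev2",
    "interaction",
    "density",
    "freq",
)

_REQUIRED_COLS = [
    "E_prev",
    "E_cur",
    "duration",
    "n0",
    "N0",
    "m0",
    "M0",
    "n1",
    "N1",
    "m1",
    "M1",
]


def _design_matrix(pairs: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = {
        "intercept": np.ones(len(pairs)),
        "E_cur": pairs["E_cur"].to_numpy(float),
        "E_cur2": pairs["E_cur"].to_numpy(float) ** 2,
        "E_prev": pairs["E_prev"].to_numpy(float),
        "E_prev2": pairs["E_prev"].to_numpy(float) ** 2,
        "interaction": pairs["E_cur"].to_numpy(float) * pairs["E_prev"].to_numpy(float),
    }
    if "density" in terms:
        cols["density"] = pairs["log10_density"].to_numpy(float)
    if "freq" in terms:
        cols["freq"] = pairs["logit_freq"].to_numpy(float)
    return np.column_stack([cols[t] for t in terms])


@dataclass
class TransferFitResult:
    """Laplace-ML fit of the per-transfer bivariate selection model."""

    terms: Tuple[str, ...]
    params: Dict[str, float]
    se: Dict[str, float]
    cov: pd.DataFrame
    loglik: float
    converged: bool
    n_pairs: int
    latents: pd.DataFrame

    @property
    def n_free(self) -> int:
        return len(self.terms) + 1  # + log sigma_s_sq

    def reaction_norm(self) -> ReactionNormBi:
        g = self.params.get
        return ReactionNormBi(
            a=g("intercept", 0.0),
            b=g("E_cur", 0.0),
            c=g("E_cur2", 0.0),
            d=g("E_prev", 0.0),
            e=g("E_prev2", 0.0),
            f=g("interaction", 0.0),
            g_density=g("density", 0.0),
            g_freq=g("freq", 0.0),
        )


def _pairs_loglik(
    s_vec: np.ndarray,
    sigma_sq: float,
    data: Dict[str, np.ndarray],
    alpha: float,
    beta: float,
    psi_warm: np.ndarray,
    max_iter: int = 100,
    grad_tol: float = 1e-6,
):
    """Bivariate Laplace marginal log-likelihood of every transfer pair."""
    t = data["duration"]
    drift = t * s_vec
    r = 1.0 / (t * t * sigma_sq)
    psi0, psi1 = psi_warm[:, 0].copy(), psi_warm[:, 1].copy()

    def objective(p0, p1):
        obs = (
            _obs_loglik(p0, data["n0"], data["N0"], data["m0"], data["M0"], alpha, beta)
            + _obs_loglik(p1, data["n1"], data["N1"], data["m1"], data["M1"], alpha, beta)
        )
        resid = p1 - p0 - drift
        return obs - 0.5 * resid * resid * r - 0.5 * np.log(2 * np.pi / r)

    f = objective(psi0, psi1)
    for _ in range(max_iter):
        g0, _, w0 = _obs_derivs(psi0, data["n0"], data["N0"], data["m0"], data["M0"], alpha, beta)
        g1, _, w1 = _obs_derivs(psi1, data["n1"], data["N1"], data["m1"], data["M1"], alpha, beta)
        resid = psi1 - psi0 - drift
        grad0 = g0 + resid * r
        grad1 = g1 - resid * r
        if max(np.max(np.abs(grad0)), np.max(np.abs(grad1))) < grad_tol:
            break
        # Newton step with the (PD) Fisher metric, explicit 2x2 solve
        a11 = w0 + r
        a22 = w1 + r
        a12 = -r
        det = a11 * a22 - a12 * a12
        step0 = (a22 * grad0 - a12 * grad1) / det
        step1 = (a11 * grad1 - a12 * grad0) / det
        scale = np.ones_like(psi0)
        slack = 1e-9 * (1.0 + np.abs(f))
        for _ in range(15):
            f_new = objective(psi0 + scale * step0, psi1 + scale * step1)
            bad = f_new < f - slack
            if not np.any(bad):
                break
            scale[bad] *= 0.5
        psi0 = psi0 + scale * step0
        psi1 = psi1 + scale * step1
        f = f_new

    psi_warm[:, 0], psi_warm[:, 1] = psi0, psi1
    _, h0_true, w0f = _obs_derivs(psi0, data["n0"], data["N0"], data["m0"], data["M0"], alpha, beta)
    _, h1_true, w1f = _obs_derivs(psi1, data["n1"], data["N1"], data["m1"], data["M1"], alpha, beta)
    w0 = np.where(h0_true > 0, h0_true, w0f)
    w1 = np.where(h1_true > 0, h1_true, w1f)
    det = (w0 + r) * (w1 + r) - r * r
    det = np.clip(det, 1e-300, None)
    ll = f + np.log(2 * np.pi) - 0.5 * np.log(det)
    return ll, psi0, psi1


def fit_transfer_model(
    pairs: pd.DataFrame,
    terms: Sequence[str] = ("intercept", "E_cur", "E_cur2", "E_prev", "E_prev2", "interaction"),
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
    start: Optional[Dict[str, float]] = None,
    compute_cov: bool = True,
) -> TransferFitResult:
    """Fit the per-transfer model by Laplace-approximated maximum likelihood.

    ``pairs`` must have columns E_prev, E_cur (salinity deviations),
    duration (days), and the counts n0/N0/m0/M0 and n1/N1/m1/M1 at the
    two loci before and after the transfer; ``log10_density`` and
    ``logit_freq`` are needed only when those terms are requested.
    """
    for col in _REQUIRED_COLS:
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    if len(pairs) == 0:
        raise ValueError("no consecutive sequenced transfer pairs")
    for t in terms:
        if t not in TRANSFER_TERMS:
            raise ValueError(f"unknown term {t!r}")
    X = _design_matrix(pairs, terms)
    data = {c: pairs[c].to_numpy(float) for c in _REQUIRED_COLS}
    alpha, beta = calibration.alpha, calibration.beta

    def emp_logit(n, N, m, M):
        p = np.where(N > 0, (n + 0.5) / (N + 1.0), np.clip(((m + 0.5) / (M + 1.0) - alpha) / beta, 0.02, 0.98))
        return np.log(np.clip(p, 1e-4, 1 - 1e-4) / (1 - np.clip(p, 1e-4, 1 - 1e-4)))

    psi_warm = np.column_stack(
        [
            emp_logit(data["n0"], data["N0"], data["m0"], data["M0"]),
            emp_logit(data["n1"], data["N1"], data["m1"], data["M1"]),
        ]
    )

    if start is None:
        s_emp = (psi_warm[:, 1] - psi_warm[:, 0]) / data["duration"]
        coef, *_ = np.linalg.lstsq(X, s_emp, rcond=None)
        resid_var = float(np.clip(np.var(s_emp - X @ coef), 1e-4, None))
        x0 = np.append(coef, np.log(resid_var))
    else:
        x0 = np.array([start.get(t, 0.0) for t in terms] + [np.log(start.get("sigma_s_sq", 1e-2))])

    def negll(x):
        s_vec = X @ x[:-1]
        sigma_sq = float(np.exp(x[-1]))
        try:
            ll, _, _ = _pairs_loglik(s_vec, sigma_sq, data, alpha, beta, psi_warm)
        except (ValueError, FloatingPointError):
            return 1e10
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(np.sum(ll))

    def negll_grad(x):
        g = np.zeros_like(x)
        for i in range(len(x)):
            h = 1e-5 * max(1.0, abs(x[i]))
            xp = x.copy()
            xp[i] += h
            xm = x.copy()
            xm[i] -= h
            g[i] = (negll(xp) - negll(xm)) / (2 * h)
        return g

    res = optimize.minimize(
        negll,
        x0,
        jac=negll_grad,
        method="L-BFGS-B",
        bounds=[(None, None)] * len(terms) + [(-18.0, 5.0)],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-5},
    )
    names = list(terms) + ["sigma_s_sq"]
    params = {t: float(v) for t, v in zip(terms, res.x[:-1])}
    params["sigma_s_sq"] = float(np.exp(res.x[-1]))
    ll_final, psi0, psi1 = _pairs_loglik(
        X @ res.x[:-1], params["sigma_s_sq"], data, alpha, beta, psi_warm
    )

    se = {n: np.nan for n in names}
    cov_nat = np.full((len(names), len(names)), np.nan)
    if compute_cov:
        try:
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
            cov_log = np.linalg.pinv(H)
            jac = np.ones(len(names))
            jac[-1] = params["sigma_s_sq"]
            cov_nat = cov_log * np.outer(jac, jac)
            for i, n in enumerate(names):
                if np.isfinite(cov_nat[i, i]) and cov_nat[i, i] >= 0:
                    se[n] = float(np.sqrt(cov_nat[i, i]))
        except (np.linalg.LinAlgError, ValueError):
            pass

    lat = pd.DataFrame(
        {
            "pair": np.arange(len(pairs)),
            "psi_prev_mode": psi0,
            "psi_cur_mode": psi1,
            "s_realized": (psi1 - psi0) / data["duration"],
        }
    )
    return TransferFitResult(
        terms=tuple(terms),
        params=params,
        se=se,
        cov=pd.DataFrame(cov_nat, index=names, columns=names),
        loglik=float(np.sum(ll_final)),
        converged=bool(res.success),
        n_pairs=len(pairs),
        latents=lat,
    )


def transfer_lr_tests(
    pairs: pd.DataFrame,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
    with_density: bool = False,
    with_freq: bool = False,
) -> Dict[str, TestResult]:
    """Nested LR tests of the per-transfer selection model.

    Tests, in the order used on the real data: current-salinity terms
    (constant vs univariate), past-salinity terms (univariate vs
    bivariate), and optionally the density and frequency terms added on
    top of the bivariate norm.
    """
    fits = {
        "constant": fit_transfer_model(pairs, ("intercept",), calibration, compute_cov=False),
        "univariate": fit_transfer_model(
            pairs, ("intercept", "E_cur", "E_cur2"), calibration, compute_cov=False
        ),
        "bivariate": fit_transfer_model(
            pairs,
            ("intercept", "E_cur", "E_cur2", "E_prev", "E_prev2", "interaction"),
            calibration,
            compute_cov=False,
        ),
    }
    out = {
        "current_salinity": _lr(fits["univariate"], fits["constant"]),
        "past_salinity": _lr(fits["bivariate"], fits["univariate"]),
    }
    base_terms = ("intercept", "E_cur", "E_cur2", "E_prev", "E_prev2", "interaction")
    if with_density:
        full = fit_transfer_model(pairs, base_terms + ("density",), calibration, compute_cov=False)
        out["density"] = _lr(full, fits["bivariate"])
    if with_freq:
        full = fit_transfer_model(pairs, base_terms + ("freq",), calibration, compute_cov=False)
        out["frequency"] = _lr(full, fits["bivariate"])
    return out


def _lr(full: TransferFitResult, reduced: TransferFitResult) -> TestResult:
    df = full.n_free - reduced.n_free
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return TestResult(float(stat), df, float(stats.chi2.sf(stat, df)), "LR")
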