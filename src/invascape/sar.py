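"""Spatial-lag (SAR) model fitted by concentrated maximum likelihood.

The model is  y = ρ W y + X β + ε,  ε ~ N(0, σ² I):  each unit's response
depends on the weighted average of its neighbors' responses (the spatial
lag ρWy) plus a linear predictor.  Writing A(ρ) = I − ρW, the
log-likelihood is

    ℓ(ρ, β, σ²) = −(n/2) ln(2πσ²) − ‖A(ρ)y − Xβ‖² / (2σ²) + ln|A(ρ)|

For fixed ρ the optimal β and σ² have closed forms, so ℓ concentrates to a
one-dimensional function of ρ maximized by Brent search on the feasible
interval; ln|A(ρ)| is evaluated exactly from the eigenvalues of W.
Standard errors come from the inverse of the numerically differentiated
information matrix over (ρ, β, σ²).

Also here: covariate utilities used around the fit — neighbor averaging
(the "neighborhood population" style covariate), correlation screening,
stepwise AIC search, and the residual Moran diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from invascape.errors import InfeasibleRhoError, SingularDesignError
from invascape.moran import MoranResult, morans_test
from invascape.weights import SpatialWeights

__all__ = [
    "SarFit",
    "neighbor_average",
    "screen_collinear",
    "feasible_rho_interval",
    "log_det_factor",
    "concentrated_loglik",
    "full_loglik",
    "fit_sar_ml",
    "stepwise_aic",
    "residual_autocorrelation",
]

_EDGE = 1e-6  # relative margin kept from the feasible-interval endpoints


def neighbor_average(v, w: SpatialWeights):
    """Average of ``v`` over each unit's neighbors, (Wv) for row-standard W.

    Islands have no neighbors and get NaN.  ``v`` may be a Series indexed
    by unit id or an array in ``w.ids`` order; the return type matches.
    """
    if w.style != "row":
        raise ValueError("neighbor_average requires row-standardized weights")
    series_in = isinstance(v, pd.Series)
    vals = v.reindex(w.ids).to_numpy(dtype=float) if series_in else np.asarray(v, float)
    out = w.sparse().dot(vals)
    out[w.cardinalities == 0] = np.nan
    return pd.Series(out, index=w.ids) if series_in else out


def screen_collinear(
    x: pd.DataFrame, y, threshold: float = 0.6
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop covariates until no pair has |Pearson r| above ``threshold``.

    While any offending pair exists, the member with the smaller |r|
    against the response is removed.  Zero-variance columns are dropped
    first.  Returns the reduced table and a removal log.
    """
    if x.shape[1] < 2:
        raise ValueError("screening needs at least two covariates")
    y = pd.Series(np.asarray(y, float), index=x.index)
    log: list[dict] = []
    keep = x.copy()
    for col in list(keep.columns):
        if np.isclose(keep[col].std(ddof=0), 0.0):
            keep = keep.drop(columns=col)
            log.append({"removed": col, "reason": "zero variance", "r": np.nan})
    while keep.shape[1] >= 2:
        corr = keep.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        r_max = float(corr.values.max())
        if r_max <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        ry_a = abs(keep[a].corr(y))
        ry_b = abs(keep[b].corr(y))
        drop = a if ry_a < ry_b else b
        log.append(
            {"removed": drop, "reason": f"|r|={r_max:.3f} with "
             f"{b if drop == a else a}", "r": r_max}
        )
        keep = keep.drop(columns=drop)
    return keep, log


def feasible_rho_interval(w: SpatialWeights) -> tuple[float, float]:
    """Interval of ρ keeping I − ρW nonsingular, from real eigenvalues.

    For row-standardized weights the largest eigenvalue is 1, so the
    interval is (1/ω_min, 1) with ω_min the most negative real eigenvalue.
    """
    eigs = w.eigenvalues()
    real = eigs[np.abs(eigs.imag) < 1e-9].real
    pos = real[real > 1e-12]
    neg = real[real < -1e-12]
    hi = 1.0 / pos.max() if pos.size else np.inf
    lo = 1.0 / neg.min() if neg.size else -np.inf
    return float(lo), float(hi)


def log_det_factor(rho: float, w: SpatialWeights) -> float:
    """ln|I − ρW| via the eigenvalue expansion Σ ln(1 − ρω_i).

    Complex eigenvalues come in conjugate pairs whose product is real, so
    the sum of logs is taken on the complex numbers and the real part
    returned.  ρ at or beyond the feasible interval is rejected.
    """
    eigs = w.eigenvalues()
    fac = 1.0 - rho * eigs
    if np.any(np.abs(fac) < 1e-12):
        raise InfeasibleRhoError(f"I - rho*W is singular at rho={rho}")
    lo, hi = feasible_rho_interval(w)
    if not (lo < rho < hi):
        raise InfeasibleRhoError(
            f"rho={rho} outside feasible interval ({lo:.6g}, {hi:.6g})"
        )
    return float(np.log(fac).sum().real)


def _design(x, n: int) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        mat = x.to_numpy(dtype=float)
    elif x is None:
        names, mat = [], np.empty((n, 0))
    else:
        mat = np.asarray(x, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    return mat, names


def _beta_sigma(rho: float, y, x, wy) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form β(ρ), residuals, σ²(ρ) of the concentrated likelihood."""
    yd = y - rho * wy
    beta, _, rank, _ = np.linalg.lstsq(x, yd, rcond=None)
    if rank < x.shape[1]:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        worst = np.nanmax(np.abs(corr - np.eye(len(corr))))
        raise SingularDesignError(
            f"design matrix rank {rank} < {x.shape[1]} columns "
            f"(max |corr| {worst:.4f})"
        )
    e = yd - x @ beta
    sigma2 = float(e @ e) / len(y)
    return beta, e, sigma2


def concentrated_loglik(rho: float, y, x, w: SpatialWeights) -> float:
    """Profile log-likelihood of ρ with β and σ² concentrated out."""
    y = np.asarray(y, dtype=float)
    xmat, _ = _design(x, len(y))
    wy = w.sparse().dot(y)
    _, _, sigma2 = _beta_sigma(rho, y, xmat, wy)
    n = len(y)
    return -(n / 2.0) * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + log_det_factor(
        rho, w
    )


def full_loglik(rho, beta, sigma2, y, x, w: SpatialWeights) -> float:
    """Exact SAR log-likelihood at an arbitrary parameter point."""
    y = np.asarray(y, dtype=float)
    xmat, _ = _design(x, len(y))
    n = len(y)
    e = y - rho * w.sparse().dot(y) - xmat @ np.asarray(beta, float)
    return (
        -(n / 2.0) * np.log(2 * np.pi * sigma2)
        - float(e @ e) / (2.0 * sigma2)
        + log_det_factor(rho, w)
    )


@dataclass
class SarFit:
    """Maximum-likelihood SAR fit.

    ``aic = 2k − 2·loglik`` with ``k = len(beta) + 2`` (ρ and σ² count as
    parameters).  ``residuals = y − ρ̂Wy − Xβ̂`` indexed like the input.
    """

    rho: float
    beta: pd.Series
    sigma2: float
    loglik: float
    aic: float
    se_rho: float
    se_beta: pd.Series
    p_rho: float
    p_beta: pd.Series
    residuals: pd.Series
    fitted: pd.Series
    n: int
    k: int
    ids: list = field(default_factory=list)
    rho_interval: tuple = (np.nan, np.nan)
    at_boundary: bool = False
    residual_moran: MoranResult | None = None

    @property
    def z_rho(self) -> float:
        return self.rho / self.se_rho if self.se_rho else np.nan

    def summary(self) -> str:
        lines = [
            f"SAR (spatial lag) fit: n={self.n}, k={self.k}",
            f"  rho    = {self.rho:10.4f}  (se {self.se_rho:.4f}, p {self.p_rho:.4g})",
        ]
        for name in self.beta.index:
            lines.append(
                f"  {name:<16} {self.beta[name]:10.4f}  "
                f"(se {self.se_beta[name]:.4f}, p {self.p_beta[name]:.4g})"
            )
        lines.append(f"  sigma2 = {self.sigma2:10.4f}")
        lines.append(f"  loglik = {self.loglik:.4f}   AIC = {self.aic:.2f}")
        if self.residual_moran is not None:
            rm = self.residual_moran
            verdict = "lag model adequate" if rm.p >= 0.05 else "residual clustering"
            lines.append(
                f"  residual Moran I = {rm.i:.4f} (z {rm.z:.3f}, p {rm.p:.3f}) "
                f"-> {verdict}"
            )
        return "\n".join(lines)


def _numeric_hessian(fun, theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(theta)
    hess = np.empty((p, p))
    f0 = fun(theta)
    for a in range(p):
        ea = np.zeros(p)
        ea[a] = steps[a]
        fpp = fun(theta + ea)
        fmm = fun(theta - ea)
        hess[a, a] = (fpp - 2 * f0 + fmm) / steps[a] ** 2
        for b in range(a + 1, p):
            eb = np.zeros(p)
            eb[b] = steps[b]
            fab = fun(theta + ea + eb)
            fa_b = fun(theta + ea - eb)
            f_ab = fun(theta - ea + eb)
            f_a_b = fun(theta - ea - eb)
            hess[a, b] = hess[b, a] = (fab - fa_b - f_ab + f_a_b) / (
                4 * steps[a] * steps[b]
            )
    return hess


def fit_sar_ml(
    y,
    x,
    w: SpatialWeights,
    optimizer_tol: float = 1e-8,
    add_intercept: bool = True,
    fix_rho: float | None = None,
) -> SarFit:
    """Fit y = ρWy + Xβ + ε by maximum likelihood.

    ρ̂ maximizes the concentrated log-likelihood by bounded Brent search on
    the feasible interval (ρ = 0 is always also evaluated, so the fit never
    does worse than OLS).  Setting ``fix_rho`` skips the search and profiles
    at that value — ``fix_rho=0`` reproduces OLS exactly, with k = p + 1.
    """
    if isinstance(y, pd.Series):
        ids = list(y.index)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        ids = list(w.ids) if len(yv) == w.n else list(range(len(yv)))
    n = len(yv)
    xmat, names = _design(x, n)
    if add_intercept:
        xmat = np.column_stack([np.ones(n), xmat])
        names = ["intercept"] + names
    p = xmat.shape[1]
    if n <= p + 2:
        raise SingularDesignError(f"n={n} too small for {p} coefficients plus rho")
    wy = w.sparse().dot(yv)
    lo, hi = feasible_rho_interval(w)
    span = hi - lo

    def nll(r: float) -> float:
        _, _, s2 = _beta_sigma(r, yv, xmat, wy)
        return (n / 2.0) * (np.log(2 * np.pi) + np.log(s2) + 1.0) - log_det_factor(
            r, w
        )

    at_boundary = False
    if fix_rho is not None:
        if not (lo < fix_rho < hi) and fix_rho != 0.0:
            raise InfeasibleRhoError(f"fix_rho={fix_rho} outside ({lo:.4g}, {hi:.4g})")
        rho_hat = float(fix_rho)
    else:
        res = optimize.minimize_scalar(
            nll,
            bounds=(lo + _EDGE * span, hi - _EDGE * span),
            method="bounded",
            options={"xatol": optimizer_tol},
        )
        rho_hat = float(res.x)
        if nll(0.0) < nll(rho_hat):  # guard: the search includes rho = 0
            rho_hat = 0.0
        if min(rho_hat - lo, hi - rho_hat) < 10 * _EDGE * span:
            at_boundary = True
            warnings.warn(
                f"rho estimate {rho_hat:.4f} sits at the feasible-interval "
                "boundary; the fit is returned but may be unstable",
                stacklevel=2,
            )
    beta_hat, e, sigma2_hat = _beta_sigma(rho_hat, yv, xmat, wy)
    loglik = full_loglik(rho_hat, beta_hat, sigma2_hat, yv, xmat if p else None, w)

    # --- standard errors: numeric information matrix over (rho?, beta, s2)
    free_rho = fix_rho is None
    theta = np.concatenate([[rho_hat] if free_rho else [], beta_hat, [sigma2_hat]])

    def negll(th: np.ndarray) -> float:
        if free_rho:
            r, b, s2 = th[0], th[1:-1], th[-1]
        else:
            r, b, s2 = rho_hat, th[:-1], th[-1]
        if s2 <= 0 or not (lo < r < hi):
            return np.inf
        return -full_loglik(r, b, s2, yv, xmat if p else None, w)

    scale = np.maximum(np.abs(theta), 1.0)
    steps = 1e-4 * scale
    hess = _numeric_hessian(negll, theta, steps)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta), np.nan)
    if free_rho:
        se_rho = float(se_all[0])
        se_beta = se_all[1 : 1 + p]
    else:
        se_rho = np.nan
        se_beta = se_all[:p]
    z_beta = np.divide(beta_hat, se_beta, out=np.full(p, np.nan), where=se_beta > 0)
    p_beta = 2 * stats.norm.sf(np.abs(z_beta))
    p_rho = (
        float(2 * stats.norm.sf(abs(rho_hat / se_rho)))
        if free_rho and se_rho > 0
        else np.nan
    )
    k = p + (2 if free_rho else 1)
    resid = yv - rho_hat * wy - xmat @ beta_hat
    return SarFit(
        rho=rho_hat,
        beta=pd.Series(beta_hat, index=names),
        sigma2=sigma2_hat,
        loglik=float(loglik),
        aic=2.0 * k - 2.0 * float(loglik),
        se_rho=se_rho,
        se_beta=pd.Series(se_beta, index=names),
        p_rho=p_rho,
        p_beta=pd.Series(p_beta, index=names),
        residuals=pd.Series(resid, index=ids),
        fitted=pd.Series(yv - resid, index=ids),
        n=n,
        k=k,
        ids=ids,
        rho_interval=(lo, hi),
        at_boundary=at_boundary,
    )


def stepwise_aic(
    y, candidate_x: pd.DataFrame, w: SpatialWeights, direction: str = "both"
) -> tuple[SarFit, pd.DataFrame]:
    """Greedy AIC search over SAR models, starting from intercept + lag.

    At each step every single addition (and, for ``direction="both"``,
    every single removal) is refitted; the move with the lowest AIC is
    taken while it improves.  Covariates are tried in column order, so the
    path is deterministic.  Returns the best fit and the full path log.
    Variables are never pruned on p-values — only AIC drives the search.
    """
    if direction not in ("forward", "both"):
        raise ValueError("direction must be 'forward' or 'both'")
    included: list[str] = []
    candidates = list(candidate_x.columns)

    def fit_with(cols: list[str]) -> SarFit:
        xm = candidate_x[cols] if cols else None
        return fit_sar_ml(y, xm, w)

    current = fit_with(included)
    path = [
        {"step": 0, "action": "start", "variable": "", "aic": current.aic,
         "included": ""}
    ]
    step = 0
    while True:
        step += 1
        moves: list[tuple[float, str, str]] = []
        for var in candidates:
            if var not in included:
                try:
                    trial = fit_with(included + [var])
                    moves.append((trial.aic, "add", var))
                except SingularDesignError:
                    continue
        if direction == "both":
            for var in included:
                cols = [c for c in included if c != var]
                trial = fit_with(cols)
                moves.append((trial.aic, "drop", var))
        if not moves:
            break
        best_aic, action, var = min(moves, key=lambda t: (t[0], t[2]))
        if best_aic >= current.aic - 1e-9:
            break
        included = (
            included + [var] if action == "add" else [c for c in included if c != var]
        )
        current = fit_with(included)
        path.append(
            {"step": step, "action": action, "variable": var, "aic": current.aic,
             "included": "+".join(included)}
        )
    return current, pd.DataFrame(path)


def residual_autocorrelation(
    fit: SarFit, w: SpatialWeights, alternative: str = "greater"
) -> MoranResult:
    """Moran's test of the SAR residuals under the model's own weights.

    A non-significant result (p ≥ 0.05) indicates the lag term absorbed
    the spatial structure — the lag model is adequate.  The result is also
    stored on ``fit.residual_moran``.
    """
    res = morans_test(
        pd.Series(fit.residuals.to_numpy(), index=fit.ids), w, alternative=alternative
    )
    fit.residual_moran = res
    return res
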