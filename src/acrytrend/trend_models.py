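"""Time-trend models for harmonized study-level biomarker means.

All models weight observations by study population size N, under the
assumption that a mean from a larger study determines the population mean
more precisely (Var(y_i) = sigma^2 / w_i with w_i = N_i).

Three fits are provided:

* :func:`fit_weighted_mlr` — weighted multiple linear regression of the
  yearly mean on sampling year plus optional covariates (mean age of the
  study population, percent male), with Student-t inference.
* :func:`fit_loess` — locally weighted scatter-plot smoothing with a
  tricube distance kernel multiplied by the study weights.
* :func:`fit_segmented` — one-breakpoint piecewise-linear model
  y = b0 + b1*t + b2*(t - psi)_+, estimated by iterative linearization
  (re-fitting with the gap covariate V = -1[t > psi] and updating
  psi <- psi + gamma/b2), with a weighted-SSE grid search as fallback.
* :func:`test_breakpoint` — parametric bootstrap test for the existence
  of a breakpoint, simulating from the fitted no-breakpoint model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .study_data import HarmonizedRecord

#: |gamma| threshold declaring the breakpoint iteration converged
SEGMENTED_TOL = 1e-6
SEGMENTED_MAX_ITER = 100
#: grid resolution (years) of the fallback breakpoint search
SEGMENTED_GRID_STEP = 0.05


class CollinearityError(ValueError):
    """The design matrix is rank deficient; message names the column."""


class ModelError(ValueError):
    """A model precondition is violated or a fit cannot be used."""


# --------------------------------------------------------------------------
# weighted least squares

@dataclass
class TrendFit:
    """Weighted linear model output with per-coefficient inference."""

    names: tuple[str, ...]
    coefficients: dict[str, float]
    se: dict[str, float]
    t_stat: dict[str, float]
    p_value: dict[str, float]
    weighted_sse: float
    df_resid: int
    n_obs: int
    residuals: np.ndarray          # raw residuals y - Xb
    fitted: np.ndarray
    weights: np.ndarray
    dropped: tuple[str, ...] = ()  # study ids dropped for missing covariates

    @property
    def sigma2(self) -> float:
        """Weighted residual mean square (error variance estimate)."""
        return self.weighted_sse / self.df_resid


def weighted_least_squares(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                           names: Sequence[str]) -> TrendFit:
    """WLS fit minimizing sum(w_i (y_i - x_i b)^2), Student-t inference.

    Standard errors use the weighted information matrix (X'WX)^-1 scaled by
    the weighted residual mean square; p-values are two-sided Student t
    with df = n - p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    if np.any(w <= 0):
        raise ModelError("weights must be strictly positive")
    if n <= p:
        raise ModelError(f"need n_obs > n_params, got n={n}, p={p}")
    # rank check, naming the offending column where identifiable
    for j, name in enumerate(names):
        col = X[:, j]
        if name != "intercept" and float(np.ptp(col)) == 0.0:
            raise CollinearityError(f"covariate '{name}' is constant")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    if np.linalg.matrix_rank(Xw) < p:
        raise CollinearityError(
            f"design matrix is rank deficient (columns {list(names)})")
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    resid = y - X @ beta
    wsse = float(w @ resid**2)
    df = n - p
    sigma2 = wsse / df
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)
    return TrendFit(
        names=tuple(names),
        coefficients=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        t_stat=dict(zip(names, t.tolist())),
        p_value=dict(zip(names, pv.tolist())),
        weighted_sse=wsse, df_resid=df, n_obs=n,
        residuals=resid, fitted=X @ beta, weights=w)


def _panel_arrays(panel: Sequence[HarmonizedRecord],
                  covariates: Sequence[str]):
    """Extract (t, y, w, Z, kept_ids, dropped_ids); drops records missing
    a requested covariate."""
    kept, dropped = [], []
    for rec in panel:
        if any(getattr(rec, c) is None for c in covariates):
            dropped.append(rec.study_id)
        else:
            kept.append(rec)
    t = np.array([r.year for r in kept], dtype=float)
    y = np.array([r.mean_ugL for r in kept], dtype=float)
    w = np.array([r.n for r in kept], dtype=float)
    Z = (np.column_stack([[getattr(r, c) for r in kept] for c in covariates])
         if covariates and kept else np.empty((len(kept), 0)))
    return t, y, w, Z, [r.study_id for r in kept], dropped


def fit_weighted_mlr(panel: Sequence[HarmonizedRecord],
                     covariates: Sequence[str] = ("mean_age", "pct_male"),
                     ) -> TrendFit:
    """Study-size-weighted regression of mean concentration on calendar year.

    The response is the harmonized yearly mean (ug/L); the year enters as
    calendar year plus the requested record covariates (e.g. ``mean_age``
    in years, ``pct_male`` in percent).  Records missing a covariate are
    dropped and reported in ``fit.dropped``.
    """
    t, y, w, Z, _, dropped = _panel_arrays(panel, covariates)
    X = np.column_stack([np.ones_like(t), t, Z])
    names = ["intercept", "year", *covariates]
    fit = weighted_least_squares(X, y, w, names)
    fit.dropped = tuple(dropped)
    return fit


# --------------------------------------------------------------------------
# LOESS

@dataclass
class LoessFit:
    """Locally weighted polynomial smooth on an evaluation grid."""

    span: float
    degree: int
    grid_x: np.ndarray
    fitted: np.ndarray
    se_fitted: np.ndarray
    robustness_iters: int = 0


def _local_fit(x0: float, x: np.ndarray, y: np.ndarray, w: np.ndarray,
               k: int, degree: int) -> tuple[float, float]:
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h == 0.0:
        h = max(d.max(), 1.0) * 1e-12  # all neighbors coincide with x0
    tri = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    ww = tri * w
    active = ww > 0
    if active.sum() < degree + 1:
        # boundary ties can zero out the edge of the window; widen it
        h = np.partition(d, min(k, d.size - 1))[min(k, d.size - 1)] * (1 + 1e-9)
        tri = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        ww = tri * w
        active = ww > 0
    if active.sum() < degree + 1:
        raise ModelError(
            f"window at x0={x0} has {int(active.sum())} usable neighbors; "
            f"need >= {degree + 1}")
    xa, ya, wa = x[active] - x0, y[active], ww[active]
    B = np.vander(xa, degree + 1, increasing=True)
    sw = np.sqrt(wa)
    coef, *_ = np.linalg.lstsq(B * sw[:, None], ya * sw, rcond=None)
    # pointwise SE from the local weighted normal equations
    A = B.T @ (B * wa[:, None])
    r = ya - B @ coef
    dof = max(int(active.sum()) - (degree + 1), 1)
    s2 = float(wa @ r**2) / dof
    try:
        var0 = s2 * np.linalg.inv(A)[0, 0]
    except np.linalg.LinAlgError:
        var0 = float("nan")
    return float(coef[0]), math.sqrt(max(var0, 0.0))


def fit_loess(x: Sequence[float], y: Sequence[float],
              w: Sequence[float] | None = None,
              span: float = 0.75, degree: int = 2,
              grid_x: Sequence[float] | None = None,
              robustness_iters: int = 0) -> LoessFit:
    """Tricube-kernel local polynomial smoothing with study weights.

    At each grid point the ``ceil(span * n)`` nearest observations are
    weighted by tricube(distance / bandwidth) times the study weight and a
    degree-``degree`` polynomial is fitted by weighted least squares; the
    smoothed value is its evaluation at the grid point.  Optional
    robustness iterations downweight outliers by Tukey's bisquare.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    n = x.size
    if not 0.0 < span <= 1.0:
        raise ModelError(f"span must be in (0, 1], got {span}")
    if n < degree + 2:
        raise ModelError(f"need >= {degree + 2} observations, got {n}")
    k = int(math.ceil(span * n))
    if k < degree + 1:
        raise ModelError(
            f"span*n = {k} neighbors < degree + 1 = {degree + 1}")
    if grid_x is None:
        grid_x = np.linspace(x.min(), x.max(), 200)
    grid_x = np.asarray(grid_x, dtype=float)

    robust = np.ones_like(x)
    for _ in range(robustness_iters):
        at_data = np.array([_local_fit(xi, x, y, w * robust, k, degree)[0]
                            for xi in x])
        r = y - at_data
        s = np.median(np.abs(r))
        robust = (np.clip(1 - (r / (6 * s)) ** 2, 0, None) ** 2
                  if s > 0 else np.ones_like(x))

    out = np.array([_local_fit(x0, x, y, w * robust, k, degree)
                    for x0 in grid_x])
    return LoessFit(span=span, degree=degree, grid_x=grid_x,
                    fitted=out[:, 0], se_fitted=out[:, 1],
                    robustness_iters=robustness_iters)


# --------------------------------------------------------------------------
# one-breakpoint segmented regression

@dataclass
class SegmentedFit:
    """One-breakpoint piecewise-linear fit y = b0 + b1 t + b2 (t - psi)_+."""

    psi: float
    se_psi: float
    slope_left: float
    slope_right: float
    coefficients: dict[str, float]
    se: dict[str, float]
    weighted_sse: float
    df_resid: int
    n_obs: int
    gamma_final: float
    converged: bool
    method: str                       # "muggeo" or "grid"
    p_break: float | None = None
    n_boot: int | None = None
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None


def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    r = y - X @ beta
    return beta, float(w @ r**2), r


def _segmented_design(t: np.ndarray, Z: np.ndarray, psi: float,
                      with_gap: bool) -> np.ndarray:
    U = np.clip(t - psi, 0.0, None)
    cols = [np.ones_like(t), t, U]
    if with_gap:
        cols.append(-(t > psi).astype(float))
    if Z.size:
        cols.append(Z)
    return np.column_stack(cols)


def _grid_candidates(t: np.ndarray, step: float) -> np.ndarray:
    lo, hi = t.min(), t.max()
    n_steps = int(math.floor((hi - lo) / step))
    psis = lo + step * np.arange(1, n_steps)
    # the weighted SSE profile is piecewise smooth with kinks at observed
    # times; its minimum can sit exactly on a knot, so interior observed
    # years are candidates too
    knots = np.unique(t)
    psis = np.union1d(psis, knots)
    return psis[(psis > lo) & (psis < hi)]


def grid_search_breakpoint(t: np.ndarray, y: np.ndarray, w: np.ndarray,
                           Z: np.ndarray | None = None,
                           step: float = SEGMENTED_GRID_STEP,
                           ) -> tuple[float, float]:
    """Exhaustive weighted-SSE minimization over a psi grid.

    Returns (psi, weighted SSE at psi).  Serves both as the fallback
    optimizer and as the independent oracle for the iterative scheme.
    """
    Z = np.empty((t.size, 0)) if Z is None else Z
    best = (np.nan, np.inf)
    for psi in _grid_candidates(t, step):
        X = _segmented_design(t, Z, psi, with_gap=False)
        try:
            _, sse, _ = _wls_solve(X, y, w)
        except np.linalg.LinAlgError:
            continue
        if sse < best[1]:
            best = (float(psi), sse)
    if not np.isfinite(best[1]):
        raise ModelError("no admissible breakpoint candidate")
    return best


def fit_segmented(panel_or_t, y=None, w=None,
                  covariates: Sequence[str] = (),
                  psi_init: float | None = None) -> SegmentedFit:
    """Fit the one-breakpoint model by iterative linearization.

    Accepts either a harmonized panel (records; year-only model plus
    ``covariates``) or raw arrays ``(t, y, w)``.  The design is augmented
    with U = (t - psi)_+ and the gap covariate V = -1[t > psi]; each
    iteration updates psi <- psi + gamma/b2 until |gamma| < 1e-6 (at most
    100 iterations).  On non-convergence a 0.05-year grid search over the
    weighted SSE provides the estimate.
    """
    if y is None:
        panel = list(panel_or_t)
        t, y, w, Z, _, _ = _panel_arrays(panel, covariates)
    else:
        t = np.asarray(panel_or_t, dtype=float)
        y = np.asarray(y, dtype=float)
        w = (np.ones_like(t) if w is None else np.asarray(w, dtype=float))
        Z = np.empty((t.size, 0))
    if np.unique(t).size < 5:
        raise ModelError("need >= 5 distinct year values for a breakpoint fit")
    lo, hi = t.min(), t.max()
    if psi_init is None:
        psi_init = float(np.average(t, weights=w))
    if not lo < psi_init < hi:
        raise ModelError(f"psi_init {psi_init} not strictly inside "
                         f"[{lo}, {hi}]")

    def _iterate(psi0: float):
        psi, gamma = psi0, np.inf
        eps = 1e-3 * (hi - lo)
        for _ in range(SEGMENTED_MAX_ITER):
            X = _segmented_design(t, Z, psi, with_gap=True)
            try:
                beta, _, _ = _wls_solve(X, y, w)
            except np.linalg.LinAlgError:
                return None
            gamma, b2 = float(beta[3]), float(beta[2])
            if abs(gamma) < SEGMENTED_TOL:
                return psi
            if b2 == 0.0 or not np.isfinite(gamma / b2):
                return None
            psi = float(np.clip(psi + gamma / b2, lo + eps, hi - eps))
        return None

    def _sse_at(psi: float) -> float:
        X = _segmented_design(t, Z, psi, with_gap=False)
        _, sse, _ = _wls_solve(X, y, w)
        return sse

    # the weighted SSE profile can be multimodal: keep the best of the
    # iterative solution and a grid-polished one
    candidates: list[tuple[float, float, str]] = []
    psi_m = _iterate(psi_init)
    if psi_m is not None:
        candidates.append((_sse_at(psi_m), psi_m, "muggeo"))
    psi_grid, sse_grid = grid_search_breakpoint(t, y, w, Z)
    psi_gp = _iterate(psi_grid)           # polish from the grid optimum
    if psi_gp is not None:
        candidates.append((_sse_at(psi_gp), psi_gp, "muggeo"))
    candidates.append((sse_grid, psi_grid, "grid"))
    _, psi, method = min(candidates, key=lambda c: (c[0], c[2] == "grid"))

    # final fits: reduced design for coefficients, gap design for se(psi)
    Xr = _segmented_design(t, Z, psi, with_gap=False)
    beta, wsse, resid = _wls_solve(Xr, y, w)
    n, p = Xr.shape
    df = n - (p + 1)                      # + 1 for the estimated psi
    if df < 1:
        raise ModelError("not enough observations for the segmented model")
    sigma2 = wsse / max(df, 1)
    sw = np.sqrt(w)
    covr = sigma2 * np.linalg.inv((Xr * sw[:, None]).T @ (Xr * sw[:, None]))
    se_beta = np.sqrt(np.clip(np.diag(covr), 0.0, None))
    Xg = _segmented_design(t, Z, psi, with_gap=True)
    try:
        covg = sigma2 * np.linalg.inv((Xg * sw[:, None]).T @ (Xg * sw[:, None]))
        gamma_beta, _, _ = _wls_solve(Xg, y, w)
        gamma_final = float(gamma_beta[3]) if method == "muggeo" else 0.0
        b2 = float(beta[2])
        se_psi = (math.sqrt(max(covg[3, 3], 0.0)) / abs(b2)
                  if b2 != 0 else float("inf"))
    except np.linalg.LinAlgError:
        gamma_final, se_psi = 0.0, float("nan")

    names = ["intercept", "year", "u_break", *covariates]
    return SegmentedFit(
        psi=float(psi), se_psi=se_psi,
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        coefficients=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se_beta.tolist())),
        weighted_sse=wsse, df_resid=df, n_obs=n,
        gamma_final=gamma_final,
        converged=(method == "muggeo" and abs(gamma_final) < SEGMENTED_TOL)
                  or method == "grid",
        method=method, residuals=resid, fitted=Xr @ beta)


# --------------------------------------------------------------------------
# bootstrap breakpoint existence test

def _grid_sse_batch(t: np.ndarray, w: np.ndarray, Y: np.ndarray,
                    step: float = SEGMENTED_GRID_STEP) -> np.ndarray:
    """Min-over-psi weighted SSE of the segmented model for each row of Y."""
    psis = _grid_candidates(t, step)
    Xs = np.stack([np.column_stack(
        [np.ones_like(t), t, np.clip(t - p, 0.0, None)]) for p in psis])
    XtW = Xs.transpose(0, 2, 1) * w[None, None, :]      # (P, 3, n)
    A = XtW @ Xs                                        # (P, 3, 3)
    Ainv = np.linalg.pinv(A)
    c = np.einsum("pkn,bn->pbk", XtW, Y)                # (P, B, 3)
    explained = np.einsum("pbk,pkl,pbl->pb", c, Ainv, c)
    total = (Y**2 * w[None, :]).sum(axis=1)             # (B,)
    sse = total[None, :] - explained                    # (P, B)
    return np.clip(sse.min(axis=0), 0.0, None)


def breakpoint_f_stat(sse_linear: float, sse_segmented: float,
                      df_segmented: int) -> float:
    """F = ((SSE_lin - SSE_seg)/2) / (SSE_seg/df); 2 extra params (b2, psi)."""
    if sse_segmented <= 0:
        return float("inf")
    return ((sse_linear - sse_segmented) / 2.0) / (sse_segmented / df_segmented)


def test_breakpoint(panel_or_t, fit: SegmentedFit, y=None, w=None,
                    n_boot: int = 499, seed: int = 0) -> float:
    """Parametric bootstrap p-value for the existence of a breakpoint.

    Simulates ``n_boot`` responses from the fitted no-breakpoint weighted
    linear model (normal errors with variance sigma^2 / w_i taken from its
    weighted residual mean square), recomputes the F statistic comparing
    linear and segmented fits for each, and returns
    (1 + #{F_boot >= F_obs}) / (n_boot + 1).
    """
    if n_boot < 99:
        raise ModelError(f"n_boot must be >= 99, got {n_boot}")
    if not fit.converged:
        raise ModelError(
            "segmented fit did not converge "
            f"(gamma_final={fit.gamma_final:.3g}); breakpoint test refused")
    if y is None:
        t, y, w, _, _, _ = _panel_arrays(list(panel_or_t), ())
    else:
        t = np.asarray(panel_or_t, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones_like(t) if w is None else np.asarray(w, dtype=float)

    Xlin = np.column_stack([np.ones_like(t), t])
    beta_lin, sse_lin, _ = _wls_solve(Xlin, y, w)
    sigma2 = sse_lin / (t.size - 2)
    df_seg = fit.df_resid
    f_obs = breakpoint_f_stat(sse_lin, fit.weighted_sse, df_seg)

    rng = np.random.default_rng(seed)
    scale = np.sqrt(sigma2 / w)
    Y = (Xlin @ beta_lin)[None, :] + rng.normal(
        0.0, 1.0, size=(n_boot, t.size)) * scale[None, :]
    # linear SSE per replicate via the hat matrix of the null design
    sw = np.sqrt(w)
    Q, _ = np.linalg.qr(Xlin * sw[:, None])
    Yw = Y * sw[None, :]
    sse_lin_b = (Yw**2).sum(axis=1) - ((Yw @ Q) ** 2).sum(axis=1)
    sse_seg_b = _grid_sse_batch(t, w, Y)
    f_boot = ((sse_lin_b - sse_seg_b) / 2.0) / (sse_seg_b / df_seg)
    p = (1.0 + int(np.sum(f_boot >= f_obs))) / (n_boot + 1.0)
    fit.p_break = p
    fit.n_boot = n_boot
    return p


# --------------------------------------------------------------------------
# residual diagnostics

def export_residual_diagnostics(fit: TrendFit):
    """Sorted standardized residuals paired with normal plotting positions.

    Residuals are standardized as sqrt(w_i) r_i / sqrt(weighted MSE) and
    paired with Phi^-1((i - 0.5)/n), for visual inspection of normality
    and heteroscedasticity.
    """
    import pandas as pd

    n = fit.residuals.size
    if n < 3:
        raise ModelError(f"need >= 3 residuals, got {n}")
    scaled = np.sqrt(fit.weights) * fit.residuals
    rms = math.sqrt(fit.sigma2)
    # an (exactly or numerically) perfect fit has no residual scale
    tiny = 1e-10 * max(1.0, float(np.sqrt(np.mean(fit.weights * fit.fitted**2))))
    std = scaled / rms if rms > tiny else np.zeros_like(scaled)
    std = np.sort(std)
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"standardized_residual": std,
                         "normal_quantile": q})
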