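"""Voxelwise mono-exponential T2 estimation with significance gating.

The signal of a multiple-spin-echo voxel follows ``SI = beta *
exp(-TE/T2)`` from the second echo onward (the first echo is a pure
primary echo while later echoes are enhanced by stimulated-echo
pathways, so it is discarded unconditionally).  Trailing echoes whose
signal-to-noise ratio falls below 2 are also discarded.  The nonlinear
fit is initialized from a robust (Tukey-bisquare IRLS) linear regression
of ``ln(SI)`` on TE when that fit is itself significant, and from the
defaults ``beta=500, T2=50 ms`` otherwise; it is solved by
Levenberg-Marquardt.  A voxel enters the T2 map only if both parameter
estimates reject the null at p < 0.05 on the t-distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize
from scipy import stats as sps

LN2 = math.log(2.0)

# reject-reason codes
REASON_NONE = ""
REASON_INSUFFICIENT = "insufficient_points"
REASON_NONSIGNIFICANT = "nonsignificant"
REASON_NONCONVERGED = "nonconverged"
REASON_BELOW_NOISE = "below_noise"


def halflife_ms(t2_ms: float) -> float:
    """Transverse-magnetization half-life ``T2 * ln 2`` (ms).

    Used for TE-grid design: T2 ~ 50 ms gives a half-life of ~35 ms, so a
    last TE of ~103 ms samples about three half-lives of the decay.
    """
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("t2_ms must be positive")
    out = t2 * LN2
    return float(out) if out.ndim == 0 else out


@dataclass
class FitConfig:
    """Tunables of the voxelwise fit; defaults follow the pipeline text."""

    alpha: float = 0.05          # significance level for both gates
    snr_cut: float = 2.0         # trailing echoes below this SNR are dropped
    min_points: int = 3          # 2-parameter fit + >=1 dof for the t-test
    default_beta: float = 500.0  # fallback initial values
    default_t2_ms: float = 50.0
    t2_bounds_ms: tuple[float, float] = (1.0, 2000.0)
    lm_max_iter: int = 200
    lm_tol: float = 1e-8
    irls_max_iter: int = 50
    irls_tol: float = 1e-8
    bisquare_c: float = 4.685

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class EchoSeries:
    """One voxel's signal intensities over the TE grid."""

    te_ms: np.ndarray
    si: np.ndarray
    noise_sd: float = 0.0  # 0 disables the SNR-based trailing cut

    def __post_init__(self):
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.te_ms.shape != self.si.shape or self.te_ms.ndim != 1:
            raise ValueError("te_ms and si must be 1-D of equal length")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("te_ms must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class VoxelFit:
    beta: float = np.nan
    t2_ms: float = np.nan
    se_beta: float = np.nan
    se_t2: float = np.nan
    p_beta: float = 1.0
    p_t2: float = 1.0
    ci95_beta: tuple[float, float] = (np.nan, np.nan)
    ci95_t2: tuple[float, float] = (np.nan, np.nan)
    n_points_used: int = 0
    accepted: bool = False
    init_source: str = "default"  # robust_linear | default
    reject_reason: str = REASON_NONE
    first_echo_si: float = np.nan  # fallback for the synthetic PDW image


@dataclass
class T2Map:
    """Accepted T2 values and acceptance bookkeeping over an ROI."""

    t2_ms: np.ndarray          # NaN where not accepted
    accept_mask: np.ndarray    # bool
    reject_reason: np.ndarray  # object/str codes, "" where accepted
    fits: pd.DataFrame | None = None  # flat per-voxel table (row, col, ...)


def select_points(series: EchoSeries, config: FitConfig | None = None):
    """Apply the echo-selection rules; returns (reduced series, n kept).

    The first echo is removed unconditionally.  Then the trailing
    contiguous run of echoes with ``SI/noise_sd`` below the SNR cut is
    removed, scanning from the last echo backward; isolated low points in
    the interior of the curve are kept (the discard rule targets the long
    TEs where the curve sinks into the noise floor, and removing interior
    dips would bias the fit against downward noise excursions).
    """
    config = config or FitConfig()
    te, si = series.te_ms[1:], series.si[1:]
    n = len(si)
    if series.noise_sd > 0:
        thr = config.snr_cut * series.noise_sd
        while n > 0 and si[n - 1] < thr:
            n -= 1
    kept = EchoSeries(te[:n].copy(), si[:n].copy(), series.noise_sd)
    return kept, n


def robust_loglinear_fit(series: EchoSeries, config: FitConfig | None = None):
    """Tukey-bisquare IRLS fit of ``ln(SI)`` against TE.

    Returns a dict with beta0, t2_ms0, p_beta, p_t2, ok.  The slope s and
    intercept a of the weighted line map back through ``T2 = -1/s`` (only
    for s < 0) and ``beta = exp(a)``.  Standard errors come from the
    weighted normal equations; p-values are two-tailed t-tests of
    estimate/SE with n - 2 degrees of freedom.  Ordinary least squares on
    log-transformed magnitudes is noise-sensitive because the log skews
    the error distribution, hence the redescending bisquare weights.
    """
    config = config or FitConfig()
    pos = series.si > 0
    te, y = series.te_ms[pos], np.log(series.si[pos])
    n = len(y)
    out = dict(beta0=np.nan, t2_ms0=np.nan, p_beta=1.0, p_t2=1.0, ok=False)
    if n < 3:
        return out

    X = np.column_stack([np.ones(n), te])
    w = np.ones(n)
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(config.irls_max_iter):
        r = y - X @ coef
        # normalized MAD about zero (residuals are already centered); the
        # median-centered form degenerates when one abscissa-centered
        # outlier shifts only the intercept
        scale = np.median(np.abs(r)) / 0.6745
        if scale < 1e-12:
            if np.max(np.abs(r)) < 1e-9:  # exact fit: weights irrelevant
                break
            scale = np.max(np.abs(r)) * 1e-6  # majority exact, outliers remain
        u = r / (config.bisquare_c * scale)
        w_new = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w_new.sum() < 2:  # degenerate: fall back to unweighted
            w_new = np.ones(n)
        coef = np.linalg.lstsq(X * np.sqrt(w_new)[:, None], y * np.sqrt(w_new), rcond=None)[0]
        if np.max(np.abs(w_new - w)) < config.irls_tol:
            w = w_new
            break
        w = w_new

    a, s = coef
    r = y - X @ coef
    dof = n - 2
    sw = np.sum(w * r**2) / dof if dof > 0 else np.inf
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = sw * np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return out
    se_a, se_s = np.sqrt(np.maximum(np.diag(cov), 0.0))
    p_a = _p_two_tailed(a, se_a, dof)
    p_s = _p_two_tailed(s, se_s, dof)
    if s >= 0:  # non-decaying: no admissible T2
        out.update(beta0=math.exp(min(a, 700)), p_beta=p_a, p_t2=1.0)
        return out
    out.update(beta0=math.exp(min(a, 700)), t2_ms0=-1.0 / s,
               p_beta=p_a, p_t2=p_s, ok=True)
    return out


def _p_two_tailed(est: float, se: float, dof: int) -> float:
    if dof <= 0 or not np.isfinite(se):
        return 1.0
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * sps.t.sf(abs(est) / se, dof))


def _model_residual(params, te, si):
    return si - params["beta"].value * np.exp(-te / params["t2"].value)


def fit_monoexponential(series: EchoSeries, config: FitConfig | None = None) -> VoxelFit:
    """Full single-voxel pipeline: select points, initialize, LM fit, gate.

    Acceptance requires both ``beta`` and ``T2`` to reject the null at
    ``config.alpha`` (two-tailed t-test of estimate over its standard
    error, ``n - 2`` degrees of freedom, covariance = residual variance
    times the inverse Gauss-Newton curvature).
    """
    config = config or FitConfig()
    fit = VoxelFit(first_echo_si=float(series.si[0]))
    kept, n = select_points(series, config)
    fit.n_points_used = n
    if n < config.min_points:
        fit.reject_reason = REASON_INSUFFICIENT if n > 0 or series.noise_sd == 0 \
            else REASON_BELOW_NOISE
        return fit

    init = robust_loglinear_fit(kept, config)
    lo, hi = config.t2_bounds_ms
    if init["ok"] and init["p_beta"] < config.alpha and init["p_t2"] < config.alpha:
        beta0 = init["beta0"]
        t20 = min(max(init["t2_ms0"], lo * 1.001), hi)
        fit.init_source = "robust_linear"
    else:
        beta0, t20 = config.default_beta, config.default_t2_ms
        fit.init_source = "default"

    params = Parameters()
    params.add("beta", value=max(beta0, 1e-6), min=0.0)
    params.add("t2", value=t20, min=lo, max=hi)
    try:
        res = lm_minimize(_model_residual, params, args=(kept.te_ms, kept.si),
                          method="leastsq", xtol=config.lm_tol, ftol=config.lm_tol,
                          max_nfev=config.lm_max_iter * 3)
    except Exception:
        fit.reject_reason = REASON_NONCONVERGED
        return fit

    beta = float(res.params["beta"].value)
    t2 = float(res.params["t2"].value)
    fit.beta, fit.t2_ms = beta, t2
    dof = n - 2
    resid = kept.si - beta * np.exp(-kept.te_ms / t2)
    s2 = float(resid @ resid) / dof

    J = np.column_stack([
        np.exp(-kept.te_ms / t2),
        beta * kept.te_ms / t2**2 * np.exp(-kept.te_ms / t2),
    ])
    JtJ = J.T @ J
    if np.linalg.cond(JtJ) > 1e12:
        fit.se_beta = fit.se_t2 = np.inf
        fit.reject_reason = REASON_NONSIGNIFICANT
        return fit
    cov = s2 * np.linalg.inv(JtJ)
    fit.se_beta, fit.se_t2 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    fit.p_beta = _p_two_tailed(beta, fit.se_beta, dof)
    fit.p_t2 = _p_two_tailed(t2, fit.se_t2, dof)
    tcrit = float(sps.t.ppf(1 - config.alpha / 2, dof))
    fit.ci95_beta = (beta - tcrit * fit.se_beta, beta + tcrit * fit.se_beta)
    fit.ci95_t2 = (t2 - tcrit * fit.se_t2, t2 + tcrit * fit.se_t2)
    fit.accepted = bool(fit.p_beta < config.alpha and fit.p_t2 < config.alpha)
    if not fit.accepted:
        fit.reject_reason = REASON_NONSIGNIFICANT
    return fit


def fit_t2_map(series_stack: np.ndarray, te_ms: np.ndarray, roi_mask: np.ndarray,
               noise_sd: float, config: FitConfig | None = None) -> T2Map:
    """Fit every ROI voxel of an (n_echo, rows, cols) stack.

    Returns the T2 map (NaN outside acceptance), the acceptance mask,
    per-voxel reject reasons and a flat results table.
    """
    config = config or FitConfig()
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if series_stack.shape[0] != len(te_ms):
        raise ValueError("stack echo count does not match TE vector")
    if series_stack.shape[1:] != roi_mask.shape:
        raise ValueError("stack grid and ROI mask differ")

    t2 = np.full(roi_mask.shape, np.nan)
    acc = np.zeros(roi_mask.shape, dtype=bool)
    why = np.full(roi_mask.shape, "", dtype=object)
    rows = []
    te = np.asarray(te_ms, dtype=float)
    for r, c in zip(*np.nonzero(roi_mask)):
        f = fit_monoexponential(EchoSeries(te, series_stack[:, r, c], noise_sd), config)
        acc[r, c] = f.accepted
        why[r, c] = f.reject_reason
        if f.accepted:
            t2[r, c] = f.t2_ms
        rows.append(dict(row=r, col=c, beta=f.beta, t2_ms=f.t2_ms,
                         se_beta=f.se_beta, se_t2=f.se_t2, p_beta=f.p_beta,
                         p_t2=f.p_t2, n_points_used=f.n_points_used,
                         accepted=f.accepted, init_source=f.init_source,
                         reject_reason=f.reject_reason, first_echo_si=f.first_echo_si))
    return T2Map(t2_ms=t2, accept_mask=acc, reject_reason=why,
                 fits=pd.DataFrame(rows))


def synthetic_image(t2map: T2Map, te_query_ms: float, noise_sd: float):
    """Evaluate the fitted decay curves at ``te_query_ms``.

    For accepted voxels the intensity is ``beta * exp(-te_query/T2)``; for
    fit-rejected voxels (e.g. calcification, which has no decaying
    signal) the measured first-echo intensity stands in, so the
    calcification SNR rule can still evaluate them.  Returns (intensity,
    SNR) images; SNR is NaN when no noise level is known.
    """
    if te_query_ms <= 0:
        raise ValueError("te_query_ms must be positive")
    if t2map.fits is None:
        raise ValueError("T2Map carries no per-voxel fit table")
    img = np.full(t2map.t2_ms.shape, np.nan)
    for rec in t2map.fits.itertuples():
        if rec.accepted:
            img[rec.row, rec.col] = rec.beta * math.exp(-te_query_ms / rec.t2_ms)
        else:
            img[rec.row, rec.col] = rec.first_echo_si
    snr = img / noise_sd if noise_sd > 0 else np.full_like(img, np.nan)
    return img, snr


def estimate_noise_sd(series_stack: np.ndarray, background_mask: np.ndarray,
                      method: str = "mean") -> float:
    """Estimate the per-channel noise SD from a signal-free background.

    On magnitude images the background is Rayleigh distributed, so
    ``sigma = mean / sqrt(pi/2)`` ("mean" method) or ``sigma = SD /
    sqrt(2 - pi/2)`` ("sd" method).  The last echo is used: it is the
    closest to signal-free everywhere.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("background mask is empty")
    vals = series_stack[-1][background_mask].astype(float)
    if method == "mean":
        est = float(vals.mean() / math.sqrt(math.pi / 2.0))
    elif method == "sd":
        est = float(vals.std(ddof=1) / math.sqrt(2.0 - math.pi / 2.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    if est == 0:
        import warnings

        warnings.warn("background is identically zero; noise SD estimate is 0")
    return est
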