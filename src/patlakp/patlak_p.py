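"""Patlak-P: AIF-free parametric mapping of late-time dynamic PET.

Under the well-mixed assumption the late-time plasma curve decays
mono-exponentially, AIF(t) = AIF0 * exp(-lambda (t - t0)), and the tissue
curve of an irreversible tracer relative to the first late frame becomes

    P(t) = P(t0) + alpha * (1 - exp(-lambda (t - t0)))

with alpha = AIF0 * (Ki/lambda - V).  The extrapolated activity at infinite
time, Pinf = P(t0) + alpha, equals Ki * (iAIF0 + AIF0/lambda): a parametric
map of Pinf is a Ki map up to one global scale factor, obtained without
measuring the input function.

The fit proceeds in two stages: (1) lambda, the only nonlinear parameter
and global by assumption, is estimated once from a high-statistics ROI
time-activity curve by multi-start weighted Levenberg-Marquardt; (2) with
lambda fixed, each voxel needs only a 2-parameter weighted *linear* fit on
the design [1, 1 - exp(-lambda (t - t0))].  Weights are dt_j * DF_j
throughout (frame duration times radioactive decay factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    ConfigurationError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
)
from .kinetics import InputFunction
from .phantom import DynamicImage, FrameSchedule

__all__ = [
    "PatlakPConfig",
    "PatlakPResult",
    "roi_tac",
    "fit_lambda_roi",
    "voxel_fit_linear",
    "ki_from_pinf",
    "suv_infinity",
]


@dataclass(frozen=True)
class PatlakPConfig:
    """Tuning knobs of the two-stage fit.

    ``lambda_bounds`` constrain the tail decay constant (1/min); 25
    log-spaced starts inside the bounds guard against local minima of the
    nonlinear stage.  ``voxel_mask_fraction`` skips voxels whose mean
    activity falls below that fraction of the brightest voxel mean
    (background air), and ``floor_negative_pinf`` clamps negative
    extrapolations to zero (both are flagged, never silent).
    """

    lambda_bounds: tuple = (1e-3, 1.0)
    n_multistart: int = 25
    tol: float = 1e-10
    max_iter: int = 200
    voxel_mask_fraction: float = 0.05
    floor_negative_pinf: bool = False
    start_jitter: float = 0.0  # relative log-jitter of the lambda starts

    def __post_init__(self):
        lo, hi = self.lambda_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("need 0 < lambda_min < lambda_max")
        if self.n_multistart < 1:
            raise ConfigurationError("n_multistart must be >= 1")


@dataclass(frozen=True)
class PatlakPResult:
    """Two-stage fit output: global lambda plus voxel maps.

    ``pinf_map = p0_map + alpha_map`` elementwise (before optional
    flooring, recorded in ``floored``).
    """

    lambda_hat: float
    p0_map: np.ndarray
    alpha_map: np.ndarray
    pinf_map: np.ndarray
    r2_map: np.ndarray
    t0: float
    skipped: np.ndarray
    floored: np.ndarray
    roi_fit_diagnostics: dict = field(default_factory=dict)


def roi_tac(img: DynamicImage, mask: np.ndarray) -> np.ndarray:
    """Mean time-activity curve of a region: rows (mid_min, Bq/mL).

    Unweighted spatial mean of the masked voxels in each frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape3d:
        raise ConfigurationError("mask shape does not match image grid")
    if not mask.any():
        raise ConfigurationError("empty ROI mask")
    tac = img.data[mask].mean(axis=0)
    return np.column_stack([img.schedule.mids, tac])


def _model(theta: np.ndarray, dt: np.ndarray) -> np.ndarray:
    p0, alpha, lam = theta
    return p0 + alpha * (1.0 - np.exp(-lam * dt))


def fit_lambda_roi(tac: np.ndarray, schedule: FrameSchedule,
                   config: PatlakPConfig = PatlakPConfig(),
                   seed: int = 0,
                   lambda_starts: np.ndarray | None = None):
    """Stage 1: estimate the global tail decay constant from an ROI TAC.

    Parameters
    ----------
    tac:
        Array of rows (mid_min, activity) as returned by :func:`roi_tac`.
    schedule:
        Frame schedule supplying the dt * DF weights.
    config:
        Multi-start / bounds configuration.
    seed:
        Only used when ``config.start_jitter > 0``; the fit is otherwise
        fully deterministic.
    lambda_starts:
        Explicit initial lambda values overriding the log-spaced starts
        (all must lie within the bounds); mainly for reproducing the
        multi-start selection with a chosen start.

    Returns
    -------
    (lambda_hat, p0, alpha, diagnostics) where diagnostics holds the
    weighted SSE of every start, the chosen start and iteration counts.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.ndim != 2 or tac.shape[1] != 2:
        raise ConfigurationError("tac must be an (n, 2) array of (mid, value)")
    times, y = tac[:, 0], tac[:, 1]
    if len(times) < 4:
        raise InsufficientDataError("lambda fit needs at least 4 frames")
    if len(times) != schedule.n_frames or not np.allclose(times, schedule.mids):
        raise ConfigurationError("TAC times do not match the frame schedule mids")

    t0 = times[0]
    dt = times - t0
    sw = np.sqrt(schedule.weights)
    lo, hi = config.lambda_bounds

    if lambda_starts is not None:
        lam_starts = np.asarray(lambda_starts, dtype=float)
        if np.any((lam_starts < lo) | (lam_starts > hi)):
            raise ConfigurationError("explicit lambda starts outside bounds")
    else:
        lam_starts = np.geomspace(lo, hi, config.n_multistart)
    if config.start_jitter > 0:
        rng = np.random.default_rng(seed)
        jitter = np.exp(config.start_jitter * rng.standard_normal(lam_starts.shape))
        lam_starts = np.clip(lam_starts * jitter, lo, hi)

    p0_init = y[0]
    alpha_init = y[-1] - y[0]

    def resid(theta):
        return sw * (_model(theta, dt) - y)

    bounds = ([-np.inf, -np.inf, lo], [np.inf, np.inf, hi])
    results = []
    for i, lam0 in enumerate(lam_starts):
        try:
            sol = least_squares(resid, x0=[p0_init, alpha_init, lam0],
                                bounds=bounds, method="trf",
                                xtol=config.tol, ftol=config.tol, gtol=config.tol,
                                max_nfev=config.max_iter * 4)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            results.append({"idx": i, "lam0": float(lam0), "sse": np.inf,
                            "ok": False, "error": str(exc)})
            continue
        sse = float(2.0 * sol.cost)
        results.append({"idx": i, "lam0": float(lam0), "sse": sse,
                        "ok": bool(sol.success), "theta": sol.x.copy(),
                        "nfev": int(sol.nfev)})
    ok = [r for r in results if r.get("ok")]
    if not ok:
        raise FitFailureError("no multi-start converged", diagnostics=results)
    # lowest weighted SSE; ties (within tol) broken toward smaller lambda
    best_sse = min(r["sse"] for r in ok)
    tol = 1e-9 * max(best_sse, 1e-30) + 1e-30
    contenders = [r for r in ok if r["sse"] <= best_sse + tol]
    best = min(contenders, key=lambda r: r["theta"][2])
    p0, alpha, lam = best["theta"]
    diagnostics = {
        "sse_per_start": [r["sse"] for r in results],
        "lambda_starts": [r["lam0"] for r in results],
        "chosen_start": best["idx"],
        "iterations": [r.get("nfev", 0) for r in results],
        "t0": float(t0),
    }
    return float(lam), float(p0), float(alpha), diagnostics


def voxel_fit_linear(img: DynamicImage, lambda_hat: float,
                     mask: np.ndarray | None = None,
                     config: PatlakPConfig = PatlakPConfig()) -> PatlakPResult:
    """Stage 2: linearized voxel-wise fit with the global lambda fixed.

    Weighted least squares on the design ``[1, 1 - exp(-lambda (t - t0))]``
    gives P(t0) and alpha per voxel; ``pinf = p0 + alpha`` is the
    extrapolated activity at infinite time.  Dim voxels (mean below
    ``voxel_mask_fraction`` of the brightest voxel mean) are skipped and
    flagged.
    """
    if lambda_hat <= 0:
        raise DomainError("lambda_hat must be positive")
    sched = img.schedule
    mids = sched.mids
    t0 = mids[0]
    g = 1.0 - np.exp(-lambda_hat * (mids - t0))
    w = sched.weights

    shape = img.shape3d
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ConfigurationError("mask shape does not match image grid")
    Y = img.data[mask]  # (n_vox, m)

    vox_mean = Y.mean(axis=1)
    if config.voxel_mask_fraction > 0 and vox_mean.size:
        active = vox_mean >= config.voxel_mask_fraction * vox_mean.max()
    else:
        active = np.ones(vox_mean.shape, dtype=bool)

    # closed-form 2-parameter WLS shared across voxels (common design)
    sw = w.sum()
    gbar = (w * g).sum() / sw
    sgg = (w * (g - gbar) ** 2).sum()
    Ya = Y[active]
    ybar = (Ya * w).sum(axis=1) / sw
    if sgg <= 0:
        raise DomainError("degenerate design: lambda too small for this schedule")
    sgy = ((Ya - ybar[:, None]) * (w * (g - gbar))).sum(axis=1)
    syy = ((Ya - ybar[:, None]) ** 2 * w).sum(axis=1)
    alpha = sgy / sgg
    p0 = ybar - alpha * gbar
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, np.clip(sgy ** 2 / (sgg * syy), 0.0, 1.0), 0.0)
    pinf = p0 + alpha

    floored_v = np.zeros_like(pinf, dtype=bool)
    if config.floor_negative_pinf:
        floored_v = pinf < 0
        pinf = np.where(floored_v, 0.0, pinf)

    def scatter(vals, dtype=float):
        out = np.zeros(shape, dtype=dtype)
        idx = np.zeros(mask.sum(), dtype=dtype)
        idx[active] = vals
        out[mask] = idx
        return out

    skipped = np.zeros(shape, dtype=bool)
    tmp = np.zeros(mask.sum(), dtype=bool)
    tmp[~active] = True
    skipped[mask] = tmp

    return PatlakPResult(
        lambda_hat=float(lambda_hat),
        p0_map=scatter(p0),
        alpha_map=scatter(alpha),
        pinf_map=scatter(pinf),
        r2_map=scatter(r2),
        t0=float(t0),
        skipped=skipped,
        floored=scatter(floored_v, dtype=bool),
    )


def ki_from_pinf(pinf_map: np.ndarray, tail: InputFunction) -> np.ndarray:
    """Convert an extrapolated-activity map to Ki [1/min] via a known tail.

    Requires an exponential-tail AIF with prior knowledge of the pre-tail
    integral ``iaif0``: Ki = Pinf / (iAIF0 + AIF0/lambda).
    """
    if tail.kind != "exponential_tail":
        raise ConfigurationError("Ki conversion needs an exponential_tail AIF")
    if tail.iaif0 is None:
        raise ConfigurationError(
            "iaif0 unknown: Ki conversion requires a-priori knowledge of the "
            "input function (e.g. a population-based AIF)")
    if tail.aif0 <= 0:
        raise ConfigurationError("tail AIF0 must be positive")
    denom = tail.iaif0 + tail.aif0 / tail.lam
    return np.asarray(pinf_map, dtype=float) / denom


def suv_infinity(pinf_map: np.ndarray, dose_bq: float, weight_g: float) -> np.ndarray:
    """SUV normalization of the extrapolated activity: Pinf / (dose/weight).

    The result [g/mL] reflects total irreversible uptake rather than the
    activity of one static frame.
    """
    if dose_bq <= 0 or weight_g <= 0:
        raise DomainError("dose and weight must be positive")
    return np.asarray(pinf_map, dtype=float) / (dose_bq / weight_g)
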