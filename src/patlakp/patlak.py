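"""Classic Patlak graphical analysis.

For an irreversibly trapped tracer at late times t > t*, the tissue
concentration obeys

    P(t) / AIF(t) = Ki * int_0^t AIF(s) ds / AIF(t) + V

so a weighted linear regression of y = P/AIF on the "stretched time"
x = iAIF/AIF yields the net influx rate Ki (slope) and the apparent
distribution volume V (intercept) per voxel.  Weights are dt_j * DF_j
(frame duration times decay factor), matching the extrapolation fitter so
the two methods are compared on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, SingularNormalizationError
from .kinetics import InputFunction, evaluate_aif, integrate_aif
from .phantom import DynamicImage

__all__ = ["PatlakResult", "patlak_fit"]


@dataclass(frozen=True)
class PatlakResult:
    """Voxel-wise Patlak maps: Ki [1/min], V [mL/mL], weighted R^2."""

    ki_map: np.ndarray
    v_map: np.ndarray
    r2_map: np.ndarray
    t_star: float
    frames_used: np.ndarray
    flags: np.ndarray  # True where the voxel regression was degenerate


def _weighted_line_fit(x: np.ndarray, Y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares of many responses on one abscissa.

    x: (m,), Y: (n_vox, m), w: (m,).  Returns slope, intercept, r2, flag.
    Degenerate voxels (zero spread in x or zero signal) get (0, 0, 0, True).
    """
    sw = w.sum()
    xbar = (w * x).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    ybar = (Y * w).sum(axis=1) / sw
    sxy = ((Y - ybar[:, None]) * (w * (x - xbar))).sum(axis=1)
    syy = ((Y - ybar[:, None]) ** 2 * w).sum(axis=1)

    if sxx <= 0:
        raise InsufficientDataError("no spread in Patlak abscissa over the used frames")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy ** 2) / (sxx * syy), 0.0)
    flag = syy <= 0
    # all-zero voxels: report (0, 0) rather than a meaningless intercept
    zero = np.all(Y == 0, axis=1)
    slope[zero] = 0.0
    intercept[zero] = 0.0
    return slope, intercept, np.clip(r2, 0.0, 1.0), flag | zero


def patlak_fit(img: DynamicImage, aif: InputFunction, t_star: float | None = None,
               mask: np.ndarray | None = None) -> PatlakResult:
    """Fit the Patlak model voxel-wise on frames with mid-time >= t*.

    Parameters
    ----------
    img:
        Dynamic study; the AIF must be defined on [0, last frame end]
        (an exponential-tail AIF with known ``iaif0`` qualifies, its
        pre-tail integral being taken from the prior).
    aif:
        Arterial input function.
    t_star:
        Start of the linear regime; defaults to the first frame mid
        (i.e. all frames of a late-time acquisition are used).
    mask:
        Optional 3-D boolean array restricting the fit.
    """
    sched = img.schedule
    mids = sched.mids
    if t_star is None:
        t_star = float(mids[0])
    used = np.flatnonzero(mids >= t_star - 1e-9)
    if used.size < 3:
        raise InsufficientDataError(
            f"need >= 3 frames with mid >= t*={t_star}, have {used.size}")

    aif_mid = evaluate_aif(aif, mids[used])
    if np.any(aif_mid <= 0):
        raise SingularNormalizationError("AIF is zero at a used frame mid")
    iaif = np.array([integrate_aif(aif, 0.0, m) for m in mids[used]])

    x = iaif / aif_mid
    w = sched.weights[used]

    shape = img.shape3d
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    vox = img.data[mask][:, used]  # (n_vox, m)
    Y = vox / aif_mid

    slope, intercept, r2, flag = _weighted_line_fit(x, Y, w)

    ki_map = np.zeros(shape)
    v_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    flags = np.zeros(shape, dtype=bool)
    ki_map[mask] = slope
    v_map[mask] = intercept
    r2_map[mask] = r2
    flags[mask] = flag
    return PatlakResult(ki_map=ki_map, v_map=v_map, r2_map=r2_map,
                        t_star=float(t_star), frames_used=used, flags=flags)
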