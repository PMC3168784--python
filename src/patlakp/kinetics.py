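"""Forward model of tracer kinetics: input functions and tissue curves.

This module provides the arterial input function (AIF) representations and
the irreversible two-tissue-compartment forward model used both as the
simulation ground truth for phantoms and as the reference ("oracle") against
which all fitters in the package are validated.

Units are fixed throughout the package: time in minutes post-injection,
rate constants in 1/min, activity concentrations in Bq/mL.

The tissue model is the standard FDG-type two-tissue compartment model

    dC1/dt = K1 * AIF(t) - (k2 + k3) * C1 + k4 * C2
    dC2/dt = k3 * C1 - k4 * C2

with the PET-measured signal ``P(t) = (1 - Vb) * (C1 + C2) + Vb * AIF(t)``.
For irreversible trapping (k4 = 0) the net influx rate is the Patlak slope
``Ki = K1 * k3 / (k2 + k3)``.

Tissue curves are computed by *analytic* convolution of the compartmental
impulse response (a sum of exponentials) with the AIF: exactly for
parametric AIFs, and segment-wise exactly for piecewise-linear sampled
AIFs.  There is therefore no ODE-solver tolerance in the reference model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    OutOfRangeError,
    UnsupportedError,
)

__all__ = [
    "InputFunction",
    "CompartmentParams",
    "evaluate_aif",
    "integrate_aif",
    "tissue_curve",
    "macro_ki",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_AIF_KINDS = ("sampled", "tri_exponential", "exponential_tail")


@dataclass(frozen=True)
class InputFunction:
    """Arterial input function in one of three representations.

    Parameters
    ----------
    kind:
        ``"sampled"`` -- plasma samples, linearly interpolated;
        ``"tri_exponential"`` -- sum of (up to three) exponential terms
        ``sum_i A_i * exp(-r_i * t)`` defined for all t >= 0;
        ``"exponential_tail"`` -- mono-exponential late-time tail
        ``AIF0 * exp(-lambda * (t - t0))`` defined only for t >= t0.
    times, activities:
        Sample grid (min) and values (Bq/mL) for the sampled kind.
    amplitudes, rates:
        Term amplitudes (Bq/mL) and decay rates (1/min) for the
        tri-exponential kind.  Negative amplitudes are allowed (they shape
        the initial rise) as long as the curve is non-negative for t >= 0.
    t0, aif0, lam:
        Tail start (min), tail value at t0 (Bq/mL) and tail decay constant
        (1/min) for the exponential-tail kind.
    iaif0:
        Integral of the AIF from 0 to t0 (Bq*min/mL); optional prior
        knowledge used to convert extrapolated activity into Ki.
    """

    kind: str
    times: np.ndarray | None = None
    activities: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    rates: np.ndarray | None = None
    t0: float | None = None
    aif0: float | None = None
    lam: float | None = None
    iaif0: float | None = None

    def __post_init__(self):
        if self.kind not in _AIF_KINDS:
            raise ConfigurationError(f"unknown AIF kind {self.kind!r}")
        if self.kind == "sampled":
            if self.times is None or self.activities is None:
                raise ConfigurationError("sampled AIF needs times and activities")
            t = np.asarray(self.times, dtype=float)
            a = np.asarray(self.activities, dtype=float)
            if t.ndim != 1 or t.shape != a.shape or t.size < 2:
                raise ConfigurationError("sampled AIF needs matching 1-D arrays, >= 2 samples")
            if np.any(np.diff(t) <= 0):
                raise ConfigurationError("sample times must be strictly increasing")
            if np.any(a < 0) or np.any(t < 0):
                raise ConfigurationError("sample times and activities must be non-negative")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "activities", a)
        elif self.kind == "tri_exponential":
            if self.amplitudes is None or self.rates is None:
                raise ConfigurationError("tri_exponential AIF needs amplitudes and rates")
            A = np.asarray(self.amplitudes, dtype=float)
            r = np.asarray(self.rates, dtype=float)
            if A.shape != r.shape or A.ndim != 1 or A.size < 1:
                raise ConfigurationError("amplitudes and rates must be matching 1-D arrays")
            if np.any(r <= 0):
                raise ConfigurationError("tri-exponential rates must be positive")
            object.__setattr__(self, "amplitudes", A)
            object.__setattr__(self, "rates", r)
            # non-negativity of the modelled curve, checked on a dense grid
            tchk = np.linspace(0.0, 5.0 / r.min(), 2048)
            vals = np.exp(-np.outer(tchk, r)) @ A
            if np.any(vals < -1e-9 * max(1.0, np.abs(A).max())):
                raise ConfigurationError("tri-exponential AIF is negative for some t >= 0")
        else:  # exponential_tail
            if self.t0 is None or self.aif0 is None or self.lam is None:
                raise ConfigurationError("exponential_tail AIF needs t0, aif0 and lam")
            if self.lam <= 0:
                raise ConfigurationError("tail decay constant lambda must be > 0")
            if self.aif0 < 0 or self.t0 < 0:
                raise ConfigurationError("t0 and aif0 must be non-negative")
            if self.iaif0 is not None and self.iaif0 < 0:
                raise ConfigurationError("iaif0 must be non-negative")

    # -- convenience ---------------------------------------------------

    @property
    def iaif_inf(self) -> float:
        """Total integrated activity from 0 to infinity (Bq*min/mL).

        For the exponential-tail kind this is ``iAIF0 + AIF0/lambda`` and
        requires ``iaif0``; for the tri-exponential kind it is
        ``sum_i A_i / r_i``.
        """
        if self.kind == "exponential_tail":
            if self.iaif0 is None:
                raise ConfigurationError("iaif0 unknown: cannot form total integral")
            return float(self.iaif0 + self.aif0 / self.lam)
        if self.kind == "tri_exponential":
            return float(np.sum(self.amplitudes / self.rates))
        raise UnsupportedError("infinite integral undefined for sampled AIF")

    def tail(self, t0: float) -> "InputFunction":
        """Exponential-tail view of a parametric AIF at a chosen tail start.

        Uses the slowest exponential term as the asymptotic tail and folds
        everything before ``t0`` into ``iaif0``.  Only meaningful when the
        faster terms have decayed by ``t0``.
        """
        if self.kind == "exponential_tail":
            if t0 < self.t0:
                raise DomainError("cannot move tail start before t0")
            new_iaif0 = None
            if self.iaif0 is not None:
                new_iaif0 = self.iaif0 + integrate_aif(self, self.t0, t0)
            return InputFunction(
                kind="exponential_tail",
                t0=t0,
                aif0=float(evaluate_aif(self, [t0])[0]),
                lam=self.lam,
                iaif0=new_iaif0,
            )
        if self.kind == "tri_exponential":
            lam = float(self.rates.min())
            return InputFunction(
                kind="exponential_tail",
                t0=float(t0),
                aif0=float(evaluate_aif(self, [t0])[0]),
                lam=lam,
                iaif0=float(integrate_aif(self, 0.0, t0)),
            )
        raise UnsupportedError("tail extraction requires a parametric AIF")

    # -- (de)serialization --------------------------------------------

    def to_json_dict(self) -> dict:
        if self.kind == "sampled":
            return {
                "kind": "sampled",
                "time_min": self.times.tolist(),
                "activity_bq_ml": self.activities.tolist(),
            }
        if self.kind == "tri_exponential":
            return {
                "kind": "tri_exponential",
                "amplitudes": self.amplitudes.tolist(),
                "rates": self.rates.tolist(),
            }
        d = {
            "kind": "exponential_tail",
            "t0": self.t0,
            "aif0": self.aif0,
            "lambda": self.lam,
        }
        if self.iaif0 is not None:
            d["iaif0"] = self.iaif0
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "InputFunction":
        kind = d.get("kind")
        if kind == "sampled":
            return cls(kind="sampled", times=np.asarray(d["time_min"], float),
                       activities=np.asarray(d["activity_bq_ml"], float))
        if kind == "tri_exponential":
            return cls(kind="tri_exponential",
                       amplitudes=np.asarray(d["amplitudes"], float),
                       rates=np.asarray(d["rates"], float))
        if kind == "exponential_tail":
            return cls(kind="exponential_tail", t0=float(d["t0"]),
                       aif0=float(d["aif0"]), lam=float(d["lambda"]),
                       iaif0=(float(d["iaif0"]) if "iaif0" in d and d["iaif0"] is not None else None))
        raise FormatError(f"unknown AIF kind in JSON: {kind!r}")


def read_aif(path) -> InputFunction:
    """Read an AIF from disk: CSV (`time_min,activity_bq_ml`) or JSON."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return InputFunction.from_json_dict(json.load(fh))
    df = pd.read_csv(path)
    if not {"time_min", "activity_bq_ml"} <= set(df.columns):
        raise FormatError("sampled AIF CSV needs columns time_min,activity_bq_ml")
    return InputFunction(kind="sampled",
                         times=df["time_min"].to_numpy(float),
                         activities=df["activity_bq_ml"].to_numpy(float))


def write_aif(aif: InputFunction, path) -> None:
    path = str(path)
    if aif.kind == "sampled" and path.endswith(".csv"):
        pd.DataFrame({"time_min": aif.times, "activity_bq_ml": aif.activities}).to_csv(
            path, index=False)
        return
    with open(path, "w") as fh:
        json.dump(aif.to_json_dict(), fh, indent=2)
        fh.write("\n")


@dataclass(frozen=True)
class CompartmentParams:
    """Two-tissue-compartment rate constants.

    K1 [mL/min/mL] is delivery (GLUT transport for FDG), k2 [1/min] efflux,
    k3 [1/min] trapping (hexokinase phosphorylation), k4 [1/min] release
    (zero in the irreversible regime), Vb the fractional blood volume.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    Vb: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ConfigurationError("rate constants must be non-negative")
        if not (0.0 <= self.Vb < 1.0):
            raise ConfigurationError("Vb must lie in [0, 1)")

    @property
    def ki(self) -> float:
        return macro_ki(self)

    @property
    def patlak_volume(self) -> float:
        """Apparent distribution volume V of the Patlak intercept.

        For the irreversible model this is ``Vb + K1*k2/(k2+k3)^2``
        (reversible free compartment plus blood fraction).
        """
        if self.k2 + self.k3 == 0:
            raise DomainError("V undefined for k2 + k3 = 0")
        return self.Vb + (1.0 - self.Vb) * self.K1 * self.k2 / (self.k2 + self.k3) ** 2


def macro_ki(params: CompartmentParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) [1/min] of the irreversible model."""
    if params.k2 + params.k3 <= 0:
        raise DomainError("Ki undefined when k2 + k3 = 0")
    return params.K1 * params.k3 / (params.k2 + params.k3)


# ---------------------------------------------------------------------------
# AIF evaluation / integration
# ---------------------------------------------------------------------------


def evaluate_aif(aif: InputFunction, times: Sequence[float]) -> np.ndarray:
    """Evaluate the AIF at the given times (min), returning Bq/mL."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise DomainError("negative time")
    if aif.kind == "exponential_tail":
        if np.any(t < aif.t0 - 1e-12):
            raise DomainError("exponential tail undefined before t0")
        return aif.aif0 * np.exp(-aif.lam * (t - aif.t0))
    if aif.kind == "tri_exponential":
        return np.exp(-np.outer(t, aif.rates)) @ aif.amplitudes
    # sampled: linear interpolation, no extrapolation
    if np.any(t < aif.times[0] - 1e-12) or np.any(t > aif.times[-1] + 1e-12):
        raise OutOfRangeError("time outside sampled AIF support")
    return np.interp(t, aif.times, aif.activities)


def integrate_aif(aif: InputFunction, t_from: float, t_to: float) -> float:
    """Integral of the AIF over [t_from, t_to] in Bq*min/mL.

    Analytic for parametric kinds (``t_to`` may be ``inf``); exact
    trapezoidal integral of the piecewise-linear interpolant for sampled
    AIFs.  For the exponential-tail kind, ``t_from = 0`` is allowed when
    ``iaif0`` is known (the pre-tail area is taken from it).
    """
    if t_to < t_from:
        raise DomainError("t_to must be >= t_from")
    if t_from == t_to:
        return 0.0
    if aif.kind == "tri_exponential":
        A, r = aif.amplitudes, aif.rates
        upper = np.zeros_like(A) if np.isinf(t_to) else np.exp(-r * t_to)
        return float(np.sum(A / r * (np.exp(-r * t_from) - upper)))
    if aif.kind == "exponential_tail":
        extra = 0.0
        if t_from < aif.t0 - 1e-12:
            if aif.iaif0 is None or t_from > 1e-12:
                raise DomainError("exponential tail undefined before t0")
            extra, t_from = aif.iaif0, aif.t0
        upper = 0.0 if np.isinf(t_to) else np.exp(-aif.lam * (t_to - aif.t0))
        lower = np.exp(-aif.lam * (t_from - aif.t0))
        return float(extra + aif.aif0 / aif.lam * (lower - upper))
    # sampled
    if np.isinf(t_to):
        raise UnsupportedError("infinite integral of a sampled AIF")
    for t in (t_from, t_to):
        if t < aif.times[0] - 1e-12 or t > aif.times[-1] + 1e-12:
            raise OutOfRangeError("integration bound outside sampled AIF support")
    inner = aif.times[(aif.times > t_from) & (aif.times < t_to)]
    grid = np.concatenate([[t_from], inner, [t_to]])
    vals = np.interp(grid, aif.times, aif.activities)
    return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# Tissue curve: analytic convolution of the compartmental impulse response
# ---------------------------------------------------------------------------


def _irf_terms(p: CompartmentParams) -> list[tuple[float, float, int]]:
    """Impulse response of C1+C2 as [(coefficient, decay rate, t-power)].

    Each term contributes ``coef * t**power * exp(-rate*t)`` (power 0 or 1;
    power 1 only at the measure-zero repeated-eigenvalue point).
    """
    K1, k2, k3, k4 = p.K1, p.k2, p.k3, p.k4
    s = k2 + k3 + k4
    if s == 0.0:
        return [(K1, 0.0, 0)]  # pure integrator
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - sq)
    a2 = 0.5 * (s + sq)
    if sq > 1e-12 * s:
        c1 = K1 * (k3 + k4 - a1) / (a2 - a1)
        c2 = K1 * (a2 - k3 - k4) / (a2 - a1)
        return [(c1, a1, 0), (c2, a2, 0)]
    # repeated eigenvalue a1 == a2 == s/2
    a = 0.5 * s
    return [(K1, a, 0), (K1 * (k3 + k4 - a), a, 1)]


def _conv_exp_with_exp(alpha: float, r: float, t: np.ndarray) -> np.ndarray:
    """exp(-alpha t) (*) exp(-r t) on [0, t]."""
    if abs(alpha - r) > 1e-12 * max(1.0, alpha, r):
        return (np.exp(-r * t) - np.exp(-alpha * t)) / (alpha - r)
    return t * np.exp(-alpha * t)


def _conv_texp_with_exp(alpha: float, r: float, t: np.ndarray) -> np.ndarray:
    """(t exp(-alpha t)) (*) exp(-r t) on [0, t]."""
    if abs(alpha - r) > 1e-9 * max(1.0, alpha, r):
        d = alpha - r
        return (np.exp(-r * t) - np.exp(-alpha * t)) / d**2 - t * np.exp(-alpha * t) / d
    return 0.5 * t * t * np.exp(-alpha * t)


def _conv_exp_with_linear_segments(alpha: float, st: np.ndarray, sv: np.ndarray,
                                   t: np.ndarray) -> np.ndarray:
    """exp(-alpha u) convolved with a piecewise-linear curve, exactly.

    ``st, sv`` define the sampled curve; output at each time in ``t``
    (all within the sampled support).  Closed-form per linear segment.
    """
    out = np.zeros_like(t)
    slopes = np.diff(sv) / np.diff(st)
    for j, tj in enumerate(t):
        acc = 0.0
        for i in range(len(st) - 1):
            u, v = st[i], min(st[i + 1], tj)
            if v <= u:
                break
            a = sv[i] - slopes[i] * st[i]  # segment value = a + b*s
            b = slopes[i]
            if alpha > 1e-14:
                # \int_u^v e^{-alpha (tj - s)} (a + b s) ds
                eu = np.exp(-alpha * (tj - u))
                ev = np.exp(-alpha * (tj - v))
                term = (ev * ((a + b * v) / alpha - b / alpha**2)
                        - eu * ((a + b * u) / alpha - b / alpha**2))
                acc += term
            else:
                acc += a * (v - u) + 0.5 * b * (v * v - u * u)
        out[j] = acc
    return out


def tissue_curve(params: CompartmentParams, aif: InputFunction,
                 times: Sequence[float]) -> np.ndarray:
    """PET tissue signal P(t) [Bq/mL] of the two-tissue model at ``times``.

    ``P(t) = (1-Vb) * (C1+C2)(t) + Vb * AIF(t)`` with zero initial
    conditions.  The compartmental response is evaluated by analytic
    convolution, so this routine can serve as the exact reference for the
    fitters.  The AIF must be defined on ``[0, max(times)]``.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise DomainError("negative time")
    if aif.kind == "exponential_tail" and aif.t0 > 1e-12:
        raise DomainError("exponential-tail AIF is undefined on [0, t0); "
                          "use a full-support AIF to drive the tissue model")

    terms = _irf_terms(params)
    ct = np.zeros_like(t)
    if aif.kind == "tri_exponential" or aif.kind == "exponential_tail":
        if aif.kind == "tri_exponential":
            amps, rates = aif.amplitudes, aif.rates
        else:  # tail with t0 == 0: single exponential
            amps, rates = np.array([aif.aif0]), np.array([aif.lam])
        for coef, alpha, power in terms:
            for A, r in zip(amps, rates):
                if power == 0:
                    ct += coef * A * _conv_exp_with_exp(alpha, r, t)
                else:
                    ct += coef * A * _conv_texp_with_exp(alpha, r, t)
    else:  # sampled: exact convolution with the linear interpolant
        if np.any(t > aif.times[-1] + 1e-12):
            raise OutOfRangeError("time outside sampled AIF support")
        for coef, alpha, power in terms:
            if power == 0:
                ct += coef * _conv_exp_with_linear_segments(
                    alpha, aif.times, aif.activities, t)
            else:  # repeated root with sampled AIF: derivative trick
                eps = 1e-6 * max(alpha, 1.0)
                hi = _conv_exp_with_linear_segments(alpha + eps, aif.times,
                                                    aif.activities, t)
                lo = _conv_exp_with_linear_segments(alpha - eps, aif.times,
                                                    aif.activities, t)
                ct += coef * (lo - hi) / (2 * eps)
    signal = (1.0 - params.Vb) * ct
    if params.Vb > 0:
        signal = signal + params.Vb * evaluate_aif(aif, t)
    return signal
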