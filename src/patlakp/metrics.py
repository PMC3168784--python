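"""Uptake metrics: SUV maps, target-to-background ratios, paired t-tests.

Also ships, as fixture data, the published table of target-to-background
(TB) ratios of 19 regions of elevated uptake from three head-and-neck
patients, each measured on extrapolation (Patlak-P), classic Patlak and
SUV maps — so the cross-method statistical comparison is reproducible
offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import ConfigurationError, DegenerateTestError, DomainError

__all__ = ["TBRecord", "suv_map", "tb_ratio", "paired_ttest", "table1_dataset"]


@dataclass(frozen=True)
class TBRecord:
    """One region's target-to-background ratio under one mapping method."""

    study_id: str
    tracer: str  # "FDG" | "FLT"
    method: str  # "PatlakP" | "Patlak" | "SUV"
    tb_ratio: float

    def __post_init__(self):
        if self.tracer not in ("FDG", "FLT"):
            raise ConfigurationError(f"unknown tracer {self.tracer!r}")
        if self.method not in ("PatlakP", "Patlak", "SUV"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if not (np.isfinite(self.tb_ratio) and self.tb_ratio > 0):
            raise ConfigurationError("tb_ratio must be finite and positive")


def suv_map(img_frame: np.ndarray, dose_bq: float, weight_g: float) -> np.ndarray:
    """Standardized uptake value: activity / (injected dose / body weight).

    ``img_frame`` is a decay-corrected activity map [Bq/mL]; the result is
    in g/mL.
    """
    if dose_bq <= 0 or weight_g <= 0:
        raise DomainError("dose and weight must be positive")
    return np.asarray(img_frame, dtype=float) / (dose_bq / weight_g)


def tb_ratio(map3d: np.ndarray, target: np.ndarray, background: np.ndarray) -> float:
    """Target-to-background ratio: mean over target / mean over background."""
    m = np.asarray(map3d, dtype=float)
    t = np.asarray(target, dtype=bool)
    b = np.asarray(background, dtype=bool)
    if t.shape != m.shape or b.shape != m.shape:
        raise ConfigurationError("mask shape does not match map")
    if not t.any() or not b.any():
        raise ConfigurationError("target and background masks must be non-empty")
    if np.any(t & b):
        raise ConfigurationError("target and background masks overlap")
    bg = m[b].mean()
    if bg <= 0:
        raise DomainError("background mean is non-positive: TB ratio undefined")
    return float(m[t].mean() / bg)


def paired_ttest(a, b):
    """Paired two-tailed Student t-test.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = a - b, with the
    sample standard deviation (n-1 denominator); the two-tailed p-value
    comes from the t distribution with n-1 degrees of freedom.

    Returns (t, p).  Raises :class:`DegenerateTestError` when all
    differences are equal (zero-variance), where t is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("need two equal-length 1-D samples, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero-variance differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    # two-tailed p via the regularized incomplete beta function
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return float(t), float(p)


# TB ratios of all 19 regions of elevated uptake, by study and method
# (patient number - tracer; several regions per study).
_TABLE1 = [
    ("1", "FLT", 3.448, 3.773, 2.977),
    ("1", "FLT", 3.625, 3.638, 3.149),
    ("1", "FLT", 2.537, 2.617, 2.163),
    ("1", "FLT", 5.606, 5.663, 3.525),
    ("1", "FLT", 1.280, 1.541, 1.127),
    ("1", "FLT", 2.039, 2.197, 1.814),
    ("1", "FDG", 2.736, 2.481, 2.270),
    ("1", "FDG", 1.543, 1.506, 1.411),
    ("2", "FLT", 5.329, 3.932, 3.451),
    ("2", "FLT", 5.637, 4.370, 3.710),
    ("2", "FLT", 1.555, 1.417, 1.289),
    ("2", "FDG", 1.922, 2.661, 1.952),
    ("2", "FDG", 1.600, 2.116, 1.591),
    ("3", "FLT", 2.040, 1.433, 1.364),
    ("3", "FLT", 4.639, 2.912, 2.774),
    ("3", "FLT", 6.272, 3.313, 3.735),
    ("3", "FDG", 1.712, 1.591, 1.688),
    ("3", "FDG", 2.237, 2.234, 2.116),
    ("3", "FDG", 1.562, 1.589, 1.417),
]


def table1_dataset() -> list[TBRecord]:
    """The 19 published TB-ratio triplets as a flat record list."""
    records = []
    for patient, tracer, pp, pk, suv in _TABLE1:
        sid = f"{patient}-{tracer}"
        records.append(TBRecord(sid, tracer, "PatlakP", pp))
        records.append(TBRecord(sid, tracer, "Patlak", pk))
        records.append(TBRecord(sid, tracer, "SUV", suv))
    return records


def table1_method_columns() -> dict:
    """The same data as one column per method, row-aligned across methods."""
    cols = {"PatlakP": [], "Patlak": [], "SUV": []}
    for _, _, pp, pk, suv in _TABLE1:
        cols["PatlakP"].append(pp)
        cols["Patlak"].append(pk)
        cols["SUV"].append(suv)
    return {k: np.array(v) for k, v in cols.items()}


def table1_ttests() -> dict:
    """Paired two-tailed t-tests between the three method columns."""
    cols = table1_method_columns()
    out = {}
    for a, b in (("PatlakP", "Patlak"), ("Patlak", "SUV"), ("PatlakP", "SUV")):
        t, p = paired_ttest(cols[a], cols[b])
        out[f"{a}_vs_{b}"] = {"t": t, "p": p, "n": len(cols[a])}
    return out
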