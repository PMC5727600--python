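"""Error prediction for SURS-based number estimates.

Systematic uniform random sampling makes the per-section counts Q_i⁻
non-independent, so the precision of ΣQ⁻ is predicted from two parts: the
counting *noise* (for number estimates, equal to ΣQ⁻ itself) and the
between-section SURS variance computed from the serial product sums

    A = Σ Q_i⁻ Q_i⁻,   B = Σ Q_i⁻ Q_{i+1}⁻,   C = Σ Q_i⁻ Q_{i+2}⁻

as

    Var_SURS = (3(A − noise) − 4B + C) / 240

where 240 is the smoothness constant appropriate for this class of
sampling design.  The coefficient of error is then

    CE = sqrt(noise + Var_SURS) / ΣQ⁻.

A group's mean CE is the root mean square of the member CEs, and the
observed group variance decomposes as CV_obs² = CV_biol² + CE²; the
sampling design is conventionally acceptable when the CE contributes less
than 50% of the total observed variance.

The shorter B and C sums simply run out of terms near the end of the
series; negative raw Var_SURS values (possible for short or flat series)
are clamped to zero with a warning, and both raw and clamped values are
kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    EmptySeriesError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "PrecisionResult",
    "GroupStats",
    "surs_products",
    "var_surs",
    "ce_number",
    "mean_ce",
    "variance_decomposition",
    "precision_for_counts",
    "DEFAULT_SMOOTHNESS_CONSTANT",
]

DEFAULT_SMOOTHNESS_CONSTANT = 240.0


@dataclass(frozen=True)
class PrecisionResult:
    """Noise, SURS products, Var_SURS and CE for one number estimate."""

    q_list: tuple[int, ...]
    noise: float
    a: float
    b: float
    c: float
    var_surs_raw: float
    var_surs: float  # clamped at zero
    ce: float
    smoothness_constant: float = DEFAULT_SMOOTHNESS_CONSTANT

    @property
    def clamped(self) -> bool:
        return self.var_surs_raw < 0.0

    def to_dict(self) -> dict:
        return {
            "q_list": list(self.q_list),
            "noise": self.noise,
            "A": self.a,
            "B": self.b,
            "C": self.c,
            "var_surs_raw": self.var_surs_raw,
            "var_surs": self.var_surs,
            "ce": self.ce,
            "ce_display": round(self.ce, 2),
            "smoothness_constant": self.smoothness_constant,
        }


def _as_series(q_list) -> np.ndarray:
    q = np.asarray(q_list, dtype=float)
    if q.ndim != 1 or len(q) == 0:
        raise EmptySeriesError("count series must be 1D and non-empty")
    if np.any(q < 0):
        raise ValidationError("counts must be non-negative")
    return q


def surs_products(q_list) -> tuple[float, float, float]:
    """Serial product sums (A, B, C) of a count series in cutting order."""
    q = _as_series(q_list)
    a = float(np.dot(q, q))
    b = float(np.dot(q[:-1], q[1:])) if len(q) >= 2 else 0.0
    c = float(np.dot(q[:-2], q[2:])) if len(q) >= 3 else 0.0
    return a, b, c


def var_surs(
    q_list,
    noise: float | None = None,
    constant: float = DEFAULT_SMOOTHNESS_CONSTANT,
) -> tuple[float, float]:
    """SURS variance of ΣQ⁻: returns ``(raw, clamped)``.

    ``noise`` defaults to the series total, which is the noise term for
    number estimates.  Negative raw values are clamped to zero with a
    warning (they arise for short or flat series where the predictor's
    smoothness assumption overshoots).
    """
    if constant <= 0:
        raise ValidationError("smoothness constant must be positive")
    q = _as_series(q_list)
    if noise is None:
        noise = float(q.sum())
    a, b, c = surs_products(q)
    raw = (3.0 * (a - noise) - 4.0 * b + c) / constant
    clamped = raw
    if raw < 0.0:
        warnings.warn(
            f"negative raw Var_SURS ({raw:.4g}) clamped to 0", stacklevel=2
        )
        clamped = 0.0
    return raw, clamped


def ce_number(
    q_list,
    constant: float = DEFAULT_SMOOTHNESS_CONSTANT,
) -> float:
    """Coefficient of error of a SURS number estimate.

    ``CE = sqrt(noise + Var_SURS) / ΣQ⁻`` with noise = ΣQ⁻ and the clamped
    Var_SURS.  Undefined (raises) for an all-zero series.
    """
    q = _as_series(q_list)
    total = float(q.sum())
    if total <= 0:
        raise UndefinedStatisticError("CE undefined for zero total count")
    _, v = var_surs(q, noise=total, constant=constant)
    return math.sqrt(total + v) / total


def precision_for_counts(
    q_list,
    constant: float = DEFAULT_SMOOTHNESS_CONSTANT,
) -> PrecisionResult:
    """Full precision chain (noise, A/B/C, Var_SURS, CE) for one series."""
    q = _as_series(q_list)
    total = float(q.sum())
    a, b, c = surs_products(q)
    raw = (3.0 * (a - total) - 4.0 * b + c) / constant
    clamped = max(raw, 0.0)
    if raw < 0.0:
        warnings.warn(
            f"negative raw Var_SURS ({raw:.4g}) clamped to 0", stacklevel=2
        )
    if total > 0:
        ce = math.sqrt(total + clamped) / total
    else:
        ce = float("nan")
    return PrecisionResult(
        q_list=tuple(int(v) for v in q),
        noise=total,
        a=a,
        b=b,
        c=c,
        var_surs_raw=raw,
        var_surs=clamped,
        ce=ce,
        smoothness_constant=constant,
    )


def mean_ce(ce_list) -> float:
    """Group mean CE: the root mean square of the member CEs."""
    ces = np.asarray(ce_list, dtype=float)
    if ces.ndim != 1 or len(ces) == 0:
        raise EmptySeriesError("need a non-empty list of CEs")
    if np.any(ces < 0):
        raise ValidationError("CEs must be non-negative")
    return float(np.sqrt(np.mean(ces**2)))


@dataclass(frozen=True)
class GroupStats:
    """Observed group variation decomposed into biological and sampling parts."""

    n: int
    mean: float
    sem: float
    cv_obs: float
    mean_ce: float
    cv_biol: float
    ce_variance_fraction: float
    acceptable: bool               # CE contributes < 50% of total variance
    negative_variance_flag: bool   # mean CE exceeded observed CV


def variance_decomposition(estimates, ces) -> GroupStats:
    """Split observed group CV into biological CV and sampling CE.

    ``CV_biol = sqrt(max(CV_obs² − mean_CE², 0))``.  When the mean CE
    exceeds the observed CV the biological variance is reported as zero
    and flagged.
    """
    est = np.asarray(estimates, dtype=float)
    ce_arr = np.asarray(ces, dtype=float)
    if est.shape != ce_arr.shape or est.ndim != 1 or len(est) < 2:
        raise ValidationError("need matched estimates/CEs for >= 2 subjects")
    mean = float(np.mean(est))
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined for zero mean estimate")
    sd = float(np.std(est, ddof=1))
    cv_obs = sd / mean
    mce = mean_ce(ce_arr)
    diff = cv_obs**2 - mce**2
    negative = diff < 0.0
    if negative:
        warnings.warn(
            "mean CE exceeds observed CV: biological variance set to 0",
            stacklevel=2,
        )
    cv_biol = math.sqrt(max(diff, 0.0))
    fraction = (mce**2 / cv_obs**2) if cv_obs > 0 else float("inf")
    return GroupStats(
        n=int(len(est)),
        mean=mean,
        sem=sd / math.sqrt(len(est)),
        cv_obs=cv_obs,
        mean_ce=mce,
        cv_biol=cv_biol,
        ce_variance_fraction=fraction,
        acceptable=bool(fraction < 0.5),
        negative_variance_flag=bool(negative),
    )
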