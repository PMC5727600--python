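"""Fractionator and Cavalieri estimators, plus study-level summaries.

Total particle number by the fractionator:

    N = (1/ssf) * (1/asf) * ΣQ⁻        (divided by 2 for bidirectional
                                        counting, since each pair is
                                        compared both ways)

Regional volume by point counting (Cavalieri):

    V = ΣP * a(point) * t * (1/ssf),   a(point) = step_x * step_y

with t the mean section thickness.  Reported values follow the field's
display conventions (N to the nearest integer, half away from zero; V in
mm³ at two decimals); unrounded values are retained for all downstream
arithmetic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counting import CountTable
from .design import SamplingDesign
from .exceptions import UndefinedStatisticError, ValidationError

__all__ = [
    "CaliperRecord",
    "EstimateResult",
    "GroupSummary",
    "SpearmanResult",
    "estimate_total_number",
    "estimate_volume",
    "mean_section_thickness",
    "shrinkage_index",
    "group_summary",
    "rank_correlation",
    "estimate_from_table",
    "round_half_away",
]

UM3_PER_MM3 = 1.0e9


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (9,937.5 → 9,938)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CaliperRecord:
    """Block measurements around sectioning, for thickness and shrinkage."""

    block_height_before_mm: float
    block_height_after_mm: float
    sections_cut_total: int
    formalin_weight_g: float | None = None
    paraffin_weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.sections_cut_total <= 0:
            raise ValidationError("sections_cut_total must be positive")
        if self.block_height_before_mm < self.block_height_after_mm:
            raise ValidationError(
                "block height before sectioning must be >= height after"
            )


@dataclass(frozen=True)
class EstimateResult:
    """A number/volume estimate with its provenance and precision."""

    label: str
    n: float
    n_reported: int
    v_mm3: float | None = None
    v_reported: float | None = None
    precision: "object | None" = None  # PrecisionResult; avoids import cycle

    def __post_init__(self) -> None:
        if self.n < 0 or (self.v_mm3 is not None and self.v_mm3 < 0):
            raise ValidationError("estimates must be non-negative")


def estimate_total_number(
    sum_q: int,
    inv_ssf: float,
    inv_asf: float,
    bidirectional: bool = True,
) -> float:
    """Fractionator estimate of total particle number (unrounded).

    ``sum_q`` is the total number of disector counting events; with
    ``bidirectional=True`` it is the both-ways sum and the product is
    divided by two.  Use :func:`round_half_away` for the reported integer.
    """
    if sum_q < 0:
        raise ValidationError("sum_q must be non-negative")
    if not (inv_ssf > 0 and inv_asf > 0):
        raise ValidationError("inverse sampling fractions must be positive")
    n = inv_ssf * inv_asf * sum_q
    if bidirectional:
        n /= 2.0
    return n


def estimate_volume(
    sum_p: int,
    step_x: float,
    step_y: float,
    t: float,
    inv_ssf: float,
) -> float:
    """Cavalieri point-counting volume estimate in mm³ (unrounded).

    One test point per grid position, so the area per point is
    ``step_x * step_y`` (µm²); ``t`` is the mean section thickness (µm).
    """
    if sum_p < 0:
        raise ValidationError("sum_p must be non-negative")
    if t <= 0:
        raise ValidationError("section thickness must be positive")
    if not (step_x > 0 and step_y > 0 and inv_ssf > 0):
        raise ValidationError("steps and inverse ssf must be positive")
    return sum_p * step_x * step_y * t * inv_ssf / UM3_PER_MM3


def mean_section_thickness(caliper: CaliperRecord) -> float:
    """Mean section thickness t in µm from the two caliper measurements."""
    delta_um = (caliper.block_height_before_mm - caliper.block_height_after_mm) * 1000.0
    t = delta_um / caliper.sections_cut_total
    if t == 0.0:
        warnings.warn("degenerate thickness: caliper difference is zero", stacklevel=2)
    return t


def shrinkage_index(caliper: CaliperRecord) -> float:
    """Fractional weight loss upon paraffin embedding.

    ``(formalin − paraffin)/formalin``; a negative value (weight gain) is
    allowed but flagged with a warning.
    """
    if caliper.formalin_weight_g is None or caliper.paraffin_weight_g is None:
        raise ValidationError("caliper record lacks embedding weights")
    if caliper.formalin_weight_g <= 0:
        raise ValidationError("formalin weight must be positive")
    idx = (
        caliper.formalin_weight_g - caliper.paraffin_weight_g
    ) / caliper.formalin_weight_g
    if idx < 0:
        warnings.warn(
            "negative shrinkage index: paraffin weight exceeds formalin weight",
            stacklevel=2,
        )
    return idx


@dataclass(frozen=True)
class GroupSummary:
    """Paired ipsi/contra group summary for a lesion cohort."""

    n: int
    mean_ipsi: float
    sem_ipsi: float
    mean_contra: float
    sem_contra: float
    percent_reduction_per_animal: float  # mean over animals of (1 - ipsi/contra)
    percent_reduction_of_means: float    # 1 - mean_ipsi/mean_contra
    excluded: tuple[int, ...] = ()


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def group_summary(
    n_ipsi,
    n_contra,
) -> GroupSummary:
    """Mean ± SEM per side and the percent reduction, both conventions.

    The per-animal convention (mean of the paired ratios) is the default
    headline number for a hemiparkinsonian paired design; the ratio of the
    group means is reported alongside, labelled.  Animals with a zero
    contralateral count cannot form a ratio and are excluded with a
    warning.
    """
    ipsi = np.asarray(n_ipsi, dtype=float)
    contra = np.asarray(n_contra, dtype=float)
    if ipsi.shape != contra.shape or ipsi.ndim != 1 or len(ipsi) < 1:
        raise ValidationError("need matched ipsi/contra vectors, >= 1 animal")
    bad = np.nonzero(contra == 0)[0]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} animal(s) with zero contralateral count",
            stacklevel=2,
        )
    keep = contra != 0
    ratios = ipsi[keep] / contra[keep]
    per_animal = float(np.mean(1.0 - ratios)) * 100.0 if keep.any() else float("nan")
    mean_contra = float(np.mean(contra))
    of_means = (
        (1.0 - float(np.mean(ipsi)) / mean_contra) * 100.0
        if mean_contra != 0
        else float("nan")
    )
    return GroupSummary(
        n=int(len(ipsi)),
        mean_ipsi=float(np.mean(ipsi)),
        sem_ipsi=_sem(ipsi),
        mean_contra=mean_contra,
        sem_contra=_sem(contra),
        percent_reduction_per_animal=per_animal,
        percent_reduction_of_means=of_means,
        excluded=tuple(int(i) for i in bad),
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    method: str  # "exact" or "permutation"
    n_permutations: int | None = None


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise UndefinedStatisticError("constant vector: Spearman rho undefined")
    return float(rx @ ry) / denom


def rank_correlation(
    x,
    y,
    *,
    seed: int | None = None,
    n_permutations: int = 9999,
    exact_max_n: int = 8,
) -> SpearmanResult:
    """Spearman rank correlation with a permutation p-value.

    rho is computed on mid-ranks (ties averaged).  The two-sided p-value
    is exact (full enumeration of the n! orderings) for ``n <= exact_max_n``
    and a seeded Monte Carlo permutation estimate otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need matched 1D vectors of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    thresh = abs(rho) - 1e-12

    n = len(x)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt(float(rc @ rc) * np.einsum("ij,ij->i", pc, pc))
        rhos = (pc @ rc) / denom
        p = float(np.mean(np.abs(rhos) >= thresh))
        return SpearmanResult(rho=rho, p_value=p, method="exact")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rho_p = _rho_from_ranks(rx, rng.permutation(ry))
        if abs(rho_p) >= thresh:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return SpearmanResult(
        rho=rho, p_value=p, method="permutation", n_permutations=n_permutations
    )


def estimate_from_table(
    table: CountTable,
    design: SamplingDesign,
    *,
    label: str = "",
    bidirectional: bool = True,
    inv_asf: float | None = None,
    inv_ssf: float | None = None,
    thickness: float | None = None,
) -> EstimateResult:
    """N, V and the CE chain for one count table under a design.

    ``inv_asf``/``inv_ssf`` override the design's full-precision fractions
    (used when reproducing printed worked examples whose inputs are the
    rounded fractions); ``thickness`` overrides the nominal t, e.g. with a
    caliper-calculated mean.
    """
    from .precision import precision_for_counts

    inv_ssf = design.inv_ssf if inv_ssf is None else inv_ssf
    inv_asf = design.inv_asf if inv_asf is None else inv_asf
    t = design.section_thickness_nominal if thickness is None else thickness
    n = estimate_total_number(table.sum_q, inv_ssf, inv_asf, bidirectional)
    v = v_rep = None
    if table.p is not None:
        v = estimate_volume(table.sum_p, design.step_x, design.step_y, t, inv_ssf)
        v_rep = round(v, 2)
    prec = precision_for_counts(table.q_list, constant=design.smoothness_constant)
    return EstimateResult(
        label=label,
        n=n,
        n_reported=round_half_away(n),
        v_mm3=v,
        v_reported=v_rep,
        precision=prec,
    )
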