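"""Synthetic 3D particle phantoms and in-silico disector studies.

A phantom is a population of spheres with known count and a region of
interest (ROI) with known volume, standing in for an immunolabelled
neuron population in a tissue block.  The phantom is virtually sectioned
into half-open slabs of thickness t, each sphere leaving a disc profile
(radius evaluated at the slab midplane) in every slab its z-extent
touches.  Because each sphere has exactly one "top" slab (the slab
containing its highest point), the physical disector on adjacent sections
with identity matching counts tops, and summing tops over all sections
recovers the true particle number exactly — the conservation law that
anchors every validation test here.

:func:`simulate_study` runs the full sampling chain of a fractionator
study on a phantom — SURS section selection, adjacent-pair formation,
systematic frame grids with random offsets, bidirectional disector
counting, and point counting for Cavalieri volume — and returns a
:class:`~disector.counting.CountTable` ready for the estimators.

The lesion-cohort generator emulates a unilateral-lesion study: per-animal
bilateral neuron numbers with a configurable mean ipsilateral loss, plus
drug-induced rotation scores that increase with the fractional loss, for
exercising the group-summary and rank-correlation operations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .counting import CountTable, ParticleProfile, discs_sampled_by_frame
from .design import SamplingDesign, surs_section_indices
from .exceptions import PackingError, ValidationError

__all__ = [
    "BoxRoi",
    "EllipsoidRoi",
    "Phantom",
    "SectionStack",
    "generate_phantom",
    "virtual_sectioning",
    "simulate_study",
    "generate_lesion_cohort",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: Minimum profile radius (µm): discs in a sphere's top/bottom slab whose
#: midplane falls outside the sphere are clipped to this size.
PROFILE_EPS = 0.25


@dataclass(frozen=True)
class BoxRoi:
    """An axis-aligned box ROI; lengths in µm."""

    size: tuple[float, float, float] = (2000.0, 1200.0, 3000.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValidationError("box ROI must have positive extent")

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.size))

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 / 1.0e9

    @property
    def bbox(self) -> np.ndarray:
        o = np.asarray(self.origin, float)
        return np.stack([o, o + np.asarray(self.size, float)])

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo, hi = self.bbox
        return np.all((p >= lo) & (p < hi), axis=1)


@dataclass(frozen=True)
class EllipsoidRoi:
    """An axis-aligned ellipsoid ROI; lengths in µm."""

    semiaxes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semiaxes):
            raise ValidationError("ellipsoid ROI must have positive semiaxes")

    @property
    def volume_um3(self) -> float:
        return float(4.0 / 3.0 * math.pi * np.prod(self.semiaxes))

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 / 1.0e9

    @property
    def bbox(self) -> np.ndarray:
        c = np.asarray(self.center, float)
        s = np.asarray(self.semiaxes, float)
        return np.stack([c - s, c + s])

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        u = (p - np.asarray(self.center, float)) / np.asarray(self.semiaxes, float)
        return np.einsum("ij,ij->i", u, u) <= 1.0


@dataclass(frozen=True)
class Phantom:
    """A synthetic particle population with known ground truth."""

    centers: np.ndarray  # (n, 3) µm
    radii: np.ndarray    # (n,) µm
    roi: BoxRoi | EllipsoidRoi
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float).reshape(-1, 3)
        r = np.asarray(self.radii, float).reshape(-1)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)
        if len(c) != len(r):
            raise ValidationError("centers and radii length mismatch")
        if len(r) and np.any(r <= 0):
            raise ValidationError("particle radii must be positive")
        if len(c) and not bool(np.all(self.roi.contains(c))):
            raise ValidationError("all particle centers must lie inside the ROI")

    @property
    def true_n(self) -> int:
        return len(self.radii)

    @property
    def true_volume_mm3(self) -> float:
        return self.roi.volume_mm3

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "r": self.radii,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roi) -> "Phantom":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df["r"].to_numpy(), roi)


def generate_phantom(
    n: int,
    roi: BoxRoi | EllipsoidRoi | None = None,
    radius_range: tuple[float, float] = (5.0, 10.0),
    min_separation: float = 2.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    max_rounds: int = 200,
) -> Phantom:
    """Place ``n`` spheres uniformly in the ROI with a surface-gap constraint.

    Radii are uniform in ``radius_range`` (soma scale by default).  Pairs
    closer than ``r_i + r_j + min_separation`` centre-to-centre are
    resolved by resampling one member; if the constraint cannot be met
    within ``max_rounds`` a :class:`PackingError` is raised.  Deterministic
    for a fixed seed.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if roi is None:
        roi = BoxRoi()
    gen = rng if rng is not None else np.random.default_rng(seed)

    def _draw(k: int) -> np.ndarray:
        lo, hi = roi.bbox
        out = np.empty((0, 3))
        while len(out) < k:
            cand = gen.uniform(lo, hi, size=(max(2 * k, 64), 3))
            out = np.vstack([out, cand[roi.contains(cand)]])
        return out[:k]

    centers = _draw(n)
    radii = gen.uniform(radius_range[0], radius_range[1], size=n)
    if n > 1 and min_separation >= 0:
        reach = 2.0 * radii.max() + min_separation if n else 0.0
        for _ in range(max_rounds):
            pairs = cKDTree(centers).query_pairs(reach, output_type="ndarray")
            if len(pairs) == 0:
                break
            d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
            need = radii[pairs[:, 0]] + radii[pairs[:, 1]] + min_separation
            bad = pairs[d < need]
            if len(bad) == 0:
                break
            redo = np.unique(bad.max(axis=1))
            centers[redo] = _draw(len(redo))
        else:
            raise PackingError(
                f"could not satisfy min_separation={min_separation} for n={n}"
            )
    return Phantom(centers=centers, radii=radii, roi=roi, seed=seed)


# ---------------------------------------------------------------------------
# virtual sectioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionStack:
    """A phantom cut into an ordered stack of half-open slabs.

    Slab ``i`` (absolute index) occupies ``axial in [i*t, (i+1)*t)`` along
    the cutting axis.  The stack covers the particle support and the ROI,
    padded by one empty slab at each end, so that every sphere's top and
    bottom slab lies strictly inside the stack.
    """

    phantom: Phantom
    thickness: float
    axis: str
    i_min: int            # absolute index of the first slab in the stack
    n_sections: int
    axial: np.ndarray     # (n,) particle centre coordinate along the axis
    planar: np.ndarray    # (n, 2) in-plane particle coordinates
    top_slab: np.ndarray  # (n,) absolute slab holding each sphere's top
    bottom_slab: np.ndarray

    @property
    def i_max(self) -> int:
        return self.i_min + self.n_sections - 1

    def _axes(self) -> tuple[int, list[int]]:
        ax = _AXES[self.axis]
        return ax, [i for i in range(3) if i != ax]

    def present_in(self, abs_slab: int) -> np.ndarray:
        """Indices of particles with a profile in the given slab."""
        return np.nonzero(
            (self.bottom_slab <= abs_slab) & (self.top_slab >= abs_slab)
        )[0]

    def profile_discs(
        self, abs_slab: int, particle_idx: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Disc profiles ``(idx, x, y, rho)`` in a slab, radius at midplane."""
        idx = self.present_in(abs_slab) if particle_idx is None else particle_idx
        z_mid = (abs_slab + 0.5) * self.thickness
        dz = z_mid - self.axial[idx]
        rho2 = self.phantom.radii[idx] ** 2 - dz**2
        rho = np.sqrt(np.maximum(rho2, PROFILE_EPS**2))
        return idx, self.planar[idx, 0], self.planar[idx, 1], rho

    def section_profiles(self, abs_slab: int) -> list[ParticleProfile]:
        """Profiles of one slab as :class:`ParticleProfile` objects."""
        idx, x, y, rho = self.profile_discs(abs_slab)
        return [
            ParticleProfile(
                centroid=(float(xi), float(yi)),
                radius=float(ri),
                particle_id=int(i),
                section_index=int(abs_slab),
            )
            for i, xi, yi, ri in zip(idx, x, y, rho)
        ]

    def tops_per_section(self) -> np.ndarray:
        """Number of sphere tops in each slab of the stack (length n_sections)."""
        rel = self.top_slab - self.i_min
        return np.bincount(rel, minlength=self.n_sections)

    def midplane(self, abs_slab: int) -> float:
        return (abs_slab + 0.5) * self.thickness


def virtual_sectioning(
    phantom: Phantom,
    thickness: float,
    axis: str = "z",
) -> SectionStack:
    """Cut a phantom into slabs of the given thickness along one axis."""
    if thickness <= 0:
        raise ValidationError("thickness must be positive")
    if axis not in _AXES:
        raise ValidationError(f"axis must be one of {sorted(_AXES)}")
    ax = _AXES[axis]
    planar_axes = [i for i in range(3) if i != ax]
    axial = phantom.centers[:, ax] if phantom.true_n else np.empty(0)
    planar = (
        phantom.centers[:, planar_axes] if phantom.true_n else np.empty((0, 2))
    )
    r = phantom.radii
    lo_roi, hi_roi = phantom.roi.bbox[:, ax]
    support_lo = min(lo_roi, float((axial - r).min()) if phantom.true_n else lo_roi)
    support_hi = max(hi_roi, float((axial + r).max()) if phantom.true_n else hi_roi)
    i_min = math.floor(support_lo / thickness) - 1
    i_max = math.floor(support_hi / thickness) + 1
    top = (
        np.floor((axial + r) / thickness).astype(np.int64)
        if phantom.true_n
        else np.empty(0, np.int64)
    )
    bottom = (
        np.floor((axial - r) / thickness).astype(np.int64)
        if phantom.true_n
        else np.empty(0, np.int64)
    )
    return SectionStack(
        phantom=phantom,
        thickness=thickness,
        axis=axis,
        i_min=int(i_min),
        n_sections=int(i_max - i_min + 1),
        axial=axial,
        planar=planar,
        top_slab=top,
        bottom_slab=bottom,
    )


# ---------------------------------------------------------------------------
# full in-silico study
# ---------------------------------------------------------------------------

def _lattice_sampled(
    x: np.ndarray,
    y: np.ndarray,
    rho: np.ndarray,
    anchor: tuple[float, float],
    offset: tuple[float, float],
    design: SamplingDesign,
) -> np.ndarray:
    """Counting-frame decision against the (conceptually unbounded) grid.

    Frames sit at ``anchor + offset + (i*step_x, j*step_y)``.  Profiles are
    small relative to the step, so only the frame of a disc's own grid cell
    and its eight neighbours can interact with it.
    """
    if len(x) == 0:
        return np.zeros(0, dtype=bool)
    sx, sy = design.step_x, design.step_y
    w, h = design.frame_width, design.frame_height
    ax0 = anchor[0] + offset[0]
    ay0 = anchor[1] + offset[1]
    i0 = np.floor((x - ax0) / sx)
    j0 = np.floor((y - ay0) / sy)
    sampled = np.zeros(len(x), dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            fx = ax0 + (i0 + di) * sx
            fy = ay0 + (j0 + dj) * sy
            sampled |= discs_sampled_by_frame(x, y, rho, fx, fy, w, h)
    return sampled


def _count_points(
    roi,
    planar_axes: list[int],
    ax: int,
    z_mid: float,
    anchor: tuple[float, float],
    offset: tuple[float, float],
    design: SamplingDesign,
) -> int:
    """Test points (one per grid position) falling inside the ROI cross-section."""
    bx = roi.bbox[:, planar_axes[0]]
    by = roi.bbox[:, planar_axes[1]]
    sx, sy = design.step_x, design.step_y
    ax0 = anchor[0] + offset[0]
    ay0 = anchor[1] + offset[1]
    i_lo = math.ceil((bx[0] - ax0) / sx)
    i_hi = math.floor((bx[1] - ax0) / sx)
    j_lo = math.ceil((by[0] - ay0) / sy)
    j_hi = math.floor((by[1] - ay0) / sy)
    if i_hi < i_lo or j_hi < j_lo:
        return 0
    px = ax0 + np.arange(i_lo, i_hi + 1) * sx
    py = ay0 + np.arange(j_lo, j_hi + 1) * sy
    gx, gy = np.meshgrid(px, py, indexing="ij")
    pts = np.zeros((gx.size, 3))
    pts[:, planar_axes[0]] = gx.ravel()
    pts[:, planar_axes[1]] = gy.ravel()
    pts[:, ax] = z_mid
    return int(np.count_nonzero(roi.contains(pts)))


def simulate_study(
    phantom: Phantom,
    design: SamplingDesign,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    axis: str = "z",
) -> CountTable:
    """Run the full fractionator sampling chain on a phantom.

    Sections are selected by SURS with the design's period, paired with
    their cutting-order neighbour, and counted bidirectionally with the
    unbiased frame rule (identity matching — particle identity is known in
    simulation).  Point counts (one test point per grid position, counted
    when inside the ROI cross-section of the reference section) accompany
    each pair for Cavalieri volume estimation.

    Returns a :class:`CountTable` in cutting order, ready for
    :func:`disector.estimators.estimate_from_table`.
    """
    gen = rng if rng is not None else np.random.default_rng(seed)
    rng_sections, rng_grid = gen.spawn(2)
    t = design.section_thickness_nominal
    stack = virtual_sectioning(phantom, t, axis=axis)
    ax, planar_axes = stack._axes()

    rel = surs_section_indices(
        stack.n_sections, design.ssf_period, rng=rng_sections
    )
    rel = rel[rel + 1 < stack.n_sections]
    if len(rel) == 0:
        warnings.warn("design yields no sampled section pairs", stacklevel=2)
        return CountTable(
            pair_index=np.empty(0, np.int64),
            q=np.empty(0, np.int64),
            q_forward=np.empty(0, np.int64),
            q_reverse=np.empty(0, np.int64),
            p=np.empty(0, np.int64),
        )

    anchor = (
        float(phantom.roi.bbox[0, planar_axes[0]]),
        float(phantom.roi.bbox[0, planar_axes[1]]),
    )
    q_fwd = np.zeros(len(rel), dtype=np.int64)
    q_rev = np.zeros(len(rel), dtype=np.int64)
    p_pts = np.zeros(len(rel), dtype=np.int64)
    for k, j in enumerate(rel):
        s = stack.i_min + int(j)
        offset = (
            float(rng_grid.uniform(0.0, design.step_x)),
            float(rng_grid.uniform(0.0, design.step_y)),
        )
        # forward: in reference (s), absent in lookup (s+1) == top slab at s
        fwd_idx = np.nonzero(stack.top_slab == s)[0]
        _, x, y, rho = stack.profile_discs(s, fwd_idx)
        q_fwd[k] = int(
            np.count_nonzero(_lattice_sampled(x, y, rho, anchor, offset, design))
        )
        # reverse: in lookup (s+1), absent in reference == bottom slab at s+1
        rev_idx = np.nonzero(stack.bottom_slab == s + 1)[0]
        _, x, y, rho = stack.profile_discs(s + 1, rev_idx)
        q_rev[k] = int(
            np.count_nonzero(_lattice_sampled(x, y, rho, anchor, offset, design))
        )
        p_pts[k] = _count_points(
            phantom.roi, planar_axes, ax, stack.midplane(s), anchor, offset, design
        )
    return CountTable(
        pair_index=np.asarray(rel, np.int64),
        q=q_fwd + q_rev,
        q_forward=q_fwd,
        q_reverse=q_rev,
        p=p_pts,
    )


# ---------------------------------------------------------------------------
# lesion cohorts
# ---------------------------------------------------------------------------

def generate_lesion_cohort(
    n_animals: int = 26,
    effect_size: float = 0.55,
    between_animal_cv: float = 0.26,
    loss_sd: float = 0.12,
    sampling_ce: float = 0.08,
    rotation_link_slope: float = 600.0,
    rotation_noise_cv: float = 0.25,
    apomorphine_threshold: float = 0.5,
    baseline_n: float = 10_000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a unilateral-lesion cohort with linked rotation behaviour.

    Per animal: the intact-side neuron number is lognormal around
    ``baseline_n`` with the given between-animal CV; the lesioned-side
    number is the intact number times ``1 - loss`` where the fractional
    loss is normal around ``effect_size`` (sd ``loss_sd``, clipped to
    [0, 1]).  Estimated numbers add multiplicative sampling noise with CV
    ``sampling_ce``.  Amphetamine rotations scale with the fractional
    loss; apomorphine rotations only engage above a loss threshold,
    mirroring their insensitivity to restricted lesions.
    """
    if not (0.0 <= effect_size <= 1.0):
        raise ValidationError("effect_size must be in [0, 1]")
    if between_animal_cv <= 0 or rotation_noise_cv < 0 or sampling_ce < 0:
        raise ValidationError("CVs must be positive (noise CVs non-negative)")
    if n_animals < 1:
        raise ValidationError("need at least one animal")
    rng = np.random.default_rng(seed)

    def _lognormal(mean: float, cv: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.full(size, mean)
        sigma = math.sqrt(math.log(1.0 + cv**2))
        mu = math.log(mean) - sigma**2 / 2.0
        return rng.lognormal(mu, sigma, size)

    contra_true = _lognormal(baseline_n, between_animal_cv, n_animals)
    loss = np.clip(rng.normal(effect_size, loss_sd, n_animals), 0.0, 1.0)
    ipsi_true = contra_true * (1.0 - loss)
    contra_est = contra_true * _lognormal(1.0, sampling_ce, n_animals)
    ipsi_est = ipsi_true * _lognormal(1.0, sampling_ce, n_animals)
    rot_amph = rotation_link_slope * loss * _lognormal(1.0, rotation_noise_cv, n_animals)
    apo_drive = np.clip(loss - apomorphine_threshold, 0.0, None) / (
        1.0 - apomorphine_threshold
    )
    rot_apo = rotation_link_slope * apo_drive * _lognormal(
        1.0, rotation_noise_cv, n_animals
    )
    return pd.DataFrame(
        {
            "animal": np.arange(1, n_animals + 1),
            "n_contra_true": contra_true,
            "n_ipsi_true": ipsi_true,
            "n_contra_est": contra_est,
            "n_ipsi_est": ipsi_est,
            "fraction_lost_true": loss,
            "rotations_amphetamine": rot_amph,
            "rotations_apomorphine": rot_apo,
        }
    )
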