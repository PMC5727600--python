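"""The unbiased counting frame and the physical disector decision.

The counting frame (Gundersen frame) is a rectangle with two *inclusion*
edges (top and right) and an *exclusion* boundary drawn as one polyline:
an infinite upward extension from the top-left corner, down the left edge,
along the bottom edge, and an infinite downward extension from the
bottom-right corner.  A profile is sampled by the frame when it intersects
the closed frame (or touches an inclusion edge) and does not touch the
exclusion polyline.  Under a complete tiling of the plane by such frames
every convex profile is sampled by exactly one frame, which is the
combinatorial fact behind the rule's unbiasedness.

The physical disector compares two adjacent, aligned sections: a particle
is counted when its profile appears in the reference section but has no
matching profile in the lookup section.  Counting both ways (swapping the
roles of the two sections) doubles the number of counting events; the
fractionator estimate is divided by two accordingly (see
:mod:`disector.estimators`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon, box

from .alignment import RigidTransform
from .exceptions import AlignmentMissingError, ValidationError

__all__ = [
    "CountingFrame",
    "ParticleProfile",
    "SectionPair",
    "DisectorCounts",
    "CountTable",
    "frame_decision",
    "discs_sampled_by_frame",
    "disector_count",
    "tally_counts",
    "profiles_from_mask",
]

#: Finite surrogate for the infinite exclusion-line extensions (µm).  Any
#: coordinate farther than this from a frame is outside the modelled field.
EXCLUSION_EXTENT = 1.0e7


@dataclass(frozen=True)
class CountingFrame:
    """An unbiased counting frame with the classic exclusion convention."""

    origin: tuple[float, float]
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValidationError("counting frame must have positive extent")

    @property
    def x0(self) -> float:
        return self.origin[0]

    @property
    def y0(self) -> float:
        return self.origin[1]

    @property
    def x1(self) -> float:
        return self.origin[0] + self.width

    @property
    def y1(self) -> float:
        return self.origin[1] + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def polygon(self) -> Polygon:
        return box(self.x0, self.y0, self.x1, self.y1)

    def exclusion_line(self) -> LineString:
        """Exclusion polyline: up-ray, left edge, bottom edge, down-ray."""
        return LineString(
            [
                (self.x0, self.y0 + EXCLUSION_EXTENT),
                (self.x0, self.y0),
                (self.x1, self.y0),
                (self.x1, self.y0 - EXCLUSION_EXTENT),
            ]
        )


@dataclass(frozen=True)
class ParticleProfile:
    """A 2D profile of a particle within one section.

    Either ``radius`` (disc profile) or ``polygon`` (n x 2 vertex array)
    must be given.  ``particle_id`` is known in simulation and absent in
    image mode.
    """

    centroid: tuple[float, float]
    radius: float | None = None
    polygon: np.ndarray | None = None
    particle_id: int | None = None
    section_index: int | None = None

    def __post_init__(self) -> None:
        if self.radius is None and self.polygon is None:
            raise ValidationError("profile needs a radius or a polygon")
        if self.radius is not None and not (self.radius > 0):
            raise ValidationError("profile radius must be positive")
        if self.polygon is not None and len(np.asarray(self.polygon)) < 3:
            raise ValidationError("profile polygon needs >= 3 vertices")

    def shape(self):
        if self.radius is not None:
            return Point(self.centroid).buffer(self.radius, quad_segs=64)
        return Polygon(np.asarray(self.polygon, dtype=float))


@dataclass(frozen=True)
class SectionPair:
    """An aligned reference/lookup pair of adjacent sections."""

    reference: tuple[ParticleProfile, ...]
    lookup: tuple[ParticleProfile, ...]
    transform: RigidTransform | None = RigidTransform()
    roi: np.ndarray | None = None
    audit_log: tuple = ()

    def __post_init__(self) -> None:
        ri = {p.section_index for p in self.reference if p.section_index is not None}
        li = {p.section_index for p in self.lookup if p.section_index is not None}
        if len(ri) > 1 or len(li) > 1:
            raise ValidationError("each section must carry one section_index")
        if ri and li and abs(ri.pop() - li.pop()) != 1:
            raise ValidationError("reference and lookup sections must be adjacent")


# ---------------------------------------------------------------------------
# frame decision
# ---------------------------------------------------------------------------

def discs_sampled_by_frame(
    cx: np.ndarray,
    cy: np.ndarray,
    r: np.ndarray,
    fx0: np.ndarray | float,
    fy0: np.ndarray | float,
    width: float,
    height: float,
) -> np.ndarray:
    """Vectorized counting-frame decision for disc profiles.

    ``fx0``/``fy0`` may be scalars (one frame, many discs) or arrays
    broadcastable against the disc arrays (one frame per disc).  Returns a
    boolean array: True where the disc is sampled.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    r = np.asarray(r, dtype=float)
    x0 = np.asarray(fx0, dtype=float)
    y0 = np.asarray(fy0, dtype=float)
    x1 = x0 + width
    y1 = y0 + height

    # distance from centre to the closed frame rectangle
    ddx = np.maximum(np.maximum(x0 - cx, cx - x1), 0.0)
    ddy = np.maximum(np.maximum(y0 - cy, cy - y1), 0.0)
    hits_frame = ddx * ddx + ddy * ddy <= r * r

    # distance to the exclusion polyline, piece by piece
    # up-ray: {x = x0, y >= y0}
    d_up = np.where(
        cy >= y0,
        np.abs(cx - x0),
        np.hypot(cx - x0, cy - y0),
    )
    # bottom edge: {y = y0, x0 <= x <= x1}
    clamped = np.clip(cx, x0, x1)
    d_bottom = np.hypot(cx - clamped, cy - y0)
    # down-ray: {x = x1, y <= y0}
    d_down = np.where(
        cy <= y0,
        np.abs(cx - x1),
        np.hypot(cx - x1, cy - y0),
    )
    touches_exclusion = np.minimum(np.minimum(d_up, d_bottom), d_down) <= r
    return hits_frame & ~touches_exclusion


def frame_decision(profile: ParticleProfile, frame: CountingFrame) -> bool:
    """Counting-frame rule for a single profile.

    True iff the profile intersects the closed frame (inclusion edges
    included) and does not touch the exclusion polyline or its infinite
    extensions.
    """
    if profile.radius is not None:
        return bool(
            discs_sampled_by_frame(
                profile.centroid[0],
                profile.centroid[1],
                profile.radius,
                frame.x0,
                frame.y0,
                frame.width,
                frame.height,
            )
        )
    shape = profile.shape()
    if not shape.intersects(frame.polygon()):
        return False
    return not shape.intersects(frame.exclusion_line())


# ---------------------------------------------------------------------------
# disector counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisectorCounts:
    """Per-frame disector counts for one section pair."""

    forward_per_frame: np.ndarray
    reverse_per_frame: np.ndarray

    @property
    def forward(self) -> int:
        return int(self.forward_per_frame.sum())

    @property
    def reverse(self) -> int:
        return int(self.reverse_per_frame.sum())

    @property
    def total(self) -> int:
        """Bidirectional Q⁻ for the pair."""
        return self.forward + self.reverse


def _match_profiles(
    ref: Sequence[ParticleProfile],
    look_xy: np.ndarray,
    look: Sequence[ParticleProfile],
    r_match: float | None,
) -> tuple[set[int], set[int]]:
    """Match profiles across the pair; return matched index sets (ref, look).

    Matching is by ``particle_id`` when every profile on both sides has
    one; otherwise greedy nearest-centroid within ``r_match``, ties broken
    by smallest distance then lowest index.
    """
    have_ids = all(p.particle_id is not None for p in ref) and all(
        p.particle_id is not None for p in look
    )
    if have_ids and (ref or look):
        ref_ids = {p.particle_id: i for i, p in enumerate(ref)}
        look_ids = {p.particle_id: j for j, p in enumerate(look)}
        common = set(ref_ids) & set(look_ids)
        return {ref_ids[c] for c in common}, {look_ids[c] for c in common}

    if not ref or not look:
        return set(), set()
    if r_match is None:
        radii = [p.radius for p in list(ref) + list(look) if p.radius is not None]
        if not radii:
            raise ValidationError(
                "r_match required for centroid matching of polygon profiles"
            )
        r_match = float(np.mean(radii))  # half the mean profile diameter
    ref_xy = np.array([p.centroid for p in ref], dtype=float)
    d = np.hypot(
        ref_xy[:, None, 0] - look_xy[None, :, 0],
        ref_xy[:, None, 1] - look_xy[None, :, 1],
    )
    order = np.argsort(d, axis=None, kind="stable")
    matched_ref: set[int] = set()
    matched_look: set[int] = set()
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > r_match:
            break
        if i in matched_ref or j in matched_look:
            continue
        matched_ref.add(int(i))
        matched_look.add(int(j))
    return matched_ref, matched_look


def _count_direction(
    profiles: Sequence[ParticleProfile],
    xy: np.ndarray,
    unmatched: Iterable[int],
    frames: Sequence[CountingFrame],
) -> np.ndarray:
    """Count unmatched profiles sampled per frame (first frame claims)."""
    counts = np.zeros(len(frames), dtype=np.int64)
    for i in sorted(unmatched):
        p = profiles[i]
        moved = ParticleProfile(
            centroid=(float(xy[i, 0]), float(xy[i, 1])),
            radius=p.radius,
            polygon=None if p.polygon is None else np.asarray(p.polygon, float)
            + (xy[i] - np.asarray(p.centroid)),
            particle_id=p.particle_id,
            section_index=p.section_index,
        )
        for k, frame in enumerate(frames):
            if frame_decision(moved, frame):
                counts[k] += 1
                break  # a profile is attributed to at most one frame
    return counts


def disector_count(
    pair: SectionPair,
    frames: Sequence[CountingFrame],
    matcher: str = "auto",
    r_match: float | None = None,
) -> DisectorCounts:
    """Bidirectional physical-disector count for one aligned section pair.

    Forward counts profiles sampled by a frame in the reference section
    with no matching profile in the (aligned) lookup section; reverse
    swaps the roles.  ``matcher`` is ``'id'``, ``'centroid'`` or ``'auto'``
    (ids when available).
    """
    if pair.transform is None:
        raise AlignmentMissingError(
            "section pair has no alignment transform; align or override first"
        )
    ref = list(pair.reference)
    look = list(pair.lookup)
    ref_xy = (
        np.array([p.centroid for p in ref], dtype=float).reshape(-1, 2)
        if ref
        else np.empty((0, 2))
    )
    look_xy = (
        np.array([p.centroid for p in look], dtype=float).reshape(-1, 2)
        if look
        else np.empty((0, 2))
    )
    if len(look):
        look_xy = pair.transform.apply(look_xy)

    if matcher == "id":
        if not all(p.particle_id is not None for p in ref + look):
            raise ValidationError("matcher='id' requires particle_id on every profile")
    elif matcher not in ("auto", "centroid"):
        raise ValidationError(f"unknown matcher {matcher!r}")

    if matcher == "centroid":
        stripped_ref = [
            ParticleProfile(p.centroid, p.radius, p.polygon, None, p.section_index)
            for p in ref
        ]
        stripped_look = [
            ParticleProfile(p.centroid, p.radius, p.polygon, None, p.section_index)
            for p in look
        ]
        m_ref, m_look = _match_profiles(stripped_ref, look_xy, stripped_look, r_match)
    else:
        m_ref, m_look = _match_profiles(ref, look_xy, look, r_match)

    fwd = _count_direction(ref, ref_xy, set(range(len(ref))) - m_ref, frames)
    rev = _count_direction(look, look_xy, set(range(len(look))) - m_look, frames)
    return DisectorCounts(forward_per_frame=fwd, reverse_per_frame=rev)


# ---------------------------------------------------------------------------
# the ΣQ⁻ / ΣP ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTable:
    """Per-pair disector counts and point counts, in cutting order.

    The row order is the cutting order of the section pairs, which is what
    the SURS variance predictor consumes.  ``q`` is the bidirectional
    per-pair total Q_i⁻; ``q_forward``/``q_reverse`` retain the split when
    known; ``p`` holds the per-pair point counts for volume estimation.
    """

    pair_index: np.ndarray
    q: np.ndarray
    q_forward: np.ndarray | None = None
    q_reverse: np.ndarray | None = None
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_index", np.asarray(self.pair_index, np.int64))
        object.__setattr__(self, "q", np.asarray(self.q, np.int64))
        for name in ("q_forward", "q_reverse", "p"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, np.int64))
        if len(self.pair_index) != len(self.q):
            raise ValidationError("pair_index and q must have equal length")
        if len(np.unique(self.pair_index)) != len(self.pair_index):
            raise ValidationError("duplicate pair indices")
        if np.any(np.diff(self.pair_index) <= 0):
            if len(self.pair_index) > 1:
                raise ValidationError("pair_index must be strictly increasing")
        if np.any(self.q < 0):
            raise ValidationError("counts must be non-negative")
        if self.q_forward is not None and self.q_reverse is not None:
            if np.any(self.q_forward < 0) or np.any(self.q_reverse < 0):
                raise ValidationError("counts must be non-negative")
            if not np.array_equal(self.q_forward + self.q_reverse, self.q):
                raise ValidationError("q must equal q_forward + q_reverse")
        if self.p is not None and np.any(self.p < 0):
            raise ValidationError("point counts must be non-negative")

    @classmethod
    def from_q_list(cls, q: Sequence[int], p: Sequence[int] | None = None) -> "CountTable":
        q = np.asarray(q, dtype=np.int64)
        return cls(pair_index=np.arange(len(q)), q=q,
                   p=None if p is None else np.asarray(p, np.int64))

    @property
    def n_pairs(self) -> int:
        return len(self.q)

    @property
    def sum_q(self) -> int:
        return int(self.q.sum())

    @property
    def sum_p(self) -> int:
        if self.p is None:
            raise ValidationError("count table has no point counts")
        return int(self.p.sum())

    @property
    def q_list(self) -> list[int]:
        return [int(v) for v in self.q]

    def to_frame(self) -> pd.DataFrame:
        data = {"pair_index": self.pair_index, "q_total": self.q}
        if self.q_forward is not None:
            data["q_forward"] = self.q_forward
            data["q_reverse"] = self.q_reverse
        if self.p is not None:
            data["p_points"] = self.p
        return pd.DataFrame(data)


def tally_counts(
    per_pair_counts: Sequence[DisectorCounts],
    p_points: Sequence[int] | None = None,
    pair_indices: Sequence[int] | None = None,
) -> CountTable:
    """Aggregate per-pair disector counts into a :class:`CountTable`.

    Order is preserved (cutting order); per-pair Q_i⁻ is the bidirectional
    forward + reverse total.
    """
    fwd = np.array([c.forward for c in per_pair_counts], dtype=np.int64)
    rev = np.array([c.reverse for c in per_pair_counts], dtype=np.int64)
    idx = (
        np.arange(len(fwd))
        if pair_indices is None
        else np.asarray(pair_indices, np.int64)
    )
    return CountTable(
        pair_index=idx,
        q=fwd + rev,
        q_forward=fwd,
        q_reverse=rev,
        p=None if p_points is None else np.asarray(p_points, np.int64),
    )


# ---------------------------------------------------------------------------
# image (raster) mode
# ---------------------------------------------------------------------------

def profiles_from_mask(
    label_mask: np.ndarray,
    pixel_size: float = 1.0,
    section_index: int | None = None,
) -> list[ParticleProfile]:
    """Extract disc-equivalent profiles from an integer label mask.

    Objects are the connected components of the mask (background 0, as
    exported by segmentation tools).  Each object becomes a profile at its
    centroid with the equivalent-area disc radius, in physical units
    (``pixel_size`` µm per pixel).  Mask rows are the y axis.
    """
    from skimage.measure import regionprops

    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValidationError("label mask must be 2D")
    out: list[ParticleProfile] = []
    for rp in regionprops(mask.astype(np.int64)):
        cy, cx = rp.centroid
        radius = float(np.sqrt(rp.area / np.pi)) * pixel_size
        out.append(
            ParticleProfile(
                centroid=(float(cx) * pixel_size, float(cy) * pixel_size),
                radius=radius,
                particle_id=None,
                section_index=section_index,
            )
        )
    return out
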