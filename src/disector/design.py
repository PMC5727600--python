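"""Sampling geometry for the fractionator design.

A :class:`SamplingDesign` collects every sampling constant of a physical
disector study in one place: the section sampling period (every k-th
section), the counting-frame area, the X/Y grid steps, the nominal section
thickness, and the smoothness constant used by the SURS variance predictor.

Systematic uniform random sampling (SURS) is implemented for both the
section axis (:func:`surs_section_indices`) and the in-plane frame grid
(:func:`surs_grid`): equidistant sampling whose first position is drawn
uniformly at random within one period, which is what makes the resulting
estimators design-unbiased.

Conventions
-----------
* lengths are in micrometres, areas in square micrometres;
* section indices are 0-based and section ``i`` occupies the half-open
  slab ``z in [i*t, (i+1)*t)``;
* all randomness flows through an explicit :class:`numpy.random.Generator`
  (or a seed that constructs one); there is no global random state.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InvalidDesignError

__all__ = [
    "SamplingDesign",
    "GridPlacement",
    "surs_section_indices",
    "surs_grid",
    "sampling_fractions",
]


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SamplingDesign:
    """All sampling constants of a physical-disector fractionator study.

    Parameters
    ----------
    ssf_period
        Section sampling period k: every k-th section is sampled
        (section sampling fraction ssf = 1/k).
    frame_area
        Area of the unbiased counting frame, a(frame), in µm².
    step_x, step_y
        X and Y steps of the systematic frame grid, in µm.  The area
        sampling fraction is asf = frame_area / (step_x * step_y).
    section_thickness_nominal
        Nominal cutting thickness t in µm.
    disector_separation
        Distance h between the two members of a disector pair, in µm.
        For adjacent sections mounted pairwise this equals t.
    smoothness_constant
        Denominator of the SURS variance predictor (default 240, the
        value appropriate for this class of smooth, monotonously
        varying count series).
    seed
        Default seed for sampling operations that are not handed an
        explicit generator.
    """

    ssf_period: int = 50
    frame_area: float = 60_000.0
    step_x: float = 387.29
    step_y: float = 387.29
    section_thickness_nominal: float = 5.0
    disector_separation: float = 5.0
    smoothness_constant: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.ssf_period) != self.ssf_period or self.ssf_period < 1:
            raise InvalidDesignError(
                f"ssf_period must be an integer >= 1, got {self.ssf_period!r}"
            )
        if not (self.frame_area > 0):
            raise InvalidDesignError("frame_area must be positive")
        if not (self.step_x > 0 and self.step_y > 0):
            raise InvalidDesignError("grid steps must be positive")
        # Non-overlapping frames: each grid cell holds at most one frame.
        if self.frame_area > self.step_x * self.step_y * (1 + 1e-12):
            raise InvalidDesignError(
                "frame_area exceeds step_x*step_y: counting frames would overlap"
            )
        if not (self.section_thickness_nominal > 0):
            raise InvalidDesignError("section thickness must be positive")
        if not (self.disector_separation > 0):
            raise InvalidDesignError("disector separation must be positive")
        if not (self.smoothness_constant > 0):
            raise InvalidDesignError("smoothness constant must be positive")

    # -- derived fractions ------------------------------------------------
    @property
    def ssf(self) -> float:
        """Section sampling fraction, 1/k."""
        return 1.0 / self.ssf_period

    @property
    def asf(self) -> float:
        """Area sampling fraction, a(frame)/(step_x*step_y), full precision."""
        return self.frame_area / (self.step_x * self.step_y)

    @property
    def inv_ssf(self) -> float:
        return float(self.ssf_period)

    @property
    def inv_asf(self) -> float:
        return (self.step_x * self.step_y) / self.frame_area

    @property
    def step_area(self) -> float:
        return self.step_x * self.step_y

    @property
    def frame_width(self) -> float:
        """Side length of the (square) counting frame in µm."""
        return math.sqrt(self.frame_area)

    @property
    def frame_height(self) -> float:
        return math.sqrt(self.frame_area)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingDesign":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise InvalidDesignError(f"unknown design fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SamplingDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GridPlacement:
    """A concrete placement of the systematic frame grid.

    ``frame_origins`` holds the lower-left corner of every emitted frame
    whose counting frame intersects the requested region bounding box.
    Offsets are the uniformly random starts within one grid period.
    """

    offset_x: float
    offset_y: float
    frame_origins: np.ndarray  # (k, 2) float array of (x, y) in µm
    step_x: float
    step_y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.offset_x < self.step_x):
            raise InvalidDesignError("offset_x outside [0, step_x)")
        if not (0.0 <= self.offset_y < self.step_y):
            raise InvalidDesignError("offset_y outside [0, step_y)")

    @property
    def n_frames(self) -> int:
        return len(self.frame_origins)


def surs_section_indices(
    n_total: int,
    period: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Systematic uniform random sample of section indices.

    The first sampled section is drawn uniformly from ``{0, ..., period-1}``
    and every ``period``-th section after it is included, up to ``n_total``.

    Returns a sorted integer array; deterministic for a fixed seed.
    """
    if period < 1 or int(period) != period:
        raise InvalidDesignError(f"period must be an integer >= 1, got {period!r}")
    if n_total < 0:
        raise InvalidDesignError("n_total must be >= 0")
    gen = _rng(seed, rng)
    start = int(gen.integers(period))
    return np.arange(start, n_total, period, dtype=np.int64)


def surs_grid(
    roi_bbox: tuple[float, float, float, float],
    design: SamplingDesign,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> GridPlacement:
    """Place the systematic frame grid over a region bounding box.

    Parameters
    ----------
    roi_bbox
        ``(xmin, ymin, xmax, ymax)`` in µm.
    design
        Supplies the grid steps and frame size.
    seed, rng
        Source of the uniformly random offsets in ``[0, step)``.

    Every frame whose (closed) counting frame rectangle intersects the
    bounding box is emitted.  A zero-area box yields an empty placement
    with a warning.
    """
    xmin, ymin, xmax, ymax = map(float, roi_bbox)
    if xmax < xmin or ymax < ymin:
        raise InvalidDesignError("roi_bbox has negative extent")
    gen = _rng(seed if seed is not None else design.seed, rng)
    off_x = float(gen.uniform(0.0, design.step_x))
    off_y = float(gen.uniform(0.0, design.step_y))

    if xmax == xmin or ymax == ymin:
        warnings.warn("zero-area roi_bbox: empty grid placement", stacklevel=2)
        return GridPlacement(
            off_x, off_y, np.empty((0, 2)), design.step_x, design.step_y
        )

    w, h = design.frame_width, design.frame_height
    # frame [ox, ox+w] intersects [xmin, xmax]  <=>  ox in [xmin-w, xmax]
    i_lo = math.ceil((xmin - w - off_x - xmin) / design.step_x)
    i_hi = math.floor((xmax - off_x - xmin) / design.step_x)
    j_lo = math.ceil((ymin - h - off_y - ymin) / design.step_y)
    j_hi = math.floor((ymax - off_y - ymin) / design.step_y)
    xs = xmin + off_x + np.arange(i_lo, i_hi + 1) * design.step_x
    ys = ymin + off_y + np.arange(j_lo, j_hi + 1) * design.step_y
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    origins = np.column_stack([gx.ravel(), gy.ravel()])
    return GridPlacement(off_x, off_y, origins, design.step_x, design.step_y)


def sampling_fractions(design: SamplingDesign) -> tuple[float, float]:
    """Return ``(ssf, asf)`` at full precision."""
    return design.ssf, design.asf
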