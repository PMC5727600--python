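"""Rigid alignment of reference/lookup section images.

The physical disector requires the two sections of a pair to be brought
into register before profiles can be compared.  Automated systems do this
by maximizing the self-similarity of the two images; here the similarity
metric is normalized cross-correlation (NCC) and the search is a
coarse-to-fine pyramid: at each pyramid level a small set of candidate
rotations is evaluated, the best translation for each rotation is found by
phase correlation, and the rotation grid is refined around the winner.

When the best similarity stays below a confidence threshold the transform
is flagged so the caller can fall back to a manual alignment
(:func:`apply_manual_override`) instead of silently proceeding.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import rescale, rotate

from .exceptions import NoSignalError, ValidationError

__all__ = ["RigidTransform", "align_pair", "apply_manual_override", "ncc"]


@dataclass(frozen=True)
class RigidTransform:
    """A 2D rigid transform: rotation by ``theta_deg`` then translation.

    For point coordinates the convention is
    ``p' = R(theta) @ (p - center) + center + (dx, dy)`` with ``center``
    supplied by the caller (default origin).  Image coordinates are
    ``(x, y) = (col, row)`` and positive ``theta_deg`` rotates
    counter-clockwise as displayed (the y/row axis points down), matching
    ``skimage.transform.rotate``.  :meth:`warp` applies exactly the point
    transform, about the image centre, to an image.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta_deg: float = 0.0
    similarity: float | None = None
    confident: bool | None = None
    source: str = "automatic"

    def __post_init__(self) -> None:
        for v in (self.dx, self.dy, self.theta_deg):
            if not math.isfinite(v):
                raise ValidationError("transform parameters must be finite")

    # -- geometry ----------------------------------------------------------
    def rotation_matrix(self) -> np.ndarray:
        # display-CCW with the y axis pointing down (image convention)
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, s], [-s, c]])

    def apply(self, points: np.ndarray, center=(0.0, 0.0)) -> np.ndarray:
        """Apply the transform to an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ctr = np.asarray(center, dtype=float)
        out = (pts - ctr) @ self.rotation_matrix().T + ctr
        out[:, 0] += self.dx
        out[:, 1] += self.dy
        return out

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one (same rotation centre)."""
        r_inv = self.rotation_matrix().T
        d = -r_inv @ np.array([self.dx, self.dy])
        return RigidTransform(float(d[0]), float(d[1]), -self.theta_deg,
                              source=self.source)

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.theta_deg == 0.0

    def warp(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Warp an image by this transform (rotation about the image centre).

        A bright spot at point p lands at ``apply(p, center=image_centre)``.
        """
        from skimage.transform import warp as _warp

        img = np.asarray(image, dtype=float)
        rows, cols = img.shape
        center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
        inv = self.inverse()

        def inverse_map(coords: np.ndarray) -> np.ndarray:
            return inv.apply(coords, center=center)

        return _warp(img, inverse_map, order=order, cval=0.0, preserve_range=True)

    def replace(self, **kw) -> "RigidTransform":
        return dataclasses.replace(self, **kw)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped images."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return 0.0
    return float(a @ b) / denom


def _masked_ncc(ref: np.ndarray, aligned: np.ndarray, valid: np.ndarray) -> float:
    """NCC restricted to the region where the warped image has support."""
    if valid.sum() < 16:
        return -1.0
    return ncc(ref[valid], aligned[valid])


def _score(
    ref: np.ndarray,
    look: np.ndarray,
    theta: float,
) -> tuple[float, float, float]:
    """Best (dy, dx) for a candidate rotation, scored by valid-overlap NCC.

    Translation uses masked cross-correlation so that the empty borders
    introduced by rotation (or present in the lookup image itself) do not
    bias the peak.
    """
    if theta:
        rot = rotate(look, theta, preserve_range=True, order=1)
        support = rotate(np.ones_like(look), theta, preserve_range=True, order=0)
    else:
        rot, support = look, np.ones_like(look)
    moving_mask = (support > 0.5) & (np.abs(rot) > 1e-12)
    if not moving_mask.any():
        return 0.0, 0.0, -1.0
    result = phase_cross_correlation(
        ref,
        rot,
        reference_mask=np.ones(ref.shape, dtype=bool),
        moving_mask=moving_mask,
    )
    shift = result[0] if isinstance(result, tuple) else result
    aligned = ndimage.shift(rot, shift, order=1, cval=0.0)
    valid = (
        ndimage.shift(moving_mask.astype(float), shift, order=0, cval=0.0) > 0.5
    )
    return float(shift[0]), float(shift[1]), _masked_ncc(ref, aligned, valid)


def align_pair(
    reference_image: np.ndarray,
    lookup_image: np.ndarray,
    *,
    max_shift: float | None = None,
    max_rotation: float = 10.0,
    threshold: float = 0.5,
) -> RigidTransform:
    """Estimate the rigid transform registering ``lookup`` onto ``reference``.

    Parameters
    ----------
    reference_image, lookup_image
        Grayscale images at the same pixel scale.
    max_shift
        Largest admissible translation magnitude in pixels on either axis
        (default: 25% of the smaller image dimension).  A larger recovered
        shift fails the confidence check.
    max_rotation
        Half-width of the rotation search range in degrees.
    threshold
        NCC below which the result is flagged not confident, signalling
        that a manual override is required.

    Returns
    -------
    RigidTransform
        With ``similarity`` set to the best NCC and ``confident`` set by
        the threshold test.  ``transform.warp(lookup_image)`` is the
        lookup image registered onto the reference.
    """
    ref = np.asarray(reference_image, dtype=float)
    look = np.asarray(lookup_image, dtype=float)
    if ref.shape != look.shape:
        raise ValidationError("reference and lookup images must share a shape")
    if ref.size == 0 or ref.std() == 0.0 or look.std() == 0.0:
        raise NoSignalError("empty or constant image: nothing to align")
    if max_shift is None:
        max_shift = 0.25 * min(ref.shape)

    # Coarse-to-fine: (downscale factor, rotation half-range, rotation step)
    schedule = [(4, max_rotation, 1.0), (2, 1.5, 0.25), (1, 0.3, 0.1)]
    theta_center = 0.0
    best = (0.0, 0.0, 0.0, -np.inf)  # dy, dx, theta, score
    for factor, half, step in schedule:
        if factor > 1:
            r = rescale(ref, 1.0 / factor, anti_aliasing=True, preserve_range=True)
            l = rescale(look, 1.0 / factor, anti_aliasing=True, preserve_range=True)
        else:
            r, l = ref, look
        thetas = np.arange(-half, half + step / 2, step) + theta_center
        thetas = thetas[np.abs(thetas) <= max_rotation + 1e-9]
        level_best = None
        for theta in thetas:
            dy, dx, score = _score(r, l, float(theta))
            if level_best is None or score > level_best[3]:
                level_best = (dy * factor, dx * factor, float(theta), score)
        best = level_best
        theta_center = best[2]

    dy, dx, theta, score = best
    confident = bool(
        score >= threshold and abs(dx) <= max_shift and abs(dy) <= max_shift
    )
    return RigidTransform(
        dx=dx, dy=dy, theta_deg=theta,
        similarity=score, confident=confident, source="automatic",
    )


def apply_manual_override(pair, transform: RigidTransform, operator: str = "manual"):
    """Replace a pair's alignment with a manually supplied transform.

    Returns a new :class:`~disector.counting.SectionPair` whose transform is
    the given one (tagged ``source='manual'``), with an entry appended to
    the pair's audit log.
    """
    for v in (transform.dx, transform.dy, transform.theta_deg):
        if not math.isfinite(v):  # pragma: no cover - caught by RigidTransform
            raise ValidationError("manual transform must be finite")
    manual = transform.replace(source="manual")
    log = list(getattr(pair, "audit_log", ())) + [
        {
            "event": "manual_alignment_override",
            "operator": operator,
            "dx": manual.dx,
            "dy": manual.dy,
            "theta_deg": manual.theta_deg,
        }
    ]
    return dataclasses.replace(pair, transform=manual, audit_log=log)
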