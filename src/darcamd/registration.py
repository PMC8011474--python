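"""En-face to OCT coordinate registration.

Fundus (en-face cSLO) images are registered with an affine transform fitted
to manually placed fiducial pairs, optionally refined with a non-rigid
B-spline deformation (multi-resolution, gradient-descent, mean-squared
intensity difference).  Points in the registered fundus frame are then mapped
to OCT volume coordinates (slice index, column) through an
:class:`OCTGeometry` describing where each B-scan sits on the fundus.

Conventions: 0-based pixel-center coordinates, ``(x, y) = (column, row)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


class DegenerateFiducialsError(ValueError):
    """Raised when fiducial pairs cannot determine an affine transform."""


class OutOfVolumeError(ValueError):
    """Raised when a fundus point falls outside the OCT volume footprint."""


@dataclass(frozen=True)
class AffineTransform2D:
    """2-D affine map ``p -> M[:, :2] @ p + M[:, 2]`` (pixels to pixels)."""

    matrix: np.ndarray  # shape (2, 3), row-major [[a, b, tx], [c, d, ty]]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one ``(2,)`` point or an ``(n, 2)`` array of (x, y) points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.linear.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "AffineTransform2D":
        if abs(self.det) <= 1e-12:
            raise ValueError("affine transform is singular, cannot invert")
        inv_lin = np.linalg.inv(self.linear)
        inv_t = -inv_lin @ self.translation
        return AffineTransform2D(np.hstack([inv_lin, inv_t[:, None]]))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform2D":
        return cls(np.asarray(json.loads(text)["matrix"], dtype=float))


def apply_affine(t: AffineTransform2D, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AffineTransform2D.apply`."""
    return t.apply(points)


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform2D:
    """Least-squares affine fit from point correspondences.

    Parameters
    ----------
    src, dst
        ``(n, 2)`` arrays of (x, y) fiducial coordinates; ``src[i]`` maps to
        ``dst[i]``.  At least 3 non-collinear source points are required.

    Returns
    -------
    AffineTransform2D
        The minimizer of ``sum ||A src_i + t - dst_i||^2``.  With exactly
        three non-collinear pairs the residual is zero.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise DegenerateFiducialsError(
            f"affine fit needs >=3 fiducial pairs, got {n}"
        )
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateFiducialsError("source fiducials are collinear")
    design = np.hstack([src, np.ones((n, 1))])  # (n, 3)
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    return AffineTransform2D(coef.T)


@dataclass(frozen=True)
class OCTGeometry:
    """Placement of an OCT volume's B-scans on the registered fundus plane.

    Slice ``s`` images the fundus row ``row0 + s * spacing``; within a slice,
    fundus x maps to the B-scan column ``(x - col_origin[s]) / col_scale[s]``.
    """

    n_slices: int
    row0: float
    spacing: float  # fundus pixels between consecutive slices, > 0
    n_cols: int
    col_origin: np.ndarray = None  # per-slice, fundus px
    col_scale: np.ndarray = None  # fundus px per B-scan column

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        origin = self.col_origin if self.col_origin is not None else 0.0
        scale = self.col_scale if self.col_scale is not None else 1.0
        object.__setattr__(
            self, "col_origin",
            np.broadcast_to(np.asarray(origin, float), (self.n_slices,)).copy())
        object.__setattr__(
            self, "col_scale",
            np.broadcast_to(np.asarray(scale, float), (self.n_slices,)).copy())
        if np.any(self.col_scale <= 0):
            raise ValueError("col_scale must be positive")

    def slice_rows(self) -> np.ndarray:
        return self.row0 + np.arange(self.n_slices) * self.spacing

    def to_dict(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "row0": self.row0,
            "spacing": self.spacing,
            "n_cols": self.n_cols,
            "col_origin": self.col_origin.tolist(),
            "col_scale": self.col_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OCTGeometry":
        return cls(
            n_slices=int(d["n_slices"]), row0=float(d["row0"]),
            spacing=float(d["spacing"]), n_cols=int(d["n_cols"]),
            col_origin=np.asarray(d.get("col_origin", 0.0), float),
            col_scale=np.asarray(d.get("col_scale", 1.0), float),
        )


def fundus_to_oct(point: Sequence[float], geom: OCTGeometry) -> tuple[int, int]:
    """Map a registered-fundus (x, y) point to (slice index, column).

    The slice is the one whose fundus row is nearest to ``y``; a point exactly
    equidistant between two slices goes to the lower index.  The column is the
    nearest integer B-scan column under the slice's origin/scale.
    """
    x, y = float(point[0]), float(point[1])
    f = (y - geom.row0) / geom.spacing
    # nearest integer with half-way ties to the LOWER index
    s = int(np.ceil(f - 0.5))
    if s < 0 or s >= geom.n_slices or abs(f - s) > 0.5 + 1e-9:
        raise OutOfVolumeError(
            f"point y={y} outside the volume's slice footprint")
    c_float = (x - geom.col_origin[s]) / geom.col_scale[s]
    c = int(np.floor(c_float + 0.5))
    if c < 0 or c >= geom.n_cols:
        raise OutOfVolumeError(f"point x={x} outside slice {s}'s columns")
    return s, c


@dataclass
class DisplacementField:
    """Dense per-pixel 2-vector field (dx, dy) over the fixed-image grid."""

    field: np.ndarray  # (H, W, 2), pixels
    converged: bool = True
    mse_before: float = np.nan
    mse_after: float = np.nan

    def __post_init__(self):
        f = np.asarray(self.field, dtype=float)
        if f.ndim != 3 or f.shape[2] != 2:
            raise ValueError("displacement field must be (H, W, 2)")
        if not np.all(np.isfinite(f)):
            raise ValueError("displacement field contains non-finite values")
        self.field = f

    @property
    def max_magnitude(self) -> float:
        return float(np.sqrt((self.field ** 2).sum(axis=2)).max())

    def warp(self, image: np.ndarray) -> np.ndarray:
        """Resample ``image`` at ``grid + field`` (pull-back warping)."""
        h, w = self.field.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        coords = np.array([yy + self.field[..., 1], xx + self.field[..., 0]])
        return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))


def resample_affine(image: np.ndarray, t: AffineTransform2D,
                    shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``image`` into the frame reached by ``t`` (pull-back).

    Output pixel (x, y) takes the value of ``image`` at ``t^{-1}(x, y)``.
    """
    shape = shape if shape is not None else image.shape
    inv = t.inverse()
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    src = inv.apply(pts)
    coords = np.array([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def nonrigid_refine(fixed: np.ndarray, moving: np.ndarray,
                    initial: AffineTransform2D | None = None,
                    grid_spacing: float = 32.0,
                    max_iterations: int = 100) -> DisplacementField:
    """B-spline refinement of a residual non-rigid misalignment.

    ``moving`` is first resampled by the ``initial`` affine (identity if
    omitted), then a free-form B-spline deformation is optimized with a
    3-level multi-resolution schedule (downsampling 4x, 2x, 1x) and a
    gradient-descent optimizer on the mean squared intensity difference.
    The returned field is the dense interpolation of the control-point
    offsets over the fixed grid.

    The refinement never worsens the objective: if the optimized field does
    not lower the MSE against ``fixed``, the zero field is returned with
    ``converged=False``.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if initial is not None:
        moving = resample_affine(moving, initial, shape=fixed.shape)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a shape after affine")

    mse0 = _mse(fixed, moving)
    zero = np.zeros(fixed.shape + (2,))
    if mse0 == 0.0:
        # identical (or both constant) images: flat objective, nothing to do
        return DisplacementField(zero, True, mse0, mse0)

    sitk.ProcessObject_SetGlobalWarningDisplay(False)
    f_img = sitk.GetImageFromArray(fixed)
    m_img = sitk.GetImageFromArray(moving)
    mesh = [max(2, int(round(s / grid_spacing))) for s in fixed.shape[::-1]]
    tx0 = sitk.BSplineTransformInitializer(f_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    # L-BFGS-B: gradient-based quasi-Newton; plain first-order descent is
    # unstable on the mean-squares B-spline objective at this image scale
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=int(max_iterations))
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(tx0, inPlace=True)
    try:
        tx = reg.Execute(f_img, m_img)
    except RuntimeError:
        return DisplacementField(zero, False, mse0, mse0)

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(f_img)
    disp = sitk.GetArrayFromImage(to_field.Execute(tx))  # (H, W, 2) = (dx, dy)
    field = DisplacementField(disp, True, mse0, np.nan)
    warped = field.warp(moving)
    mse1 = _mse(fixed, warped)
    if not np.isfinite(mse1) or mse1 > mse0:
        return DisplacementField(zero, False, mse0, mse0)
    field.mse_after = mse1
    field.converged = mse1 <= mse0
    return field
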