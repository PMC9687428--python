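"""Affine alignment of frames to a reference image by mutual information.

Breathing and patient motion displace the kidney between frames, so every
frame (and every shape-model training image) is aligned to a common
reference with a 2-D affine transform found by maximizing the mutual
information of the joint intensity histogram. The optimizer is
derivative-free (Powell) over (tx, ty, rotation, scale-x, scale-y, shear)
on a 3-level coarse-to-fine pyramid.

Transform convention: a transform maps *reference-frame* points to
*moving-frame* points (a pull map), so ``warp(moving, t)`` resamples the
moving image into the reference frame. Points are (row, col), 0-based,
pixel-center; rotation/scale/shear act about ``center`` (image center by
default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "AffineTransform",
    "mutual_information",
    "register_affine",
    "warp",
    "RegistrationResult",
]


@dataclass
class AffineTransform:
    """2-D affine map ``p -> matrix @ (p - center) + center + offset``."""

    matrix: np.ndarray
    offset: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(2)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("singular affine matrix")

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2), _image_center(shape))

    @classmethod
    def from_params(
        cls,
        shape: tuple[int, int],
        ty: float = 0.0,
        tx: float = 0.0,
        rotation: float = 0.0,
        scale_y: float = 1.0,
        scale_x: float = 1.0,
        shear: float = 0.0,
    ) -> "AffineTransform":
        """Build from parameters: rotation in degrees, translations in pixels.

        Linear part = R(rotation) @ [[1, shear], [0, 1]] @ diag(scale_y, scale_x),
        acting on (row, col) vectors about the image center.
        """
        th = np.deg2rad(rotation)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shear_m = np.array([[1.0, shear], [0.0, 1.0]])
        scale = np.diag([scale_y, scale_x])
        return cls(rot @ shear_m @ scale, np.array([ty, tx]), _image_center(shape))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 2) reference-frame points to moving-frame points."""
        p = np.asarray(points, dtype=np.float64)
        return (p - self.center) @ self.matrix.T + self.center + self.offset

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``p -> self(other(p))`` expressed about self.center."""
        # self(other(p)) = A1 (A2 (p - c2) + c2 + b2 - c1) + c1 + b1
        a = self.matrix @ other.matrix
        shift = self.apply(other.apply(self.center))  # image of c1 under the chain
        b = shift - self.center
        return AffineTransform(a, b, self.center.copy())

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        b = -inv @ self.offset
        return AffineTransform(inv, b, self.center.copy())

    def translation_magnitude(self) -> float:
        """Displacement of the center point, in pixels."""
        return float(np.linalg.norm(self.apply(self.center) - self.center))

    def rotation_deg(self) -> float:
        """Rotation angle extracted from the polar decomposition, degrees."""
        u, _, vt = np.linalg.svd(self.matrix)
        r = u @ vt
        return float(np.rad2deg(np.arctan2(r[1, 0], r[0, 0])))

    def scales(self) -> np.ndarray:
        """Singular values of the linear part (principal scale factors)."""
        return np.linalg.svd(self.matrix, compute_uv=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.tolist(),
                "offset": self.offset.tolist(),
                "center": self.center.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        d = json.loads(text)
        return cls(np.array(d["matrix"]), np.array(d["offset"]), np.array(d["center"]))


def _image_center(shape: tuple[int, int]) -> np.ndarray:
    return (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0


def warp(
    image: np.ndarray,
    transform: AffineTransform,
    interpolation: str = "bilinear",
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a field into the reference frame through the pull map.

    ``output[p] = image[transform(p)]``. Masks should use ``nearest`` so
    they stay binary; out-of-field pixels receive ``cval``.
    """
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    offset = transform.offset + transform.center - transform.matrix @ transform.center
    out = ndimage.affine_transform(
        np.asarray(image, dtype=np.float64),
        transform.matrix,
        offset=offset,
        order=order,
        mode="constant",
        cval=cval,
    )
    if interpolation == "nearest":
        out = out.astype(np.asarray(image).dtype)
    return out


def mutual_information(image_a: np.ndarray, image_b: np.ndarray, bins: int = 32) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    Each image is binned over its own [min, max] range into ``bins`` equal
    bins; MI is computed from the normalized joint counts. Symmetric in its
    arguments; a constant image carries no information, giving MI = 0.
    """
    a = np.asarray(image_a, dtype=np.float64).ravel()
    b = np.asarray(image_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal size")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if a.max() == a.min() or b.max() == b.min():
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


@dataclass
class RegistrationResult:
    transform: AffineTransform
    mi: float
    converged: bool = True


_PARAM_SCALE = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01])  # px, px, deg, scale, scale, shear


def _transform_from_vector(v: np.ndarray, shape: tuple[int, int]) -> AffineTransform:
    ty, tx, rot, sy, sx, sh = v * _PARAM_SCALE
    return AffineTransform.from_params(
        shape, ty=ty, tx=tx, rotation=rot, scale_y=1.0 + sy, scale_x=1.0 + sx, shear=sh
    )


def _vector_from_transform(t: AffineTransform, shape: tuple[int, int]) -> np.ndarray:
    # approximate decomposition used only to seed the optimizer
    m = t.matrix
    rot = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    sv = np.linalg.svd(m, compute_uv=False)
    v = np.array([t.offset[0], t.offset[1], rot, sv[0] - 1.0, sv[1] - 1.0, 0.0])
    return v / _PARAM_SCALE


def _downsample(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return image
    smoothed = ndimage.gaussian_filter(image, sigma=factor / 2.0)
    return smoothed[::factor, ::factor]


def register_affine(
    moving: np.ndarray,
    reference: np.ndarray,
    init: AffineTransform | None = None,
    bins: int = 32,
    pyramid: tuple[int, ...] = (4, 2, 1),
) -> RegistrationResult:
    """Find the affine transform maximizing MI(warp(moving, T), reference).

    Powell optimization at each pyramid level (coarse to fine), seeded by
    the previous level's optimum. If no parameter set improves on ``init``,
    the initial transform is returned with ``converged=False``.
    """
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    shape = reference.shape
    if init is None:
        init = AffineTransform.identity(shape)
    v = _vector_from_transform(init, shape)

    for factor in pyramid:
        mov_l = _downsample(moving, factor)
        ref_l = _downsample(reference, factor)
        scale_l = np.array([factor, factor, 1.0, 1.0, 1.0, 1.0])

        def neg_mi(vl: np.ndarray) -> float:
            t = _transform_from_vector(vl * scale_l, shape)
            t_level = AffineTransform(t.matrix, t.offset / factor, _image_center(ref_l.shape))
            return -mutual_information(warp(mov_l, t_level), ref_l, bins=bins)

        res = optimize.minimize(
            neg_mi,
            v / scale_l,
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 40},
        )
        v = res.x * scale_l

    best = _transform_from_vector(v, shape)
    mi_best = mutual_information(warp(moving, best), reference, bins=bins)
    mi_init = mutual_information(warp(moving, init), reference, bins=bins)
    if mi_best < mi_init:
        return RegistrationResult(init, mi_init, converged=False)
    return RegistrationResult(best, mi_best, converged=True)
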