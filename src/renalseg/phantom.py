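"""Synthetic DCE-MRI kidney phantom sequences with ground truth.

Each subject is a bean-shaped bright region (an ellipse with a hilum
notch) over a slowly varying background. The kidney mean intensity
follows a gamma-variate enhancement curve — flat pre-contrast baseline,
rapid rise to a post-contrast peak, slow late-contrast decay — which is
the classic perfusion time course. Acquisition nuisances emulated:
per-frame small affine jitter (breathing), additive Gaussian noise, and
between-subject variation of the kidney geometry. Everything is
deterministic given the config seed.

Intensities live on a [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Image2D
from .registration import AffineTransform, warp

__all__ = [
    "KidneyGeometry",
    "PhantomConfig",
    "Subject",
    "PopulationSubject",
    "enhancement_curve",
    "kidney_mask",
    "draw_geometry",
    "make_subject",
    "make_population",
    "low_contrast_frames",
]


@dataclass
class KidneyGeometry:
    """Bean shape: ellipse (semi-axes ``a`` >= ``b``) minus a hilum notch.

    ``center`` is (row, col) in pixels; ``orientation`` is the major-axis
    angle in degrees. The notch is an ellipse centered on the medial edge.
    """

    center: tuple[float, float] = (64.0, 64.0)
    a: float = 30.0
    b: float = 18.0
    orientation: float = 20.0


@dataclass
class PhantomConfig:
    image_size: tuple[int, int] = (128, 128)
    n_frames: int = 80
    geometry: KidneyGeometry = field(default_factory=KidneyGeometry)
    # gamma-variate enhancement curve (fractions of the sequence length)
    baseline: float = 0.24
    peak_amplitude: float = 0.55
    onset_frac: float = 0.2
    peak_frac: float = 0.45
    curve_alpha: float = 3.0
    # background
    background_level: float = 0.20
    gradient_amplitude: float = 0.04
    # nuisances
    noise_sigma: float = 0.01
    breathing_translation: float = 2.0  # uniform +/- px
    breathing_rotation: float = 2.0  # uniform +/- deg
    # between-subject geometry variation (SDs)
    center_sd: float = 4.0
    axis_sd: float = 2.5
    orientation_sd: float = 8.0
    psf_sigma: float = 1.0
    seed: int = 0


@dataclass
class Subject:
    frames: list[Image2D]
    masks: list[np.ndarray]
    transforms: list[AffineTransform]
    curve: np.ndarray
    config: PhantomConfig


@dataclass
class PopulationSubject:
    """One designated post-contrast frame + truth mask, for PB-model training."""

    frame: Image2D
    mask: np.ndarray
    geometry: KidneyGeometry


def enhancement_curve(config: PhantomConfig) -> np.ndarray:
    """Kidney mean intensity per frame: baseline -> peak -> slow decay.

    Gamma-variate after contrast arrival at ``onset_frac * n_frames``:
    baseline + amplitude * x^alpha * exp(alpha * (1 - x)) with
    x = (t - t0)/(tp - t0); unit peak at ``peak_frac * n_frames``.
    """
    t = np.arange(config.n_frames, dtype=np.float64)
    t0 = config.onset_frac * config.n_frames
    tp = config.peak_frac * config.n_frames
    if tp <= t0:
        raise ValueError("peak_frac must exceed onset_frac")
    x = np.maximum(t - t0, 0.0) / (tp - t0)
    a = config.curve_alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(x > 0, x**a * np.exp(a * (1.0 - x)), 0.0)
    return config.baseline + config.peak_amplitude * g


def low_contrast_frames(config: PhantomConfig, threshold: float = 0.05) -> list[int]:
    """Frames whose enhancement is below ``threshold`` of the peak amplitude."""
    curve = enhancement_curve(config)
    rel = (curve - config.baseline) / config.peak_amplitude
    return [int(i) for i in np.nonzero(rel < threshold)[0]]


def kidney_mask(shape: tuple[int, int], geom: KidneyGeometry) -> np.ndarray:
    """Rasterize the bean shape as a binary uint8 mask."""
    rows, cols = np.indices(shape, dtype=np.float64)
    th = np.deg2rad(geom.orientation)
    dr = rows - geom.center[0]
    dc = cols - geom.center[1]
    # coordinates along the major (u) and minor (v) axes
    u = np.cos(th) * dc + np.sin(th) * dr
    v = -np.sin(th) * dc + np.cos(th) * dr
    body = (u / geom.a) ** 2 + (v / geom.b) ** 2 <= 1.0
    # hilum notch on the medial (positive-v) edge
    notch = ((u / (0.45 * geom.a)) ** 2 + ((v - 0.95 * geom.b) / (0.55 * geom.b)) ** 2) <= 1.0
    mask = body & ~notch
    if not mask.any():
        raise ValueError("kidney geometry produced an empty mask")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("kidney geometry exits the field of view")
    return mask.astype(np.uint8)


def _background(shape: tuple[int, int], config: PhantomConfig) -> np.ndarray:
    rows, cols = np.indices(shape, dtype=np.float64)
    ramp = (rows / max(shape[0] - 1, 1) + cols / max(shape[1] - 1, 1)) / 2.0
    return config.background_level + config.gradient_amplitude * (ramp - 0.5)


def _scene(config: PhantomConfig, geom: KidneyGeometry, kidney_value: float) -> np.ndarray:
    mask = kidney_mask(config.image_size, geom)
    scene = _background(config.image_size, config)
    scene = np.where(mask > 0, kidney_value, scene)
    if config.psf_sigma > 0:
        scene = ndimage.gaussian_filter(scene, sigma=config.psf_sigma)
    return scene


def _jitter(rng: np.random.Generator, config: PhantomConfig, shape) -> AffineTransform:
    ty, tx = rng.uniform(-config.breathing_translation, config.breathing_translation, 2)
    rot = rng.uniform(-config.breathing_rotation, config.breathing_rotation)
    return AffineTransform.from_params(shape, ty=ty, tx=tx, rotation=rot)


def draw_geometry(config: PhantomConfig, rng: np.random.Generator | int) -> KidneyGeometry:
    """Sample one subject's kidney geometry from the population distribution.

    ``config.geometry`` is the population mean; the draw perturbs center,
    axes and orientation by the configured between-subject SDs. Use this
    for test subjects as well as training subjects: a real patient is a
    draw from the population, not its mean.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return _draw_geometry(rng, config)


def _draw_geometry(rng: np.random.Generator, config: PhantomConfig) -> KidneyGeometry:
    g = config.geometry
    return KidneyGeometry(
        center=(
            g.center[0] + rng.normal(0.0, config.center_sd),
            g.center[1] + rng.normal(0.0, config.center_sd),
        ),
        a=max(g.a + rng.normal(0.0, config.axis_sd), 6.0),
        b=max(g.b + rng.normal(0.0, config.axis_sd), 4.0),
        orientation=g.orientation + rng.normal(0.0, config.orientation_sd),
    )


def make_subject(config: PhantomConfig, geometry: KidneyGeometry | None = None) -> Subject:
    """Generate one subject's full time sequence with ground truth.

    Frame t = warp(blurred scene at curve(t), jitter_t) + Gaussian noise;
    the truth mask is warped with the same jitter (nearest neighbor).
    """
    rng = np.random.default_rng(config.seed)
    geom = geometry if geometry is not None else config.geometry
    curve = enhancement_curve(config)
    mask0 = kidney_mask(config.image_size, geom)
    frames: list[Image2D] = []
    masks: list[np.ndarray] = []
    transforms: list[AffineTransform] = []
    for t in range(config.n_frames):
        jitter = _jitter(rng, config, config.image_size)
        scene = _scene(config, geom, float(curve[t]))
        pix = warp(scene, jitter, "bilinear", cval=config.background_level)
        if config.noise_sigma > 0:
            pix = pix + rng.normal(0.0, config.noise_sigma, pix.shape)
        frames.append(Image2D(pix, source=f"phantom[seed={config.seed},t={t}]"))
        masks.append(warp(mask0, jitter, "nearest", cval=0).astype(np.uint8))
        transforms.append(jitter)
    return Subject(frames=frames, masks=masks, transforms=transforms, curve=curve,
                   config=config)


def make_population(n_subjects: int, config: PhantomConfig) -> list[PopulationSubject]:
    """Draw subjects with varied kidney geometry; render each at peak contrast.

    Returns one designated post-contrast frame (no breathing jitter, so the
    subject is in its reference pose) plus its truth mask per subject, the
    inputs to population-shape-model training.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(config.seed)
    curve = enhancement_curve(config)
    peak_value = float(curve.max())
    out = []
    for s in range(n_subjects):
        geom = _draw_geometry(rng, config)
        scene = _scene(config, geom, peak_value)
        if config.noise_sigma > 0:
            scene = scene + rng.normal(0.0, config.noise_sigma, scene.shape)
        out.append(
            PopulationSubject(
                frame=Image2D(scene, source=f"phantom-pop[seed={config.seed},s={s}]"),
                mask=kidney_mask(config.image_size, geom),
                geometry=geom,
            )
        )
    return out
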