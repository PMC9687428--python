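"""Readers and writers for DCE-MRI frame sequences and binary masks.

Supported formats: NIfTI-1 (one 3-D volume, frames along the third axis),
DICOM directories (read-only, ordered by InstanceNumber), and PNG/TIFF
stacks (one file per frame, lexicographic order).

Coordinate convention used throughout the package: row-major ``(row, col)``
indexing, 0-based, with coordinates at pixel centers.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Image2D:
    """A single grayscale time-point frame.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities, any numeric dtype; stored as float64.
    spacing : float
        Isotropic pixel size in mm/pixel (1.0 when unknown).
    source : str
        Provenance string (file path or generator description).
    """

    pixels: np.ndarray
    spacing: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image2D requires a nonempty 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_sequence(path: str | Path, format: str | None = None) -> list[Image2D]:
    """Read an ordered frame sequence.

    ``format`` is one of ``nifti``, ``dicom-dir`` or ``png-stack``; when None
    it is inferred from the path (a ``.nii``/``.nii.gz`` file is NIfTI, a
    directory containing ``.dcm`` files is DICOM, otherwise a PNG/TIFF stack).
    Frames are ordered by acquisition index: the NIfTI third axis, the DICOM
    InstanceNumber, or lexicographic filenames for image stacks.
    """
    path = Path(path)
    if format is None:
        if path.is_file() and (path.suffix == ".nii" or path.name.endswith(".nii.gz")):
            format = "nifti"
        elif path.is_dir() and any(path.glob("*.dcm")):
            format = "dicom-dir"
        else:
            format = "png-stack"

    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-dir":
        return _read_dicom_dir(path)
    if format == "png-stack":
        return _read_stack(path)
    raise ValueError(f"unknown sequence format: {format!r}")


def _read_nifti(path: Path) -> list[Image2D]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D NIfTI volume, got ndim={data.ndim}")
    spacing = float(img.header.get_zooms()[0])
    return [
        Image2D(np.asarray(data[..., t], dtype=np.float64), spacing=spacing,
                source=f"{path}[{t}]")
        for t in range(data.shape[2])
    ]


def _read_dicom_dir(path: Path) -> list[Image2D]:
    import pydicom

    slices = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        slices.append((int(getattr(ds, "InstanceNumber", 0)), f, ds))
    if not slices:
        raise FileNotFoundError(f"no readable DICOM files under {path}")
    slices.sort(key=lambda item: item[0])
    frames = []
    shape = None
    for _, f, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError("mixed frame dimensions in DICOM directory")
        spacing = 1.0
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        frames.append(Image2D(arr, spacing=spacing, source=str(f)))
    return frames


_STACK_SUFFIXES = (".png", ".tif", ".tiff")


def _read_stack(path: Path) -> list[Image2D]:
    import imageio.v3 as iio

    files = sorted(f for f in Path(path).iterdir() if f.suffix.lower() in _STACK_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames under {path}")
    frames = []
    shape = None
    for f in files:
        arr = np.asarray(iio.imread(str(f)), dtype=np.float64)
        if arr.ndim == 3:  # collapse RGB(A) to grayscale
            arr = arr[..., :3].mean(axis=2)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError("mixed frame dimensions in image stack")
        frames.append(Image2D(arr, source=str(f)))
    return frames


def write_sequence_nifti(frames: list[Image2D], path: str | Path) -> None:
    """Write frames as a float32 3-D NIfTI volume (frames on the third axis)."""
    import nibabel as nib

    vol = np.stack([f.pixels for f in frames], axis=2).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_masks(masks: list[np.ndarray], path: str | Path, format: str = "nifti") -> None:
    """Write binary masks as uint8 {0,1}; ``format`` is ``nifti`` or ``png-stack``."""
    path = Path(path)
    arrs = [np.asarray(m) for m in masks]
    for m in arrs:
        vals = np.unique(m)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("masks must be binary {0,1}")
    if format == "nifti":
        import nibabel as nib

        vol = np.stack(arrs, axis=2).astype(np.uint8)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    elif format == "png-stack":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(arrs):
            iio.imwrite(str(path / f"mask_{i:04d}.png"), (m.astype(np.uint8) * 255))
    else:
        raise ValueError(f"unknown mask format: {format!r}")


def read_masks(path: str | Path, format: str = "nifti") -> list[np.ndarray]:
    """Read masks written by :func:`write_masks` back as uint8 {0,1} arrays."""
    if format == "nifti":
        frames = _read_nifti(Path(path))
        return [(f.pixels > 0).astype(np.uint8) for f in frames]
    if format == "png-stack":
        frames = _read_stack(Path(path))
        return [(f.pixels > 0).astype(np.uint8) for f in frames]
    raise ValueError(f"unknown mask format: {format!r}")


def write_provenance(path: str | Path, parameters: dict, seed: int | None = None) -> None:
    """Record run parameters, package versions and the RNG seed as JSON."""
    import scipy

    record = {
        "parameters": parameters,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
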