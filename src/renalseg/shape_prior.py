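"""Pixel-wise Bayesian kidney/background shape probability maps.

A shape model is built from N co-registered binary kidney masks. For a
pixel where both labels were observed among the N masks (O = 2), the
probability of label L with pseudo count beta is

    P_L = (N_L + beta) / (N + beta * O) * N / (N + l - O),

which for two labels reduces to (N_L + beta) / (N + 2 beta). Where only
one label was ever observed (O = 1) the observed label gets
N / (N + 1) from the same formula and the unobserved label receives the
remaining 1 / (N + 1), so no pixel is ever certain — the Bayesian repair
of the naive frequency model, which would assign probability exactly 0 to
a kidney pixel that happens never to be covered in the training masks.

The population-based (PB) model is built offline from many subjects; the
subject-specific (SS) model is grown incrementally from the subject's own
converged segmentations and frozen once the scheduled frames are done.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .registration import AffineTransform, warp

__all__ = ["ShapePrior", "estimate_prior", "update_prior", "prior_lookup"]

N_LABELS = 2  # kidney / background


@dataclass
class ShapePrior:
    """Kidney/background probability maps plus the counts that produced them.

    Keeping the per-pixel kidney counts ``n_k`` makes the incremental
    update exact: adding a mask increments the counts and recomputes the
    probabilities, which is identical to rebuilding from the full mask set.
    """

    p_k: np.ndarray
    p_b: np.ndarray
    n: int
    n_k: np.ndarray
    beta: float
    reference_shape: tuple[int, int]
    reference_image: np.ndarray | None = None
    frozen: bool = False
    provenance: list = field(default_factory=list)

    @property
    def background_floor(self) -> tuple[float, float]:
        """(P_K, P_B) for a pixel observed as background in all N masks."""
        return 1.0 / (self.n + 1.0), self.n / (self.n + 1.0)

    def maps(self) -> tuple[np.ndarray, np.ndarray]:
        return self.p_k, self.p_b

    def freeze(self) -> None:
        self.frozen = True

    def save(self, path: str | Path) -> None:
        """Serialize as .npz plus a JSON sidecar with counts and provenance."""
        path = Path(path)
        arrays = {"p_k": self.p_k, "p_b": self.p_b, "n_k": self.n_k}
        if self.reference_image is not None:
            arrays["reference_image"] = self.reference_image
        np.savez(path, **arrays)
        sidecar = {
            "n": self.n,
            "beta": self.beta,
            "reference_shape": list(self.reference_shape),
            "frozen": self.frozen,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ShapePrior":
        path = Path(path)
        data = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            p_k=data["p_k"],
            p_b=data["p_b"],
            n=int(sidecar["n"]),
            n_k=data["n_k"],
            beta=float(sidecar["beta"]),
            reference_shape=tuple(sidecar["reference_shape"]),
            reference_image=data["reference_image"] if "reference_image" in data else None,
            frozen=bool(sidecar["frozen"]),
            provenance=list(sidecar["provenance"]),
        )


def _probabilities(n_k: np.ndarray, n: int, beta: float) -> tuple[np.ndarray, np.ndarray]:
    n_b = n - n_k
    # O = 2 branch: both labels observed
    p_k = (n_k + beta) / (n + N_LABELS * beta)
    # O = 1 branch: observed label N/(N+1), unobserved 1/(N+1)
    hi = n / (n + 1.0)
    lo = 1.0 / (n + 1.0)
    p_k = np.where(n_k == n, hi, np.where(n_k == 0, lo, p_k))
    return p_k, 1.0 - p_k


def _validate_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    m = np.asarray(mask)
    if m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match reference {tuple(shape)}")
    if not np.all(np.isin(np.unique(m), [0, 1])):
        raise ValueError("masks must be binary {0,1}")
    return m.astype(np.float64)


def estimate_prior(
    masks: list[np.ndarray],
    beta: float = 1.0,
    reference_image: np.ndarray | None = None,
    provenance: list | None = None,
) -> ShapePrior:
    """Build a shape prior from co-registered binary masks.

    Order of the masks is irrelevant (only per-pixel counts matter). With
    beta > 0 every output probability lies strictly in (0, 1).
    """
    if not masks:
        raise ValueError("at least one mask is required")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    shape = np.asarray(masks[0]).shape
    stack = np.stack([_validate_mask(m, shape) for m in masks])
    n = len(masks)
    n_k = stack.sum(axis=0)
    p_k, p_b = _probabilities(n_k, n, beta)
    return ShapePrior(
        p_k=p_k,
        p_b=p_b,
        n=n,
        n_k=n_k,
        beta=beta,
        reference_shape=tuple(shape),
        reference_image=None if reference_image is None else np.asarray(reference_image, float),
        provenance=list(provenance or []),
    )


def update_prior(prior: ShapePrior, new_mask: np.ndarray, label: str = "") -> ShapePrior:
    """Add one mask to the prior; exactly equivalent to rebuilding from scratch."""
    if prior.frozen:
        raise RuntimeError("shape prior is frozen; no further updates accepted")
    m = _validate_mask(new_mask, prior.reference_shape)
    n = prior.n + 1
    n_k = prior.n_k + m
    p_k, p_b = _probabilities(n_k, n, prior.beta)
    return replace(
        prior, p_k=p_k, p_b=p_b, n=n, n_k=n_k, provenance=prior.provenance + [label]
    )


def prior_lookup(
    prior: ShapePrior, transform: AffineTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the prior maps from the reference frame into an image frame.

    ``transform`` maps image-frame points to reference-frame points (the
    inverse of the frame's registration result). Bilinear interpolation;
    pixels that fall outside the reference field of view receive the
    background-certain floor (the beta-smoothed probability of a pixel
    observed as background in all N masks). Normalization P_K + P_B = 1 is
    preserved exactly because the out-of-field weight is filled with a
    normalized pair.
    """
    floor_k, floor_b = prior.background_floor
    w = warp(np.ones(prior.reference_shape), transform, "bilinear")  # in-field weight
    p_k = warp(prior.p_k, transform, "bilinear") + (1.0 - w) * floor_k
    p_b = warp(prior.p_b, transform, "bilinear") + (1.0 - w) * floor_b
    return p_k, p_b
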