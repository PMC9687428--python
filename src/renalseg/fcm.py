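"""Fuzzy c-means memberships embedded in the level-set evolution.

Two clusters (kidney K and background B) with fuzziness exponent 2. Unlike
classic FCM, which clusters the image once up front, the memberships and
centroids here are re-estimated at every contour iteration, with the
centroid update weighted by the region indicators R_K = H_eps(phi) and
R_B = 1 - H_eps(phi) so that each cluster's centroid is drawn from the
side of the contour it currently labels. The memberships are then blended
with shape-prior probabilities into the per-pixel label energies that
drive the contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .levelset import EvolutionParams, LevelSetField, evolve_step, smeared_heaviside

__all__ = [
    "MembershipField",
    "LabelEnergy",
    "init_centroids",
    "update_memberships",
    "update_centroids",
    "label_energy",
    "coupled_step",
    "fcm_objective",
    "static_fcm",
]


class DegenerateInputError(ValueError):
    """Raised when centroids or regions collapse (constant image, empty side)."""


@dataclass
class MembershipField:
    """Per-pixel kidney/background memberships plus the two cluster centroids.

    Invariant: mu_K + mu_B = 1 at every pixel.
    """

    mu_K: np.ndarray
    mu_B: np.ndarray
    C_K: float
    C_B: float


@dataclass
class LabelEnergy:
    """Per-pixel kidney/background label energies, each in [0, 1]."""

    F_K: np.ndarray
    F_B: np.ndarray


def init_centroids(image: np.ndarray, field: LevelSetField) -> tuple[float, float]:
    """Initial centroids: mean intensity inside ({phi>0}) and outside ({phi<0}).

    Pixels exactly on the contour (phi = 0) belong to neither mean. Raises
    :class:`DegenerateInputError` if either side is empty or the image is
    constant (no kidney/background intensity structure to cluster).
    """
    inside = field.phi > 0
    outside = field.phi < 0
    if not inside.any() or not outside.any():
        raise DegenerateInputError("initial contour must enclose and exclude >= 1 pixel")
    if np.ptp(image) == 0:
        raise DegenerateInputError("constant image: kidney/background clusters undefined")
    return float(image[inside].mean()), float(image[outside].mean())


def update_memberships(image: np.ndarray, C_K: float, C_B: float) -> MembershipField:
    """Inverse-squared-distance memberships to the two centroids.

    mu_L = d_L^-2 / (d_K^-2 + d_B^-2) with d_L = |I - C_L|, computed in the
    algebraically equivalent form mu_K = d_B^2 / (d_K^2 + d_B^2) so that a
    pixel exactly at a centroid gets membership 1 there and 0 elsewhere.
    """
    if C_K == C_B:
        raise DegenerateInputError("C_K must differ from C_B")
    d_k2 = (image - C_K) ** 2
    d_b2 = (image - C_B) ** 2
    denom = d_k2 + d_b2  # > 0 everywhere since C_K != C_B
    mu_k = d_b2 / denom
    return MembershipField(mu_K=mu_k, mu_B=1.0 - mu_k, C_K=C_K, C_B=C_B)


def update_centroids(
    image: np.ndarray,
    memberships: MembershipField,
    field: LevelSetField | None,
) -> tuple[float, float]:
    """Membership-weighted centroids restricted to each side of the contour.

    C_L = sum R_L I mu_L^2 / sum R_L mu_L^2 with R_K = H_eps(phi) and
    R_B = 1 - H_eps(phi). ``field=None`` sets both indicators to one
    (full-domain update), which reduces to the classic FCM centroid step.
    """
    if field is None:
        r_k = r_b = np.ones_like(image)
    else:
        r_k = smeared_heaviside(field.phi, field.epsilon)
        r_b = 1.0 - r_k
    w_k = r_k * memberships.mu_K**2
    w_b = r_b * memberships.mu_B**2
    den_k = float(w_k.sum())
    den_b = float(w_b.sum())
    if den_k <= 0 or den_b <= 0:
        raise DegenerateInputError("empty effective region in centroid update")
    return float((w_k * image).sum() / den_k), float((w_b * image).sum() / den_b)


def label_energy(
    memberships: MembershipField,
    pb_maps: tuple[np.ndarray, np.ndarray],
    ss_maps: tuple[np.ndarray, np.ndarray] | None,
    omega_t: float,
) -> LabelEnergy:
    """Blend memberships with shape priors: F_L = w mu_L P_L + (1-w) mu_L S_L.

    ``pb_maps``/``ss_maps`` are (kidney, background) probability maps from
    the population-based and subject-specific shape models; ``omega_t`` in
    [0, 1] weights the population model. The subject-specific maps may be
    absent only when omega_t = 1.
    """
    if not 0.0 <= omega_t <= 1.0:
        raise ValueError("omega_t must lie in [0, 1]")
    if ss_maps is None:
        if omega_t < 1.0:
            raise ValueError("subject-specific prior required when omega_t < 1")
        s_k = s_b = None
    else:
        s_k, s_b = ss_maps
    p_k, p_b = pb_maps
    f_k = omega_t * memberships.mu_K * p_k
    f_b = omega_t * memberships.mu_B * p_b
    if s_k is not None:
        f_k = f_k + (1.0 - omega_t) * memberships.mu_K * s_k
        f_b = f_b + (1.0 - omega_t) * memberships.mu_B * s_b
    return LabelEnergy(F_K=f_k, F_B=f_b)


def coupled_step(
    image: np.ndarray,
    field: LevelSetField,
    memberships: MembershipField,
    pb_maps: tuple[np.ndarray, np.ndarray],
    ss_maps: tuple[np.ndarray, np.ndarray] | None,
    omega_t: float,
    params: EvolutionParams,
) -> tuple[LevelSetField, MembershipField, float]:
    """One coupled iteration: centroids -> memberships -> energies -> phi step.

    Returns the updated field, memberships, and mean |dphi| of the step.
    """
    c_k, c_b = update_centroids(image, memberships, field)
    memberships = update_memberships(image, c_k, c_b)
    energy = label_energy(memberships, pb_maps, ss_maps, omega_t)
    field, change = evolve_step(field, energy.F_K, energy.F_B, params)
    return field, memberships, change


def fcm_objective(
    image: np.ndarray,
    memberships: MembershipField,
    field: LevelSetField | None = None,
) -> float:
    """Region-weighted FCM objective sum_L sum R_L mu_L^2 (I - C_L)^2.

    Diagnostic only; with ``field=None`` it is the textbook two-cluster
    objective that the alternating updates monotonically decrease.
    """
    if field is None:
        r_k = r_b = 1.0
    else:
        r_k = smeared_heaviside(field.phi, field.epsilon)
        r_b = 1.0 - r_k
    j_k = r_k * memberships.mu_K**2 * (image - memberships.C_K) ** 2
    j_b = r_b * memberships.mu_B**2 * (image - memberships.C_B) ** 2
    return float(np.sum(j_k) + np.sum(j_b))


def static_fcm(
    image: np.ndarray,
    C_K: float,
    C_B: float,
    max_iters: int = 100,
    tol: float = 1e-8,
) -> MembershipField:
    """Classic two-cluster FCM run to convergence on the full image domain.

    Used by the static-membership ablation scenario: the returned
    memberships are computed once, before any contour evolution, and are
    not updated afterwards.
    """
    memberships = update_memberships(image, C_K, C_B)
    for _ in range(max_iters):
        c_k, c_b = update_centroids(image, memberships, field=None)
        if abs(c_k - memberships.C_K) < tol and abs(c_b - memberships.C_B) < tol:
            memberships = update_memberships(image, c_k, c_b)
            break
        memberships = update_memberships(image, c_k, c_b)
    return memberships
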