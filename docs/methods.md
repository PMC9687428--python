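# Methods

`renalseg` segments the kidney in every frame of a dynamic
contrast-enhanced MRI (DCE-MRI) sequence. This note describes the model,
the numerical choices behind the implementation, the synthetic phantom the
tests run on, and the known limitations.

## Segmentation model

Each frame is a 2-D image `I_t(x, y)` on a domain Ω. The kidney contour is
the zero level set of a scalar field φ, positive inside, negative outside.
The contour evolves to minimize

```
E(φ) = λ₁ L(φ) + λ₂ ∫ H_ε(φ) F_B + (1 − H_ε(φ)) F_K dΩ
```

where `L(φ) = ∫ δ_ε(φ) |∇φ| dΩ` penalizes contour length, and `H_ε`, `δ_ε`
are the smeared (band-limited) Heaviside and Dirac functions with half-width
ε: within `|φ| ≤ ε`,

```
H_ε(φ) = 1/2 + φ/2ε + sin(πφ/ε)/2π,      δ_ε(φ) = (1 + cos(πφ/ε)) / 2ε.
```

Gradient descent gives the explicit update

```
φ ← φ + τ δ_ε(φ) [ λ₁ div(∇φ/|∇φ|) + λ₂ (F_K − F_B) ].
```

The per-pixel label energies blend three sources of evidence:

```
F_L = ω_t μ_L P_L + (1 − ω_t) μ_L S_L,     L ∈ {K, B},
```

* `μ_L` — fuzzy c-means membership of the pixel in the kidney/background
  intensity cluster (`μ_K + μ_B = 1`, fuzziness exponent 2). Memberships
  and cluster centroids are *embedded* in the evolution: they are
  re-estimated at every iteration, with centroids weighted by the region
  indicators `R_K = H_ε(φ)`, `R_B = 1 − H_ε(φ)` so each cluster draws its
  centroid from the side of the contour it currently labels.
* `P_L` — population-based (PB) shape model: per-pixel Bayesian label
  probabilities estimated from N co-registered training masks of different
  subjects. With pseudo count β, a pixel where both labels occur gets
  `P_L = (N_L + β)/(N + 2β)`; a pixel with a unanimous label gets
  `N/(N+1)` for the observed label and `1/(N+1)` for the unobserved one,
  so no pixel is ever certain.
* `S_L` — subject-specific (SS) shape model: the same estimator applied to
  the subject's own converged segmentations, grown on the fly.

### Sequence scheduling

The blend weight ω_t is scheduled automatically. Every frame is first
registered (2-D affine, mutual-information metric) to the PB model's
reference image; the prior-weighted mean kidney intensity
`m_t = Σ P_K I_t / Σ P_K` then ranks the frames by contrast without any
segmentation. The N₁ highest-m_t frames (post-contrast) form S1 and are
segmented with the PB model alone (ω = 1); their masks build the SS model.
The next N₂ frames (S2) use a blend, ω stepping down as `(N₂ − i)/N₂` by
descending-m_t rank i, while the SS model keeps growing; it is then frozen.
The remaining low-contrast frames (S3) rely on the SS model alone (ω = 0),
which by then captures this subject's exact kidney shape. Ties in m_t are
broken by frame index, so the plan is deterministic and invariant to the
order frames are supplied in.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| ε | 1.5 px | smearing half-width of H_ε, δ_ε |
| λ₁, λ₂ | 6, 6 | length- and data-term weights |
| β | 1 | pseudo count of the Bayesian shape estimator |
| N₁, N₂ | 20, 10 | S1/S2 sizes for ~80-frame sequences (scaled to 8, 6 for the 20-frame phantom studies) |
| τ | 0.1 | explicit time step |
| tol, max_iters | 1e−4, 500 | stop when mean \|Δφ\| < tol |
| MI bins | 32 | joint-histogram size for registration |

## Numerical choices

* **Initial φ.** The seed contour is a circle (by default centered on the
  PB model's kidney centroid with radius `0.75·√(area/π)`); φ is its
  Euclidean signed distance *saturated to ±2ε/3*. Because δ_ε vanishes
  outside `|φ| ≤ ε`, a full-range signed distance would freeze every pixel
  farther than ε from the seed and the contour could never travel;
  saturating into the band puts the whole domain under the force's
  influence, which is what makes the result independent of seed placement.
* **Time step.** τ = 0.1 with tol = 1e−4. With the bounded update
  `|δ_ε| ≤ 1/ε` and `F ∈ [0,1]` larger steps are stable, but the coupled
  system then classifies pixels before the FCM centroids have equilibrated:
  pixels pushed past ±ε freeze (δ_ε = 0), locking in early errors and
  re-introducing a dependence on the seed position. The smaller step lets
  memberships, centroids and region co-evolve; convergence takes ~100–200
  iterations per frame.
* **No reinitialization.** φ is never reset to a signed distance during
  evolution; it is clamped to ±10ε to bound drift (the smeared functions
  are insensitive beyond ±ε, so the clamp is inert).
* **Curvature.** Central differences with replicate padding; the gradient
  norm is floored at 1e−8, so flat regions get zero curvature. Verified
  against the closed form −1/r on a circle's signed distance.
* **FCM degeneracies.** A pixel whose intensity equals a centroid gets
  membership 1 in that cluster (the continuous limit of the
  inverse-squared-distance rule, computed in the singularity-free algebraic
  form). A constant image is rejected. At initialization the kidney
  cluster is anchored to the *brighter* of the two inside/outside means —
  the kidney is the contrast-enhancing structure — so a seed circle placed
  over background cannot swap the cluster labels.
* **Intensities** are used on their native scale; no normalization before
  clustering.
* **Shape-prior resampling.** Priors are bilinear-resampled between frames;
  out-of-field pixels receive the background-certain floor
  `(1/(N+1), N/(N+1))`, filled proportionally to the out-of-field weight so
  `P_K + P_B = 1` holds exactly everywhere.
* **Registration.** Powell optimization of MI over (tx, ty, rotation,
  scale-x, scale-y, shear) on a (4, 2, 1) Gaussian pyramid, centered at the
  image center. Masks are warped with nearest-neighbor; images bilinear.
  A frame whose optimization fails to improve on the initial transform is
  flagged and processed with that initial transform.
* **HD95.** Boundary pixels are mask pixels with a background 4-neighbor;
  nearest distances are pooled from both directions before the 95th
  percentile (linear interpolation between order statistics). Reported in
  pixels unless a spacing is supplied.

## The synthetic phantom

The phantom generates what the method needs to be tested end to end: a
bean-shaped kidney (ellipse minus a hilum notch, semi-axes 30×18 px in a
128×128 field) whose mean intensity follows a gamma-variate enhancement
curve (baseline 0.24, peak 0.79 on a [0,1] scale, onset at 20% and peak at
45% of the sequence), over a background of 0.20 with a gentle linear
gradient, blurred by a 1-px Gaussian PSF. Nuisances: per-frame uniform
affine jitter (±2 px, ±2°) emulating breathing, additive Gaussian noise
(σ = 0.01 in the noise studies), and between-subject variation of the
kidney geometry (SDs: 4 px center, 2.5 px axes, 8° orientation). Subjects
— including test subjects — are drawn from this population distribution;
an atlas built from draws would otherwise be unrealistically well matched
to a subject placed exactly at the population mean. Frames whose
enhancement is below 5% of the peak amplitude form the designated
low-contrast subset (the pre-contrast frames, plus late frames in long
sequences).

What the phantom does **not** emulate: MR acquisition physics (k-space,
coil sensitivity, bias fields), neighboring organs of similar intensity,
through-plane motion, and deformable (non-affine) breathing motion.
Passing the phantom studies therefore demonstrates the correctness and
internal consistency of the machinery — not clinical-grade accuracy.

One phantom-specific caveat: a completely noise-free phantom frame is
nearly piecewise-constant, so its joint intensity histogram occupies only
a few bins and the MI surface the registration climbs is almost flat.
Registration robustness is therefore assessed on frames with the realistic
noise level, which is also the condition real acquisitions present.

## Study sizes used in the automated checks

The validation studies run at desk scale: 128×128 frames, 20-frame
sequences, a 10-subject atlas, N₁ = 8, N₂ = 6. The headline quantities
(mean DSC/IoU/HD95 over all frames, low-contrast DSC, noise degradation,
the three-scenario ablation, initialization-robustness range, and the
registration recovery rate over 20 random perturbations) are recomputed
from scratch by `scripts/acceptance.py`.

## Known limitations

* 2-D only; each frame is segmented independently given the priors.
* Errors in the affine alignment propagate into both shape priors; there
  is no joint segmentation–registration.
* The S1/S2/S3 schedule assumes the PB model is reliable on high-contrast
  frames; a pathological subject far outside the atlas distribution would
  seed the SS model with poor masks.
* No narrow-band acceleration: cost is O(pixels) per iteration, ~1 s per
  128×128 frame at the default settings.
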