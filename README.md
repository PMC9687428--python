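# renalseg

Automated kidney segmentation for dynamic contrast-enhanced MRI (DCE-MRI)
sequences. During contrast-agent perfusion the kidney's intensity rises
from a dim pre-contrast baseline to a bright post-contrast peak and then
decays slowly, so some frames in a sequence are easy to segment and many
are not; breathing shifts the kidney between frames. `renalseg` is aimed
at researchers analyzing renal DCE-MRI (e.g., transplant-function
studies), where a per-frame kidney mask is the first step of any
downstream renogram analysis.

## Method

The contour is the zero level set of a field φ (positive inside), evolved
by the explicit flow

```
φ ← φ + τ δ_ε(φ) [ λ₁ div(∇φ/|∇φ|) + λ₂ (F_K − F_B) ],
F_L = ω_t μ_L P_L + (1 − ω_t) μ_L S_L,          L ∈ {K, B},
```

with smeared Heaviside/Dirac kernels H_ε, δ_ε of half-width ε. The label
energies combine three ingredients:

- **μ_L** — two-cluster fuzzy c-means memberships *embedded* in the
  evolution: centroids and memberships are re-estimated at every
  iteration, with the centroid update weighted by H_ε(φ) so each cluster
  tracks its own side of the contour;
- **P_L** — a population-based shape model: pixel-wise Bayesian label
  probabilities `(N_L + β)/(N + 2β)` from N co-registered training masks,
  with unanimously labeled pixels smoothed to `N/(N+1)` vs `1/(N+1)`;
- **S_L** — a subject-specific shape model built on the fly from the
  subject's own converged masks.

The blend ω_t is scheduled automatically: frames are ranked by the
prior-weighted mean kidney intensity `m_t = Σ P_K I_t / Σ P_K` after
affine registration (mutual information, Powell, coarse-to-fine) to the
population model's reference image. The highest-contrast N₁ frames use
the population model alone (ω = 1) and seed the subject-specific model;
the next N₂ frames blend the two with ω stepping down to 0; the
remaining low-contrast frames rely on the subject-specific model alone.

Accuracy is evaluated with DSC, IoU and HD95. A synthetic DCE-MRI phantom
(bean-shaped kidney, gamma-variate enhancement, breathing jitter, noise,
between-subject shape variation) makes the whole pipeline testable
without clinical data. See `docs/methods.md` for the details and the
numerical choices.

## Worked example

```python
import dataclasses
import numpy as np

from renalseg import (
    PhantomConfig, PipelineConfig, build_pb_prior, dice,
    make_population, make_subject, segment_sequence,
)
from renalseg.phantom import draw_geometry, low_contrast_frames

phantom = PhantomConfig(n_frames=20, noise_sigma=0.01, seed=7)

# 10-subject training set -> population shape model
population = make_population(10, dataclasses.replace(phantom, seed=100))
pb_prior = build_pb_prior([s.frame for s in population],
                          [s.mask for s in population], beta=1.0)

# an unseen subject, drawn from the same population distribution
subject = make_subject(phantom, geometry=draw_geometry(phantom, 7000))

config = PipelineConfig(n1=8, n2=6)
results, plan = segment_sequence(subject.frames, pb_prior, config)

scores = [dice(r.mask, m) for r, m in zip(results, subject.masks)]
low = low_contrast_frames(phantom)
print(f"mean DSC over {len(scores)} frames: {np.mean(scores):.3f}")
print(f"mean DSC on low-contrast frames {low}: {np.mean([scores[i] for i in low]):.3f}")
for i in (0, 9):
    print(f"frame {i:2d}: subset={plan.subset[i]} omega={plan.omega_t[i]:.2f} "
          f"m_t={plan.m_t[i]:.3f} DSC={scores[i]:.3f}")
```

Output:

```
mean DSC over 20 frames: 0.968
mean DSC on low-contrast frames [0, 1, 2, 3, 4]: 0.962
frame  0: subset=S3 omega=0.00 m_t=0.220 DSC=0.967
frame  9: subset=S1 omega=1.00 m_t=0.494 DSC=0.980
```

Frame 9 is a bright post-contrast frame: it lands in S1 (high `m_t`) and
is segmented with the population prior alone. Frame 0 is pre-contrast —
the kidney is barely visible (`m_t` at the background level) — yet it is
segmented just as accurately because by the time S3 is processed the
subject-specific model pins down this kidney's exact shape.

A command-line interface mirrors the library:

```
renalseg make-phantom     --out phantom/ --n-frames 20 --seed 7
renalseg build-pbshape    --frames pop_frames.nii.gz --masks pop_masks.nii.gz \
                          --beta 1 --out prior.npz
renalseg segment-sequence --frames phantom/frames.nii.gz --prior prior.npz \
                          --n1 8 --n2 6 --out results/
renalseg evaluate         --pred results/masks.nii.gz \
                          --truth phantom/truth.nii.gz --out metrics.csv
```

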