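# synemg

Synergy-assisted EMG-driven neuromusculoskeletal (NMSK) modelling of
upper-limb mechanics during double poling — the propulsion technique of
cross-country sit-skiing, where athletes with lower-limb impairments
generate all forward drive through simultaneous bilateral pole thrusts.

Surface EMG is the input that drives this kind of model, and it is fragile:
during vigorous motion an electrode can detach or lose contact, and deep
muscles cannot be recorded at all. `synemg` implements a complete
EMG-driven pipeline for 10 upper-limb muscles and 4 shoulder/elbow degrees
of freedom, plus the *synergy extrapolation* step that reconstructs a
missing channel's activation from the muscle synergies of the remaining
channels.

## What the pipeline computes

1. **Signal conditioning** — raw EMG is band-pass filtered (50–300 Hz),
   rectified, enveloped and normalized per muscle; double-poling cycles are
   segmented from the pole-tip height (poling = highest → lowest marker
   position) and every series is resampled to a 100-point grid, 50 points
   per phase.
2. **Activation dynamics** — the delayed envelope e(t − d) drives a
   second-order recursive filter,
   `u(t) = α·e(t−d) − (C1+C2)·u(t−1) − C1·C2·u(t−2)`,
   followed by the nonlinear shaping `a = (e^{A·u} − 1)/(e^{A} − 1)`.
3. **Contraction dynamics** — a Hill-type musculotendon unit with an
   elastic tendon: at each frame the fiber length solves
   `F̄_T(l̄_t) = (F̄_CE + F̄_PE)·cos α`, with a Gaussian active
   force–length curve, exponential passive curve, two-branch
   force–velocity relation and a toe/linear tendon curve.
4. **Forward moments** — `M_i = Σ_j F0m_j (F̄_CE + F̄_PE)_j r_ij cos α_j`,
   with the anatomical moment-arm sign structure of the 10 muscles.
5. **Calibration** — 34 subject parameters (per-muscle F0m, l0m, lst
   within ±50% of nominal; A, C1, C2, d) fitted by seeded simulated
   annealing minimizing `J = Σ_c Σ_i (1/n) Σ_p (M^mod − M^exp)²` against
   reference joint moments, validated on held-out cycles.
6. **Synergy extrapolation** — the measured 9-muscle activation matrix is
   factorized `V ≈ W·H` (NMF; PCA/ICA/FA for comparison); the missing
   muscle's activation is `a_x = clip(W_x·H_m, 0, 1)` with nonnegative
   weights `W_x` optimized so the full model tracks the reference moments.
7. **Evaluation** — %RMSE / r / %MAE for moments, RMSE / r / MAE for
   activations; paired t-tests and Kruskal–Wallis with Dunn's post-hoc for
   group comparisons.

Because no recordings ship with the package, a first-class synthetic-data
module generates a double-poling subject with known ground truth (synergy
primitives, musculotendon parameters, moment arms), closing the loop: under
the true parameters the forward model reproduces the reference moments
exactly.

## Worked example

Withhold the triceps channel of a synthetic subject and reconstruct it from
the other nine muscles' synergies:

```python
import numpy as np
from synemg import make_dataset
from synemg.extrapolation import extrapolate_missing
from synemg.optimize import AnnealingSettings

subject, dataset = make_dataset(seed=42)
ds10 = dataset.subset(range(10))          # the 10 evaluation cycles
tb = ds10.muscle_labels.index("TB")

result = extrapolate_missing(
    ds10, subject.model(), missing_idx=tb, l=5, method="nmf", seed=42,
    annealing=AnnealingSettings(max_evals=2000),
    truth=ds10.activations_true[:, :, tb],
)
print("synergy weights Wx:", np.round(result.Wx, 3))
print("tracking objective:", round(result.objective, 2),
      "(muscle dropped:", round(result.objective_zero, 2), ")")
print("prediction vs withheld truth:",
      {k: round(v, 3) for k, v in result.metrics.items()})
```

prints

```
synergy weights Wx: [0.019 0.121 0.198 0.849 0.06 ]
tracking objective: 81.24 (muscle dropped: 2515.67 )
prediction vs withheld truth: {'rmse': 0.041, 'r': 0.998, 'mae': 0.03}
```

The optimized weights load mostly on one motor primitive; the
moment-tracking objective drops ~30-fold relative to simply dropping the
muscle, and the reconstructed activation correlates at r ≈ 1.0 with the
withheld ground truth with an RMSE of 0.04 (on the 0–1 activation scale).

The same workflow is available from the shell:

```bash
synemg synth --seed 42 --out data/
synemg calibrate --data data/ --seed 42 --out cal.json
synemg validate --data data/ --result cal.json --out val.csv
synemg extrapolate --data data/ --missing TB --synergies 5 --seed 42 --out tb.json
synemg compare-methods --data data/ --seed 42 --out methods.csv
```

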