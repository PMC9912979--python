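# bafsogl

Bayesian adaptive fused sparse overlapping group lasso (Ba-FSOGL) image
reconstruction for functional near-infrared spectroscopy (fNIRS).

fNIRS probes record optical-density changes between scalp source-detector
pairs at two near-infrared wavelengths. Under the modified Beer–Lambert law
the channel measurement is linear in the voxel-space oxy/deoxy-hemoglobin
changes,

```
y = X (β + ξ) + ν,      β = [Δ[HbO]; Δ[HbR]],
```

with `X` the N × P sensitivity (Jacobian) matrix, P = 2V ≫ N. Recovering the
image β from dozens of channels is a severely ill-posed inverse problem.
Ba-FSOGL regularizes it with anatomical and hemodynamic priors: the voxels
are split into possibly overlapping regions of interest g = 1…G and the
estimate minimizes

```
‖y* − X*β‖² + Σ_g λ_g [ θγ‖β_g‖₁ + (1−γ)‖D_g β_g‖₁ + (1−θ)γ‖β_g‖_{Σ_g⁻¹} ]
```

on noise-whitened data — an adaptive (per-group λ_g) blend of sparse, fused
(spatial-difference) and Σ-weighted group penalties. Overlapping groups are
handled by duplicating shared covariates; the model is solved by Gibbs
sampling from the equivalent scale-mixture hierarchy, with λ_g optimized
inside the chain, and significance is decided from the posterior draws
(credible intervals, the scaled-neighborhood criterion, and group-level
comparison of β_gᵀΣ_g⁻¹β_g).

The package is aimed at methods researchers who want a self-contained,
desk-scale implementation of the full pipeline: an analytic semi-infinite
diffusion forward model, a synthetic-data generator with the statistical
structure of an event-related fNIRS experiment, the sampler, the
initial-λ selection protocol, posterior inference, and ROI-ROC evaluation.

## Worked example

```python
import numpy as np
from bafsogl import (
    build_probe, slab_grid, build_sensitivity_model, prune_voxels,
    rectangular_parcellation, expand_overlapping_groups, whiten,
    SimScenario, generate_stimulus_train, simulate_timeseries, channel_glm,
    PenaltyConfig, ChainConfig, gibbs_run, group_comparison, evaluate_image,
)

probe = build_probe(9, 8, 20.0, 25.0, (760.0, 850.0))   # 16 pairs, 32 channels
grid = slab_grid(13, 2, 10.0, depth=15.0, x0=20.0, y0=7.5)
model, _ = prune_voxels(build_sensitivity_model(probe, grid))
parc = rectangular_parcellation(model.grid, 3, overlap=1)

scen = SimScenario.from_parcellation(model, parc, "ROI-2", seed=42)  # 7/−2 µM
design = generate_stimulus_train(mean_isi=15.0, duration=300.0, rate=4.0, seed=7)
data = channel_glm(simulate_timeseries(scen, model, design))

Xw, yw, W = whiten(model, data)
V = model.n_voxels
Xe = np.hstack([np.hstack([Xw[:, g], Xw[:, V + np.asarray(g)]]) for g in parc.groups])
_, structure = expand_overlapping_groups(model, parc)

samples = gibbs_run(yw, Xe, structure, PenaltyConfig(lambda_init=20.0),
                    ChainConfig(4000, 1000, 3, seed=5))
est = samples.posterior_median()
print("active HbO mean:", round(est[parc.groups[1]].mean(), 2))
print("active HbR mean:", round(est[V + parc.groups[1]].mean(), 2))
print("dominant group:", group_comparison(samples).dominant.tolist())
print(evaluate_image(scen.beta_true, est))
```

prints

```
active HbO mean: 6.68
active HbR mean: -1.8
dominant group: [False, True, False]
{'mse_hbo': 3.565..., 'cnr_hbo': 8.880..., 'mse_hbr': 1.223..., 'cnr_hbr': 3.804...}
```

— the simulated 7/−2 µM activation in the middle region is recovered at
6.68/−1.80 µM (regularized estimates are slightly shrunk toward zero), the
middle group is the single dominant one, and the contrast-to-noise ratios of
the reconstruction are 8.9 dB (HbO) and 3.8 dB (HbR).

The full simulation study — per region, replicate activity datasets plus
matched noise-only datasets, each tuned, reconstructed, inferred and scored,
with pooled ROI-ROC curves — is one call:

```python
from bafsogl.study import StudyConfig, run_study
report = run_study(StudyConfig(seed=1))
print(report.roc)        # 3 regions × {voxel HbO, voxel HbR, region} AUCs
```

A thin CLI mirrors the stages: `bafsogl simulate|tune|reconstruct|infer|evaluate|study`.

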