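# Methods

This note documents the models, defaults and numerical choices behind
`bafsogl`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The measurement model

A continuous-wave fNIRS probe measures optical-density changes between
source-detector pairs at two wavelengths. Under the modified Beer–Lambert
law the effect-level measurement is linear in the voxel hemoglobin changes:

    y = X (β + ξ) + ν,    β = [Δ[HbO] voxels 1..V | Δ[HbR] voxels 1..V]ᵀ,

with `X` of shape N × 2V. The row for pair c at wavelength l carries
`ε_HbO(l)·S_l[c, v]` on the HbO block and `ε_HbR(l)·S_l[c, v]` on the HbR
block, where `S_l` is the photon-path sensitivity and ε are molar extinction
coefficients in 1/(µM·mm) — so `X β` is a dimensionless ΔOD when β is in µM
and `S` in mm. Channels are ordered wavelength-major.

### Forward model

The sensitivity is the closed-form Rytov "banana" of a semi-infinite
homogeneous diffusive medium:

    S(c, v) = G(s_c, v) · G(v, d_c) / G(s_c, d_c),

with `G` the CW diffusion Green's function using an extrapolated-boundary
image source (source depth z₀ = 1/(µa+µs′), extrapolation length 2·zb with
zb = 2D, D = 1/(3(µa+µs′))). This replaces Monte-Carlo/FEM photon transport
on a segmented head: it is deterministic, runs in milliseconds, and
preserves the two structural features an inverse solver must cope with —
exponential depth attenuation and smooth lateral blur. It does not model
tissue heterogeneity (skull/CSF light piping), curved geometry, or optode
coupling variation; conclusions from the synthetic studies therefore
concern the reconstruction machinery, not quantitative accuracy on real
heads. Default optics: µa = 0.0187/0.0186 mm⁻¹ and µs′ = 1.1/1.0 mm⁻¹ at
760/850 nm, with standard literature extinction coefficients; all are
configurable, and reconstructed amplitudes are insensitive to their exact
values because the channel GLM and whitening normalize the scale.

### Probe and voxel grid

The standard montage interleaves 9 sources and 8 detectors on two parallel
lines (20 mm along-row spacing, 25 mm between rows); optical density is
measured only between nearest source-detector pairs (ties within 1 nm keep
all minimal pairs), giving 16 pairs and 32 channels at two wavelengths.
The default image space is a 13 × 2 voxel slab (10 mm spacing) at 15 mm
depth spanning the probe interior (x ∈ [20, 140] mm, rows straddling the
probe midline). This is the analog of screening regions of interest for
detectability before simulating: voxel columns outside the probe interior
are effectively blind to this montage and no reconstruction method could
recover them. Voxels further than 50 mm from every pair midpoint are pruned.

## Synthetic data

The generator emulates an event-related experiment:

* stimulus onsets with i.i.d. exponential gaps (mean ISI 15 s) over a 300 s
  scan at 4 Hz;
* a canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6),
  peak-normalized so an isolated event attains exactly the configured
  amplitudes — 7 µM HbO and −2 µM HbR on every voxel of the active region;
* channel noise: stationary AR(3) with coefficients (0.5, 0.2, 0.1), scaled
  so that SNR = (peak channel signal amplitude)/(noise SD) = 5; matched
  noise-only datasets reuse the SNR-derived noise level of their region;
* optional spatially smooth image-space physiological noise (off by
  default).

ISI, duration, rate, AR structure and SNR are study conventions, not
measured constants; they are all config keys. What the generator does not
emulate: motion artifacts, superficial/systemic physiology requiring
short-separation regression, HRF variability across subjects. Passing tests
therefore demonstrate correct machinery under the stated statistical
structure, not robustness to those real-world effects.

Each dataset is reduced to effect level by a channel-wise GLM: ordinary
least squares of every channel course on the unit-peak HRF regressor (plus
intercept), Yule-Walker AR fit of the residuals, prewhitening of both
sides, and a refit. `y` stacks the effect estimates; `C_ν` is the diagonal
matrix of their variances (floored at 1e-12). Whitening uses W = L⁻¹ from
the lower Cholesky factor of `C_ν`, so WᵀW = C_ν⁻¹ exactly.

## The estimator

On whitened, overlap-expanded data the estimate targets

    min_β ‖y* − X*β‖² + Σ_g λ_g [ θγ‖β_g‖₁ + (1−γ)‖D_g β_g‖₁
                                  + (1−θ)γ √(β_gᵀ Σ_g⁻¹ β_g) ].

* **Overlap expansion.** Shared voxels are duplicated — one column per
  (group, voxel, chromophore) triple — making the groups disjoint; an
  original coefficient is the *sum* of its copies (the latent-decomposition
  convention under which the duplicated regular group lasso is equivalent to
  the overlapping one).
* **D_g** has one ±1 row per connected voxel pair (lattice neighbors at one
  grid spacing), block-diagonal over the HbO and HbR halves: the two
  chromophores are never fused to each other.
* **Σ_g** couples each voxel's HbO/HbR pair with correlation ρ = −0.75 and
  HbR/HbO scale c = 2/7 (activation anticorrelates the chromophores, and
  HbR changes are smaller — c matches the simulated amplitude ratio 2/7);
  distinct voxels are a priori uncorrelated. Both are config keys.
* **Weights.** (θγ, 1−γ, (1−θ)γ); the reference choice θ = 0.125, γ = 0.4
  gives (0.05, 0.6, 0.35) — mostly fused and group shrinkage, consistent
  with spatially uniform activations and anticorrelated chromophores.

## The Gibbs sampler

The hierarchy is the standard scale mixture with priors conditioned on σ²
(Park–Casella convention): exponential mixing for the sparse (τ²) and fused
(ω²) latents, Gamma((m_g+1)/2, (λ_g w_g)²/2) for the group scale, and

    β_g | latents, σ² ~ N(0, σ² V_g),
    V_g⁻¹ = diag(1/τ²) + D_gᵀ diag(1/ω²) D_g + Σ_g⁻¹/τ_g².

Full conditionals: a Gaussian for β (Cholesky solve of
A = X*ᵀX* + blockdiag(V_g⁻¹)), inverse-Gaussian draws for the reciprocal
latents, InvGamma(r + (N+P̃)/2, s + rss/2 + βᵀV⁻¹β/2) for σ², and
Gamma for λ_g² with shape a_λ + m_g + q_g + (m_g+1)/2 and rate
b_λ + weighted latent-scale sums. For fixed (λ, σ²) the posterior mode of β
minimizes the objective above with effective tuning 2σλ_g — the acceptance
suite verifies this against a direct numerical minimizer.

Hyperpriors: r = 2500, s = 0 for σ². On whitened data this pins σ² near
rss/(2(r + (N+P̃)/2)) ≈ 0.005, large enough for coefficient draws to move
off zero and small enough not to destabilize the chain. λ_g² uses
a_λ = 1, b_λ = 1e-4 — deliberately small b_λ so that groups the data do not
support can be shrunk hard (their λ_g equilibrium is ≈ √(shape/b_λ),
around 10³ at the default problem sizes).

### Stability of the underdetermined chain

Because P̃ > N the joint chain has a second, degenerate attractor: the
coefficients interpolate the data exactly, the residual sum of squares
drops to zero, and σ² and every λ_g collapse together (the latent
inverse-Gaussian means scale with σ). Three design choices keep
well-initialized chains in the regular basin:

1. **Warm-start latents.** All latent scales start at their no-signal fixed
   point 1/scale = (λ_init·w)², i.e. the maximally regularized state — a
   lasso-path-style warm start. The data then pull coefficients out where
   the likelihood insists. (Starting from neutral scales lets the first few
   draws fit the noise before the tuning parameters can react.)
2. **σ² floor** (1e-4): a one-sided numerical guard on the collapse
   direction, mirroring the requirement that σ² stay near its working
   magnitude; r = 2500 only guards the upward direction.
3. **λ floor** (0.5): with two wavelengths, neighboring voxels' columns are
   near-collinear, so a group the chain treats as active exposes near-null
   directions in which an *unregularized* fit wanders to tens of µM. The
   floor keeps a baseline fused/sparse penalty alive inside active groups;
   noise-fitting excursions need large spatial differences and are
   suppressed, while spatially uniform activations have ‖D β‖₁ ≈ 0 and pay
   essentially nothing.

Chains started at small λ_init can still land on "phantom" modes — activity
reconstructed in the wrong region, or noise partially fit. That is the
start-point sensitivity the initial-λ selection protocol exists to resolve.

### Chain schedule

The reference schedule is 100,000 iterations, 10,000 burn-in, retention
every 9 iterations — exactly 10,000 retained draws. The desk-scale study
default is 4,000/1,000/3 for final chains and 800/200/3 for tuning sweeps;
retained counts stay well above the 100-draw floor the inference procedures
require. The point estimate is the per-coefficient posterior median.

## Initial-λ selection

λ_g is optimized inside the chain but the result depends on its common
initial value. Per dataset:

1. **Channel screening.** For each region, a sensitivity-weighted contrast
   (weights ∝ row sums of X over the region's columns, normalized to sum
   one) gives t = cᵀy/√(cᵀC_ν c) and a two-sided normal p-value.
2. **Sweep.** One reconstruction per candidate λ_init with shortened
   chains. The protocol-replication default grid is 50 values from 0.05 to
   2.5; the study default is (2.4, 10, 20, 50), which spans both that range's
   working value and the stable plateau of the package's synthetic slab
   (the whitened design scale differs from atlas-scale problems, so the
   plateau sits higher).
3. **Selection.** If no region screens significant (all p ≥ 0.05) the
   dataset is treated as noise-only, the ground truth is the zero image,
   and the candidate minimizing MSE against zero wins; *its sweep
   reconstruction is the final result* (re-running a chain would re-enter
   the start-point lottery the selection just resolved). Otherwise the most
   significant region is taken as putatively active; candidates are scored
   by ROC AUC (that region's voxels as positives, rating HbO and −HbR) and
   by MSE over the remaining regions against zero; among candidates within
   0.01 of the maximal AUC, minimal off-target MSE wins, ties to the
   smallest λ; the final reconstruction re-runs the full schedule there.

The plateau tolerance (0.01) and smallest-λ tie-break make a deterministic
rule out of what is otherwise a judgment call.

## Posterior inference

At moderate levels α = η = 0.5 (95% intervals are far too conservative for
these posteriors):

* **Credible interval:** equal-tailed (α/2, 1−α/2) interval from Weibull
  (type-6) quantiles — linear interpolation of order statistics at (n+1)q;
  significant iff 0 lies outside.
* **Scaled neighborhood:** a coefficient is insignificant iff the posterior
  probability of |β| ≤ one posterior SD exceeds η. (A literal ±variance
  neighborhood is dimensionally inconsistent; ±1 SD is the standard
  scaled-neighborhood criterion and is the adopted reading.)
* **Group comparison:** per draw, β_gᵀΣ_g⁻¹β_g on the group's expanded
  coefficients; a group dominates iff its interval's lower bound exceeds
  every other group's upper bound.

Batch-level inference pools retained draws across a batch's datasets before
applying these procedures, matching how multi-dataset significance is
reported; single noise datasets whose realization happens to mimic a signal
(an irreducible ~few-percent event at SNR 5) are diluted by the batch.

## Evaluation

Per chromophore: MSE = ‖β − β̂‖²/(P/2) and CNR = 10·log₁₀(‖β̂‖²/‖β − β̂‖²) dB
(a flag switches to the alternative halved-estimate reading of the
contrast; the primary definition is the plain one). ROI-ROC pools ratings
across a region's activity and noise datasets at three levels — voxel HbO
(rating β̂_HbO), voxel HbR (rating −β̂_HbR), and region (rating the
posterior median of β_gᵀΣ_g⁻¹β_g) — with positives the truly active
coefficients/regions of activity datasets. Ties share one threshold, so the
trapezoid AUC equals the Mann–Whitney pair statistic. FPR-at-TPR fixes the
threshold at the smallest rating reaching the target sensitivity in the
active region. Batch summaries report medians (a few wrong-mode
reconstructions would dominate means).

## Study defaults and problem sizes

The default `StudyConfig` runs 3 overlapping rectangular regions
(one-voxel shared margins) on the 13 × 2 slab, 6 activity + 6 noise
datasets per region (36 total), a 4-candidate λ sweep with 800-iteration
chains and 4,000-iteration final chains. These sizes are chosen so a full
study runs in minutes on one CPU core while preserving every structural
element of the full-scale design (overlap, adaptivity, screening,
selection, pooled ROC); replicate counts and chain lengths scale up by
config for sharper estimates.

## Known limitations

* The homogeneous semi-infinite forward model understates depth ambiguity
  relative to layered tissue; absolute amplitudes on real heads would need
  a transport-based Jacobian.
* The sampler's stabilization (floors, warm start) is tuned for
  underdetermined problems at these scales; heavily overdetermined inputs
  do not need it but are unaffected by it.
* Only one active region per dataset is modeled, and the selection protocol
  assumes it; simultaneous multi-region activations would confuse the
  screening step.
* No frequentist error control: significance is interval-based and its
  type-I behaviour is characterized empirically, not guaranteed.
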