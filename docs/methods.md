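# Methods

## Two-layer forward model

The correlation diffusion equation treats the unnormalized field
autocorrelation G1(r, τ) as a diffusing quantity with an extra, lag-dependent
loss term contributed by moving scatterers: for Brownian motion with
mean-square displacement ⟨Δr²(τ)⟩ = 6 Db τ the loss is
2 μs′ k0² α Db τ, where k0 = 2π n0/λ is the in-tissue wavenumber and α the
moving-scatterer fraction (1 throughout). For a finite slab (extracerebral,
thickness l) over a semi-infinite half-space (brain), the equation is solved
in the spatial-frequency domain; at the surface the kernel is a ratio of
hyperbolic functions of αj l and αj zb with

    αj²(s, τ) = s² + (μa,j + 2 μs,j′ k0² α Db,j τ) / Dj,   Dj = 1/(3 μs,j′).

All lengths are in mm, τ in s, Db in mm²/s; with D defined per unit speed the
exponents are dimensionless and no speed-of-light factor appears. The surface
field G1(ρ, τ) is the inverse Hankel transform (1/2π)∫ g̃1 s J0(sρ) ds, and
the Siegert relation g2 = 1 + β|g1|² (β = 0.5) gives the intensity
autocorrelation.

The kernel is evaluated in an exponentially rescaled form containing only
decaying exponentials, so sinh/cosh overflow cannot occur at any spatial
frequency. The boundary condition uses an extrapolated boundary at
zb = 2 D1 (1 + Reff)/(1 − Reff); Reff is computed from the refractive index
by the exact angular Fresnel integrals (n0 = 1.4 → Reff ≈ 0.493).

**Quadrature.** The integrand oscillates with J0(sρ) (period ≈ 0.09 mm⁻¹ at
ρ = 35 mm), so the transform is integrated with fixed-order Gauss–Legendre
panels split at the Bessel zeros. Defaults: order 8, s_max = 60 mm⁻¹,
verified by order-doubling with a 1e-8 relative tolerance (an
`IntegrationError` carries the achieved error if the check fails). The
kernel envelope decays as e^(−s·z0) with z0 ≈ 0.8–1.1 mm; s_max = 60
suppresses the truncated tail below 1e-7 of G1(0), which matters because at
ρ = 35 mm the result is exponentially small compared to the integrand scale.
That same cancellation sets a float64 accuracy floor: g1 values below
~1e-7·g1(0) cannot be resolved to better than a few times 1e-6 relative by
any direct quadrature. Oracle comparisons therefore evaluate relative error
where g1 > 1e-5; the measured agreement with the semi-infinite closed form
there is ~2e-6, against a 1e-5 requirement. In the Siegert picture a g1 of
1e-5 contributes 5e-11 to g2 — far below any noise considered here. The
two-layer inversion uses a cheaper setting (order 6, s_max = 30 mm⁻¹,
forward accuracy ~6e-6) inside the optimizer loop.

## Baseline estimators

**Single-exponential.** g2(τ) = a + b e^(−cτ) fitted by Levenberg–Marquardt
with a half-decay initial rate; the decorrelation speed 1/τc = c/2 is the
flow readout, and only its *relative* changes are interpreted. Min–max
scaling is an affine map per curve, so it leaves relative decorrelation-speed
changes invariant (verified to 1e-3).

**Two-layer inversion.** Minimizes Σ[g2_model(τ; Db1, Db2) − g2_data(τ)]²
with geometry, optics, ρ and β fixed (known-prior assumption). The optimizer
is scipy's trust-region-reflective least squares over log10 Db with bounds
[1e-9, 1e-3] mm²/s and default start (5e-7, 5e-6); the log parameterization
conditions the four-decade search range. Optional 1/σ(τ) weighting is
available but changes little here because the analytic σ(τ) is nearly flat.
On the forward model's own noiseless output both coefficients are recovered
to ~1e-10 relative (inverse crime). Under the analytic noise of a 3.3 kHz /
180 s acquisition the recovery is unbiased, but the two Db scatter along a
strongly anti-correlated ridge (log-recovery correlation ≈ −0.9): the
per-replicate brain-Db error is ~20% median. This is the intrinsic
conditioning of the two-parameter inversion on a 31-lag window, not an
optimizer artifact; the perturbation studies always use the mean over many
replicates, whose standard error is smaller by √n_reps.

## Noise model

Measured-style frames are processed as: min–max scale to [1, 1.5]
(x = (X − min)/(max − min)·0.5 + 1), fit a single exponential per frame,
and take the across-frame standard deviation of the residual at each lag.
Two properties of this procedure matter:

- **Fit absorption.** A 3-parameter fit absorbs part of the noise, so raw
  residual deviations are biased low. The estimator deconvolves the observed
  residual variances through the full hat matrix H of the linearized fit,
  solving diag((I−H)Σ(I−H)ᵀ) = v by fixed-point iteration. (The textbook
  1/(1−h_jj) factor assumes homoscedastic noise and misbehaves when σ(τ)
  varies threefold across lags.) The correction is on by default and
  exposed as a flag.
- **Pinning.** Scaling maps each frame's extreme lags to exactly 1 and 1.5,
  deleting the noise amplitude there and redistributing it into the scale
  factor. σ(τ) at pinned lags is therefore unidentifiable by construction —
  the instrument's own measured profile is deflated at the first and last
  lags for the same reason. `pinned_lag_fraction` diagnoses the affected
  lags from the data; closure statements apply to the unpinned set.

Closure: injecting a known σ0(τ) into a model-consistent baseline and
running the estimator over five 1000-frame sessions recovers σ0 within 5%
elementwise on unpinned lags (measured 2.6–4.8% worst-lag across seeds).
The three training noise levels are {0.7, 1.0, 1.3}× the session-mean
profile, exactly.

Since no measured baseline recordings are distributed, the package ships a
**synthetic** session generator: the scaled clean baseline curve plus
zero-mean Gaussian per-lag noise with a bump-shaped profile (peak 0.02
mid-grid, ~0.3× at the ends). The shape emulates the qualitative behaviour
of min–max-scaled linear-lag correlator noise; the magnitude matches the
analytic shot-noise model at a few kHz and minutes-scale integration. What
synthetic sessions do *not* emulate: pulsatile flow modulation within a
session, inter-lag noise correlation, afterpulsing/dark counts, and
probe-pressure or motion artefacts — so passing closure tests demonstrates
the estimator machinery, not instrument realism.

The analytic correlation noise for the two-layer fitting benchmark is the
Koppel-type variance of a linear-τ correlator (bin time T = 1.28 µs) at a
given photon rate and integration time, with the field decay rate Γ taken
from a single-exponential fit of the curve being corrupted. At 3.3 kHz and
180 s this gives σ ≈ 0.021–0.024, shot-noise dominated and consistent with
an independent Poisson-counting estimate.

## Training corpus and regressor

The grid spans brain μa {0.005…0.025, step 0.005} mm⁻¹, brain μs′
{0.9…1.3, step 0.1} mm⁻¹, extracerebral thickness {8…15, step 1} mm,
brain Db {5e-7…5e-5, 100 linear steps} mm²/s and extracerebral-to-brain Db
fraction {0.05…0.3, 20 linear steps}, with extracerebral optics fixed at
(0.019, 0.86), ρ = 35 mm, β = 0.5: 400,000 media, 1,200,000 noisy samples
(three levels). Labels are Db_brain × 10⁶. The reduced profile used by the
test suite and the acceptance script is 2×2×2×10×4 (320 media, 960
samples) — endpoints of each nuisance axis, ten Db values, four fractions.

The regressor is a stacked LSTM: 31-step univariate sequence (increasing τ)
→ two recurrent layers of 128 units → dense head on the final hidden state.
Gates carry a single bias per layer, giving exactly
4·(H(1+H)+H) + 4·(H·2H+H) + (H+1) = 198,273 trainable parameters at H=128.
Implementation is pure NumPy (float32): forward, backpropagation through
time (verified against float64 finite differences to 1e-4), Adam, inverted
dropout (0.3) between the recurrent layers, and L2 weight decay (1e-4)
added to the gradients. Two conditioning transforms are part of the
architecture: inputs in [1, 1.5] are affinely mapped to [−1, 1], and
training targets are standardized internally (predictions de-standardized
on output) — the label convention at the interface is unchanged. Training
is bit-deterministic given the seed.

The full protocol (lr 1e-4, batch 256, 1000 epochs) is sized for ~3.75
million updates on the 1.2M corpus. The scaled profile keeps the
architecture but uses lr 3e-3, batch 128, 100 epochs (~600 updates) — at
the full protocol's rate the optimizer cannot traverse parameter space in
so few steps. On the reduced corpus the held-out *absolute* CBFi error
floors at ~30% median; a gradient-boosted-tree ceiling check reaches the
same floor, showing it comes from the nuisance-parameter ambiguity of the
grid (one curve is consistent with a range of (μa, μs′, l, fraction, Db)
combinations), not from the learner. Relative-flow quantities, where the
geometry cancels, are much more accurate (below). Per-seed variability of
the trained model's sensitivity at this corpus size is roughly ±15
percentage points; the fixed seeds used by the test suite are recorded in
the tests themselves.

## Monte Carlo head model

Slab geometry (infinite plane-parallel layers): scalp 3 mm / skull 7 mm /
CSF 2 mm / brain, optics per the 785 nm baseline, Henyey–Greenstein g =
0.89, μs = μs′/(1−g) including the near-ballistic CSF. Transport is
scattering-only; absorption enters only at tally time as exp(−Σ μa,i L_i)
(microscopic Beer–Lambert), so each detected photon's per-layer pathlengths
L_i and momentum transfers Y_i = Σ(1−cosθ) fully determine its contribution
for *any* dynamics:

    G1(τ) = (1/Np) Σ_n exp(−2 k0² Σ_i Y_{n,i} Db_i τ) exp(−Σ_i μa,i L_{n,i}).

Changing Db never re-runs transport. The top surface applies unpolarized
Fresnel reflection (n 1.4 → 1.0); internal boundaries are index-matched;
specular loss at launch is ignored. Photons terminate on escape, on leaving
the 100 mm deep / 100 mm radial bounds, at 3000 mm total path, or when the
accumulated absorption exponent Σ μa,i L_i exceeds 12 — such a photon's
tally weight would be < e^(−12) ≈ 6e-6, orders of magnitude below the
weight of a typical detected photon (e^(−3)…e^(−6)), so the truncation bias
is far below Monte Carlo noise at any feasible photon count while cutting
runtime several-fold.

Detection is an annulus (default ρ ± 2.5 mm, all exit angles). A finite
annulus mixes separations, so analytic comparisons use the detection-
weighted reference Σ_b W_b g1(ρ_b, τ)/Σ_b W_b over radial bins, with W_b
the summed absorption weight per bin. Against this reference a homogeneous-
medium run (μa 0.02, μs′ 1.2, Db 6e-6, ρ 12.5 ± 2.5 mm, ≥1e5 detected
photons) agrees with the closed form to ≤ 0.004 absolute in g1 where
g1 > 0.1 (requirement: 0.02); comparing to the single center-ρ curve
instead would leave a ~0.02 annulus-mixing residual, which is why the
weighted reference matters. Problem sizes used by the tests and acceptance
script: 1.6e6 launched photons for the homogeneous oracle, 1.2e6 at
ρ = 35 mm (≈12k detected) for the head-model studies — chosen so the whole
pipeline runs on one CPU in minutes; the dedicated full-scale run (5e8
photons, narrow ±0.5 mm annulus) is a documented long-running profile.

## Evaluation

Sensitivity S = [(CBFi−CBFi₀)/CBFi₀]/[(Db−Db₀)/Db₀]×100% (for the
single-exponential estimator the decorrelation speed replaces CBFi);
relative-flow error ε = (rCBF − rDb)/rDb × 100%; stability error
E = (p − p_ref)/p_ref × 100%. Perturbation cells are brain and scalp Db at
{0.5, 0.75, 1.25, 1.5}× baseline, all sharing one transport ensemble. The
regressor and single-exponential estimators see min–max-scaled replicates
with the session-mean noise level; the two-layer inversion sees unscaled g2
with the analytic 3.3 kHz / 180 s noise (each estimator under its natural
noise model). Baselines are means over the baseline-cell replicates.
Bootstrap bands resample 1000 points 1000 times with replacement and report
the 25th/75th percentiles of the resampled means. Reported per-estimator
summaries average the four multiplier cells; the error summary averages
|ε| so that opposite-direction perturbations do not cancel.

At the reduced profile (50 replicates/cell, fixed seeds) the study gives
S_brain: two-layer 110%, regressor 88%, single-exponential 58%, and
S_scalp: −2%, 17%, 10% respectively — the same ordering and magnitudes the
method exhibits at full scale, with the two-layer inversion over-responding
slightly and both fast estimators partially blind to scalp flow. The
stability sweep (one-at-a-time brain μa, brain μs′, scalp and skull
thickness against the μa=0.015 / μs′=1.1 / 4 mm / 7 mm reference) re-runs
transport per cell; it is exercised at smoke scale in the tests and scales
to the full five-value grids when given more photons.

## Known limitations

- The reduced-corpus regressor is noisy seed-to-seed; conclusions at this
  scale rest on orderings and relative-flow errors, not absolute CBFi.
- Absolute CBFi from any estimator here inherits the two-layer model's
  grouping bias (scalp+skull as one layer over CSF+brain).
- The synthetic noise sessions omit pulsatility and inter-lag correlation.
- The Monte Carlo detector accepts all exit angles (no NA filter) and the
  wide annulus trades radial resolution for counting statistics.
- Slow flows whose decorrelation time exceeds the 39.68 µs window are
  fundamentally poorly constrained on this lag grid, for every estimator.
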