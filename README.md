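# dcs2l — two-layer diffuse correlation spectroscopy modelling and CBFi regression

Diffuse correlation spectroscopy (DCS) infers microvascular blood flow from
the temporal intensity autocorrelation g2(τ) of multiply scattered coherent
light. At large source–detector separations (ρ = 35 mm) the signal carries
cerebral information, but extracting the cerebral blood flow index (CBFi,
the brain's effective Brownian coefficient αDb in mm²/s) is confounded by
scalp and skull and, with multilayer analytical fitting, computationally
slow. `dcs2l` implements a complete in-silico version of a layer-aware
deep-learning approach to this problem, for researchers in diffuse optics
who want to study it without the instrument:

- **Forward models** — the two-layer correlation diffusion equation solved
  in the Hankel domain, g̃1(s, τ) with
  αj² = s² + (μa,j + 2 μs,j′ k0² α Db,j τ)/Dj, Dj = 1/(3 μs,j′), inverted by
  panel Gauss–Legendre quadrature split at the zeros of J0(sρ); the
  semi-infinite closed form
  g1(τ) ∝ e^(−K(τ)r1)/r1 − e^(−K(τ)rb)/rb, K²(τ) = 3μs′μa + 6μs′²k0²Dbτ,
  as an independent oracle; and the Siegert relation g2 = 1 + β|g1|².
- **Baseline estimators** — single-exponential fitting
  g2 = a + b·e^(−cτ) (decorrelation speed 1/τc = c/2) and full two-layer
  inversion of (Db_extra, Db_brain).
- **Noise pipeline** — min–max scaling of ACF frames to [1, 1.5], empirical
  σ(τ) estimation from baseline frame stacks (with an unbiasing leverage
  correction), ±30% level construction, and the Koppel-type analytic
  correlation-noise model for a linear-τ correlator.
- **Dataset generation** — the 5×5×8×100×20 two-layer parameter grid
  (400,000 media; 1,200,000 noisy samples at three noise levels) and a
  reduced 320-medium profile that runs in minutes.
- **Monte Carlo test bed** — a numba slab-geometry photon Monte Carlo with
  per-layer pathlength L and momentum-transfer Y tallies;
  G1(τ) = ⟨exp(−2k0² Σᵢ Yᵢ Db,ᵢ τ)·exp(−Σᵢ μa,ᵢ Lᵢ)⟩ separates transport
  from dynamics, so one ensemble serves every flow perturbation.
- **Sequence regressor** — a stacked LSTM (2 × 128 units, 198,273
  trainable parameters) mapping 31-lag scaled g2 curves to CBFi × 10⁶,
  implemented in NumPy (BPTT, Adam, dropout, weight decay) with fully
  deterministic seeded training.
- **Evaluation harness** — sensitivity S, relative-flow error ε and
  stability error E with bootstrap bands, orchestrated over brain/scalp
  Db perturbations (±25%, ±50%) on a four-layer (scalp/skull/CSF/brain)
  Monte Carlo head model.

## Worked example

```python
import numpy as np
from dcs2l import LayerOptics, TwoLayerMedium, g2_curve, lag_grid
from dcs2l.fitting import fit_two_layer

medium = TwoLayerMedium(
    layer1=LayerOptics(mua=0.019, musp=0.86, Db=1.05e-6, thickness=10.0),
    layer2=LayerOptics(mua=0.020, musp=1.21, Db=6e-6),
    rho=35.0, beta=0.5)

curve = g2_curve(medium, lag_grid(31, 1.28e-6))
print(np.round(curve.values[:4], 4))
res = fit_two_layer(curve, medium)
print(f"Db_extra = {res.Db_extra:.3e}  Db_brain = {res.Db_brain:.3e}")
```

prints

```
[1.415  1.3489 1.2963 1.2539]
Db_extra = 1.050e-06  Db_brain = 6.000e-06
```

— the clean intensity autocorrelation starts at 1 + β·g1(τ1)² ≈ 1.415 at the
first 1.28 µs lag and decays toward 1, and the two-layer inversion recovers
both generating Brownian coefficients from the model's own noiseless output
to ≈10 significant figures (an inverse-crime consistency check).

The full reduced-profile study — instrument-noise estimation, corpus
generation, regressor training, Monte Carlo head-model transport, and the
three-estimator perturbation study — runs from the CLI:

```bash
dcs2l make-dataset --out ds/ --seed 7
dcs2l train --data ds/ --seed 1 --out model.dcs2l
dcs2l simulate-mc --photons 1.2e6 --rho 35 --seed 3 --out ens.h5
dcs2l evaluate --model model.dcs2l --ensemble ens.h5 --reps 50 --out report.json
```

In a representative run the report's summary reads (percent):

```
S_brain_twolayer  110.4    S_brain_dl   87.6    S_brain_singleexp  57.5
S_scalp_twolayer   -2.4    S_scalp_dl   16.7    S_scalp_singleexp   9.7
```

i.e. the two-layer inversion slightly over-responds to true brain-flow
changes, the regressor recovers most of the response, single-exponential
fitting recovers about half, and all three are far less responsive to scalp
flow — the qualitative fingerprint of the method at full scale, reproduced
by the minutes-scale profile. Per-seed training variability at this reduced
corpus size moves the regressor's sensitivity by roughly ±15 points (see
`docs/methods.md`).

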