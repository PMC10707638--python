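# bonevisc

Viscoelastic constitutive modelling of human alveolar cancellous bone —
the porous, trabecular bone that supports tooth sockets — parameterized by
bone mineral density (BMD), from dynamic mechanical analysis (DMA)
frequency-sweep data.

During orthodontic treatment the alveolar bone remodels and its BMD
changes, which changes how the bone stores and dissipates mechanical
energy. `bonevisc` is for biomechanics researchers who want to quantify
that relationship: it identifies a generalized Maxwell (Prony-series)
material model per bone sample from measured storage and loss moduli, ties
the resulting moduli to BMD through power laws, and ships a fully synthetic
nine-sample mandibular study so the entire pipeline is testable without any
experimental data.

## The model

A generalized Maxwell solid with `n` spring–dashpot branches plus an
equilibrium spring has relaxation modulus

```
E(t) = E∞ + Σᵢ Eᵢ exp(−t/τᵢ),      τᵢ = ηᵢ/Eᵢ
```

and, in Prony form with weights `gᵢ = Eᵢ/E0` (instantaneous modulus `E0`),
storage and loss moduli

```
E′(ω) = E∞ + E0 Σᵢ gᵢ τᵢ²ω² / (1 + τᵢ²ω²)
E″(ω) =      E0 Σᵢ gᵢ τᵢ ω  / (1 + τᵢ²ω²)
```

For bone of mineral density ρ (g/cm³) the amplitudes scale as power laws,
giving the fourth-order (`n = 4`) BMD constitutive model

```
E′(ρ, ω) = A ρᵐ + A ρⁿ Σᵢ gᵢ τᵢ²ω² / (1 + τᵢ²ω²)
E″(ρ, ω) = B ρ^q  Σᵢ gᵢ τᵢ ω  / (1 + τᵢ²ω²)
```

Parameters are identified by minimizing the unweighted sum of squared
storage and loss residuals

```
D = Σₖ (E′_fit(ωₖ) − E′_exp(ωₖ))² + (E″_fit(ωₖ) − E″_exp(ωₖ))²
```

subject to `τᵢ > 0` and `0 < gᵢ < 1`, via multi-start local least squares
with the constraints enforced by log/logit reparameterization. Across
samples, the equilibrium modulus follows the power law
`E∞ = 1213.482 · ρ^2.039` (MPa), which the package can refit from any set
of (ρ, E∞) pairs.

## Worked example

Simulate the default synthetic study (nine cube samples, 3 tooth regions ×
3 root depths, four 20-minute sweeps each at 0.5/1/2/5 Hz, 2 % measurement
noise), fit every sample, and fit the BMD power law:

```sh
bonevisc report --seed 7 --out-dir out/
```

prints

```
warning: R1-apical: under-determined fit: 10 parameters from 8 observations; returned parameters are not unique
...
power law: E_inf = 1178.527 * rho^2.093 (r^2 = 0.787)
wrote out/report.json
```

The warnings are expected: a fourth-order model has more free parameters
than a four-frequency protocol has observations, so each per-sample
parameter set is one representative of a family of equally good fits (the
fitted curves and the equilibrium modulus trend are still well behaved).
The recovered power law (exponent ≈ 2.09) sits close to the generating
relation `1213.482 · ρ^2.039`; the residual gap comes from the per-sample
reference parameter rows not lying exactly on that power law plus the
simulated measurement noise. `out/` then contains:

- `report.json` — every per-sample fit (parameters, objective `D`, per-channel
  and joint R², convergence, seed) and the power-law fit;
- `params.csv` — the per-sample parameter table
  (`A, m, n, B, q, g1..g4, tau1..tau4`) with diagnostics;
- `powerlaw.json` — coefficient, exponent, r² of the `E∞`–BMD power law;
- `changes.csv` — percent change of tail-mean storage and loss modulus
  across the frequency ladder per sample (storage rises with frequency,
  loss falls, for every sample).

The same stages are available individually (`bonevisc simulate`,
`bonevisc fit --input study.csv`, `bonevisc powerlaw --input report.json`)
and as library calls (`bonevisc.run_pipeline`, `bonevisc.fit_prony`,
`bonevisc.fit_powerlaw`).

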