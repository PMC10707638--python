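# Methods

## Material model

The package models cancellous alveolar bone as a linear viscoelastic solid
— a generalized Maxwell assembly of `n` spring–dashpot branches in parallel
with an equilibrium spring. The relaxation modulus is the Prony series
`E(t) = E∞ + Σ Eᵢ e^{−t/τᵢ}`; harmonic loading at angular frequency ω gives
the Debye sums for storage `E′` and loss `E″` written in the README. The
loss kernel uses the standard Debye numerator `τᵢω` (not `τᵢ²ω`), which is
the only form consistent with the Prony substitution `gᵢ = Eᵢ/E0` applied
to both channels.

Assumptions worth keeping in mind:

- **Linearity and thermorheological simplicity are not tested.** All data
  are at one temperature (25 °C) and one force amplitude; the model has no
  temperature dependence and no time–temperature superposition.
- **ω is angular frequency.** The DMA drive frequency f (Hz) enters as
  ω = 2πf. A config switch (`StudyConfig.angular_frequency`,
  `dataset_from_sweeps(angular_frequency=...)`) allows the ω = f convention
  for sensitivity checks; simulator and fitter always share one convention,
  so fits of simulated data are convention-invariant.
- **Moduli are in MPa**, times in seconds, BMD in g/cm³. The 260–985 MPa
  equilibrium-modulus range implied by the reference parameter rows is a
  physically plausible range for cancellous bone.
- **E0 and E∞ are stored independently.** The textbook identity
  `E0 = E∞/(1 − Σgᵢ)` is available (`PronySeries.consistent`,
  `is_consistent`) but not enforced, because the published per-sample
  parameter rows this package reproduces have weight sums well above one
  and therefore cannot satisfy it. `from_prony` warns (rather than
  rejects) when converting an inconsistent spectrum, and refuses Σgᵢ ≥ 1,
  where the implied equilibrium spring would be non-positive.
- **Canonical spectrum form.** `PronySeries` sorts relaxation times
  ascending and merges times equal to within a relative 1e−9 by summing
  their weights, so fitted spectra are comparable across runs.
  `BMDConstitutiveParams` sorts but never merges: a published parameter row
  may legitimately assign the same relaxation time to two branches
  (one reference row repeats τ = 0.519 s), and merging would push the
  combined weight above 1.

## The BMD constitutive model and its identifiability boundary

The per-sample model `E′ = Aρᵐ + Aρⁿ·(storage sum)`, `E″ = Bρ^q·(loss sum)`
has 13 parameters. For a single sample, ρ is one fixed number, so only the
three *lumped amplitudes* `E_eq = Aρᵐ`, `C_s = Aρⁿ`, `C_l = Bρ^q` are
observable — no single-density experiment can split an amplitude into a
coefficient and an exponent. The fitter therefore works in lumped form and
offers:

- **`mode="reduced"`** (default): `E_eq`, per-branch storage amplitudes
  `aᵢ`, a loss/storage amplitude ratio, and the τᵢ — storage and loss
  amplitudes decoupled, matching the structure of the published per-sample
  rows. Weights are reported under the normalization convention
  `max gᵢ = 1/2` (the product `amplitude·gᵢ` is what the data determine;
  the convention fixes the remaining scale). A table-schema representative
  (`A = E_eq, m = 0, n = ln(C_s/E_eq)/ln ρ, B = C_l, q = 0`) is attached to
  each fit; it reproduces the fitted curves exactly at the sample's ρ and
  is explicitly non-unique.
- **`mode="prony"`**: physical-branch parameterization (E∞, Eᵢ, τᵢ) with a
  shared storage/loss amplitude. The result satisfies the Prony identity by
  construction and all 2n+1 parameters are identifiable from dense data —
  this is the mode used for parameter-recovery validation.
- **`fit_global`**: one shared (A, m, n, B, q, gᵢ, τᵢ) set fit jointly to
  all samples. With amplitudes observed at several densities the exponents
  become identifiable; this is the estimator for the *population* model.

**Counting matters.** The four-frequency DMA protocol yields 8 observations
per sample (E′, E″ at four frequencies, after tail-mean extraction), while
the reduced fourth-order model has 10 parameters. Such fits interpolate the
data (D at the numerical noise floor) but lie on a solution manifold along
which, in particular, the fitted equilibrium modulus varies by several
percent. The fitter flags this with an identifiability warning instead of
refusing, since sparse-frequency DMA is the field's standard protocol; but
quantitative per-parameter claims (including exact equilibrium-modulus
round trips through the pipeline) are only made, and only tested, on
over-determined grids (≥ 6 frequencies for order 4). This is a property of
the experimental design, not of the optimizer.

## Fitting procedure and numerical choices

- Objective: unweighted pooled squared residuals of both channels (the
  quantity `D`); no weighting scheme is offered by design.
- Constraints `τᵢ > 0`, `0 < gᵢ < 1` are enforced by transform (log for
  times and amplitudes; logit for weights in the global mode), so every
  local solve is smooth and unconstrained and every returned parameter set
  satisfies the constraints strictly.
- Local solver: `scipy.optimize.least_squares` (trust-region reflective),
  ftol = xtol = gtol = 1e−10, at most 2000 function evaluations per start.
  Log-parameters are clipped at ±250 inside the model only to keep trial
  steps finite; the clip cannot bind at any physical optimum.
- Multi-start: 32 starts by default. Start 0 is deterministic — τ's
  log-spaced over the data window widened by one decade each side, equal
  weights, equilibrium amplitude at the smallest measured storage modulus;
  subsequent starts jitter times log-normally, draw weight fractions
  uniform(0.05, 0.95), and scale amplitudes from the data extremes. The
  best final objective wins; ties keep the earliest start. All randomness
  flows from one integer seed through `numpy.random.default_rng`, making
  results bitwise reproducible; single-threaded scipy keeps them
  platform-stable.
- Relaxation times are returned sorted ascending. Degenerate inputs:
  negative times/frequencies raise; zero target variance makes R²
  undefined and raises; a constant-modulus power-law input returns
  exponent 0 with the common value as coefficient.
- The power-law fit (`E∞ = aρᵇ`) solves the log-log linear problem first
  and refines by nonlinear least squares on the original scale; R² is
  reported on the original scale, which is why log-log-exact data return
  r² = 1 to machine precision while noisy data score slightly differently
  than a pure log-space fit would.
- R² definitions: per channel `1 − SS_res/SS_tot` about that channel's
  mean; the joint value pools both channels' residual and total sums of
  squares. The satisfactory-fit threshold used in tests is joint
  R² ≥ 0.991, met on noise-free model-generated data and on the pipeline
  route at 1 % sweep noise (tail-averaging ~300 points suppresses point
  noise ~17-fold). On a dense grid with 1 % *point* noise the R² ceiling
  set by the noise-to-signal variance ratio is ≈ 0.986 even for the true
  parameters — R² thresholds are only meaningful relative to a noise
  model.

## Synthetic study generator

The generator emulates a nine-sample cadaveric mandible study: 3 tooth
regions (canine, premolar, molar sites) × 3 root depths (cervical, middle,
apical), each cell carrying a measured BMD (0.604–0.926 g/cm³) and a
trabecular count density, tested in compression DMA at 0.5/1/2/5 Hz for
20 min per frequency at 25 °C (0.5 mN preload, 5 N force amplitude, carried
as metadata).

Each sweep is steady state × transient × noise:

- **Steady state** from the BMD constitutive model at ω = 2πf. Ground
  truth per sample is the published reference parameter row for that BMD
  (verbatim), or the smooth power-law parameter set for non-reference
  densities.
- **Transient**: `E′(t) = E′_ss(1 − c·e^{−t/τ_r})`,
  `E″(t) = E″_ss(1 + c·e^{−t/τ_r})` with recovery time τ_r = 120 s and
  depth `c = 0.05 + 0.15·(ρ − ρ_min)/(ρ_max − ρ_min)` — denser samples
  show the more pronounced initial rise seen experimentally. The form is a
  modelling choice; no functional form is available from experiments. It
  leaves the tail mean (final 25 % of the sweep, the fitter's input)
  within ~5·10⁻⁴ of the steady state.
- **Noise**: i.i.d. multiplicative Gaussian, CV 2 % by default (no
  experimental error bars exist to calibrate against; 2 % is typical of
  modulus repeatability in DMA).

The smooth power-law parameter set (`powerlaw_constitutive_params`) puts
both storage amplitudes on the reported `1213.482·ρ^2.039` relation and
gives the loss amplitude a negative BMD exponent (B = 60 MPa, q = −2), so
storage increases and loss decreases with BMD at every frequency —
the study's central qualitative finding. Its relaxation times
(0.01, 0.04, 0.16, 0.64 s) are log-spaced inside the 0.5–5 Hz excitation
band so that every relaxation process of the synthetic material is
observable by the protocol; a process far slower than 1/ω_min would be
experimentally indistinguishable from equilibrium stiffness and would make
round-trip validation meaningless.

**What passing tests do and do not show.** The generator produces data
that are exactly in the model family, with known noise. Tests built on it
validate the estimation machinery (recovery, determinism, constraint
compliance, diagnostics), not the constitutive model's adequacy for real
bone: real DMA data carry structured drift, inter-sample biological
variability, nonlinearity at high force amplitude, and frequency-dependent
instrument error, none of which are emulated.

## Known limitations

- Per-sample coefficient/exponent pairs (A, m, …) are reported for schema
  compatibility only; they are non-unique representatives and should not
  be interpreted across samples — use `fit_global` for population-level
  exponents.
- The loss-modulus sign convention of the percent-change table assumes the
  steady-state loss modulus decreases over the full frequency ladder;
  between *adjacent* frequencies a branch whose 1/τ lies inside the band
  can locally raise the loss modulus, which is physical, not an error.
- No Bayesian or global-optimization alternatives, no residual weighting,
  no temperature dependence, no micro-CT image processing (BMD values are
  inputs), no finite-element material export.
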