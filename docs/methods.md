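# Methods

This note records the scientific and numerical choices behind
`serialbump`: what is simulated, which constants are used, how ambiguities
in the reference formulation were resolved, and what the package does and
does not claim.

## Model

The memory circuit is a firing-rate ring network of `N = 256` units, each
labelled by a preferred angle uniformly tiling [0°, 360°). Excitatory
signalling is carried by one slow NMDA-like gating variable `s_i` per
neuron:

    ds_i/dt = -s_i / tau_s + (1 - s_i) * gamma * f(I_i)

with `tau_s = 60 ms` and `gamma = 0.641`. Firing rates come from the
smoothed threshold-linear transfer curve

    f(I) = (a*I - b) / (1 - exp(-d*(a*I - b)))

with `a = 270 Hz/nA`, `b = 108 Hz`, `d = 0.154 s`. The singularity at
`a*I - b = 0` is removable; the implementation returns the limit `1/d`
there, uses `expm1` for numerical accuracy near it, and returns the limit
value 0 deep below threshold.

The total current `I_i = I_rec,i + I_stim,i + I_noise,i` has three parts:

- **Recurrent.** Coupling from neuron j to i follows a Gaussian profile of
  the circular distance between preferred angles on top of uniform
  inhibition, `g(d) = J- + J+ exp(-d^2 / (2 sigma^2))`, with `J- = -0.5 nA`
  and, in the fixed-synapse configuration, `J+ = 2.2 nA`, `sigma = 43.2°`.
  The profile is divided by `N` (a population-mean convention; see
  "Recurrent normalization" below) and applied as `I_rec = W s`.
- **Stimulus.** During a 1-s cue, a Gaussian current bump of peak
  `g_s = 0.02 nA` and width 43.2° centered on the stimulus angle. During
  the 300-ms response period, a uniform reset current: −0.08 nA (full
  reset), −0.00925 nA (weakened reset, the activity-leak variant), or 0
  (no reset).
- **Noise.** Independent Ornstein–Uhlenbeck background per neuron with
  mean `I0 = 0.3297 nA`, time constant `tau_n = 2 ms`, magnitude
  `sigma_n = 0.009 nA` (see "Noise convention").

The plastic-synapse variant adds presynaptic augmentation `F` and vesicle
depression `D`, one scalar per presynaptic neuron:

    dF/dt = alpha (x - F) f - F / tau_F
    dD/dt = -p f F D + (1 - D) / tau_D

with `alpha = 0.015`, `x = 0.008`, `tau_F = 4.2 s`, `p = 0.01`,
`tau_D = 1 s`, baseline release probability `y = 0.992`; the gating drive
becomes `gamma (y + F) D f`. The sensory-adaptation plasticity variant
uses `tau_F = 3.8 s`, `p = 0.006`, `x = 0.014`, `y = 0.986`.

## Task and analysis

Each simulation is a pair of back-to-back delayed-response trials:
500-ms settling, cue 1 (1 s), delay 1, response 1 (300-ms reset), ITI,
cue 2 (1 s), delay 2, response 2. The remembered angle is decoded by the
population vector of a 100-ms rate window ending at each requested decode
time (an offset into the second delay). Batteries run 32 second-stimulus
angles uniformly spanning the circle (the first stimulus fixed at 180°)
with many independent seeds per angle.

Serial dependence is quantified by fitting the signed circular error
against the relative angle `wrap(theta1 - theta2)` with a
derivative-of-Gaussian curve

    y(x) = x a w c exp(-(w x)^2),   c = sqrt(2) e^{1/2},

whose extrema are ±a at `x = ±1/(w sqrt 2)`; the signed peak-to-peak `2a`
is the reported magnitude (positive = attraction toward the previous
stimulus). The fit is a global least squares: the model is linear in `a`
at fixed `w`, so the amplitude is profiled out analytically and the
(multimodal) width objective is minimized on a 96-point log grid, then
polished locally. Confidence intervals come from a 10,000-rep percentile
bootstrap over resampled rows, with every resample refit by that same
global estimator (expressed as multinomial row weights, so the whole
bootstrap reduces to matrix products). Refitting resamples from the
point estimate alone would lock them into its width/sign basin and
undercover on null data; the estimator-consistent bootstrap attains
≈94/100 empirical coverage at nominal 95% in the null-coverage oracle
test.

The optional sensory-adaptation input stage shifts the second cue angle by
a DoG of the stimulus difference **in radians** (`a = −0.015 rad`,
`w = 0.6 rad⁻¹`), with the amplitude calibrated at a 1-s ITI and decaying
as `exp(-(iti - 1)/5.592 s)`.

## Resolved ambiguities and calibrations

**Recurrent normalization.** Summing nA-scale couplings over 256 neurons
without normalization produces currents two orders of magnitude above the
transfer function's operating range (no bump; runaway). Dividing the
profile by `N` — i.e. reading the recurrent drive as a population mean —
restores the intended scale. Under this convention the fixed-synapse
constants are strikingly self-consistent: the measured bump-ignition
threshold at `sigma = 43.2°` is `J+* = 2.185 nA`, so the configured 2.2 nA
sits 0.7% above it; a 1-s cue at 0.02 nA ignites a ~32-Hz bump that
persists beyond 10 s; the −0.08 nA reset abolishes it; the −0.00925 nA
reset leaves a residual. An alternative (normalizing the Gaussian to unit
ring mean) produces uniform runaway and was rejected. A 100-ms NMDA time
constant (sometimes quoted for such models) was also tested and rejected:
it produces unrealistically strong bumps (~60 Hz) and defeats the −0.08 nA
reset.

**Coupling of the broad- and narrow-tuning variants.** With the tuning
width changed to 50° or 30°, the bump-ignition threshold moves (measured:
1.997 nA and 2.799 nA respectively, with plasticity active). The package
sets each variant's `J+` to the same fractional margin above its own
threshold as the fixed-synapse network (factor 1.0069), i.e.
`J+ = 2.0105 nA` at 50° and `2.8180 nA` at 30°. This "balanced for
persistent firing" calibration is structural — it references only bump
persistence, not any serial-dependence outcome. Calibration protocol: 1-s
cue at 0.02 nA, noiseless, criterion bump amplitude > 5 Hz after a 10-s
delay, threshold found by bisection to 2×10⁻⁴ nA.

**Noise convention.** The white-noise normalization in the OU equation is
ambiguous as printed. The package adopts the convention of standard
reduced-model implementations — Euler–Maruyama increment
`sigma_n sqrt(dt / tau_n) z` — equivalent to the SDE
`dI = -(I - I0)/tau_n dt + sigma_n/sqrt(tau_n) dW`, whose stationary sd is
`sigma_n / sqrt 2 ≈ 6.4 pA`. The integrator uses the exact OU update
(decay factor `exp(-dt/tau_n)`), which matches this convention's
stationary distribution and autocorrelation while remaining correct for
steps comparable to `tau_n`. The implied stationary variance is asserted
in tests.

**DoG constant.** The normalizing constant is `c = sqrt(2) e^{1/2}`, the
choice that makes the fitted amplitude equal the curve's peak height so
that peak-to-peak = `2a`.

**Adaptation units.** With `w = 0.6` the adaptation DoG is absurdly narrow
if its argument is in degrees; in radians it peaks at ≈0.86° shift near a
67° stimulus difference, the magnitude scale expected of a weak repulsive
adaptation. Radians are the default (a degrees reading can be obtained by
scaling the parameters).

**Residual-leak reference time.** The weakened reset leaves a residual
bump that decays through the ITI (it passes a quarter of the mid-delay
amplitude shortly after the response period and continues to dissipate).
The leak statistic therefore samples the trial-averaged profile over the
first 200 ms of the ITI (`iti_at="early"`), where the residual-to-bump
ratio is ≈0.26; an ITI-midpoint window is available as an option. Bump
"amplitude" is the peak of the trial-averaged rate profile minus its
circular minimum, averaged over a 200-ms window.

## Numerical choices

- Explicit Euler at `dt = 0.5 ms` for gating and plasticity; exact update
  for the OU noise. Halving `dt` changes noiseless decoded angles by less
  than 0.5°.
- Batched integration: all simulations of a battery that share timing are
  advanced as a `(batch, N)` array, so the per-step cost is dominated by
  one BLAS matrix product.
- Each simulation owns an independent `numpy` Generator seeded from
  `SeedSequence([master_seed, angle_index, repetition])` (masked to 31
  bits), so results are bit-identical whether a simulation runs alone or
  inside any batch, at any chunk size.
- Runtime invariant checks (every 100 ms of simulated time) verify
  `s ∈ [0, 1]`, `F ∈ [0, x]`, `D ∈ [0, 1]` and raise with the variable and
  time on violation.

## Generator scope and problem sizes

The package's own reduced study scale is 32 angles × 20 seeds per
condition (12,800 trials for a five-decode-time battery); the full scale
of 100 seeds per angle is a flag away (`--scale full`,
`seeds_per_angle=100`). Reduced-size networks (e.g. 64 neurons) behave
qualitatively identically because the coupling normalization is a
population mean; they are used in the fast test suite. Synthetic
behavioral datasets drawn from a known DoG + Gaussian noise model validate
the fitter independently of the simulator.

## Limitations

- The deterministic residual after the weakened reset decays with a
  ~300-ms time constant, so the activity-leak bias it produces at a 1-s
  ITI is small (≈0.3° peak-to-peak at reduced scale, noise included)
  — an order of magnitude below the reference 2.53°. The basin boundary
  is razor-thin in the coupling: at `J+ = 2.20` the residual dies, by
  2.25 it re-grows into a full bump and the weakened reset no longer
  resets. A slowly decaying intermediate regime does not exist in this
  reconstruction; see the repository's acceptance results for the honest
  numbers.
- The broad- and narrow-tuning couplings are calibrated (see above), not
  taken verbatim; the verbatim values are subcritical under the
  reconstructed normalization and sustain no persistent activity at all.
  With that calibration the plastic-synapse model reproduces the full
  phenomenology (delay growth, asymptote by 10 s, ITI decay) but its
  asymptotic magnitude runs ≈16% high: at reduced scale the 10-s
  peak-to-peak is 2.58° with 95% CI [2.30, 2.86], just above the
  reference 2.23°.
- Rates are deterministic functions of current (no spiking); response
  selection is the population vector, with no motor noise.
- Only two-trial sequences are modelled; multi-trial history effects are
  out of scope.
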