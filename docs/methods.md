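# Methods

This note documents the models, numerical choices, defaults, and known
limitations of `mpspec`. It is the place to look when a default looks
arbitrary or a tolerance looks magic.

## Particle model

**Adiabatic response.** The ensemble-equilibrium magnetization is
`m_ad(t) = M_sat · L(β H(t))` with the Langevin function
`L(x) = coth x − 1/x`. For `|x| < 1e-4` the series `x/3 − x³/45` is used;
at the switch point the truncation error (~x⁵/945 ≈ 1e-23) is far below
double-precision roundoff of the direct expression, so the function is
smooth across the switch. `β` is defined against the applied field in mT
(i.e. against µ₀H): every field in the instrument's vocabulary — drive
amplitude, bias amplitude, loop axes — is quoted in mT, so keeping β in
1/mT avoids a unit conversion at every interface. For a particle of
diameter d at temperature T, β(1/mT) = µ·1e-3/(k_B T) with µ the core
moment; β ≈ 1/mT corresponds to a core moment of ~4e-18 Am², a realistic
multi-core MPI tracer scale.

**Relaxation kernels.** Debye: `r(t) = (1/τ)e^(−t/τ)u(t)`. Two-pole: the
normalized biexponential difference
`r₂(t) = (e^(−t/τ₁) − e^(−t/τ₂))/(τ₁ − τ₂)`, which integrates to one and
degenerates to the critically damped shape `t·e^(−t/τ)/τ²` as τ₂ → τ₁ and
to the Debye kernel as τ₂ → 0. Kernels are discretized by sampling on the
record's time grid and renormalizing so the discrete sum times dt is
exactly one: this preserves the static (DC) magnetization at any sampling
interval, which the continuous normalization does not after sampling. The
Debye kernel's t = 0 sample carries half weight (the one-sided trapezoid
treatment of its jump discontinuity); this makes the discrete frequency
response second-order accurate in ω·dt, which is what lets the convolution
match the analytic `1/(1+iωτ)` to better than 1e-4 at practical sampling
rates. A warning is issued when `dt > τ/5` (the kernel is then
under-resolved; results remain self-consistent but the discrete kernel is
no longer a faithful sampling of the continuous one).

**Steady state by circular convolution.** Drive and bias are exactly
periodic over the record by the timing contract, so the periodic steady
state is computed by folding the kernel (truncated where it has decayed to
1e-12 of its peak, i.e. at ~27.6 τ) into the record length and multiplying
spectra — no transient is simulated or discarded; this is exact for
periodic input, mirroring hardware practice of discarding the spin-up
data. Kernels whose support exceeds 10 fundamental periods are rejected by
default as unphysical for this regime; `max_support_periods=None` disables
the guard for deliberate probing of slow kernels (the analytic cross-check
at ωτ = 10 needs this, since its kernel rings for ~44 periods).

## Synthetic instrument

**Timing contract.** 2 MHz sampling; 42 µs drive period (84 samples,
23.8095 kHz); 84 ms bias period (11.905 Hz); exactly 2000 drive periods per
bias period. All waveform frequencies are commensurate with the sampling
grid, so every period is sampled identically and harmonic bins are
leakage-free. The config rejects non-commensurate settings rather than
rounding silently. Acquisition lengths are integer numbers of drive
periods; the spectroscopy preset uses 2000 periods (84 ms) per measurement
and the quasistatic presets 24 bias periods (2.016 s) — the commensurate
neighbours of the instrument's nominal 83 ms / 2000 ms.

**Receive model.** `V(f) = TF(f) · c_j · [M_sample(f) + M_feed(f)] + n(t)`.
The default parametric transfer function is a flat-gain differentiator
(5e-4 V·s/Am², i.e. |TF| ≈ 2.36 V/Am² at f₀ ≈ 23.8 kHz before the notch,
the scale of a ~50-turn receive coil with 0.5 mT/A sensitivity) times a
second-order 30 dB notch at the drive frequency, Q = 5. Feedthrough is an
equivalent moment at f₀ (default 7.5e-5 Am², the design-budget value,
scaled linearly with drive amplitude) plus a 3f₀ component at −108 dBc (the
hardware-grade drive purity). Noise is white Gaussian voltage noise at
3.3 nV/√Hz (the preamp's input noise). Drift multiplies the coherent
content of measurement j by `(1 + a·j)·e^(i p·j)` with defaults
a = 1e-5 and p = 1e-5 rad per measurement — the instrument's stated
stability target of 0.1% and 1 mrad per 100 measurements.

**Seeding.** One master seed per run; measurement j draws from
`default_rng([seed, j])`, so whole runs and individual measurements are
independently reproducible. Everything downstream is deterministic;
identical seeds give byte-identical HDF5 containers (datasets are written
with `track_times=False`).

**Auxiliary channels.** The drive monitor is the drive field divided by the
coil sensitivity (0.5 mT/A); the bias monitor likewise (9.36 mT/A); the
BMon field-monitor channel is `g·dB/dt` of the total applied field with
g = 9e-7 V/(mT/s), a two-turn pickup coil scale. These channels are
noiseless: their hardware counterparts have orders of magnitude more signal
than the receive channel, and modeling their noise would only obscure the
quantities under test. Hardware multiplexing artifacts ("ghosting" when
alternating Rx and monitor recording) are not modeled; the simulator
records all channels simultaneously.

## Preprocessing

TF correction divides the one-sided FFT by TF(f) and reconstructs by
inverse FFT with conjugate symmetry, returning a real moment series. Bins
where the response magnitude is below 1e-9 of its maximum (DC, for an
inductive chain) are zeroed: the magnetization mean is unobservable, which
is why every m(H) product carries a zero-mean boundary condition. If the
transfer function vanishes on a bin that carries signal the correction
raises instead of dividing. Corrected series are tagged (an ndarray
subclass) and a second correction attempt raises — dividing by TF twice is
a silent, plausible-looking corruption otherwise.

BMon integration uses cumulative trapezoidal integration, scaled by the
calibration constant and mean-removed over the record (the drive field has
no DC component over whole periods, pinning the integration constant). At
84 samples/period the trapezoid amplitude error is `(2π/84)²/12 ≈ 4.7e-4`
relative — the accuracy limit of loop field axes. An optional detrend
removes the linear ramp a DC-offset monitor channel would integrate to.

The harmonic mask keeps bins k·f₀ for k = 1..39 (the instrument's saved
range; 39 ≤ Nyquist harmonic 42 at the default timing) and zeroes all
others; it is an orthogonal projection.

## Spectroscopy (in/out lock-in)

Schedule: 11 out, 11 in, 11 out, 11 in, 11 out — 55 measurements. The run
must begin and end with sample-out blocks so the drift model has anchors on
both ends; this is the only consistent reading of "11 out, 11 in, repeated
2.5 times".

Per harmonic, the complex amplitude series is optionally smoothed with a
five-point centered rolling average applied within contiguous same-state
segments only (smoothing across an in/out boundary would bleed the signal
step into the baseline); the drift model is the line through the means of
the first and last five sample-out points, subtracted everywhere; the GLM
regresses the complex series on [1, j, in/out] jointly in real and
imaginary parts. The GLM is fit on the unsmoothed series by default:
least squares is already optimal under white noise, and pre-smoothing
correlates residuals without improving the estimate (the smoothed path
exists for parity with the simple in-minus-out estimator).

Noise and detection: `residual_sd` is the standard deviation of the complex
sample-out residuals and `snr = |amplitude|/residual_sd`. The detection
statistic `zscore` is the *in-phase (real) component* of the amplitude over
its standard error: with the drive phase locked to the acquisition, a real
particle's TF-corrected response at each harmonic is real-valued up to its
relaxation phase, while the quadrature carries only noise. Under the
no-sample null the zscore is standard normal, so a 3σ threshold yields the
expected ~0.27% false-positive rate (measured 0.28% over 19 500 null
trials); a threshold on the Rayleigh-distributed |amplitude| could not be
given a Gaussian σ interpretation.

Dilution sensitivity fits `signal = slope · mass` through the origin
(Faraday detection is linear in moment, hence in iron mass), averages the
per-run amplitude noise over all but the two most concentrated samples
(which on real hardware show sample-correlated noise), and reports the
SNR = 1 and SNR = 5 mass intersections.

## Relaxometry

Loops are built by folding all periods onto one (exact phase alignment by
the commensurate-sampling contract) and fit by minimizing the time-domain
SSE between the measured loop and
`s · [L(β H(t)) ∗ r(t)]`, with the scale s profiled out analytically
(the model is linear in it). The search runs Nelder–Mead over (log τ,
log β), preceded by a coarse log-spaced grid scan — the objective has a
broad spurious basin at very large β, where a saturated loop looks nearly
square for any β, and simplex starts inside that basin do not escape it.
Three starts spread geometrically (×1/3, ×1, ×3 in τ; ×1, ×0.5, ×2 in β)
around the scan optimum; best objective wins, ties broken toward the
smaller time-constant sum. Fitted time constants below dt/10 are floored
and flagged `tau_floor` rather than silently clamped: the data cannot
resolve them (this is how near-adiabatic loops and the collapsed second
pole of a two-pole fit on single-pole data are reported). Default initial
guesses: τ₀ = 1/(2πf₀) ≈ 6.7 µs, β₀ from the loop's saturation knee (field
where |m| reaches 80% of max, mapped through L(x) = 0.8 at x ≈ 5.0).

Measured performance under the study conditions (10 mT, 23.8 kHz, τ ∈
0.5–5 µs, β ∈ 0.5–2 /mT): noiseless recovery to ~1e-5 %, SNR-100 recovery
within 10% (worst case ~7% for β at the smallest τ).

## Quasistatic modes

**Spectrogram.** Hanning window of 4 drive periods (336 samples), 50%
overlap. The hop (2 drive periods) is a whole number of drive periods, so
every frame sees the drive at the same phase and complex frames can be
averaged directly. Amplitudes are normalized so a stationary unit cosine
reports 1. Each frame is paired with the *Hanning-weighted mean* bias field
over its window — the field its amplitude estimate actually averages — not
the centre-sample value.

**Folding and binning.** The first 10 bias periods are discarded
(electronics and particle settling; configurable), the remaining complete
bias periods are folded onto one cycle (1000 frames per bias period at the
default timing) and averaged, then the rising and falling half-cycles are
merged into 101 uniform bias-field bins over ±bias amplitude (a flag keeps
the branches separate to expose quasistatic hysteresis). At the default
bias amplitude the densest frame spacing in field is ~0.31 mT, so 1 mT bins
are never empty.

**Magnetometry.** χ(H) is the fundamental line divided by the drive
amplitude; its cumulative trapezoidal integral with zero-mean boundary
condition is the quasistatic m(H). The mode presumes linear probing
(`β·a ≲ 0.3`, warned otherwise): at larger drive the measured χ is the
finite-difference rather than the differential susceptibility, which
widens the curve (at β·a = 1 the integrated curve is ~2% off and β fits
~4% low). The notch filter is omitted from the magnetometry transfer
function — at 1 mT drive the fundamental *is* the signal, and the notch
only amplifies moment-referred noise there; this mirrors how the hardware
would be run with the notch disconnected. Closure measured at β = 0.25/mT,
1 mT drive, 24 bias periods: max |m − M_sat L(βH)| ≈ 0.4% of M_sat, β
recovered within ~1%.

**System matrix.** Identical processing with all harmonic lines kept
(default display range 1..39; the validation suite uses 1..12). Odd
harmonics are even functions of bias and even harmonics odd (vanishing at
zero bias) — the parity of the Langevin nonlinearity. The quasistatic
validity check compares the pipeline against a frozen-bias brute force:
the steady-state particle response evaluated with the bias held constant
at each frame's weighted bias value, folded and binned identically.
Agreement is ~1% up to the 12th harmonic at the default 2000:1
drive:bias frequency ratio; comparing against an oracle on abstract grid
points instead would conflate the quasistatic claim with the estimator's
finite field resolution (the in-window bias sweep of ~0.6 mT dominates
there for sharp high-harmonic lobes).

## Design-budget calculations

Pure algebra, SI units: feedthrough moment N·I·A·A_grad; required drive
purity m_Fe·M_sat·S₃/₁ / feedthrough (dBc via 20·log₁₀ — amplitude
convention, consistent with −60 dB ↔ 1e-3 for the gradiometer);
shielded-solenoid efficiency factor 1 − r_sol²/r_shield² (radii from the
24 mm mean winding and 37 mm shield inner diameters); transformer core
flux V_pk/(2πfNA_e); skin depth √(ρ/(πfµ₀)) with copper at 1.68e-8 Ωm
(20 °C); duty cycle (j_ref/j_target)²; turns ratio √(L ratio); noise
referral e_n/n, i_n·n.

## Study conditions and problem sizes

The validation suite runs scaled-down acquisitions chosen to keep each
check's statistical error well below its tolerance: spectroscopy
measurements of 50–100 drive periods (the null-rate check uses 500 runs ×
39 harmonics = 19 500 trials, giving ~0.04% standard error on a 0.27%
rate), quasistatic runs of 6 bias periods for unit tests and the full 24
for closure checks, and 20 noise seeds per relaxometry cell. Generator
defaults (drift rates, noise density, feedthrough, timing) are the
instrument's stated operating values and are never tuned per test.

## What the generator does and does not emulate

Emulated: exact timing commensurability, Langevin + kernel physics,
inductive transfer function with notch, feedthrough at f₀/3f₀, slow
complex drift, white receive noise, the in/out schedule, monitor channels.
Not emulated: amplifier/electronics nonlinearity, eddy-current phase shifts
between field and current monitors (reducible to a configurable phase
offset), 1/f noise within a measurement, 16-bit quantization, multiplexer
ghosting, sample positioning errors, field inhomogeneity, particle
polydispersity and field-dependent time constants. Passing tests therefore
demonstrate the correctness of the analysis chain under the stated noise
and drift model, not the instrument-hardware performance figures (absolute
sensitivity in grams of iron, measured noise floors, THD), which depend on
physical coils and amplifiers.

## Known limitations

* The two-pole kernel nests the Debye kernel only in the τ₂ → 0 limit; on
  a discrete grid the fit lands at the τ₂ floor with a small residual
  rather than matching a single-pole fit exactly.
* Loop field axes recovered from the BMon channel carry the ~4.7e-4
  trapezoid error at 84 samples/period.
* `estimate_langevin` fits a single-β Langevin; real multi-core tracers
  need a moment distribution, which is out of scope.
* The magnetometry χ estimate is first-order in drive amplitude; no
  deconvolution of the finite-amplitude kernel is attempted.
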