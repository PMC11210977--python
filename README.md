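# mpspec

Simulation and analysis toolkit for **magnetic particle spectroscopy (MPS)**,
relaxometry, hysteresis loop tracing, quasistatic magnetometry, and 1-D
MPI system-matrix measurement — a software twin of a benchtop magnetic
nanoparticle characterization instrument.

## The problem

Superparamagnetic iron oxide nanoparticles (SPIONs) are the tracers behind
magnetic particle imaging (MPI), magnetic hyperthermia, immunoassays and
remote thermometry. Developing and validating them requires measuring how
their magnetization m responds to oscillating fields at MPI-relevant
amplitudes and frequencies (~10 mT peak, ~25 kHz) — something neither VSM
nor SQUID magnetometry is tailored to. A magnetic particle spectrometer
drives the sample with a pure sinusoidal field, senses dm/dt inductively
through a gradiometric receive coil, and extracts the harmonic spectrum,
the dynamic hysteresis loop, the relaxation time constant, the quasistatic
m(H) curve, or the harmonic-vs-bias-field "system matrix" used in MPI
image reconstruction.

`mpspec` implements the computational core of such an instrument for people
who build, modify, or analyze data from one: the nanoparticle physics, a
synthetic signal generator with the instrument's exact timing contract, the
five analysis modes, and the closed-form hardware design budget.

## The model

The equilibrium (adiabatic) magnetization of a SPION ensemble follows the
Langevin function,

    m_ad(t) = M_sat · L(β·H(t)),      L(x) = coth(x) − 1/x,

with `M_sat` the saturation moment (Am²) and `β` (1/mT) the steepness of
the magnetization curve. Finite relaxation is modeled by convolution with a
causal kernel r(t),

    m(t) = (m_ad ∗ r)(t),

either the Debye kernel r(t) = (1/τ_eff)·e^(−t/τ_eff)·u(t) or a normalized
two-pole biexponential. In the frequency domain the Debye kernel is the
familiar first-order low-pass 1/(1 + iωτ), which is the independent oracle
the implementation is tested against.

The receive chain maps moment to voltage through a complex transfer
function TF_Rx(f) (V per Am²) — essentially a differentiator shaped by a
notch filter at the drive frequency — and analysis inverts it spectrally so
every pipeline works on the magnetization itself, not its derivative.
Detection of tiny samples uses in/out lock-in logic: the sample is shuttled
in and out of the coil on a fixed schedule and a per-harmonic general
linear model (constant + linear drift + in/out boxcar) separates particle
signal from baseline drift.

## Worked example: relaxometry on a simulated loop

```python
import numpy as np
from mpspec import ParticleModel, FieldWaveform, magnetization_response, RelaxationModel
from mpspec.relaxometry import build_loop

# 500 drive periods at 10 mT / 23.8 kHz, sampled at 2 MHz (84 samples/period)
dt, spp = 5e-7, 84
t = np.arange(spp * 500) * dt
h = 10.0 * np.cos(2 * np.pi * t / (spp * dt))
fw = FieldWaveform(h, dt, spp)

# ground truth: Msat = 1e-6 Am^2, beta = 1 /mT, Debye tau = 2.5 us
particle = ParticleModel(saturation_moment=1e-6, beta=1.0,
                         kernel="debye", tau_eff=2.5e-6)
m = magnetization_response(fw, particle, max_support_periods=None)

rng = np.random.default_rng(0)
noisy = m + rng.normal(0, np.sqrt((m**2).mean()) / 100, m.size)   # SNR 100

loop = build_loop(noisy, h, spp, dt)        # fold 500 periods onto one
result = RelaxationModel.from_loop(loop, kernel="debye").fit()
print(result.summary())
```

prints

```
Relaxation fit (debye kernel)
======================================
converged             True
iterations            170
SSE                   8.3824e-18
beta_per_mT           0.998975
msat_Am2              1.00009e-06
tau_eff_s             2.49985e-06
```

i.e. the time constant, Langevin steepness and saturation moment are
recovered to about 0.1% from a loop with 1% noise: folding the 500 periods
averages the noise down by √500, and the Nelder–Mead fit (seeded by a
coarse grid scan over τ and β) lands on the generating parameters. The
loop's enclosed area, `loop.enclosed_area()` ≈ 1.1e-5 mT·Am², is the energy
dissipated per cycle — zero for an adiabatic particle, positive and growing
with ωτ for a relaxing one.

## Command line

A thin CLI wraps the pipelines:

```sh
mpspec design                              # closed-form hardware budget (JSON)
mpspec simulate --mode in_out --seed 1 --output run.h5
mpspec spectroscopy --input run.h5         # per-harmonic amplitude / noise / SNR
mpspec loop --input run.h5 --output loop.csv
mpspec relaxometry --input run.h5 --model two_pole
mpspec simulate --mode magnetometry --seed 1 --output mag.h5
mpspec magnetometry --input mag.h5 --output mh.csv
mpspec sysmatrix --input mag.h5 --output sm.h5
```

Run containers are self-describing HDF5 files (schema documented in
`src/mpspec/io.py`): acquisition config, transfer function, every channel
of every measurement with its sample-in/out label, the seed, and any
analysis products. Identical seeds give byte-identical files.

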