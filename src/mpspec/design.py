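"""Closed-form design-budget calculations for an MPS/MPI drive–receive chain.

These are the back-of-envelope quantities a designer computes before winding
a single coil: how much drive field leaks through the gradiometric receive
coil ("feedthrough"), how spectrally pure the drive must therefore be, how
much a conductive shield costs in drive efficiency, transformer core flux,
skin depth, thermal duty cycle, and noise referral through a matching
transformer.  Everything here is algebraic and dimensionally explicit; SI
units throughout unless a function says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MU_0 = 4e-7 * math.pi
"""Vacuum permeability, H/m."""

COPPER_RESISTIVITY = 1.68e-8
"""Resistivity of copper at 20 degC, ohm m."""


class DesignError(ValueError):
    """Raised when a design calculation receives out-of-domain inputs."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise DesignError(message)


@dataclass(frozen=True)
class DriveCoilSpec:
    """Drive-coil electrical/geometric budget.

    Parameters
    ----------
    amp_turns : float
        N*I product of the drive coil, ampere-turns.
    cross_section_area : float
        Effective coupling cross-section of one receive-coil half, m^2.
    gradiometer_attenuation : float
        Residual linear coupling of the gradiometric receive coil to the
        drive field (1e-3 corresponds to -60 dB of cancellation).
    mean_winding_radius : float
        Mean radius of the drive winding, m.
    shield_inner_radius : float
        Inner radius of the surrounding conductive shielding tube, m.
    """

    amp_turns: float
    cross_section_area: float
    gradiometer_attenuation: float
    mean_winding_radius: float = 0.012
    shield_inner_radius: float = 0.0185

    def __post_init__(self) -> None:
        _require(self.amp_turns > 0, "amp_turns must be positive")
        _require(self.cross_section_area > 0, "cross_section_area must be positive")
        _require(
            0 < self.gradiometer_attenuation <= 1,
            "gradiometer_attenuation must lie in (0, 1]",
        )
        _require(self.mean_winding_radius > 0, "mean_winding_radius must be positive")
        _require(
            self.mean_winding_radius < self.shield_inner_radius,
            "winding radius must be smaller than the shield inner radius",
        )


@dataclass(frozen=True)
class SampleSpec:
    """Nanoparticle sample described by its iron content.

    iron_mass in kg, saturation magnetization per unit mass in Am^2/kg,
    and the particle's intrinsic third-to-first harmonic ratio S_3/1.
    """

    iron_mass: float
    saturation_magnetization_per_mass: float = 110.0
    third_to_first_ratio: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        _require(self.iron_mass >= 0, "iron_mass must be non-negative")
        _require(
            0 <= self.third_to_first_ratio <= 1,
            "third_to_first_ratio must lie in [0, 1]",
        )


@dataclass(frozen=True)
class TransformerSpec:
    """Cantilever-model transformer: leakage + magnetizing inductance.

    inductance_ratio is side A : side B; the turns ratio must be its square
    root to within 1%.
    """

    leakage_inductance: float
    magnetizing_inductance: float
    inductance_ratio: float
    turns_ratio: float

    def __post_init__(self) -> None:
        _require(self.leakage_inductance > 0, "leakage_inductance must be positive")
        _require(
            self.magnetizing_inductance > 0, "magnetizing_inductance must be positive"
        )
        _require(self.inductance_ratio > 0, "inductance_ratio must be positive")
        _require(self.turns_ratio > 0, "turns_ratio must be positive")
        expected = math.sqrt(self.inductance_ratio)
        _require(
            abs(self.turns_ratio - expected) <= 0.01 * expected,
            "turns_ratio must equal sqrt(inductance_ratio) within 1%",
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Amplifier input noise: voltage density V/sqrt(Hz), current density A/sqrt(Hz)."""

    voltage_noise_density: float
    current_noise_density: float

    def __post_init__(self) -> None:
        _require(self.voltage_noise_density >= 0, "voltage noise must be >= 0")
        _require(self.current_noise_density >= 0, "current noise must be >= 0")


def feedthrough_moment(coil: DriveCoilSpec) -> float:
    """Equivalent magnetic moment of the drive field leaking through the gradiometer.

    M_d = (N*I) * A * A_grad, in Am^2.  This is the fictitious sample moment
    that would induce the same receive voltage as the residual drive coupling,
    and sets the scale every purity requirement is measured against.
    """
    return coil.amp_turns * coil.cross_section_area * coil.gradiometer_attenuation


def purity_requirement(coil: DriveCoilSpec, sample: SampleSpec) -> float:
    """Required third-harmonic purity of the drive waveform, as a linear ratio.

    The drive's 3f0 content, seen through the gradiometer, should stay at or
    below the third-harmonic moment of the smallest sample of interest:

        D_3/1 = m_Fe * M_sat * S_3/1 / (N*I * A * A_grad)

    Use :func:`to_dbc` to express the result in dB relative to carrier.
    """
    denom = feedthrough_moment(coil)
    _require(denom > 0, "feedthrough moment must be positive")
    return (
        sample.iron_mass
        * sample.saturation_magnetization_per_mass
        * sample.third_to_first_ratio
        / denom
    )


def to_dbc(ratio: float) -> float:
    """Convert an amplitude ratio to dB relative to carrier (20 log10)."""
    _require(ratio > 0, "ratio must be positive for dB conversion")
    return 20.0 * math.log10(ratio)


def shield_attenuation_factor(coil: DriveCoilSpec) -> float:
    """Central-field retention factor of a solenoid inside a long conductive tube.

    For a shield many skin depths thick the field at the solenoid center is
    reduced by the image currents in the tube:

        B_center / B_unshielded = 1 - r_solenoid^2 / r_shield^2

    Returns the retention factor in [0, 1); the percentage *reduction* is
    ``100 * (1 - factor)``.
    """
    r_sol = coil.mean_winding_radius
    r_shield = coil.shield_inner_radius
    _require(r_sol < r_shield, "solenoid radius must be inside the shield")
    return 1.0 - (r_sol / r_shield) ** 2


def core_flux_peak(v_peak: float, freq: float, turns: float, core_area: float) -> float:
    """Peak flux density in a transformer core, tesla.

    B_pk = V_pk / (2 pi f N A_e) for a sinusoidal primary voltage V_pk at
    frequency ``freq`` across ``turns`` turns on a core of effective area
    ``core_area`` (m^2).  Keeping B_pk far below saturation keeps the core
    from contributing harmonics of its own.
    """
    _require(v_peak >= 0, "v_peak must be non-negative")
    _require(freq > 0 and turns > 0 and core_area > 0, "freq, turns, area must be positive")
    return v_peak / (2.0 * math.pi * freq * turns * core_area)


def turns_for_flux(v_peak: float, freq: float, b_peak: float, core_area: float) -> float:
    """Primary turns needed to hold the core flux at ``b_peak`` tesla (inverse of core_flux_peak)."""
    _require(v_peak > 0, "v_peak must be positive")
    _require(freq > 0 and b_peak > 0 and core_area > 0, "freq, b_peak, area must be positive")
    return v_peak / (2.0 * math.pi * freq * b_peak * core_area)


def skin_depth(resistivity: float = COPPER_RESISTIVITY, freq: float = 23.8e3) -> float:
    """Skin depth delta = sqrt(rho / (pi f mu0)), meters.

    Default resistivity is copper at 20 degC; at 23.8 kHz this is ~0.42 mm,
    which sets the maximum useful strand diameter for litz wire.
    """
    _require(resistivity > 0 and freq > 0, "resistivity and freq must be positive")
    return math.sqrt(resistivity / (math.pi * freq * MU_0))


def duty_cycle_for_equal_power(j_target: float, j_reference: float) -> float:
    """Duty cycle at current density ``j_target`` dissipating like DC at ``j_reference``.

    Ohmic power scales with the square of current density, so running at a
    higher density for a fraction (j_ref/j_target)^2 of the time dissipates
    the same average power.  Both densities in the same units (e.g. A/mm^2).
    """
    _require(j_target > 0 and j_reference > 0, "current densities must be positive")
    return (j_reference / j_target) ** 2


def turns_ratio_from_inductance_ratio(l_ratio: float) -> float:
    """Turns ratio implied by an inductance ratio: n = sqrt(L_b / L_a)."""
    _require(l_ratio > 0, "inductance ratio must be positive")
    return math.sqrt(l_ratio)


def refer_noise_through_transformer(noise: NoiseSpec, turns_ratio: float) -> NoiseSpec:
    """Refer amplifier input noise through a step-up transformer to its primary.

    Looking back through a 1:n transformer from the coil (primary) side,
    voltage noise divides by n and current noise multiplies by n; the optimal
    source impedance therefore drops by n^2.
    """
    _require(turns_ratio > 0, "turns_ratio must be positive")
    return NoiseSpec(
        voltage_noise_density=noise.voltage_noise_density / turns_ratio,
        current_noise_density=noise.current_noise_density * turns_ratio,
    )


def optimal_source_impedance(noise: NoiseSpec) -> float:
    """Noise-matched source impedance e_n / i_n, ohms."""
    _require(noise.current_noise_density > 0, "current noise must be positive")
    return noise.voltage_noise_density / noise.current_noise_density


def reactance(inductance: float, freq: float) -> float:
    """Inductive reactance X_L = 2 pi f L, ohms."""
    _require(inductance >= 0 and freq >= 0, "inductance and freq must be non-negative")
    return 2.0 * math.pi * freq * inductance


def design_report(
    coil: DriveCoilSpec,
    sample: SampleSpec,
    *,
    drive_freq: float = 23.8e3,
    preamp_noise: NoiseSpec | None = None,
    rx_inductance_ratio: float = 18.9,
    core_v_peak: float = 20.0,
    core_freq: float = 23.8e3,
    core_turns: float = 44.0,
    core_area: float = 306e-6,
    j_target: float = 15.0,
    j_reference: float = 5.0,
) -> dict[str, float]:
    """Assemble the full design budget as a flat name -> value mapping.

    The defaults mirror a benchtop 10 mT / 23.8 kHz spectrometer front end;
    every entry is computed by the corresponding function in this module.
    """
    if preamp_noise is None:
        preamp_noise = NoiseSpec(3.3e-9, 1.5e-12)
    n = turns_ratio_from_inductance_ratio(rx_inductance_ratio)
    referred = refer_noise_through_transformer(preamp_noise, n)
    ratio = purity_requirement(coil, sample)
    return {
        "feedthrough_moment_am2": feedthrough_moment(coil),
        "purity_requirement_ratio": ratio,
        "purity_requirement_dbc": to_dbc(ratio),
        "shield_retention_factor": shield_attenuation_factor(coil),
        "shield_reduction_percent": 100.0 * (1.0 - shield_attenuation_factor(coil)),
        "skin_depth_m": skin_depth(freq=drive_freq),
        "duty_cycle_fraction": duty_cycle_for_equal_power(j_target, j_reference),
        "core_flux_peak_t": core_flux_peak(core_v_peak, core_freq, core_turns, core_area),
        "rx_turns_ratio": n,
        "referred_voltage_noise_v_rthz": referred.voltage_noise_density,
        "referred_current_noise_a_rthz": referred.current_noise_density,
    }
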