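"""Astrocyte membrane mechanisms, osmolarity, and stimulus/decay sources.

Transmembrane ionic flux densities (positive = out of the ICS into the ECS)
combine passive conductive fluxes, an inward-rectifying K+ channel, and a
Na+/K+ pump with 3:2 stoichiometry:

    j_m^Na = g_Na / (F z_Na) * (phi_m - E_Na) + 3 j_pump
    j_m^K  = g_K f_Kir / (F z_K) * (phi_m - E_K) - 2 j_pump
    j_m^Cl = g_Cl / (F z_Cl) * (phi_m - E_Cl)

Transmembrane water flux (positive = water leaving the ICS):

    w_m = eta_m (p_i - p_e + i R T (O_e - O_i)),   O_r = a_r/alpha_r + sum_k [k]_r

Neuronal activity is mimicked by a K+ input flux into the ECS with an equal
and opposite Na+ flux (so the stimulus is charge- and osmolarity-neutral),
restricted to the input zone and the 10-210 s window, plus a domain-wide
decay flux proportional to the [K+]_e excess over baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .parameters import Domain1D, ModelParameters

__all__ = [
    "KIR_DELTA_V", "KIR_V_HALF", "KIR_SLOPE1", "KIR_SHIFT", "KIR_SLOPE2",
    "FrozenMembrane", "MembraneFluxes", "StimulusProtocol",
    "nernst_potential", "kir_factor", "pump_flux", "membrane_ion_fluxes",
    "osmolarity", "solute_potential", "water_flux", "decay_flux",
]

# Kir rectification constants (V); fixed sigmoid shape of the channel.
KIR_DELTA_V = 18.4 / 42.4    # dimensionless exponent of the constant factor A
KIR_V_HALF = 0.1186          # V
KIR_SLOPE1 = 0.0441          # V
KIR_SHIFT = 0.0185           # V
KIR_SLOPE2 = 0.0425          # V


def nernst_potential(z_k: float, c_e, c_i, params: ModelParameters):
    """Reversal potential E_k = RT/(F z_k) ln([k]_e/[k]_i) in volts."""
    c_e = np.asarray(c_e, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    if np.any(c_e <= 0) or np.any(c_i <= 0):
        raise ValueError("Nernst potential requires positive concentrations")
    return params.psi / z_k * np.log(c_e / c_i)


def kir_factor(k_e, k_e_init: float, phi_m, E_K, E_K_init: float):
    """Inward-rectification factor of the astrocytic Kir channel.

    f_Kir = sqrt([K+]_e / [K+]_e,init) * (A * B) / (C * D) with

        A = 1 + exp(18.4/42.4)
        B = 1 + exp(-(0.1186 + E_K,init)/0.0441)
        C = 1 + exp((phi_m - E_K + 0.0185)/0.0425)
        D = 1 + exp(-(0.1186 + phi_m)/0.0441)

    The square-root dependence on the extracellular K+ ratio and the sigmoid
    voltage dependence follow the classic astrocyte Kir parameterization; the
    factor grows with [K+]_e and shrinks with depolarization above E_K, which
    is what makes the channel take up K+ where it is in excess and release it
    distally (spatial buffering).  Strictly positive for positive [K+]_e.
    """
    k_e = np.asarray(k_e, dtype=float)
    if np.any(k_e <= 0):
        raise ValueError("kir_factor requires positive [K+]_e")
    A = 1.0 + np.exp(KIR_DELTA_V)
    B = 1.0 + np.exp(-(KIR_V_HALF + E_K_init) / KIR_SLOPE1)
    C = 1.0 + np.exp((np.asarray(phi_m) - np.asarray(E_K) + KIR_SHIFT) / KIR_SLOPE2)
    D = 1.0 + np.exp(-(KIR_V_HALF + np.asarray(phi_m)) / KIR_SLOPE1)
    return np.sqrt(k_e / k_e_init) * (A * B) / (C * D)


def pump_flux(na_i, k_e, params: ModelParameters):
    """Na+/K+ pump flux density (mol/(m^2 s)).

    Saturating Hill-type product, bounded by the maximum rate rho_pump:
    j_pump = rho * [Na]_i^1.5/([Na]_i^1.5 + P_Nai^1.5) * [K]_e/([K]_e + P_Ke).
    """
    na_i = np.asarray(na_i, dtype=float)
    k_e = np.asarray(k_e, dtype=float)
    na15 = np.clip(na_i, 0.0, None) ** 1.5
    ke = np.clip(k_e, 0.0, None)
    return (params.rho_pump
            * na15 / (na15 + params.P_Nai ** 1.5)
            * ke / (ke + params.P_Ke))


@dataclass(frozen=True)
class FrozenMembrane:
    """Quantities frozen at simulator start from the initial state.

    ``k_e_init`` and ``E_K_init`` parameterize the Kir rectification and the
    decay flux; ``alpha_i_init`` enters the membrane force balance.
    """

    k_e_init: float
    E_K_init: float
    alpha_i_init: float = 0.4

    @classmethod
    def from_concentrations(cls, params: ModelParameters, c: dict[str, float]) -> "FrozenMembrane":
        E_K = float(nernst_potential(params.z_K, c["k_e"], c["k_i"], params))
        return cls(k_e_init=c["k_e"], E_K_init=E_K, alpha_i_init=c.get("alpha_i", 0.4))


@dataclass
class MembraneFluxes:
    """Per-species membrane flux densities and the pump rate (mol/(m^2 s))."""

    j_Na: np.ndarray
    j_K: np.ndarray
    j_Cl: np.ndarray
    j_pump: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack([np.atleast_1d(self.j_Na), np.atleast_1d(self.j_K),
                         np.atleast_1d(self.j_Cl)])


def membrane_ion_fluxes(params: ModelParameters, frozen: FrozenMembrane, *,
                        na_i, na_e, k_i, k_e, cl_i, cl_e, phi_m) -> MembraneFluxes:
    """Evaluate all transmembrane ionic flux densities at a point or field."""
    E_Na = nernst_potential(params.z_Na, na_e, na_i, params)
    E_K = nernst_potential(params.z_K, k_e, k_i, params)
    E_Cl = nernst_potential(params.z_Cl, cl_e, cl_i, params)
    f = kir_factor(k_e, frozen.k_e_init, phi_m, E_K, frozen.E_K_init)
    jp = pump_flux(na_i, k_e, params)
    j_Na = params.g_Na / (params.F * params.z_Na) * (phi_m - E_Na) + 3.0 * jp
    j_K = params.g_K * f / (params.F * params.z_K) * (phi_m - E_K) - 2.0 * jp
    j_Cl = params.g_Cl / (params.F * params.z_Cl) * (phi_m - E_Cl)
    return MembraneFluxes(j_Na=j_Na, j_K=j_K, j_Cl=j_Cl, j_pump=jp)


def osmolarity(a_r: float, alpha_r, *concentrations):
    """Compartment osmolarity O_r = a_r/alpha_r + sum_k [k]_r (mol/m^3)."""
    alpha_r = np.asarray(alpha_r, dtype=float)
    if np.any(alpha_r <= 0):
        raise ZeroDivisionError("osmolarity undefined for vanishing volume fraction")
    total = a_r / alpha_r
    for c in concentrations:
        total = total + np.asarray(c, dtype=float)
    return total


def solute_potential(O_r, params: ModelParameters):
    """Solute potential Pi_r = -i R T O_r (Pa)."""
    return -params.vant_hoff * params.R * params.T * np.asarray(O_r, dtype=float)


def water_flux(p_i, p_e, O_i, O_e, params: ModelParameters):
    """Transmembrane water velocity w_m = eta_m (p_i - p_e + iRT (O_e - O_i)).

    Positive w_m moves water out of the ICS (shrinks alpha_i).
    """
    iRT = params.vant_hoff * params.R * params.T
    return params.eta_m * (np.asarray(p_i) - np.asarray(p_e)
                           + iRT * (np.asarray(O_e) - np.asarray(O_i)))


Waveform = Literal["constant", "slow", "ultraslow"]

_WAVE_FREQ = {"slow": 1.0, "ultraslow": 0.05}


@dataclass
class StimulusProtocol:
    """K+/Na+ input flux protocol in the input zone.

    ``j_input^K = -j_input^Na`` pointwise and at all times, so the stimulus
    injects no net charge and no net osmolytes.  Waveforms:

        constant:   j_in
        slow:       (j_in/2) sin(2 pi t) + j_in/2          (1 Hz)
        ultraslow:  (j_in/2) sin(2 pi 0.05 t) + j_in/2     (0.05 Hz)

    The sinusoid phase references absolute time t by default (the waveform
    formula uses bare t); set ``phase_at_onset=True`` to reference the
    stimulus onset instead.
    """

    waveform: Waveform = "constant"
    j_in: float = 8.0e-7
    t_on: float = 10.0
    t_off: float = 210.0
    phase_at_onset: bool = False

    def __post_init__(self) -> None:
        if self.waveform not in ("constant", "slow", "ultraslow"):
            raise ValueError(f"unknown stimulus waveform {self.waveform!r}")

    @property
    def period(self) -> float:
        """Cycle period (s) for the pulsatile waveforms."""
        if self.waveform == "constant":
            raise ValueError("constant stimulus has no period")
        return 1.0 / _WAVE_FREQ[self.waveform]

    def amplitude(self, t: float) -> float:
        """Input flux density at time t (zone geometry not applied)."""
        if not (self.t_on < t <= self.t_off):
            return 0.0
        if self.waveform == "constant":
            return self.j_in
        tau = t - self.t_on if self.phase_at_onset else t
        f = _WAVE_FREQ[self.waveform]
        return 0.5 * self.j_in * np.sin(2.0 * np.pi * f * tau) + 0.5 * self.j_in

    def fluxes(self, domain: Domain1D, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(j_input^K, j_input^Na) per node; zero outside zone and window."""
        amp = self.amplitude(t)
        jK = amp * domain.zone_weights
        return jK, -jK


def decay_flux(k_e, params: ModelParameters, frozen: FrozenMembrane):
    """(j_decay^K, j_decay^Na): removal of excess ECS K+, matched Na+ return.

    j_decay^K = -j_decay^Na = -k_dec ([K+]_e - [K+]_e,init), active over the
    whole domain at all times; mimics neuronal pumps and cotransporters.
    """
    jK = -params.k_dec * (np.asarray(k_e, dtype=float) - frozen.k_e_init)
    return jK, -jK
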