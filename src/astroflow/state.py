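"""Tissue state vector, baseline initial conditions, and immobile anions.

The unknown fields at one time level are: the ICS volume fraction
``alpha_i``, three ion concentrations per compartment, the electrical
potentials ``phi_i``/``phi_e``, the ECS hydrostatic pressure ``p_e``, and a
scalar Lagrange multiplier ``c_e`` enforcing the zero-mean constraint on
``phi_e``.  ``alpha_e`` and ``p_i`` are algebraic closures:

    alpha_e = (1 - 0.4) - alpha_i
    p_i     = p_e + K_m (alpha_i - alpha_i_init) + p_m_init

Baseline values are the post-calibrated steady state of the unstimulated
model (Table of initial conditions); the immobile-anion triple (z_0, a_i,
a_e) is re-solved at simulator start from whatever initial concentrations
are configured, so the initial state is electroneutral and in osmotic
equilibrium to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import Domain1D, ModelParameters

__all__ = [
    "POST_CALIBRATED",
    "PRE_CALIBRATED",
    "TissueState",
    "ImmobileAnions",
    "solve_immobile_anions",
    "resting_potential",
    "default_initial_state",
]

#: Post-calibrated baseline concentrations (mol/m^3) and ICS volume fraction.
POST_CALIBRATED = {
    "alpha_i": 0.4,
    "na_i": 15.475, "na_e": 144.091,
    "k_i": 99.892, "k_e": 3.216,
    "cl_i": 5.364, "cl_e": 133.273,
}

#: Pre-calibrated seed values used by the relaxation calibration.
PRE_CALIBRATED = {
    "alpha_i": 0.4,
    "na_i": 15.189, "na_e": 144.662,
    "k_i": 99.959, "k_e": 3.082,
    "cl_i": 5.145, "cl_e": 133.71,
}

FIELD_NAMES = ("alpha_i", "na_i", "na_e", "k_i", "k_e", "cl_i", "cl_e",
               "phi_i", "phi_e", "p_e")


@dataclass
class TissueState:
    """Spatial fields of the coupled system at one time level.

    All arrays have one value per grid node.  Positive membrane fluxes leave
    the ICS; the membrane potential is ``phi_m = phi_i - phi_e``.
    """

    t: float
    alpha_i: np.ndarray
    na_i: np.ndarray
    na_e: np.ndarray
    k_i: np.ndarray
    k_e: np.ndarray
    cl_i: np.ndarray
    cl_e: np.ndarray
    phi_i: np.ndarray
    phi_e: np.ndarray
    p_e: np.ndarray
    c_e: float = 0.0

    @property
    def alpha_e(self) -> np.ndarray:
        return 0.6 - self.alpha_i

    @property
    def phi_m(self) -> np.ndarray:
        return self.phi_i - self.phi_e

    def p_i(self, params: ModelParameters, alpha_i_init: float | np.ndarray) -> np.ndarray:
        return self.p_e + params.K_m * (self.alpha_i - alpha_i_init) + params.p_m_init

    def validate(self) -> None:
        if not np.all((self.alpha_i > 0.0) & (self.alpha_i < 0.6)):
            raise ValueError("alpha_i out of (0, 0.6)")
        for name in ("na_i", "na_e", "k_i", "k_e", "cl_i", "cl_e"):
            if not np.all(getattr(self, name) > 0.0):
                raise ValueError(f"non-positive concentration in {name}")

    def copy(self) -> "TissueState":
        return TissueState(
            t=self.t,
            **{n: getattr(self, n).copy() for n in FIELD_NAMES},
            c_e=self.c_e,
        )

    # packing to/from the flat solver vector (node-blocked layout)
    def to_vector(self) -> np.ndarray:
        n = self.alpha_i.size
        x = np.empty(10 * n + 1)
        m = np.stack([getattr(self, f) for f in FIELD_NAMES], axis=1)
        x[:-1] = m.ravel()
        x[-1] = self.c_e
        return x

    @classmethod
    def from_vector(cls, x: np.ndarray, t: float) -> "TissueState":
        m = x[:-1].reshape(-1, 10)
        return cls(t=t, **{f: m[:, j].copy() for j, f in enumerate(FIELD_NAMES)},
                   c_e=float(x[-1]))


@dataclass(frozen=True)
class ImmobileAnions:
    """Immobile macromolecule concentrations (per total tissue volume) and
    their average charge number z_0.

    ``a_i`` and ``a_e`` are constant in time; the local concentration seen
    by a compartment is ``a_r / alpha_r``, so swelling dilutes them.
    """

    z_0: float
    a_i: float
    a_e: float


def solve_immobile_anions(params: ModelParameters,
                          concentrations: dict[str, float] | None = None,
                          alpha_i_init: float = 0.4,
                          p_m_init: float | None = None) -> ImmobileAnions:
    """Solve the closed-form system fixing z_0, a_i, a_e.

    The three conditions are electroneutrality of each compartment and zero
    transmembrane water flux at t = 0:

        z_0 = (sum_k z_k [k]_e - sum_k z_k [k]_i)
              / (p_m_init/(RT) + sum_k [k]_e - sum_k [k]_i)
        a_i = -sum_k z_k [k]_i * alpha_i / z_0
        a_e = -sum_k z_k [k]_e * alpha_e / z_0

    Raises if the denominator vanishes (the initial state is already
    iso-osmotic and charge balanced, leaving z_0 undetermined).
    """
    c = dict(POST_CALIBRATED if concentrations is None else concentrations)
    for name in ("na_i", "na_e", "k_i", "k_e", "cl_i", "cl_e"):
        if c[name] <= 0:
            raise ValueError(f"initial concentration {name} must be positive")
    if p_m_init is None:
        p_m_init = params.p_m_init
    alpha_e_init = params.total_cell_fraction - alpha_i_init
    z = params.valences
    ci = np.array([c["na_i"], c["k_i"], c["cl_i"]])
    ce = np.array([c["na_e"], c["k_e"], c["cl_e"]])
    zci, zce = float(z @ ci), float(z @ ce)
    denom = p_m_init / (params.R * params.T) + ce.sum() - ci.sum()
    scale = max(ce.sum(), ci.sum())
    if abs(denom) < 1e-12 * scale:
        if abs(zce - zci) < 1e-12 * scale:
            # fully symmetric baseline: only the products z_0 a_r are
            # physical (charge densities); fix the gauge with z_0 = -1
            z_0 = -1.0
        else:
            raise ZeroDivisionError(
                "initial state is iso-osmotic but not charge balanced; "
                "z_0 has no finite solution")
    else:
        z_0 = (zce - zci) / denom
    if abs(z_0) < 1e-12 and (abs(zci) > 1e-12 * scale or abs(zce) > 1e-12 * scale):
        raise ZeroDivisionError(
            "compartment charge imbalances are equal but nonzero; no finite "
            "immobile-anion content can restore electroneutrality")
    a_i = -zci * alpha_i_init / z_0
    a_e = -zce * alpha_e_init / z_0
    return ImmobileAnions(z_0=z_0, a_i=a_i, a_e=a_e)


def resting_potential(params: ModelParameters,
                      concentrations: dict[str, float] | None = None,
                      kir_frozen=None) -> float:
    """Membrane potential at which the net membrane charge flux vanishes.

    With electroneutral dynamics the membrane potential is slaved to the
    concentrations; at a spatially uniform state it solves
    ``sum_k z_k j_m^k(phi_m) = 0``.  With the baseline concentrations this
    gives ~ -85.9 mV.
    """
    from .membrane import FrozenMembrane, membrane_ion_fluxes

    c = dict(POST_CALIBRATED if concentrations is None else concentrations)
    if kir_frozen is None:
        kir_frozen = FrozenMembrane.from_concentrations(params, c)
    z = params.valences

    def net_charge_flux(phi_m: float) -> float:
        j = membrane_ion_fluxes(
            params, kir_frozen,
            na_i=c["na_i"], na_e=c["na_e"], k_i=c["k_i"], k_e=c["k_e"],
            cl_i=c["cl_i"], cl_e=c["cl_e"], phi_m=phi_m)
        return z[0] * j.j_Na + z[1] * j.j_K + z[2] * j.j_Cl

    return brentq(net_charge_flux, -0.2, 0.05, xtol=1e-14)


def default_initial_state(params: ModelParameters, domain: Domain1D,
                          concentrations: dict[str, float] | None = None) -> TissueState:
    """Spatially uniform baseline state from the post-calibrated values.

    ``phi_e = 0`` (zero mean), ``phi_i`` is the resting potential solving
    net membrane charge flux = 0 (~ -85.9 mV at baseline), ``p_e = 0`` so
    ``p_i - p_e = p_m_init = 1000 Pa``.
    """
    c = dict(POST_CALIBRATED if concentrations is None else concentrations)
    n = domain.N + 1
    phi_m = resting_potential(params, c)
    ones = np.ones(n)
    return TissueState(
        t=0.0,
        alpha_i=c["alpha_i"] * ones,
        na_i=c["na_i"] * ones, na_e=c["na_e"] * ones,
        k_i=c["k_i"] * ones, k_e=c["k_e"] * ones,
        cl_i=c["cl_i"] * ones, cl_e=c["cl_e"] * ones,
        phi_i=phi_m * ones, phi_e=np.zeros(n),
        p_e=np.zeros(n), c_e=0.0,
    )
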