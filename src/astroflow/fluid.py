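"""Constitutive laws for compartmental fluid flow (scenarios M0-M3).

Fluid scenarios differ in which driving forces act on the intrinsic
velocities u_i, u_e (m/s):

    M0: zero flow (u_i = u_e = 0, w_m = 0); electrodiffusion only.
    M1: Darcy flow from hydrostatic pressure in both compartments,
        u_r = -kappa_r grad p_r.
    M2: M1 plus an osmotic term in the ICS from the immobile anions
        (mobile ions pass through gap junctions and do not drive
        intercellular osmosis): u_i = -kappa_i (grad p_i - iRT grad(a_i/alpha_i)).
    M3: M2 plus Helmholtz-Smoluchowski electro-osmosis in the narrow ECS:
        u_e = -kappa_e grad p_e - (eps_r eps_0 zeta / mu) grad phi_e.

p_i is eliminated through the membrane force balance
p_i = p_e + K_m (alpha_i - alpha_i_init) + p_m_init, leaving p_e as the only
pressure unknown; it is closed by requiring the total superficial flux
alpha_i u_i + alpha_e u_e to be divergence free, which with sealed ends in
1D forces the two superficial fluxes to cancel pointwise.

Velocities are evaluated at cell faces from nodal fields with central
differences, the same basis the transport discretization uses, so the
divergence-free property holds discretely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = ["ScenarioSpec", "VelocityFields", "face_velocities", "electroosmotic_mobility"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which constitutive terms are active for a fluid scenario tag."""

    tag: str
    compartmental_flow: bool   # any u_r at all (False only for M0)
    transmembrane_water: bool  # w_m on/off
    ics_osmotic: bool          # iRT grad(a_i/alpha_i) term in u_i
    ecs_electroosmotic: bool   # Helmholtz-Smoluchowski term in u_e

    _TAGS = {
        "M0": dict(compartmental_flow=False, transmembrane_water=False,
                   ics_osmotic=False, ecs_electroosmotic=False),
        "M1": dict(compartmental_flow=True, transmembrane_water=True,
                   ics_osmotic=False, ecs_electroosmotic=False),
        "M2": dict(compartmental_flow=True, transmembrane_water=True,
                   ics_osmotic=True, ecs_electroosmotic=False),
        "M3": dict(compartmental_flow=True, transmembrane_water=True,
                   ics_osmotic=True, ecs_electroosmotic=True),
    }

    @classmethod
    def from_tag(cls, tag: str) -> "ScenarioSpec":
        try:
            return cls(tag=tag, **cls._TAGS[tag])
        except KeyError:
            raise ValueError(f"unknown scenario {tag!r}; expected M0, M1, M2 or M3") from None


@dataclass
class VelocityFields:
    """Intrinsic and superficial velocities at cell faces (m/s)."""

    u_i: np.ndarray
    u_e: np.ndarray
    superficial_i: np.ndarray  # alpha_i u_i at faces
    superficial_e: np.ndarray  # alpha_e u_e at faces


def electroosmotic_mobility(params: ModelParameters) -> float:
    """Helmholtz-Smoluchowski coefficient eps_r eps_0 zeta / mu (m^2/(V s)).

    Negative for brain ECS (zeta < 0), so u_e gains a term aligned with
    +grad(phi_e).
    """
    return params.eps_r * params.eps_0 * params.zeta / params.mu


def face_velocities(scenario: ScenarioSpec, params: ModelParameters,
                    alpha_i: np.ndarray, p_e: np.ndarray, phi_e: np.ndarray,
                    a_i: float, alpha_i_init: float, dx: float) -> VelocityFields:
    """Evaluate u_i, u_e and the superficial velocities at the N cell faces.

    Gradients are central differences of nodal fields; face volume fractions
    are arithmetic means.  ``a_i`` is the (spatially constant) immobile-anion
    content of the ICS per total tissue volume.
    """
    n_faces = alpha_i.size - 1
    if not scenario.compartmental_flow:
        z = np.zeros(n_faces)
        return VelocityFields(u_i=z, u_e=z.copy(),
                              superficial_i=z.copy(), superficial_e=z.copy())

    alpha_e = params.total_cell_fraction - alpha_i
    # p_i differs from p_e by the membrane force balance; constants drop out
    # of the gradient
    grad_pe = np.diff(p_e) / dx
    grad_pi = grad_pe + params.K_m * np.diff(alpha_i) / dx

    u_i = -params.kappa_i * grad_pi
    if scenario.ics_osmotic:
        iRT = params.vant_hoff * params.R * params.T
        grad_ai = a_i * np.diff(1.0 / alpha_i) / dx
        u_i = -params.kappa_i * (grad_pi - iRT * grad_ai)

    u_e = -params.kappa_e * grad_pe
    if scenario.ecs_electroosmotic:
        u_e = u_e - electroosmotic_mobility(params) * np.diff(phi_e) / dx

    fa_i = 0.5 * (alpha_i[1:] + alpha_i[:-1])
    fa_e = 0.5 * (alpha_e[1:] + alpha_e[:-1])
    return VelocityFields(u_i=u_i, u_e=u_e,
                          superficial_i=fa_i * u_i, superficial_e=fa_e * u_e)
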