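"""Derived quantities: pressures, potentials, velocities, swelling, flux
decompositions, phase metrics, and parameter sweeps.

This is the only module that converts out of SI: velocities are reported in
um/min, potentials in mV, pressures in Pa or kPa, concentrations in mM
(numerically identical to mol/m^3).

Conventions
-----------
* "osmotic pressure" is iRT (O_e - O_i); at baseline it equals -p_m_init
  (-1 kPa), so a drop in transmembrane osmotic support shows up as this
  quantity becoming more negative.
* Point quantities are taken at the center of the input zone (x = 150 um by
  default); velocity summaries are maxima over space, evaluated at cell
  faces where the discrete velocities live.
* Flux-fraction conventions: F_diff = |adv/diff| and F_drift = |adv/drift|
  with components evaluated at the face where |total flux| peaks
  ("peak_total", the default); the alternative "peak_components" convention
  uses each component's own spatial maximum.  Both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .membrane import osmolarity, solute_potential, water_flux
from .parameters import ModelParameters
from .solver import (ALPHA, KE, PE, PHIE, PHII, M_PER_S_TO_UM_PER_MIN,
                     SimulationResult)

__all__ = [
    "point_metrics", "summarize", "steady_state_metrics", "decompose_fluxes",
    "charge_flux", "phase_shift", "sensitivity_sweep", "timeseries_frame",
]

_IONS = ("Na", "K", "Cl")
_COMPONENT_NAMES = ("diffusive", "drift", "advective")


def _osmolarities(res: SimulationResult, m: np.ndarray):
    p = res.params
    alpha_i = m[:, ALPHA]
    alpha_e = p.total_cell_fraction - alpha_i
    O_i = osmolarity(res.anions.a_i, alpha_i, m[:, 1], m[:, 3], m[:, 5])
    O_e = osmolarity(res.anions.a_e, alpha_e, m[:, 2], m[:, 4], m[:, 6])
    return O_i, O_e


def point_metrics(res: SimulationResult, t: float, x: float | None = None) -> dict:
    """Point values (at x, default input-zone center) and spatial maxima at
    time t, all in reporting units."""
    p = res.params
    x = 0.5 * (res.domain.L1 + res.domain.L2) if x is None else x
    j = res.domain.node_index(x)
    m = res.fields[res.index_at(t)]
    b = res.fields[0]

    alpha_i = m[:, ALPHA]
    alpha_e = p.total_cell_fraction - alpha_i
    alpha_i0, alpha_e0 = b[:, ALPHA], p.total_cell_fraction - b[:, ALPHA]
    p_e = m[:, PE]
    p_i = p_e + p.K_m * (alpha_i - res.frozen.alpha_i_init) + p.p_m_init
    O_i, O_e = _osmolarities(res, m)
    O_i0, O_e0 = _osmolarities(res, b)
    iRT = p.vant_hoff * p.R * p.T
    osm_pressure = iRT * (O_e - O_i)          # Pa; baseline = -p_m_init
    osm_pressure0 = iRT * (O_e0 - O_i0)
    w_m = water_flux(p_i, p_e, O_i, O_e, p)
    system = res.system()
    _, vel = system.flux_components(m)

    return {
        "t": t,
        "x_um": res.domain.nodes[j] * 1e6,
        "ics_swelling_pct": 100.0 * (alpha_i[j] - alpha_i0[j]) / alpha_i0[j],
        "ecs_shrinkage_pct": 100.0 * (alpha_e0[j] - alpha_e[j]) / alpha_e0[j],
        "ics_osmolarity_mM": float(O_i[j]),
        "ecs_osmolarity_mM": float(O_e[j]),
        "osmotic_pressure_kPa": float(osm_pressure[j]) / 1e3,
        "max_osmotic_pressure_drop_kPa":
            float(np.max(osm_pressure0 - osm_pressure)) / 1e3,
        "ics_solute_potential_kPa": float(solute_potential(O_i, p)[j]) / 1e3,
        "ecs_solute_potential_kPa": float(solute_potential(O_e, p)[j]) / 1e3,
        "ics_pressure_kPa": float(p_i[j]) / 1e3,
        "ecs_pressure_kPa": float(p_e[j]) / 1e3,
        "transmembrane_pressure_kPa": float(p_i[j] - p_e[j]) / 1e3,
        "delta_transmembrane_pressure_Pa":
            float((p_i[j] - p_e[j]) - p.p_m_init),
        "ecs_water_potential_kPa":
            float(solute_potential(O_e, p)[j] + p_e[j]) / 1e3,
        "phi_m_mV": float(m[j, PHII] - m[j, PHIE]) * 1e3,
        "phi_e_mV": float(m[j, PHIE]) * 1e3,
        "delta_k_e_mM": float(m[j, KE] - b[j, KE]),
        "max_k_e_mM": float(np.max(m[:, KE])),
        "w_m_um_per_min": float(w_m[j]) * M_PER_S_TO_UM_PER_MIN,
        "max_u_i_um_per_min":
            float(np.max(np.abs(vel.u_i))) * M_PER_S_TO_UM_PER_MIN,
        "max_u_e_um_per_min":
            float(np.max(np.abs(vel.u_e))) * M_PER_S_TO_UM_PER_MIN,
        "max_superficial_ui_um_per_min":
            float(np.max(np.abs(vel.superficial_i))) * M_PER_S_TO_UM_PER_MIN,
        "max_superficial_ue_um_per_min":
            float(np.max(np.abs(vel.superficial_e))) * M_PER_S_TO_UM_PER_MIN,
    }


_TABLE_KEYS = (
    "ics_swelling_pct", "ecs_shrinkage_pct", "ics_osmolarity_mM",
    "ecs_osmolarity_mM", "osmotic_pressure_kPa", "ics_pressure_kPa",
    "ecs_pressure_kPa", "transmembrane_pressure_kPa",
    "max_u_i_um_per_min", "max_u_e_um_per_min",
    "max_superficial_ui_um_per_min", "max_superficial_ue_um_per_min",
    "w_m_um_per_min",
)

# quantities without meaning in the zero-flow scenario
_NOT_APPLICABLE_M0 = (
    "ics_swelling_pct", "ecs_shrinkage_pct", "ics_pressure_kPa",
    "ecs_pressure_kPa", "transmembrane_pressure_kPa",
    "max_u_i_um_per_min", "max_u_e_um_per_min",
    "max_superficial_ui_um_per_min", "max_superficial_ue_um_per_min",
    "w_m_um_per_min",
)


def summarize(res: SimulationResult, t: float = 200.0) -> dict:
    """Scenario summary: point values at the input-zone center plus spatial
    velocity maxima at time t; zero-flow (M0) entries that have no meaning
    are reported as None."""
    pm = point_metrics(res, t)
    out = {"scenario": res.scenario.tag, "t": t}
    for k in _TABLE_KEYS:
        if res.scenario.tag == "M0" and k in _NOT_APPLICABLE_M0:
            out[k] = None
        else:
            out[k] = pm[k]
    return out


def steady_state_metrics(res: SimulationResult, t: float = 200.0) -> dict:
    """The activity-response scalars: change in ECS K+, membrane potential,
    swelling, pressure difference, peak superficial velocity, and the
    largest transmembrane osmotic-pressure drop."""
    pm = point_metrics(res, t)
    return {
        "delta_k_e_mM": pm["delta_k_e_mM"],
        "phi_m_mV": pm["phi_m_mV"],
        "ics_swelling_pct": pm["ics_swelling_pct"],
        "delta_transmembrane_pressure_Pa": pm["delta_transmembrane_pressure_Pa"],
        "max_superficial_velocity_um_per_min": max(
            pm["max_superficial_ui_um_per_min"], pm["max_superficial_ue_um_per_min"]),
        "max_osmotic_pressure_drop_kPa": pm["max_osmotic_pressure_drop_kPa"],
    }


def decompose_fluxes(res: SimulationResult, t: float = 200.0) -> pd.DataFrame:
    """Split each superficial ionic flux alpha_r j_r^k into diffusive, drift,
    and advective face components and compute the advection fractions.

    One row per (ion, compartment) with the components at the location of
    peak |total flux|, F_diff and F_drift under both conventions, and the
    peak total flux itself.  Fractions with a vanishing denominator are
    reported as inf.
    """
    m = res.fields[res.index_at(t)]
    system = res.system()
    comps, _ = system.flux_components(m)
    faces_um = res.domain.faces * 1e6

    rows = []
    for ion in _IONS:
        for r in ("i", "e"):
            c = comps[(ion, r)]          # (3, n_faces): diff, drift, adv
            total = c.sum(axis=0)
            k = int(np.argmax(np.abs(total)))
            diff, drift, adv = (float(c[0, k]), float(c[1, k]), float(c[2, k]))

            def ratio(num, den):
                return float(np.inf) if den == 0.0 else abs(num / den)

            rows.append({
                "ion": ion, "compartment": r,
                "peak_face_x_um": float(faces_um[k]),
                "peak_total_flux_umol_m2_s": float(total[k]) * 1e6,
                "diffusive_umol_m2_s": diff * 1e6,
                "drift_umol_m2_s": drift * 1e6,
                "advective_umol_m2_s": adv * 1e6,
                "F_diff": ratio(adv, diff),
                "F_drift": ratio(adv, drift),
                "F_diff_peak_components":
                    ratio(np.max(np.abs(c[2])), np.max(np.abs(c[0]))),
                "F_drift_peak_components":
                    ratio(np.max(np.abs(c[2])), np.max(np.abs(c[1]))),
            })
    return pd.DataFrame.from_records(rows)


def charge_flux(res: SimulationResult, t: float = 200.0) -> dict:
    """Signed charge flux sum_k z_k alpha_r j_r^k per compartment at faces.

    Returns face arrays (mol/(m^2 s)) and their spatial maxima in
    umol/(m^2 s).
    """
    m = res.fields[res.index_at(t)]
    system = res.system()
    comps, _ = system.flux_components(m)
    z = {"Na": res.params.z_Na, "K": res.params.z_K, "Cl": res.params.z_Cl}
    out = {}
    for r in ("i", "e"):
        f = sum(z[ion] * comps[(ion, r)].sum(axis=0) for ion in _IONS)
        out[r] = f
        out[f"max_{r}_umol_m2_s"] = float(np.max(np.abs(f))) * 1e6
    return out


def _refined_argmax(t: np.ndarray, y: np.ndarray) -> float:
    """Time of the maximum with quadratic sub-sample refinement."""
    k = int(np.argmax(y))
    if 0 < k < y.size - 1:
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            delta = 0.5 * (y0 - y2) / denom
            return float(t[k] + delta * (t[k + 1] - t[k]))
    return float(t[k])


def phase_shift(times: np.ndarray, signal: np.ndarray, reference: np.ndarray,
                period: float) -> tuple[float, float]:
    """Lag of ``signal``'s cycle maximum behind ``reference``'s, in percent
    of the cycle period, over the final full cycle; also the signal's
    peak-to-trough amplitude over that cycle.

    Assumes a periodic steady state has been reached (earlier cycles are
    discarded).  Raises if fewer than two full cycles are available.
    """
    times = np.asarray(times, dtype=float)
    if times[-1] - times[0] < 2.0 * period:
        raise ValueError("need at least two full cycles of data")
    mask = times >= times[-1] - period
    t, y, u = times[mask], np.asarray(signal)[mask], np.asarray(reference)[mask]
    t_sig = _refined_argmax(t, y)
    t_ref = _refined_argmax(t, u)
    shift = (t_sig - t_ref) % period
    amplitude = float(np.max(y) - np.min(y))
    return 100.0 * shift / period, amplitude


def sensitivity_sweep(parameter: str, values, scenario: str = "M1",
                      N: int = 100, dt: float = 1.0e-2, t_end: float = 200.0,
                      params: ModelParameters | None = None) -> pd.DataFrame:
    """Max ICS superficial fluid velocity at t_end against a parameter grid.

    ``parameter`` is one of ``kappa`` (both compartments jointly), ``K_m``,
    ``eta_m``, or ``j_in_fraction`` (stimulus amplitude as a fraction of the
    scenario default).
    """
    from .solver import RunConfig, run_simulation

    base = params or ModelParameters()
    known = {"kappa", "K_m", "eta_m", "j_in_fraction"}
    if parameter not in known:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"expected one of {sorted(known)}")
    records = []
    for v in values:
        p = base
        j_in = None
        if parameter == "kappa":
            p = base.with_updates(kappa_i=v, kappa_e=v)
        elif parameter == "K_m":
            p = base.with_updates(K_m=v)
        elif parameter == "eta_m":
            p = base.with_updates(eta_m=v)
        else:
            j_in = v * base.j_in(scenario)
        cfg = RunConfig(scenario=scenario, N=N, dt=dt, t_end=t_end,
                        output_dt=t_end, j_in=j_in)
        res = run_simulation(cfg, p)
        pm = point_metrics(res, t_end)
        records.append({"parameter": parameter, "value": v,
                        "max_superficial_ui_um_per_min":
                            pm["max_superficial_ui_um_per_min"]})
    return pd.DataFrame.from_records(records)


def timeseries_frame(res: SimulationResult) -> pd.DataFrame:
    """Tidy per-time-point metrics (one row per stored time)."""
    rows = [point_metrics(res, float(t)) for t in res.times]
    return pd.DataFrame.from_records(rows)
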