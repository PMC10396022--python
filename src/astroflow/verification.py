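"""Verification scaffolding: toy problems with independent dense oracles and
golden-run targets for the headline quantities.

``make_diffusion_toy`` builds a single-species implicit diffusion problem
whose reference step is assembled with explicit dense loops, independent of
the production vectorized assembly; it validates the diffusive face-flux /
control-volume divergence primitive in isolation.

``golden_run`` executes a registered scenario, extracts one scalar, and
compares it against its reference value; the registry is also what the
acceptance script iterates over (reporting computed values only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .diagnostics import decompose_fluxes, point_metrics, steady_state_metrics
from .parameters import ModelParameters
from .solver import KE, M_PER_S_TO_UM_PER_MIN, RunConfig, SimulationResult, run_simulation
from .state import POST_CALIBRATED, solve_immobile_anions

__all__ = ["ToyProblem", "make_diffusion_toy", "RunCache", "GoldenReport",
           "golden_run", "TARGETS"]


# --------------------------------------------------------------- toy problems

@dataclass
class ToyProblem:
    """Tiny implicit single-species diffusion problem with a dense oracle.

    A concentration c(x) diffuses inside one compartment of constant volume
    fraction alpha with effective diffusivity D/lambda^2 and sealed ends:

        alpha dc/dt = d/dx ( alpha D/lambda^2 dc/dx )

    ``dense_step`` assembles the backward-Euler system with plain Python
    loops into a dense matrix and solves it directly; ``production_step``
    uses the same face-flux/divergence primitives as the production solver.
    Both conserve the discrete integral of alpha*c exactly.
    """

    c0: np.ndarray
    dx: float
    dt: float
    alpha: float = 0.4
    D_eff: float = 1.96e-9 / 3.2 ** 2
    tolerance: float = 1.0e-12

    @property
    def volumes(self) -> np.ndarray:
        v = np.full(self.c0.size, self.dx)
        v[0] = v[-1] = 0.5 * self.dx
        return v

    def dense_step(self) -> np.ndarray:
        """Independent reference: loop-assembled dense backward Euler."""
        n = self.c0.size
        V = self.volumes
        k = self.alpha * self.D_eff / self.dx
        A = np.zeros((n, n))
        for j in range(n):
            A[j, j] += self.alpha * V[j] / self.dt
            if j > 0:
                A[j, j] += k
                A[j, j - 1] -= k
            if j < n - 1:
                A[j, j] += k
                A[j, j + 1] -= k
        b = self.alpha * V * self.c0 / self.dt
        return np.linalg.solve(A, b)

    def production_step(self) -> np.ndarray:
        """Backward Euler using the production face-flux form.

        The operator is linear, so the implicit step solves
        (alpha/dt) (c_new - c0) + div(F(c_new)) = 0 with
        F = alpha * (-D_eff * grad c) at faces, via the same central
        two-point flux and sealed-end divergence as the full solver.
        """
        n = self.c0.size
        V = self.volumes

        def divergence(face_flux):
            out = np.empty(n)
            out[0] = face_flux[0]
            out[1:-1] = face_flux[1:] - face_flux[:-1]
            out[-1] = -face_flux[-1]
            return out / V

        def apply_op(c):
            face = self.alpha * (-self.D_eff) * np.diff(c) / self.dx
            return self.alpha * c / self.dt + divergence(face)

        # build the matrix column by column (linear operator), solve dense
        A = np.column_stack([apply_op(e) for e in np.eye(n)])
        return np.linalg.solve(A, self.alpha * self.c0 / self.dt)


def make_diffusion_toy(n_nodes: int = 5, dt: float = 0.05,
                       dx: float = 1.0e-6, profile: str = "step") -> ToyProblem:
    """Build a 3-10 node toy diffusion problem (default: a step profile)."""
    if not 3 <= n_nodes <= 10:
        raise ValueError("toy problems use 3-10 nodes")
    if profile == "step":
        c0 = np.where(np.arange(n_nodes) < n_nodes // 2, 2.0, 1.0)
    elif profile == "uniform":
        c0 = np.ones(n_nodes)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return ToyProblem(c0=c0.astype(float), dx=dx, dt=dt)


# ------------------------------------------------------------- golden targets

class RunCache:
    """Memoizes simulation runs shared between golden targets."""

    def __init__(self, params: ModelParameters | None = None):
        self.params = params or ModelParameters()
        self._runs: dict = {}

    def get(self, scenario: str, N: int, dt: float, t_end: float) -> SimulationResult:
        key = (scenario, N, dt, t_end)
        if key not in self._runs:
            cfg = RunConfig(scenario=scenario, N=N, dt=dt, t_end=t_end,
                            output_dt=min(1.0, t_end))
            self._runs[key] = run_simulation(cfg, self.params)
        return self._runs[key]


@dataclass(frozen=True)
class GoldenTarget:
    """One verifiable scalar: how to compute it and what to compare against."""

    id: str
    description: str
    units: str
    expected: float
    rel_tol: float
    extract: Callable[[RunCache], float]
    problem_size: Callable[[], int]


def _convergence_run(cache: RunCache) -> SimulationResult:
    return cache.get("M1", N=200, dt=1.0e-2, t_end=20.0)


def _m1_steady(cache: RunCache) -> SimulationResult:
    return cache.get("M1", N=100, dt=1.0e-2, t_end=200.0)


def _peak_ue(cache: RunCache) -> float:
    res = _convergence_run(cache)
    m = res.fields[res.index_at(20.0)]
    _, vel = res.system().flux_components(m)
    return float(np.max(np.abs(vel.superficial_e))) * M_PER_S_TO_UM_PER_MIN


def _peak_ke(cache: RunCache) -> float:
    res = _convergence_run(cache)
    return float(np.max(res.fields[res.index_at(20.0)][:, KE]))


def _anion_a_i(cache: RunCache) -> float:
    return solve_immobile_anions(cache.params, POST_CALIBRATED).a_i


def _m3_F_diff_K_ics(cache: RunCache) -> float:
    res = cache.get("M3", N=100, dt=1.0e-2, t_end=200.0)
    df = decompose_fluxes(res, 200.0)
    row = df[(df.ion == "K") & (df.compartment == "i")].iloc[0]
    return float(row.F_diff)


def _steady(key: str) -> Callable[[RunCache], float]:
    def extract(cache: RunCache) -> float:
        return steady_state_metrics(_m1_steady(cache), 200.0)[key]
    return extract


def _m2_peak_ui(cache: RunCache) -> float:
    res = cache.get("M2", N=100, dt=1.0e-2, t_end=200.0)
    return point_metrics(res, 200.0)["max_superficial_ui_um_per_min"]


TARGETS: dict[str, GoldenTarget] = {t.id: t for t in [
    GoldenTarget("t1", "peak ECS superficial velocity, M1 constant stimulus, "
                 "t=20 s, N=200, dt=1e-2 s", "um/min", 0.271, 0.01,
                 _peak_ue, lambda: 200),
    GoldenTarget("t2", "peak [K+]_e, same convergence run", "mM",
                 9.183, 0.01, _peak_ke, lambda: 200),
    GoldenTarget("t3", "steady-state increase of [K+]_e at the input-zone "
                 "center, M1, t=200 s", "mM", 6.68, 0.05,
                 _steady("delta_k_e_mM"), lambda: 100),
    GoldenTarget("t4", "membrane potential at the input-zone center, M1 "
                 "steady state", "mV", -61.0, 0.05,
                 _steady("phi_m_mV"), lambda: 100),
    GoldenTarget("t5", "relative ICS volume increase at the input-zone "
                 "center, M1 steady state", "%", 12.9, 0.05,
                 _steady("ics_swelling_pct"), lambda: 100),
    GoldenTarget("t6", "increase in transmembrane hydrostatic pressure "
                 "difference, M1 steady state", "Pa", 118.0, 0.05,
                 _steady("delta_transmembrane_pressure_Pa"), lambda: 100),
    GoldenTarget("t7", "peak superficial fluid velocity, M1, t=200 s",
                 "um/min", 0.31, 0.05,
                 _steady("max_superficial_velocity_um_per_min"), lambda: 100),
    GoldenTarget("t8", "peak ICS superficial fluid velocity, M2, t=200 s",
                 "um/min", 14.0, 0.10, _m2_peak_ui, lambda: 100),
    GoldenTarget("t9", "largest transmembrane osmotic-pressure drop, M1, "
                 "t=200 s", "kPa", 0.713, 0.05,
                 _steady("max_osmotic_pressure_drop_kPa"), lambda: 100),
    GoldenTarget("t10", "advection/diffusion fraction of the ICS K+ flux, "
                 "M3, t=200 s", "", 4.519, 0.10,
                 _m3_F_diff_K_ics, lambda: 100),
    GoldenTarget("t12", "ICS immobile-anion concentration from the "
                 "electroneutral, flux-free baseline", "mM", 73.5, 0.001,
                 _anion_a_i, lambda: 1),
]}


@dataclass
class GoldenReport:
    target: GoldenTarget
    value: float
    passed: bool
    rel_error: float

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (f"[{status}] {self.target.id}: {self.value:.4g} {self.target.units} "
                f"(reference {self.target.expected:.4g}, "
                f"rel. err. {self.rel_error:.2%}, tol {self.target.rel_tol:.1%}) "
                f"- {self.target.description}")


def golden_run(target_id: str, cache: RunCache | None = None) -> GoldenReport:
    """Execute one golden target and compare against its reference value."""
    if target_id not in TARGETS:
        raise KeyError(f"unknown target {target_id!r}; "
                       f"known: {sorted(TARGETS)}")
    cache = cache or RunCache()
    target = TARGETS[target_id]
    value = target.extract(cache)
    rel_error = abs(value - target.expected) / abs(target.expected)
    return GoldenReport(target=target, value=value,
                        passed=bool(rel_error <= target.rel_tol),
                        rel_error=rel_error)
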