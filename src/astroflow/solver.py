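"""Spatial discretization and fully implicit time stepping of the coupled
volume / electrodiffusion / electroneutrality / pressure system.

Discretization
--------------
Unknown fields live on the ``N + 1`` nodes of a uniform grid; fluxes are
evaluated at the ``N`` cell faces with central (arithmetic-mean) face values
and two-point gradients, and conservation laws are enforced on node-centered
control volumes (width dx, half-width at the sealed ends).  This is the
lumped-mass variant of continuous piecewise-linear finite elements on the
same grid: second order in space, exactly conservative, and the velocity and
transport operators share one discrete gradient so the divergence-free
closure holds discretely.  No advection stabilization is used; cell Peclet
numbers stay far below one at physiological velocities and a runtime check
warns otherwise.

Per node the ten equations are: ICS volume balance, six ion conservation
laws, two electroneutral current equations, and the pressure closure (the
last node carries the Dirichlet condition p_e = 0 instead); one extra scalar
equation pins the mean of phi_e through the Lagrange multiplier c_e.  Time
stepping is backward Euler with a monolithic Newton solve; the Jacobian is
built by finite differences over a 30-color partition of the sparsity
pattern and its LU factorization is reused across iterations and steps
until convergence degrades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .fluid import ScenarioSpec, face_velocities
from .membrane import (FrozenMembrane, StimulusProtocol, decay_flux,
                       membrane_ion_fluxes, water_flux)
from .parameters import Domain1D, ModelParameters, build_domain
from .state import (POST_CALIBRATED, FIELD_NAMES, ImmobileAnions, TissueState,
                    default_initial_state, solve_immobile_anions)

__all__ = [
    "NewtonSettings", "RunConfig", "DiscreteSystem", "SimulationResult",
    "SolverError", "NewtonDivergenceError", "run_simulation", "convergence_study",
    "M_PER_S_TO_UM_PER_MIN",
]

#: Unit conversion used for reporting velocities.
M_PER_S_TO_UM_PER_MIN = 6.0e7

# field column indices in the packed (n_nodes, 10) layout
ALPHA, NAI, NAE, KI, KE, CLI, CLE, PHII, PHIE, PE = range(10)

_ION_COLUMNS = {"Na": (NAI, NAE), "K": (KI, KE), "Cl": (CLI, CLE)}


class SolverError(RuntimeError):
    """Base class for solver failures."""


class StateBoundsError(SolverError):
    """A trial state left the physical bounds (alpha_i or a concentration)."""


class NewtonDivergenceError(SolverError):
    """Newton did not converge within the configured iteration budget."""


@dataclass(frozen=True)
class NewtonSettings:
    """Nonlinear solver controls.

    ``tol`` applies to the scaled residual (each equation class is divided
    by a characteristic magnitude, see ``DiscreteSystem._row_scales``).
    """

    tol: float = 1.0e-10
    max_iter: int = 25
    stale_iter_limit: int = 4     # iterations on a reused Jacobian before refresh
    max_refresh: int = 3          # Jacobian rebuilds allowed within one step
    fd_eps: float = 1.0e-7        # relative FD perturbation for the Jacobian
    max_dt_halvings: int = 8      # adaptive sub-stepping depth on failure


# characteristic magnitudes per field, used for FD steps and column scaling
_FIELD_TYPICAL = np.array([0.1, 50.0, 50.0, 50.0, 5.0, 50.0, 50.0,
                           0.02, 0.02, 500.0])


@dataclass
class RunConfig:
    """Configuration of one simulation run."""

    scenario: str = "M1"
    stimulus: str = "constant"
    N: int = 400
    dt: float = 1.0e-3
    t_end: float = 250.0
    L: float = 3.0e-4
    L1: float = 1.35e-4
    L2: float = 1.65e-4
    j_in: float | None = None        # None -> scenario default from Table of parameters
    t_on: float = 10.0
    t_off: float = 210.0
    phase_at_onset: bool = False
    init: str = "table3"             # "table3" | "steady"
    initial_concentrations: dict | None = None
    output_dt: float = 1.0
    newton: NewtonSettings = field(default_factory=NewtonSettings)


class DiscreteSystem:
    """Residual assembly, colored FD Jacobian, and Newton stepping."""

    def __init__(self, domain: Domain1D, params: ModelParameters,
                 scenario: ScenarioSpec, protocol: StimulusProtocol,
                 frozen: FrozenMembrane, anions: ImmobileAnions,
                 newton: NewtonSettings = NewtonSettings()):
        self.domain = domain
        self.params = params
        self.scenario = scenario
        self.protocol = protocol
        self.frozen = frozen
        self.anions = anions
        self.newton = newton

        self.n = domain.N + 1
        self.n_dof = 10 * self.n + 1
        self.volumes = domain.volumes
        self.dx = domain.dx
        self.zone_weights = domain.zone_weights

        self._lu = None
        self._refresh_pending = True
        self._build_coloring()
        self._row_scale_inv = 1.0 / self._row_scales()
        self._col_scale = np.concatenate(
            [np.tile(_FIELD_TYPICAL, self.n), [1.0e-3]])

    # ------------------------------------------------------------------ assembly

    def _unpack(self, x: np.ndarray) -> np.ndarray:
        return x[:-1].reshape(self.n, 10)

    def _check_bounds(self, m: np.ndarray) -> None:
        alpha = m[:, ALPHA]
        if not np.all((alpha > 1.0e-3) & (alpha < 0.6 - 1.0e-3)):
            raise StateBoundsError("alpha_i left (0, 0.6)")
        if not np.all(m[:, NAI:CLE + 1] > 0.0):
            raise StateBoundsError("non-positive concentration")

    def flux_components(self, m: np.ndarray):
        """Per-species superficial face fluxes split into (diffusive, drift,
        advective) components, plus the face velocity fields.

        Returns ``(components, vel)`` where ``components[(ion, r)]`` is a
        (3, N) array of the three components of alpha_r j_r^k at faces.
        """
        p = self.params
        dx = self.dx
        alpha_i = m[:, ALPHA]
        alpha_e = p.total_cell_fraction - alpha_i
        vel = face_velocities(self.scenario, p, alpha_i, m[:, PE], m[:, PHIE],
                              self.anions.a_i, self.frozen.alpha_i_init, dx)
        fa = {"i": 0.5 * (alpha_i[1:] + alpha_i[:-1]),
              "e": 0.5 * (alpha_e[1:] + alpha_e[:-1])}
        u = {"i": vel.u_i, "e": vel.u_e}
        lam2 = {"i": p.lambda_i ** 2, "e": p.lambda_e ** 2}
        phi = {"i": m[:, PHII], "e": m[:, PHIE]}
        D = {"Na": p.D_Na, "K": p.D_K, "Cl": p.D_Cl}
        z = {"Na": p.z_Na, "K": p.z_K, "Cl": p.z_Cl}
        psi = p.psi

        comps = {}
        for r in ("i", "e"):
            dphi = np.diff(phi[r]) / dx
            for ion, (col_i, col_e) in _ION_COLUMNS.items():
                c = m[:, col_i if r == "i" else col_e]
                cbar = 0.5 * (c[1:] + c[:-1])
                diff = fa[r] * (-D[ion] / lam2[r]) * (np.diff(c) / dx)
                drift = fa[r] * (-D[ion] * z[ion] / (lam2[r] * psi)) * cbar * dphi
                adv = fa[r] * u[r] * cbar
                comps[(ion, r)] = np.stack([diff, drift, adv])
        return comps, vel

    def _divergence(self, face_flux: np.ndarray) -> np.ndarray:
        """(F_{j+1/2} - F_{j-1/2}) / V_j with sealed (zero-flux) ends."""
        out = np.empty(self.n)
        out[0] = face_flux[0]
        out[1:-1] = face_flux[1:] - face_flux[:-1]
        out[-1] = -face_flux[-1]
        return out / self.volumes

    def residual(self, x_new: np.ndarray, x_old: np.ndarray,
                 t_new: float, dt: float) -> np.ndarray:
        """Backward-Euler residual of the full coupled system."""
        p, fr = self.params, self.frozen
        m = self._unpack(x_new)
        m_old = self._unpack(x_old)
        self._check_bounds(m)

        alpha_i = m[:, ALPHA]
        alpha_e = p.total_cell_fraction - alpha_i
        p_e = m[:, PE]
        p_i = p_e + p.K_m * (alpha_i - fr.alpha_i_init) + p.p_m_init
        phi_m = m[:, PHII] - m[:, PHIE]

        O_i = self.anions.a_i / alpha_i + m[:, NAI] + m[:, KI] + m[:, CLI]
        O_e = self.anions.a_e / alpha_e + m[:, NAE] + m[:, KE] + m[:, CLE]
        if self.scenario.transmembrane_water:
            w_m = water_flux(p_i, p_e, O_i, O_e, p)
        else:
            w_m = np.zeros(self.n)

        jm = membrane_ion_fluxes(
            p, fr, na_i=m[:, NAI], na_e=m[:, NAE], k_i=m[:, KI], k_e=m[:, KE],
            cl_i=m[:, CLI], cl_e=m[:, CLE], phi_m=phi_m)
        membrane = {"Na": jm.j_Na, "K": jm.j_K, "Cl": jm.j_Cl}

        amp = self.protocol.amplitude(t_new)
        j_input = {"Na": -amp * self.zone_weights, "K": amp * self.zone_weights,
                   "Cl": np.zeros(self.n)}
        jdK, jdNa = decay_flux(m[:, KE], p, fr)
        j_decay = {"Na": jdNa, "K": jdK, "Cl": np.zeros(self.n)}

        comps, vel = self.flux_components(m)

        r = np.zeros(self.n_dof)
        rows = r[:-1].reshape(self.n, 10)

        # ICS volume balance (M0: alpha_i frozen)
        if self.scenario.compartmental_flow or self.scenario.transmembrane_water:
            rows[:, ALPHA] = ((alpha_i - m_old[:, ALPHA]) / dt
                              + self._divergence(vel.superficial_i)
                              + p.gamma_m * w_m)
        else:
            rows[:, ALPHA] = (alpha_i - m_old[:, ALPHA]) / dt

        # ion conservation and electroneutral current equations
        charge_i = np.zeros(self.n)
        charge_e = np.zeros(self.n)
        z = {"Na": p.z_Na, "K": p.z_K, "Cl": p.z_Cl}
        for ion, (col_i, col_e) in _ION_COLUMNS.items():
            div_i = self._divergence(comps[(ion, "i")].sum(axis=0))
            div_e = self._divergence(comps[(ion, "e")].sum(axis=0))
            rows[:, col_i] = ((alpha_i * m[:, col_i] - m_old[:, ALPHA] * m_old[:, col_i]) / dt
                              + div_i + p.gamma_m * membrane[ion])
            src_e = membrane[ion] + j_input[ion] + j_decay[ion]
            alpha_e_old = p.total_cell_fraction - m_old[:, ALPHA]
            rows[:, col_e] = ((alpha_e * m[:, col_e] - alpha_e_old * m_old[:, col_e]) / dt
                              + div_e - p.gamma_m * src_e)
            charge_i += z[ion] * (div_i + p.gamma_m * membrane[ion])
            charge_e += z[ion] * (div_e - p.gamma_m * src_e)

        rows[:, PHII] = -charge_i
        rows[:, PHIE] = -charge_e + x_new[-1]

        # pressure closure: total superficial flux divergence free; Dirichlet
        # p_e = 0 at the right boundary
        if self.scenario.compartmental_flow:
            Q = vel.superficial_i + vel.superficial_e
            rows[0, PE] = Q[0] / self.volumes[0]
            rows[1:-1, PE] = np.diff(Q) / self.volumes[1:-1]
            rows[-1, PE] = p_e[-1]
        else:
            rows[:, PE] = p_e

        # zero-mean constraint on phi_e (scaled to a mean potential)
        r[-1] = float(self.volumes @ m[:, PHIE]) / self.domain.L
        return r

    def _row_scales(self) -> np.ndarray:
        """Characteristic magnitude per equation row for the convergence test."""
        p = self.params
        s = np.empty(self.n_dof)
        rows = s[:-1].reshape(self.n, 10)
        iRT = p.vant_hoff * p.R * p.T
        rows[:, ALPHA] = max(p.gamma_m * p.eta_m * iRT * 1.0, 1.0e-6)
        rows[:, NAI:CLE + 1] = p.gamma_m * p.rho_pump * 10.0
        rows[:, PHII] = rows[:, PHIE] = p.gamma_m * p.rho_pump * 10.0
        if self.scenario.compartmental_flow:
            # typical divergence of a superficial flux
            kappa = max(p.kappa_i, p.kappa_e)
            rows[:, PE] = max(kappa * p.K_m * 0.4 / self.dx ** 2, 1.0e-8)
            rows[-1, PE] = 1.0e3  # Dirichlet row, Pa
        else:
            rows[:, PE] = 1.0e3
        s[-1] = 1.0e-2  # mean phi_e, V
        return s

    # ------------------------------------------------------------- FD Jacobian

    def _build_coloring(self) -> None:
        n = self.n
        rows_per_color, cols_per_color, eps_per_color = [], [], []
        for color in range(30):
            j0, f = divmod(color, 10)
            nodes = np.arange(j0, n, 3)
            cols = 10 * nodes + f
            row_blocks = []
            col_repeat = []
            for node, c in zip(nodes, cols):
                lo, hi = max(node - 1, 0), min(node + 1, n - 1)
                rr = np.arange(10 * lo, 10 * (hi + 1))
                row_blocks.append(rr)
                col_repeat.append(np.full(rr.size, c))
            rows_per_color.append(np.concatenate(row_blocks))
            cols_per_color.append(np.concatenate(col_repeat))
            eps_per_color.append(self.newton.fd_eps * _FIELD_TYPICAL[f])
        self._colors = list(zip(rows_per_color, cols_per_color, eps_per_color))
        # analytic extras: c_e column (d r_phi_e / d c_e = 1) and the
        # zero-mean constraint row (d r / d phi_e,j = V_j / L)
        ce_rows = 10 * np.arange(n) + PHIE
        ce_cols = np.full(n, 10 * n)
        mean_rows = np.full(n, 10 * n)
        mean_cols = 10 * np.arange(n) + PHIE
        self._fixed_rows = np.concatenate([ce_rows, mean_rows])
        self._fixed_cols = np.concatenate([ce_cols, mean_cols])
        self._fixed_data = np.concatenate(
            [np.ones(n), self.volumes / self.domain.L])
        self._all_rows = np.concatenate(
            [np.concatenate(rows_per_color), self._fixed_rows])
        self._all_cols = np.concatenate(
            [np.concatenate(cols_per_color), self._fixed_cols])

    def jacobian(self, x: np.ndarray, x_old: np.ndarray,
                 t_new: float, dt: float) -> "coo_matrix":
        r0 = self.residual(x, x_old, t_new, dt)
        data_blocks = []
        for rows, cols, eps in self._colors:
            xp = x.copy()
            unique_cols = np.unique(cols)
            xp[unique_cols] += eps
            rp = self.residual(xp, x_old, t_new, dt)
            dr = (rp - r0) / eps
            data_blocks.append(dr[rows])
        data = np.concatenate(data_blocks + [self._fixed_data])
        J = coo_matrix((data, (self._all_rows, self._all_cols)),
                       shape=(self.n_dof, self.n_dof))
        return J

    def _factorize(self, x, x_old, t_new, dt) -> None:
        J = self.jacobian(x, x_old, t_new, dt).tocsr()
        # row/column equilibration tames the ~1e-14..1e6 coefficient spread
        Js = J.multiply(self._row_scale_inv[:, None]).tocsc()
        Js = Js.multiply(self._col_scale[None, :]).tocsc()
        self._lu = splu(Js)
        self._refresh_pending = False

    # ------------------------------------------------------------------ Newton

    def _scaled_norm(self, r: np.ndarray) -> float:
        return float(np.max(np.abs(r * self._row_scale_inv)))

    def advance(self, x_old: np.ndarray, t_new: float, dt: float) -> tuple[np.ndarray, int]:
        """One backward-Euler step; returns (x_new, newton_iterations)."""
        nt = self.newton
        x = x_old.copy()
        r = self.residual(x, x_old, t_new, dt)
        rn = self._scaled_norm(r)
        refreshes = 0
        for it in range(nt.max_iter):
            if rn < nt.tol:
                if it > nt.stale_iter_limit:
                    self._refresh_pending = True
                return x, it
            if self._lu is None or self._refresh_pending or it == nt.stale_iter_limit:
                if refreshes >= nt.max_refresh and self._lu is not None:
                    pass  # keep the current factorization
                else:
                    self._factorize(x, x_old, t_new, dt)
                    refreshes += 1
            dx = self._col_scale * self._lu.solve(-(r * self._row_scale_inv))
            # damped update keeping the state in bounds and the residual finite
            lam, accepted = 1.0, False
            while lam >= 1.0 / 256.0:
                try:
                    x_try = x + lam * dx
                    r_try = self.residual(x_try, x_old, t_new, dt)
                except StateBoundsError:
                    lam *= 0.5
                    continue
                rn_try = self._scaled_norm(r_try)
                # full Newton steps may transiently raise this norm; accept
                # mild growth at lam=1, require decrease once damping
                if np.isfinite(rn_try) and (rn_try < (1.0 - 1.0e-4) * rn
                                            or (lam == 1.0 and rn_try < 2.0 * rn)):
                    x, r, rn = x_try, r_try, rn_try
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                if refreshes < nt.max_refresh:
                    self._factorize(x, x_old, t_new, dt)
                    refreshes += 1
                    continue
                break
        if rn < nt.tol:
            return x, nt.max_iter
        self._refresh_pending = True
        raise NewtonDivergenceError(
            f"Newton stalled at t={t_new:.6g}, dt={dt:.3g}: scaled residual {rn:.3e}")

    def step_with_substepping(self, x_old: np.ndarray, t_old: float,
                              dt: float, depth: int = 0) -> tuple[np.ndarray, int]:
        """Advance by dt, halving the step on Newton failure (bounded retries)."""
        try:
            return self.advance(x_old, t_old + dt, dt)
        except NewtonDivergenceError:
            if depth >= self.newton.max_dt_halvings:
                raise
            x_mid, n1 = self.step_with_substepping(x_old, t_old, 0.5 * dt, depth + 1)
            x_new, n2 = self.step_with_substepping(x_mid, t_old + 0.5 * dt, 0.5 * dt, depth + 1)
            return x_new, n1 + n2


# ------------------------------------------------------------------ simulation

@dataclass
class SimulationResult:
    """Checkpointed states of one run plus everything needed to post-process."""

    config: RunConfig
    domain: Domain1D
    params: ModelParameters
    scenario: ScenarioSpec
    protocol: StimulusProtocol
    frozen: FrozenMembrane
    anions: ImmobileAnions
    times: np.ndarray            # (T,)
    fields: np.ndarray           # (T, n_nodes, 10)
    c_e: np.ndarray              # (T,)
    baseline: TissueState
    newton_iterations: np.ndarray

    def index_at(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1.0e-9 + 1.0e-6 * max(1.0, abs(t)):
            raise KeyError(f"time {t} not stored; nearest is {self.times[i]}")
        return i

    def state_at(self, t: float) -> TissueState:
        i = self.index_at(t)
        m = self.fields[i]
        return TissueState(t=float(self.times[i]),
                           **{f: m[:, j].copy() for j, f in enumerate(FIELD_NAMES)},
                           c_e=float(self.c_e[i]))

    def system(self) -> DiscreteSystem:
        return DiscreteSystem(self.domain, self.params, self.scenario,
                              self.protocol, self.frozen, self.anions)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py
        from dataclasses import asdict
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("fields", data=self.fields)
            fh.create_dataset("c_e", data=self.c_e)
            fh.create_dataset("newton_iterations", data=self.newton_iterations)
            fh.attrs["field_names"] = list(FIELD_NAMES)
            fh.attrs["scenario"] = self.scenario.tag
            fh.attrs["waveform"] = self.protocol.waveform
            for k, v in asdict(self.params).items():
                fh.attrs[f"param_{k}"] = v
            for k in ("L", "N", "L1", "L2"):
                fh.attrs[f"domain_{k}"] = getattr(self.domain, k)
            for k, v in (("z_0", self.anions.z_0), ("a_i", self.anions.a_i),
                         ("a_e", self.anions.a_e)):
                fh.attrs[f"anion_{k}"] = v


def _initial_state(config: RunConfig, params: ModelParameters,
                   domain: Domain1D) -> TissueState:
    if config.init == "table3":
        return default_initial_state(params, domain, config.initial_concentrations)
    if config.init == "steady":
        from .calibration import self_consistent_baseline
        c = self_consistent_baseline(params, seed=config.initial_concentrations)
        return default_initial_state(params, domain, c)
    raise ValueError(f"unknown init mode {config.init!r}")


def build_system(config: RunConfig,
                 params: ModelParameters | None = None
                 ) -> tuple[DiscreteSystem, TissueState]:
    """Assemble the discrete system and its initial state for a run config."""
    params = params or ModelParameters()
    domain = build_domain(config.L, config.N, config.L1, config.L2)
    scenario = ScenarioSpec.from_tag(config.scenario)
    j_in = params.j_in(scenario.tag) if config.j_in is None else config.j_in
    protocol = StimulusProtocol(waveform=config.stimulus, j_in=j_in,
                                t_on=config.t_on, t_off=config.t_off,
                                phase_at_onset=config.phase_at_onset)
    state0 = _initial_state(config, params, domain)
    c0 = {name: float(getattr(state0, name)[0])
          for name in ("na_i", "na_e", "k_i", "k_e", "cl_i", "cl_e")}
    c0["alpha_i"] = float(state0.alpha_i[0])
    frozen = FrozenMembrane.from_concentrations(params, c0)
    anions = solve_immobile_anions(params, c0, alpha_i_init=c0["alpha_i"])
    system = DiscreteSystem(domain, params, scenario, protocol, frozen,
                            anions, config.newton)
    return system, state0


def run_simulation(config: RunConfig,
                   params: ModelParameters | None = None,
                   progress: bool = False) -> SimulationResult:
    """Run one scenario and return checkpointed states.

    States are stored every ``config.output_dt`` of simulated time (plus the
    final time).  The run is fully deterministic.
    """
    system, state0 = build_system(config, params)
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    if abs(n_steps * dt - config.t_end) > 1e-9 * max(1.0, config.t_end):
        raise ValueError("t_end must be an integer multiple of dt")
    stride = max(1, int(round(config.output_dt / dt)))

    x = state0.to_vector()
    times, snaps, ces, iters = [0.0], [system._unpack(x).copy()], [x[-1]], []
    pe_warned = False
    for k in range(1, n_steps + 1):
        t_old = (k - 1) * dt
        x, n_it = system.step_with_substepping(x, t_old, dt)
        iters.append(n_it)
        if k % stride == 0 or k == n_steps:
            m = system._unpack(x).copy()
            times.append(k * dt)
            snaps.append(m)
            ces.append(x[-1])
            if not pe_warned:
                pe_warned = _peclet_warning(system, m)
            if progress:
                print(f"  t = {k * dt:8.2f} s  (newton {n_it})")

    return SimulationResult(
        config=config, domain=system.domain, params=system.params,
        scenario=system.scenario, protocol=system.protocol,
        frozen=system.frozen, anions=system.anions,
        times=np.array(times), fields=np.array(snaps), c_e=np.array(ces),
        baseline=state0, newton_iterations=np.array(iters))


def _peclet_warning(system: DiscreteSystem, m: np.ndarray) -> bool:
    p = system.params
    _, vel = system.flux_components(m)
    u_max = max(np.max(np.abs(vel.u_i)), np.max(np.abs(vel.u_e)), 0.0)
    D_eff = min(p.D_Na, p.D_K, p.D_Cl) / max(p.lambda_i, p.lambda_e) ** 2
    peclet = u_max * system.dx / D_eff
    if peclet > 1.0:
        warnings.warn(f"cell Peclet number {peclet:.2f} > 1; central advection "
                      "may oscillate", RuntimeWarning, stacklevel=3)
        return True
    return False


def convergence_study(Ns=(25, 50, 100, 200), dts=(1.0, 1.0e-1, 1.0e-2),
                      scenario: str = "M1", t_end: float = 20.0,
                      params: ModelParameters | None = None):
    """Grid/time-step refinement table for the M1 constant-stimulus run.

    For each (N, dt) the run is advanced to ``t_end`` and the peak ECS
    superficial fluid velocity (um/min) and peak [K+]_e (mM) are recorded.
    """
    import pandas as pd

    records = []
    for dt in dts:
        for N in Ns:
            cfg = RunConfig(scenario=scenario, N=N, dt=dt, t_end=t_end,
                            output_dt=t_end)
            res = run_simulation(cfg, params)
            m = res.fields[res.index_at(t_end)]
            sys_ = res.system()
            _, vel = sys_.flux_components(m)
            records.append({
                "N": N, "dt": dt,
                "max_superficial_ue_um_per_min":
                    float(np.max(np.abs(vel.superficial_e))) * M_PER_S_TO_UM_PER_MIN,
                "max_K_e_mM": float(np.max(m[:, KE])),
            })
    return pd.DataFrame.from_records(records)
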