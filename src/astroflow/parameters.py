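"""Physical constants, model parameters, and the 1D tissue domain.

The model describes homogenized brain tissue between two blood vessels as a
1D domain of length ``L`` (default 300 um) containing two overlapping
compartments: an astrocyte syncytium (ICS, subscript ``i``) and the
extracellular space (ECS, subscript ``e``).  Neurons occupy a fixed 40% of
tissue volume and are represented only implicitly, through K+/Na+ input and
decay fluxes in an input zone ``[L1, L2]``.

Units are strict SI throughout the package: concentrations in mol/m^3
(numerically identical to mM), pressures in Pa, potentials in V, lengths in
m, time in s.  Unit conversions happen only in :mod:`astroflow.diagnostics`
and at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "NEURON_FRACTION",
    "ModelParameters",
    "Domain1D",
    "build_domain",
    "membrane_stiffness",
    "load_parameters",
]

#: Fixed volume fraction occupied by neurons; ICS + ECS share the remainder,
#: alpha_i + alpha_e = 1 - NEURON_FRACTION at every point and time.
NEURON_FRACTION = 0.4

#: Ion species order used for all per-species arrays in the package.
SPECIES = ("Na", "K", "Cl")

#: Valences of (Na+, K+, Cl-).
VALENCES = (1.0, 1.0, -1.0)


def membrane_stiffness(youngs_modulus: float = 413.0, poisson_ratio: float = 0.47) -> float:
    """Bulk modulus K_m = E / (3 (1 - 2 nu)) of the astrocyte membrane (Pa).

    Defaults are the mean Young's modulus of hippocampal astrocytes measured
    over 30-200 Hz deformations (413 Pa) and a Poisson ratio of 0.47, which
    give K_m = 2.294e3 Pa.
    """
    if not 0 <= poisson_ratio < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return youngs_modulus / (3.0 * (1.0 - 2.0 * poisson_ratio))


@dataclass
class ModelParameters:
    """All physical, membrane, and stimulus parameters of the tissue model.

    Defaults reproduce the reference parameterization.  Attribute names
    follow the symbols used in the field: ``g_*`` are membrane conductances,
    ``kappa_*`` compartmental (Darcy) permeabilities, ``eta_m`` the lumped
    membrane water permeability, ``K_m`` the membrane stiffness.
    """

    # fundamental constants
    F: float = 96485.3          # Faraday constant, C/mol
    R: float = 8.314            # gas constant, J/(mol K)
    T: float = 310.15           # temperature, K
    vant_hoff: float = 1.0      # van't Hoff factor i (dimensionless)

    # diffusion and geometry
    D_Na: float = 1.33e-9       # m^2/s
    D_K: float = 1.96e-9        # m^2/s
    D_Cl: float = 2.03e-9       # m^2/s
    lambda_i: float = 3.2       # ICS tortuosity
    lambda_e: float = 1.6       # ECS tortuosity
    gamma_m: float = 8.0e6      # membrane area per tissue volume, 1/m

    # membrane electrophysiology
    g_Na: float = 1.0           # S/m^2
    g_K: float = 16.96          # S/m^2
    g_Cl: float = 0.5           # S/m^2
    rho_pump: float = 1.12e-6   # max Na/K pump rate, mol/(m^2 s)
    P_Nai: float = 10.0         # pump [Na+]_i threshold, mol/m^3
    P_Ke: float = 1.5           # pump [K+]_e threshold, mol/m^3

    # mechanics and fluid
    eta_m: float = 8.14e-14     # membrane water permeability, m/(Pa s)
    K_m: float = field(default_factory=membrane_stiffness)  # Pa
    kappa_i: float = 1.8375e-14  # ICS permeability, m^2/(Pa s)
    kappa_e: float = 1.8375e-14  # ECS permeability, m^2/(Pa s)
    eps_r: float = 84.6         # ECS relative permittivity
    eps_0: float = 8.85e-12     # vacuum permittivity, F/m
    zeta: float = -22.8e-3      # zeta potential, V
    mu: float = 6.4e-4          # water viscosity, Pa s
    p_m_init: float = 1.0e3     # initial transmembrane pressure difference, Pa

    # stimulus amplitudes per fluid scenario, mol/(m^2 s)
    j_in_M0: float = 8.28e-7
    j_in_M1: float = 8.0e-7
    j_in_M2: float = 9.15e-7
    j_in_M3: float = 9.05e-7

    k_dec: float = 2.9e-8       # [K+]_e decay factor, m/s

    # valences
    z_Na: float = 1.0
    z_K: float = 1.0
    z_Cl: float = -1.0

    def __post_init__(self) -> None:
        positive = [f.name for f in fields(self)
                    if f.name not in ("zeta", "z_Na", "z_K", "z_Cl")]
        for name in positive:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if self.zeta > 0:
            raise ValueError("zeta potential is negative for brain ECS")

    # --- derived quantities -------------------------------------------------

    @property
    def psi(self) -> float:
        """Thermal voltage RT/F (V), ~26.7 mV at 310.15 K."""
        return self.R * self.T / self.F

    @property
    def neuron_fraction(self) -> float:
        """Fixed neuronal volume fraction (read-only model constant)."""
        return NEURON_FRACTION

    @property
    def total_cell_fraction(self) -> float:
        """alpha_i + alpha_e = 1 - neuron fraction."""
        return 1.0 - NEURON_FRACTION

    @property
    def diffusion(self) -> np.ndarray:
        return np.array([self.D_Na, self.D_K, self.D_Cl])

    @property
    def valences(self) -> np.ndarray:
        return np.array([self.z_Na, self.z_K, self.z_Cl])

    def j_in(self, scenario: str) -> float:
        """Default constant input flux amplitude for a fluid scenario tag."""
        try:
            return getattr(self, f"j_in_{scenario}")
        except AttributeError:
            raise KeyError(f"no default input amplitude for scenario {scenario!r}") from None

    def with_updates(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Domain1D:
    """Uniform 1D grid with an input zone [L1, L2].

    ``N`` is the number of cells; unknown fields live on the ``N + 1`` nodes.
    The input-zone indicator is represented by per-node weights equal to the
    overlap fraction of each node's control volume with [L1, L2], so the
    total injected flux integrates to exactly (L2 - L1) * j_in on any grid.
    """

    L: float
    N: int
    L1: float
    L2: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("domain length L must be positive")
        if self.N < 2:
            raise ValueError("need at least 2 cells")
        if not (0 <= self.L1 < self.L2 <= self.L):
            raise ValueError("input zone must satisfy 0 <= L1 < L2 <= L")

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.N + 1)

    @property
    def faces(self) -> np.ndarray:
        """Midpoints between nodes (N of them), where fluxes are evaluated."""
        x = self.nodes
        return 0.5 * (x[1:] + x[:-1])

    @property
    def volumes(self) -> np.ndarray:
        """Control-volume widths per node: dx/2 at the two ends, dx inside."""
        v = np.full(self.N + 1, self.dx)
        v[0] = v[-1] = 0.5 * self.dx
        return v

    @property
    def zone_weights(self) -> np.ndarray:
        """Per-node overlap fraction of the control volume with [L1, L2]."""
        x, h = self.nodes, self.dx
        lo = np.maximum(x - 0.5 * h, self.L1)
        hi = np.minimum(x + 0.5 * h, self.L2)
        # end control volumes are half-width
        lo = np.maximum(lo, -0.0)
        hi = np.minimum(hi, self.L)
        return np.clip(hi - lo, 0.0, None) / self.volumes

    def in_zone(self, x: np.ndarray) -> np.ndarray:
        return (x >= self.L1) & (x <= self.L2)

    def node_index(self, x: float) -> int:
        """Index of the node nearest to coordinate ``x``."""
        return int(round(x / self.dx))


def build_domain(L: float = 3.0e-4, N: int = 400,
                 L1: float = 1.35e-4, L2: float = 1.65e-4) -> Domain1D:
    """Construct the tissue domain; defaults give the 300 um domain with a
    30 um input zone centered at 150 um."""
    return Domain1D(L=float(L), N=int(N), L1=float(L1), L2=float(L2))


_PARAM_NAMES = {f.name for f in fields(ModelParameters)}


def load_parameters(path: str | Path) -> ModelParameters:
    """Load parameters from a YAML file of ``symbol: value`` pairs.

    Keys must be attribute names of :class:`ModelParameters`; unknown keys
    are rejected to catch typos in configuration files.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a mapping of symbol: value")
    unknown = set(raw) - _PARAM_NAMES
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in raw.items()})
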