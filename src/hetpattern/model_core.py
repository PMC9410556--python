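"""Core model types and deterministic (drift) dynamics.

The model tracks six molecular species in every cell of a one-dimensional
cyanobacterial filament:

``R``  HetR monomer (master activator of differentiation),
``A``  PatA (enhances post-transcriptional activation of HetR),
``S``  combined PatS + PatX inhibitor precursors (vegetative cells only),
``N``  HetN inhibitor precursor (heterocysts only),
``I``  the mobile ERGSGR hexapeptide inhibitor, produced from S and N at the
       cell membrane during export to a neighbour,
``G``  fixed-nitrogen products (heterocysts only), which also inhibit HetR.

Concentrations are per-cell, well-mixed values in arbitrary units; time is in
hours and cell sizes in micrometres.  ``I`` and ``G`` move between neighbouring
cells; the two terminal cells additionally leak both to the exterior at a
reduced rate ``d_border * d_I`` (resp. ``d_G``), the mechanism behind terminal
heterocysts in the *patA* mutant.

This module holds the domain types and the exact deterministic right-hand side
split into production and degradation sums (the split feeds the Langevin noise
amplitude in :mod:`hetpattern.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import List, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "ModelParameters",
    "DimerKinetics",
    "CellState",
    "FilamentState",
    "DriftDecomposition",
    "regulatory_activity",
    "hetf_equilibrium",
    "mu_from_kinetics",
    "fr_from_constants",
    "compute_drift",
    "isolated_species_decay",
    "wild_type_parameters",
]

#: Species order used by every (n_cells, 6) concentration array.
SPECIES = ("R", "A", "S", "N", "I", "G")
R_IDX, A_IDX, S_IDX, N_IDX, I_IDX, G_IDX = range(6)


@dataclass(frozen=True)
class DimerKinetics:
    """Fast HetR dimerization/activation kinetics.

    Only used to derive the lumped constants ``mu`` (nonlinear HetR
    degradation) and ``F_R`` (activation scale); the stepper never sees these
    rates directly.
    """

    k_b: float = 1.0  # monomer binding rate
    k_u: float = 0.0  # unbinding rate
    alpha_d: float = 1.0  # dimer degradation rate
    K_R: float = 2.0  # dimerization equilibrium constant
    K_F: float = 1.0  # HetF-activation equilibrium constant

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"DimerKinetics.{f.name} must be finite and >= 0, got {v}")


# fields that may legitimately be zero (mutant overlays / no leakage)
_NONNEG_FIELDS = frozenset(
    {"d_border", "beta_F", "rho_S", "rho_N", "rho_A", "rho_G", "beta_R", "mu", "F_R"}
)


@dataclass(frozen=True)
class ModelParameters:
    """Every rate, affinity and threshold of the filament model.

    Units: production rates conc/h, degradation and transport rates 1/h,
    ``mu`` 1/conc, ``F_R`` 1/conc**hill_exponent, ``tau_A``/``K_d``/``K_G``/``T_R``
    conc, ``M_R`` conc*h, ``T_min`` h, ``lam`` um/h, ``M_Lambda`` um,
    ``d_border`` dimensionless.

    By default construction enforces the commitment convention
    ``M_R == 12 * T_R`` (holding HetR at the threshold for 12 h commits the
    cell); pass ``enforce_commitment_convention=False`` to override.
    """

    beta_R: float
    rho_R: float
    rho_A: float
    rho_S: float
    rho_N: float
    rho_G: float
    alpha_R: float
    alpha_A: float
    alpha_S: float
    alpha_N: float
    alpha_I: float
    alpha_G: float
    alpha_F: float
    beta_F: float
    mu: float
    c_S: float
    c_N: float
    d_I: float
    d_G: float
    d_border: float
    F_R: float
    tau_A: float
    K_d: float
    K_G: float
    hill_exponent: int
    T_R: float
    M_R: float
    T_min: float
    lam: float
    M_Lambda: float
    enforce_commitment_convention: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "enforce_commitment_convention":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"ModelParameters.{f.name} must be finite, got {v}")
            if f.name in _NONNEG_FIELDS:
                if v < 0:
                    raise ValueError(f"ModelParameters.{f.name} must be >= 0, got {v}")
            elif f.name == "hill_exponent":
                if v not in (2, 4):
                    raise ValueError(f"hill_exponent must be 2 or 4, got {v}")
            elif v <= 0:
                raise ValueError(f"ModelParameters.{f.name} must be > 0, got {v}")
        if self.enforce_commitment_convention and not np.isclose(self.M_R, 12.0 * self.T_R):
            raise ValueError(
                f"M_R = {self.M_R} violates the default convention M_R = 12*T_R "
                f"(T_R = {self.T_R}); pass enforce_commitment_convention=False to override"
            )

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        """Flat symbol-name -> value mapping (config serialization)."""
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "enforce_commitment_convention"}
        d["hill_exponent"] = int(d["hill_exponent"])
        return d

    @classmethod
    def from_dict(cls, d: dict, *, enforce_commitment_convention: bool = True) -> "ModelParameters":
        known = {f.name for f in fields(cls)} - {"enforce_commitment_convention"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**d, enforce_commitment_convention=enforce_commitment_convention)


@dataclass
class CellState:
    """One cell: concentrations, size, identity and commitment bookkeeping."""

    R: float = 0.0
    A: float = 0.0
    S: float = 0.0
    N: float = 0.0
    I: float = 0.0
    G: float = 0.0
    Lambda: float = 2.0  # size, um
    is_heterocyst: bool = False
    T_R_cell: float = 1.0  # cell-specific commitment threshold (conc)
    M_R_cell: float = 12.0  # cell-specific commitment integral (conc*h)
    M_Lambda_cell: float = 4.0  # cell-specific maximum size (um)
    commit_integral: float = 0.0
    commit_clock: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R", "A", "S", "N", "I", "G"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        if self.Lambda <= 0:
            raise ValueError("cell size must be > 0")
        if self.commit_integral < 0 or self.commit_clock < 0:
            raise ValueError("commitment bookkeeping must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([self.R, self.A, self.S, self.N, self.I, self.G])


class FilamentState:
    """Ordered sequence of cells plus the simulation clock.

    Internally a struct-of-arrays for efficient vectorized stepping; the
    ``cells`` property exposes the per-cell view.
    """

    __slots__ = (
        "conc",
        "size",
        "is_heterocyst",
        "T_R_cell",
        "M_R_cell",
        "M_Lambda_cell",
        "commit_integral",
        "commit_clock",
        "time",
    )

    def __init__(
        self,
        conc: np.ndarray,
        size: np.ndarray,
        is_heterocyst: np.ndarray,
        T_R_cell: np.ndarray,
        M_R_cell: np.ndarray,
        M_Lambda_cell: np.ndarray,
        commit_integral: np.ndarray,
        commit_clock: np.ndarray,
        time: float = 0.0,
    ) -> None:
        conc = np.asarray(conc, dtype=float)
        n = conc.shape[0]
        if n < 1 or conc.shape != (n, 6):
            raise ValueError("conc must have shape (n_cells, 6) with n_cells >= 1")
        self.conc = conc
        self.size = np.asarray(size, dtype=float)
        self.is_heterocyst = np.asarray(is_heterocyst, dtype=bool)
        self.T_R_cell = np.asarray(T_R_cell, dtype=float)
        self.M_R_cell = np.asarray(M_R_cell, dtype=float)
        self.M_Lambda_cell = np.asarray(M_Lambda_cell, dtype=float)
        self.commit_integral = np.asarray(commit_integral, dtype=float)
        self.commit_clock = np.asarray(commit_clock, dtype=float)
        self.time = float(time)
        for name in self.__slots__[1:-1]:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")

    @classmethod
    def from_cells(cls, cells: Sequence[CellState], time: float = 0.0) -> "FilamentState":
        if len(cells) < 1:
            raise ValueError("a filament needs at least one cell")
        return cls(
            conc=np.array([c.concentrations for c in cells]),
            size=np.array([c.Lambda for c in cells]),
            is_heterocyst=np.array([c.is_heterocyst for c in cells]),
            T_R_cell=np.array([c.T_R_cell for c in cells]),
            M_R_cell=np.array([c.M_R_cell for c in cells]),
            M_Lambda_cell=np.array([c.M_Lambda_cell for c in cells]),
            commit_integral=np.array([c.commit_integral for c in cells]),
            commit_clock=np.array([c.commit_clock for c in cells]),
            time=time,
        )

    @property
    def n_cells(self) -> int:
        return self.conc.shape[0]

    def __len__(self) -> int:
        return self.n_cells

    @property
    def n_heterocysts(self) -> int:
        return int(self.is_heterocyst.sum())

    @property
    def total_length(self) -> float:
        """Total filament length (um)."""
        return float(self.size.sum())

    @property
    def cells(self) -> List[CellState]:
        return [
            CellState(
                *self.conc[j],
                Lambda=self.size[j],
                is_heterocyst=bool(self.is_heterocyst[j]),
                T_R_cell=self.T_R_cell[j],
                M_R_cell=self.M_R_cell[j],
                M_Lambda_cell=self.M_Lambda_cell[j],
                commit_integral=self.commit_integral[j],
                commit_clock=self.commit_clock[j],
            )
            for j in range(self.n_cells)
        ]

    def copy(self) -> "FilamentState":
        return FilamentState(
            self.conc.copy(),
            self.size.copy(),
            self.is_heterocyst.copy(),
            self.T_R_cell.copy(),
            self.M_R_cell.copy(),
            self.M_Lambda_cell.copy(),
            self.commit_integral.copy(),
            self.commit_clock.copy(),
            self.time,
        )


@dataclass
class DriftDecomposition:
    """Right-hand side of the dynamics split into P (>=0) and D (<=0) sums.

    ``production + degradation`` reassembles the full deterministic drift; the
    Langevin noise amplitude uses ``production + |degradation|``.
    Shapes: (n_cells, 6) in :data:`SPECIES` order.
    """

    production: np.ndarray
    degradation: np.ndarray

    @property
    def drift(self) -> np.ndarray:
        return self.production + self.degradation

    @property
    def noise_intensity(self) -> np.ndarray:
        """P + |D|, the per-cell per-species Langevin variance scale."""
        return self.production + np.abs(self.degradation)


def regulatory_activity(R, A, I, G, params: ModelParameters):
    """HetR-dependent promoter activity g(R, A, I, G) in [0, 1).

    The equilibrium of fast HetR dimerization, HetF/PatA-mediated activation
    and inhibition by the hexapeptide (I) and fixed nitrogen (G):

        g = F_R R^h (1 + A/tau_A) / [1 + F_R R^h (1 + A/tau_A)
                                       + I^2/K_d^2 + G/K_G]

    with h the HetR oligomer order (2 for dimer binding, 4 for the tetramer
    variant).  Strictly increasing in R and A, strictly decreasing in I and G.
    Accepts scalars or arrays (broadcast).
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    I = np.asarray(I, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(R < 0) or np.any(A < 0) or np.any(I < 0) or np.any(G < 0):
        raise ValueError("regulatory_activity requires non-negative concentrations")
    # extreme states proposed during calibration can overflow the inhibition
    # term; the limit g -> 0 is correct, so silence the overflow warning
    with np.errstate(over="ignore"):
        act = params.F_R * R ** params.hill_exponent * (1.0 + A / params.tau_A)
        out = act / (1.0 + act + (I / params.K_d) ** 2 + G / params.K_G)
    if out.ndim == 0:
        return float(out)
    return out


def hetf_equilibrium(beta_F: float, alpha_F: float) -> float:
    """Equilibrium HetF concentration F_eq = beta_F / alpha_F."""
    if alpha_F <= 0:
        raise ValueError("alpha_F must be > 0")
    if beta_F < 0:
        raise ValueError("beta_F must be >= 0")
    return beta_F / alpha_F


def mu_from_kinetics(kin: DimerKinetics, alpha_R: float) -> float:
    """Nonlinear HetR degradation coefficient from dimerization kinetics.

    mu = (k_b / alpha_R) * (1 - k_u / (k_u + alpha_d))
    """
    if alpha_R <= 0:
        raise ValueError("alpha_R must be > 0")
    if kin.k_u + kin.alpha_d <= 0:
        raise ValueError("k_u + alpha_d must be > 0")
    return (kin.k_b / alpha_R) * (1.0 - kin.k_u / (kin.k_u + kin.alpha_d))


def fr_from_constants(F_eq: float, kin: DimerKinetics) -> float:
    """Lumped activation constant F_R = F_eq * K_F * K_R / 2."""
    if F_eq < 0:
        raise ValueError("F_eq must be >= 0")
    return F_eq * kin.K_F * kin.K_R / 2.0


def compute_drift(filament: FilamentState, params: ModelParameters) -> DriftDecomposition:
    """Deterministic right-hand side for every cell and species.

    Interior cells couple to both neighbours through the conversion fluxes
    (c_S, c_N) and the transport terms (d_I, d_G); the first and last cells
    have a single neighbour and leak I and G to the exterior at rate
    ``d_border * d_I`` (resp. ``d_G``).  A single-cell filament leaks on both
    faces and receives no conversion influx.

    PatS is produced only in vegetative cells; HetN and fixed nitrogen only in
    heterocysts.  Heterocysts otherwise keep evolving R, A, I and G.
    """
    n = filament.n_cells
    if n < 1:
        raise ValueError("empty filament")
    conc = filament.conc
    R, A, S, N, I, G = (conc[:, k] for k in range(6))
    het = filament.is_heterocyst.astype(float)
    veg = 1.0 - het
    p = params

    g = regulatory_activity(R, A, I, G, p)

    P = np.zeros((n, 6))
    D = np.zeros((n, 6))

    P[:, R_IDX] = p.beta_R + g * p.rho_R
    D[:, R_IDX] = -p.alpha_R * R * (1.0 + 2.0 * p.mu * R)

    P[:, A_IDX] = g * p.rho_A
    D[:, A_IDX] = -p.alpha_A * A

    P[:, S_IDX] = veg * g * p.rho_S
    D[:, S_IDX] = -(2.0 * p.c_S + p.alpha_S) * S

    P[:, N_IDX] = het * p.rho_N
    D[:, N_IDX] = -(2.0 * p.c_N + p.alpha_N) * N

    # neighbour sums (zero beyond the filament ends)
    def nbr_sum(x: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        out[1:] += x[:-1]
        out[:-1] += x[1:]
        return out

    # outgoing transport coefficient: interior faces pay d, each exterior face
    # pays d_border*d
    def out_coeff(d: float) -> np.ndarray:
        out = np.full(n, 2.0 * d)
        if n == 1:
            out[0] = 2.0 * p.d_border * d
        else:
            out[0] = d * (1.0 + p.d_border)
            out[-1] = d * (1.0 + p.d_border)
        return out

    P[:, I_IDX] = p.c_S * nbr_sum(S) + p.c_N * nbr_sum(N) + p.d_I * nbr_sum(I)
    D[:, I_IDX] = -(out_coeff(p.d_I) + p.alpha_I) * I

    P[:, G_IDX] = het * p.rho_G + p.d_G * nbr_sum(G)
    D[:, G_IDX] = -(out_coeff(p.d_G) + p.alpha_G) * G

    return DriftDecomposition(production=P, degradation=D)


def isolated_species_decay(x0: float, loss_rate: float, t) -> float:
    """Closed-form linear decay x0 * exp(-loss_rate * t).

    Oracle for uncoupled species, e.g. HetN in a vegetative cell decays with
    loss rate 2*c_N + alpha_N.
    """
    if loss_rate < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("loss_rate and t must be >= 0")
    return x0 * np.exp(-loss_rate * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# wild-type preset

#: Fast-kinetics constants consistent with the wild-type F_R and mu below
#: (F_eq = beta_F/alpha_F = 1, F_R = F_eq*K_F*K_R/2, mu = (k_b/alpha_R)*(1 - k_u/(k_u+alpha_d))).
WILD_TYPE_KINETICS = DimerKinetics(k_b=0.125, k_u=0.0, alpha_d=1.0, K_R=2.0, K_F=2.0)

# Calibrated wild-type parameter set.  The concentration scale is set by the
# commitment threshold T_R = 1; the hard values M_Lambda = 4 um,
# lam = 0.08 um/h, T_min = 5 h and M_R = 12*T_R are fixed from filament growth
# and commitment-time data, the rest were calibrated against the wild-type and
# mutant pattern statistics (mean vegetative interval ~10 cells, ~10 %
# heterocysts at 24-72 h, terminal-only heterocysts with elevated uniform HetR
# in the patA background, no differentiation without HetF).
_WILD_TYPE = dict(
    beta_R=0.03,
    rho_R=1.2,
    rho_A=1.0,
    rho_S=4.0,
    rho_N=3.0,
    rho_G=10.0,
    alpha_R=0.25,
    alpha_A=0.5,
    alpha_S=0.2,
    alpha_N=0.1,
    alpha_I=0.4,
    alpha_G=0.7,
    alpha_F=1.0,
    beta_F=1.0,
    mu=0.5,
    c_S=0.4,
    c_N=0.3,
    d_I=20.0,
    d_G=6.0,
    d_border=1.0,
    F_R=2.0,
    tau_A=0.7,
    K_d=0.6,
    K_G=0.7,
    hill_exponent=2,
    T_R=1.0,
    M_R=12.0,
    T_min=5.0,
    lam=0.08,
    M_Lambda=4.0,
)


def wild_type_parameters(**overrides) -> ModelParameters:
    """The calibrated wild-type parameter set (optionally with overrides)."""
    d = dict(_WILD_TYPE)
    d.update(overrides)
    return ModelParameters(**d)
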