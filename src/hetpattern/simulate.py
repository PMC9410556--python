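"""Stochastic time evolution of a growing filament.

Euler–Maruyama (Itô) integration of the chemical Langevin dynamics, stochastic
cell growth with division, HetR-integral commitment tracking and mutant
overlays.  Each concentration x of cell i advances per step by

    dx = (P + D) dt + sqrt(Omega_phi * (P + |D|) * dt) * xi

with P/D the production/degradation sums from
:func:`hetpattern.model_core.compute_drift` and xi standard normal,
independent per cell and species.  Negative excursions are clipped to zero.

Cell sizes grow as dLambda = lam dt + lam sqrt(Omega_lambda dt) xi; a
vegetative cell that reaches its (cell-specific, Gaussian) maximum size splits
into two half-size cells with identical concentrations and freshly drawn
thresholds.  Heterocysts stop growing at their maximum size and never divide.

A vegetative cell commits to differentiation by integrating HetR while it
stays above the cell's threshold T_Rj; the integral resets whenever HetR dips
below threshold, and differentiation requires both the integral to reach M_Rj
and a minimum continuous time T_min above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .model_core import (
    SPECIES,
    CellState,
    FilamentState,
    ModelParameters,
    compute_drift,
)

__all__ = [
    "NoiseSettings",
    "MutantSpec",
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "MUTANTS",
    "mutant_by_name",
    "apply_mutant",
    "langevin_step",
    "grow_and_divide",
    "update_commitment",
    "initial_filament",
    "run_simulation",
]

# thresholds drawn from a Gaussian are clipped below at this fraction of the
# mean so that noise can never produce a non-positive threshold or size
_MIN_DRAW_FRACTION = 0.1


class SimulationError(RuntimeError):
    """Numerical blow-up or invalid state during a simulation."""


@dataclass(frozen=True)
class NoiseSettings:
    """Noise amplitudes and RNG seed.

    ``omega_phi`` scales the genetic (Langevin) noise and the variance of the
    per-cell commitment thresholds; ``omega_lambda`` scales growth noise and
    the variance of the per-cell maximum size.
    """

    omega_phi: float = 0.05
    omega_lambda: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_phi < 0 or self.omega_lambda < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class MutantSpec:
    """Multiplicative loss-of-function overlay on the wild-type parameters.

    Knock-outs zero the corresponding production rate, except patS whose
    deletion keeps 10% of the combined PatS+PatX rate (the redundant patX
    contribution); conversely the patX deletion keeps 90%.  Factors compose by
    multiplication for double/triple mutants.
    """

    rho_S_factor: float = 1.0
    rho_N_factor: float = 1.0
    rho_A_factor: float = 1.0
    beta_F_factor: float = 1.0
    d_border_factor: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def combine(self, other: "MutantSpec") -> "MutantSpec":
        return MutantSpec(
            *(getattr(self, f.name) * getattr(other, f.name) for f in fields(self))
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Named mutant backgrounds.
MUTANTS: Dict[str, MutantSpec] = {
    "WT": MutantSpec(),
    "dpatS": MutantSpec(rho_S_factor=0.1),
    "dpatX": MutantSpec(rho_S_factor=0.9),
    "dpatSdpatX": MutantSpec(rho_S_factor=0.0),
    "dhetN": MutantSpec(rho_N_factor=0.0),
    "dpatA": MutantSpec(rho_A_factor=0.0),
    "dhetF": MutantSpec(beta_F_factor=0.0),
    "dpatAdhetN": MutantSpec(rho_A_factor=0.0, rho_N_factor=0.0),
    "dpatAdpatS": MutantSpec(rho_A_factor=0.0, rho_S_factor=0.1),
}

#: Overlay disabling all boundary leakage (composable with any background).
NO_BORDER_LEAK = MutantSpec(d_border_factor=0.0)


def mutant_by_name(name: str, no_border_leak: bool = False) -> MutantSpec:
    """Look up a mutant background, optionally with leakage disabled."""
    try:
        spec = MUTANTS[name]
    except KeyError:
        raise KeyError(f"unknown mutant {name!r}; known: {sorted(MUTANTS)}") from None
    return spec.combine(NO_BORDER_LEAK) if no_border_leak else spec


def apply_mutant(params: ModelParameters, mutant: MutantSpec) -> ModelParameters:
    """Return a parameter copy with the mutant factors applied.

    ``beta_F_factor`` also scales ``F_R``, since the lumped activation
    constant is proportional to the HetF equilibrium concentration
    (F_R = F_eq K_F K_R / 2 with F_eq = beta_F/alpha_F).
    """
    return params.replace(
        rho_S=params.rho_S * mutant.rho_S_factor,
        rho_N=params.rho_N * mutant.rho_N_factor,
        rho_A=params.rho_A * mutant.rho_A_factor,
        beta_F=params.beta_F * mutant.beta_F_factor,
        F_R=params.F_R * mutant.beta_F_factor,
        d_border=params.d_border * mutant.d_border_factor,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and recording settings."""

    dt: float = 0.01  # h
    t_end: float = 72.0  # h
    record_every: float = 1.0  # h
    n_initial_cells: int = 30
    initial_size_policy: str = "uniform"  # uniform on [M_Lambda/2, M_Lambda]
    initial_concentration_policy: str = "zero"  # nitrogen step-down state

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.record_every <= self.t_end):
            raise ValueError("need 0 < dt <= record_every <= t_end")
        if self.n_initial_cells < 1:
            raise ValueError("n_initial_cells must be >= 1")
        if self.initial_size_policy not in ("uniform", "half"):
            raise ValueError("initial_size_policy must be 'uniform' or 'half'")
        if self.initial_concentration_policy != "zero":
            raise ValueError("only the 'zero' initial concentration policy is defined")
        stride = self.record_every / self.dt
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("record_every must be an integer multiple of dt")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Trajectory:
    """Recorded filament snapshots plus full provenance."""

    times: List[float]
    snapshots: List[FilamentState]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def final(self) -> FilamentState:
        return self.snapshots[-1]

    def at_time(self, t: float) -> FilamentState:
        """Snapshot closest to time t (h)."""
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        return self.snapshots[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format per-cell table (one row per cell per snapshot)."""
        rows = []
        for t, snap in zip(self.times, self.snapshots):
            for j in range(snap.n_cells):
                rows.append(
                    (t, j, *snap.conc[j], snap.size[j], bool(snap.is_heterocyst[j]))
                )
        return pd.DataFrame(
            rows,
            columns=["time_h", "cell_index", *SPECIES, "size_um", "is_heterocyst"],
        )


# ---------------------------------------------------------------------------
# stepping kernels (in-place, used by run_simulation; the public operations
# below wrap them in copy-in/copy-out form)


def _check_finite(fil: FilamentState) -> None:
    if not np.all(np.isfinite(fil.conc)):
        bad = np.argwhere(~np.isfinite(fil.conc))[0]
        raise SimulationError(
            f"non-finite concentration at t={fil.time:.3f} h, "
            f"cell {bad[0]}, species {SPECIES[bad[1]]}"
        )


def _langevin_inplace(
    fil: FilamentState,
    params: ModelParameters,
    noise: NoiseSettings,
    dt: float,
    rng: np.random.Generator,
) -> None:
    d = compute_drift(fil, params)
    dx = d.drift * dt
    if noise.omega_phi > 0.0:
        amp = np.sqrt(noise.omega_phi * d.noise_intensity * dt)
        dx += amp * rng.standard_normal(fil.conc.shape)
    fil.conc += dx
    np.clip(fil.conc, 0.0, None, out=fil.conc)
    fil.time += dt
    _check_finite(fil)


def _commitment_inplace(fil: FilamentState, params: ModelParameters, dt: float) -> None:
    veg = ~fil.is_heterocyst
    R = fil.conc[:, 0]
    above = veg & (R >= fil.T_R_cell)
    below = veg & ~above
    fil.commit_integral[above] += R[above] * dt
    fil.commit_clock[above] += dt
    fil.commit_integral[below] = 0.0
    fil.commit_clock[below] = 0.0
    # tolerance absorbs float accumulation error in the running sums so a
    # threshold reached exactly on a step boundary is not delayed one step
    new = (
        veg
        & (fil.commit_integral >= fil.M_R_cell - 1e-9)
        & (fil.commit_clock >= params.T_min - 1e-9)
    )
    if np.any(new):
        fil.is_heterocyst[new] = True
        fil.commit_integral[new] = 0.0
        fil.commit_clock[new] = 0.0


def _draw_thresholds(
    n: int, params: ModelParameters, noise: NoiseSettings, rng: np.random.Generator
):
    """Fresh per-cell Gaussian thresholds (clipped away from zero)."""

    def draw(mean: float, omega: float) -> np.ndarray:
        x = rng.normal(mean, mean * np.sqrt(omega), size=n)
        return np.maximum(x, _MIN_DRAW_FRACTION * mean)

    T_R = draw(params.T_R, noise.omega_phi)
    M_R = draw(params.M_R, noise.omega_phi)
    M_L = draw(params.M_Lambda, noise.omega_lambda)
    return T_R, M_R, M_L


def _grow_divide_inplace(
    fil: FilamentState,
    params: ModelParameters,
    noise: NoiseSettings,
    dt: float,
    rng: np.random.Generator,
) -> None:
    n = fil.n_cells
    growth = np.full(n, params.lam * dt)
    if noise.omega_lambda > 0.0:
        growth += params.lam * np.sqrt(noise.omega_lambda * dt) * rng.standard_normal(n)
    het = fil.is_heterocyst
    fil.size += growth
    # heterocysts stop at their maximum size (and never shrink below it again)
    fil.size[het] = np.minimum(fil.size[het], fil.M_Lambda_cell[het])
    np.maximum(fil.size, 1e-9, out=fil.size)

    divide = (~het) & (fil.size >= fil.M_Lambda_cell)
    if not np.any(divide):
        return
    counts = np.where(divide, 2, 1)
    idx = np.repeat(np.arange(n), counts)
    daughters = np.repeat(divide, counts)  # True for both halves of a division
    fil.conc = fil.conc[idx]
    size = fil.size[idx]
    size[daughters] *= 0.5
    fil.size = size
    fil.is_heterocyst = fil.is_heterocyst[idx]
    T_R = fil.T_R_cell[idx]
    M_R = fil.M_R_cell[idx]
    M_L = fil.M_Lambda_cell[idx]
    k = int(daughters.sum())
    nT, nM, nL = _draw_thresholds(k, params, noise, rng)
    T_R[daughters] = nT
    M_R[daughters] = nM
    M_L[daughters] = nL
    fil.T_R_cell = T_R
    fil.M_R_cell = M_R
    fil.M_Lambda_cell = M_L
    ci = fil.commit_integral[idx]
    cc = fil.commit_clock[idx]
    ci[daughters] = 0.0
    cc[daughters] = 0.0
    fil.commit_integral = ci
    fil.commit_clock = cc


# ---------------------------------------------------------------------------
# public operations


def langevin_step(
    filament: FilamentState,
    params: ModelParameters,
    noise: NoiseSettings,
    dt: float,
    rng: np.random.Generator,
) -> FilamentState:
    """One Euler–Maruyama step of the concentration dynamics.

    With ``omega_phi = 0`` this is an exact deterministic Euler step.  The
    input filament is left untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = filament.copy()
    _langevin_inplace(out, params, noise, dt, rng)
    return out


def grow_and_divide(
    filament: FilamentState,
    params: ModelParameters,
    noise: NoiseSettings,
    dt: float,
    rng: np.random.Generator,
) -> FilamentState:
    """One step of stochastic growth plus any resulting divisions."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = filament.copy()
    _grow_divide_inplace(out, params, noise, dt, rng)
    return out


def update_commitment(cell: CellState, params: ModelParameters, dt: float) -> CellState:
    """Advance one vegetative cell's commitment bookkeeping by dt.

    While R >= T_Rj the HetR integral and the above-threshold clock
    accumulate; a dip below threshold resets both.  The cell differentiates
    once the integral reaches M_Rj and the clock reaches T_min.
    """
    if cell.is_heterocyst:
        raise ValueError("update_commitment called on a heterocyst")
    out = replace(cell)
    if cell.R >= cell.T_R_cell:
        out.commit_integral = cell.commit_integral + cell.R * dt
        out.commit_clock = cell.commit_clock + dt
    else:
        out.commit_integral = 0.0
        out.commit_clock = 0.0
    if (
        out.commit_integral >= cell.M_R_cell - 1e-9
        and out.commit_clock >= params.T_min - 1e-9
    ):
        out.is_heterocyst = True
        out.commit_integral = 0.0
        out.commit_clock = 0.0
    return out


def initial_filament(
    config: SimulationConfig,
    params: ModelParameters,
    noise: NoiseSettings,
    rng: np.random.Generator,
) -> FilamentState:
    """Fresh all-vegetative filament at the nitrogen step-down (t = 0).

    Concentrations start at zero; sizes are drawn uniformly on
    [M_Lambda/2, M_Lambda] (policy ``uniform``) to desynchronize divisions, or
    all at M_Lambda/2 (policy ``half``).
    """
    n = config.n_initial_cells
    if config.initial_size_policy == "uniform":
        size = rng.uniform(params.M_Lambda / 2.0, params.M_Lambda, size=n)
    else:
        size = np.full(n, params.M_Lambda / 2.0)
    T_R, M_R, M_L = _draw_thresholds(n, params, noise, rng)
    return FilamentState(
        conc=np.zeros((n, 6)),
        size=size,
        is_heterocyst=np.zeros(n, dtype=bool),
        T_R_cell=T_R,
        M_R_cell=M_R,
        M_Lambda_cell=np.maximum(M_L, size + 1e-9),
        commit_integral=np.zeros(n),
        commit_clock=np.zeros(n),
        time=0.0,
    )


def run_simulation(
    config: SimulationConfig,
    params: ModelParameters,
    mutant: Optional[MutantSpec] = None,
    noise: Optional[NoiseSettings] = None,
) -> Trajectory:
    """Simulate one filament from nitrogen step-down to ``t_end``.

    Per timestep: Langevin concentration update, then commitment tracking of
    vegetative cells, then growth and division.  Fully reproducible from
    ``noise.seed``.
    """
    noise = noise if noise is not None else NoiseSettings()
    eff = apply_mutant(params, mutant) if mutant is not None else params
    rng = np.random.default_rng(noise.seed)
    fil = initial_filament(config, eff, noise, rng)

    n_steps = int(round(config.t_end / config.dt))
    stride = int(round(config.record_every / config.dt))
    times = [0.0]
    snaps = [fil.copy()]
    for step in range(1, n_steps + 1):
        _langevin_inplace(fil, eff, noise, config.dt, rng)
        _commitment_inplace(fil, eff, config.dt)
        _grow_divide_inplace(fil, eff, noise, config.dt, rng)
        if step % stride == 0:
            fil.time = step * config.dt  # avoid accumulated float drift
            times.append(fil.time)
            snaps.append(fil.copy())
    return Trajectory(
        times=times,
        snapshots=snaps,
        provenance={
            "config": config.to_dict(),
            "params": params.to_dict(),
            "effective_params": eff.to_dict(),
            "mutant": mutant.to_dict() if mutant is not None else MutantSpec().to_dict(),
            "noise": {
                "omega_phi": noise.omega_phi,
                "omega_lambda": noise.omega_lambda,
                "seed": noise.seed,
            },
        },
    )
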