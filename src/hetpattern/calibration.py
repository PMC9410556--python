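"""Parameter calibration: objective energy, simulated annealing, sensitivity.

The calibration energy compares simulated pattern statistics against a
reference dataset split into two groups.  Group ``O`` (wild type, the patS
and hetN knock-outs at 24/48/72 h) contributes the squared
Kolmogorov–Smirnov distance between interval distributions plus squared
errors in the mean interval m and heterocyst percentage p.  Group ``N`` (the
patA and patA hetN backgrounds at 24/48/72/96 h) contributes the squared KS
distance on interval histograms plus a penalty proportional to the simulated
heterocyst percentage (these backgrounds form almost exclusively terminal
heterocysts, so interior heterocysts are penalized):

    E = sum_O [w1 KS^2 + w2 ((m_e - m_s)^2 + (p_e - p_s)^2)]
      + sum_N [w3 KS^2 + w4 p_s]
      + delta_WT_NoHc (mean_R_WT - T_R)^2

The last term only switches on when the simulated wild type formed no
heterocysts at all; it drives the HetR level towards the commitment threshold
so the annealer escapes dead regions of parameter space.  Default weights are
(w1, w2, w3, w4) = (1000, 10, 500, 1).

Annealing uses multiplicative log-normal proposals (parameters remain
positive) with Metropolis acceptance under geometric cooling.  Sensitivity of
an observable Y to a parameter X is the ratio of relative changes
S_YX = (dY/Y)/(dX/X).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import ModelParameters
from .observables import SummaryStats, ks_distance, summarize_filaments
from .simulate import (
    MutantSpec,
    NoiseSettings,
    SimulationConfig,
    Trajectory,
    run_simulation,
)

__all__ = [
    "ReferenceEntry",
    "ReferenceDataset",
    "EnergyWeights",
    "SensitivityResult",
    "AnnealingSchedule",
    "AnnealingResult",
    "energy",
    "simulated_annealing",
    "sensitivity",
    "read_reference_csv",
    "write_reference_csv",
    "make_reference_from_simulation",
    "MANUALLY_SET_PARAMETERS",
    "DEFAULT_FREE_PARAMETERS",
]

#: Parameters fixed by hand (never annealed by default): hexapeptide-HetR
#: affinity, growth rate, maximum size, and the commitment constants.
MANUALLY_SET_PARAMETERS = ("K_d", "lam", "M_Lambda", "T_R", "M_R", "T_min")

#: Default annealing search space: every kinetic rate/scale of the drift.
DEFAULT_FREE_PARAMETERS = (
    "beta_R",
    "rho_R",
    "rho_A",
    "rho_S",
    "rho_N",
    "rho_G",
    "alpha_R",
    "alpha_A",
    "alpha_S",
    "alpha_N",
    "alpha_I",
    "alpha_G",
    "mu",
    "c_S",
    "c_N",
    "d_I",
    "d_G",
    "d_border",
    "F_R",
    "tau_A",
    "K_G",
)


@dataclass
class ReferenceEntry:
    """Reference statistics for one (condition, time) point."""

    condition: str
    time_h: float
    group: str  # "O" or "N"
    intervals: List[int] = field(default_factory=list)
    m: float = float("nan")
    p: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("O", "N"):
            raise ValueError("group must be 'O' or 'N'")


@dataclass
class ReferenceDataset:
    """Reference entries keyed by (condition, time_h)."""

    entries: Dict[Tuple[str, float], ReferenceEntry] = field(default_factory=dict)

    def add(self, entry: ReferenceEntry) -> None:
        self.entries[(entry.condition, entry.time_h)] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()


@dataclass(frozen=True)
class EnergyWeights:
    w1: float = 1000.0
    w2: float = 10.0
    w3: float = 500.0
    w4: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("weights must be >= 0")


def _ks_or_worst(ref_intervals: Sequence[int], sim_intervals: Sequence[int]) -> float:
    # two empty samples agree; one empty sample is maximally distant
    if len(ref_intervals) == 0 and len(sim_intervals) == 0:
        return 0.0
    if len(ref_intervals) == 0 or len(sim_intervals) == 0:
        return 1.0
    return ks_distance(ref_intervals, sim_intervals)


def energy(
    sim: Mapping[Tuple[str, float], SummaryStats],
    ref: ReferenceDataset,
    weights: EnergyWeights = EnergyWeights(),
    mean_R_WT: float = float("nan"),
    T_R: float = 1.0,
    wt_formed_heterocysts: Optional[bool] = None,
) -> float:
    """Calibration energy of simulated statistics against a reference.

    ``sim`` must cover every key of ``ref``.  If ``wt_formed_heterocysts`` is
    None it is inferred from the sim entries whose condition is "WT" (no such
    entries: the rescue term stays off).
    """
    E = 0.0
    for key, entry in ref.entries.items():
        if key not in sim:
            raise KeyError(f"simulation statistics missing for reference entry {key}")
        s = sim[key]
        dks = _ks_or_worst(entry.intervals, s.intervals)
        if entry.group == "O":
            # a missing mean on either side counts as 0 (no pattern formed);
            # two missing means agree
            m_ref = 0.0 if math.isnan(entry.m) else entry.m
            m_sim = 0.0 if math.isnan(s.m) else s.m
            E += weights.w1 * dks**2 + weights.w2 * (
                (m_ref - m_sim) ** 2 + (entry.p - s.p) ** 2
            )
        else:
            E += weights.w3 * dks**2 + weights.w4 * s.p
    if wt_formed_heterocysts is None:
        wt = [s for (cond, _), s in sim.items() if cond == "WT"]
        wt_formed_heterocysts = any(s.p > 0 for s in wt) if wt else True
    if not wt_formed_heterocysts:
        if math.isnan(mean_R_WT):
            raise ValueError("mean_R_WT required when the wild type formed no heterocysts")
        E += (mean_R_WT - T_R) ** 2
    return E


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling schedule with log-normal proposals."""

    n_proposals: int = 5000
    t_initial: float = 1.0
    cooling_factor: float = 0.98  # applied every `steps_per_temperature`
    steps_per_temperature: int = 50
    proposal_sigma: float = 0.1  # std-dev of log-space multiplicative step

    def __post_init__(self) -> None:
        if self.n_proposals < 0 or self.t_initial < 0:
            raise ValueError("n_proposals and t_initial must be >= 0")
        if not (0 < self.cooling_factor <= 1):
            raise ValueError("cooling_factor must be in (0, 1]")


@dataclass
class AnnealingResult:
    best_params: ModelParameters
    best_energy: float
    energy_trace: List[float]  # best-ever energy after each proposal
    accepted: int = 0
    rejected_nonfinite: int = 0


def simulated_annealing(
    objective: Callable[[ModelParameters], float],
    initial: ModelParameters,
    free_params: Sequence[str] = DEFAULT_FREE_PARAMETERS,
    schedule: AnnealingSchedule = AnnealingSchedule(),
    rng: Optional[np.random.Generator] = None,
) -> AnnealingResult:
    """Minimize ``objective`` over the named parameters.

    One parameter is perturbed per proposal by a multiplicative log-normal
    factor; acceptance follows Metropolis exp(-dE/T) (greedy at T = 0).
    Proposals yielding a non-finite objective are rejected and counted.
    Returns the best-ever parameter set; bit-reproducible given ``rng``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    for name in free_params:
        if not hasattr(initial, name):
            raise ValueError(f"unknown parameter {name!r}")
    current = initial
    e_current = float(objective(current))
    best, e_best = current, e_current
    trace: List[float] = []
    accepted = 0
    nonfinite = 0
    T = schedule.t_initial
    for k in range(schedule.n_proposals):
        if k and k % schedule.steps_per_temperature == 0:
            T *= schedule.cooling_factor
        name = free_params[int(rng.integers(len(free_params)))]
        factor = float(np.exp(schedule.proposal_sigma * rng.standard_normal()))
        try:
            proposal = current.replace(
                **{name: getattr(current, name) * factor},
                enforce_commitment_convention=False,
            )
        except ValueError:
            trace.append(e_best)
            continue
        e_prop = float(objective(proposal))
        if not math.isfinite(e_prop):
            nonfinite += 1
            trace.append(e_best)
            continue
        dE = e_prop - e_current
        if dE <= 0 or (T > 0 and rng.random() < math.exp(-dE / T)):
            current, e_current = proposal, e_prop
            accepted += 1
            if e_current < e_best:
                best, e_best = current, e_current
        trace.append(e_best)
    return AnnealingResult(
        best_params=best,
        best_energy=e_best,
        energy_trace=trace,
        accepted=accepted,
        rejected_nonfinite=nonfinite,
    )


@dataclass
class SensitivityResult:
    parameter: str
    baseline_value: float
    fraction: float
    observable: str
    Y_baseline: float
    Y_perturbed: float
    S: float


def sensitivity(
    params: ModelParameters,
    X: str,
    frac: float,
    observable: Optional[Callable[[Trajectory], float]] = None,
    noise: Optional[NoiseSettings] = None,
    seeds: Sequence[int] = (0,),
    config: Optional[SimulationConfig] = None,
    mutant: Optional[MutantSpec] = None,
    evaluator: Optional[Callable[[ModelParameters], float]] = None,
    observable_name: str = "observable",
) -> SensitivityResult:
    """Relative sensitivity S_YX = (dY/Y) / (dX/X) of Y to parameter X.

    Y is evaluated at X0 and X0*(1+frac), either by running seed-averaged
    simulations and applying ``observable`` to each trajectory, or — for
    analytic checks — by a direct ``evaluator`` on the parameter set.
    A zero baseline Y leaves S undefined (nan).
    """
    if frac == 0:
        raise ValueError("frac must be nonzero")
    if not hasattr(params, X):
        raise ValueError(f"unknown parameter {X!r}")
    X0 = float(getattr(params, X))
    perturbed = params.replace(**{X: X0 * (1.0 + frac)}, enforce_commitment_convention=False)

    def evaluate(p: ModelParameters) -> float:
        if evaluator is not None:
            return float(evaluator(p))
        if observable is None:
            raise ValueError("provide either observable or evaluator")
        cfg = config if config is not None else SimulationConfig()
        base = noise if noise is not None else NoiseSettings()
        vals = []
        for s in seeds:
            ns = NoiseSettings(base.omega_phi, base.omega_lambda, seed=int(s))
            vals.append(float(observable(run_simulation(cfg, p, mutant, ns))))
        return float(np.mean(vals))

    Y0 = evaluate(params)
    Y1 = evaluate(perturbed)
    S = float("nan") if Y0 == 0 else ((Y1 - Y0) / Y0) / frac
    return SensitivityResult(
        parameter=X,
        baseline_value=X0,
        fraction=frac,
        observable=observable_name,
        Y_baseline=Y0,
        Y_perturbed=Y1,
        S=S,
    )


# ---------------------------------------------------------------------------
# reference dataset I/O
#
# CSV schema (long format), one file per dataset:
#   condition, time_h, group, kind, x, value
# kind = "interval": x = interval length, value = count
# kind = "m" | "p":  x empty,            value = the statistic


def write_reference_csv(ref: ReferenceDataset, path) -> None:
    rows = []
    for (cond, t), e in sorted(ref.entries.items()):
        for length, count in sorted(
            pd.Series(e.intervals).value_counts().items() if e.intervals else []
        ):
            rows.append((cond, t, e.group, "interval", int(length), int(count)))
        rows.append((cond, t, e.group, "m", "", e.m))
        rows.append((cond, t, e.group, "p", "", e.p))
    pd.DataFrame(
        rows, columns=["condition", "time_h", "group", "kind", "x", "value"]
    ).to_csv(path, index=False)


def read_reference_csv(path) -> ReferenceDataset:
    df = pd.read_csv(path)
    required = {"condition", "time_h", "group", "kind", "x", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    ref = ReferenceDataset()
    for (cond, t, group), sub in df.groupby(["condition", "time_h", "group"]):
        entry = ReferenceEntry(condition=cond, time_h=float(t), group=group)
        for _, row in sub.iterrows():
            if row["kind"] == "interval":
                entry.intervals.extend([int(float(row["x"]))] * int(row["value"]))
            elif row["kind"] == "m":
                entry.m = float(row["value"])
            elif row["kind"] == "p":
                entry.p = float(row["value"])
            else:
                raise ValueError(f"unknown row kind {row['kind']!r}")
        entry.intervals.sort()
        ref.add(entry)
    return ref


def simulation_objective(
    ref: ReferenceDataset,
    conditions: Mapping[str, MutantSpec],
    config: Optional[SimulationConfig] = None,
    noise: Optional[NoiseSettings] = None,
    n_runs: int = 3,
    base_seed: int = 0,
    weights: EnergyWeights = EnergyWeights(),
) -> Callable[[ModelParameters], float]:
    """Build the annealing objective: simulate every reference condition and
    score the pattern statistics with :func:`energy`.

    The same per-condition seeds are reused for every parameter proposal
    (common random numbers), which reduces the stochastic jitter of the
    energy landscape.  ``conditions`` maps each condition name appearing in
    ``ref`` to its mutant overlay.
    """
    cfg = config if config is not None else SimulationConfig()
    base = noise if noise is not None else NoiseSettings()
    times_by_cond: Dict[str, List[float]] = {}
    for cond, t in ref.keys():
        if cond not in conditions:
            raise ValueError(f"no mutant overlay given for reference condition {cond!r}")
        times_by_cond.setdefault(cond, []).append(t)
    seeds = {
        cond: [
            int(np.random.SeedSequence((base_seed, i, r)).generate_state(1)[0] % (2**31))
            for r in range(n_runs)
        ]
        for i, cond in enumerate(sorted(times_by_cond))
    }

    def objective(params: ModelParameters) -> float:
        sim: Dict[Tuple[str, float], SummaryStats] = {}
        mean_R_WT = float("nan")
        try:
            for cond, times in times_by_cond.items():
                trajs = [
                    run_simulation(
                        cfg,
                        params,
                        conditions[cond],
                        NoiseSettings(base.omega_phi, base.omega_lambda, seed=s),
                    )
                    for s in seeds[cond]
                ]
                for t in times:
                    sim[(cond, t)] = summarize_filaments([tr.at_time(t) for tr in trajs])
                if cond == "WT":
                    # time-average of the vegetative HetR mean over the run
                    from .observables import mean_hetr_vegetative

                    vals = [
                        mean_hetr_vegetative(snap)
                        for tr in trajs
                        for snap in tr.snapshots
                    ]
                    vals = [v for v in vals if math.isfinite(v)]
                    mean_R_WT = float(np.mean(vals)) if vals else float("nan")
        except Exception:
            return float("inf")
        return energy(sim, ref, weights, mean_R_WT=mean_R_WT, T_R=params.T_R)

    return objective


def make_reference_from_simulation(
    params: ModelParameters,
    conditions: Mapping[str, Tuple[MutantSpec, str]],
    times: Sequence[float],
    config: Optional[SimulationConfig] = None,
    noise: Optional[NoiseSettings] = None,
    n_runs: int = 10,
    base_seed: int = 0,
) -> ReferenceDataset:
    """Synthetic reference dataset generated by the simulator itself.

    ``conditions`` maps a condition name to (mutant overlay, group label).
    Used to make calibration testable without external data.
    """
    cfg = config if config is not None else SimulationConfig()
    base = noise if noise is not None else NoiseSettings()
    ref = ReferenceDataset()
    for i, (name, (mut, group)) in enumerate(sorted(conditions.items())):
        trajs = []
        for r in range(n_runs):
            seed = int(np.random.SeedSequence((base_seed, i, r)).generate_state(1)[0] % (2**31))
            ns = NoiseSettings(base.omega_phi, base.omega_lambda, seed=seed)
            trajs.append(run_simulation(cfg, params, mut, ns))
        for t in times:
            stats = summarize_filaments([tr.at_time(t) for tr in trajs])
            ref.add(
                ReferenceEntry(
                    condition=name,
                    time_h=float(t),
                    group=group,
                    intervals=list(stats.intervals),
                    m=stats.m,
                    p=stats.p,
                )
            )
    return ref
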