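"""Continuum reaction-diffusion analogy of boundary-induced patterning.

A non-diffusing activator r (HetR-like) and a diffusible inhibitor s on a
1-D domain x in [0, L]:

    dr/dt = beta_r + f(r, s) rho_r - alpha_r r
    ds/dt = f(r, s) rho_s - alpha_s s + d d2s/dx2

with f smooth, increasing in r and decreasing in s (default: the same Hill
form as the discrete model with no PatA or fixed-nitrogen terms,
f = F r^2 / (1 + F r^2 + s^2/K_s^2)).

Two boundary conditions for s are supported: ``zeroflux`` (no inhibitor
crosses the filament ends; the homogeneous steady state survives) and
``absorbing`` (s = 0 at both ends, i.e. free leakage; the inhibitor develops
a gradient decreasing from the centre to the ends and the activator develops
maxima at the ends — the continuum picture of terminal heterocyst
differentiation).

Discretization: second-order central differences, ghost nodes for the
zero-flux condition and pinned boundary values for the absorbing one;
method-of-lines integration to steady state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["ContinuumParams", "ContinuumResult", "integrate_to_steady_state"]


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the activator-inhibitor boundary-value problem."""

    beta_r: float = 0.2
    rho_r: float = 1.0
    rho_s: float = 1.0
    alpha_r: float = 1.0
    alpha_s: float = 1.0
    d: float = 1.0  # inhibitor diffusivity
    L: float = 10.0
    n_grid: int = 101
    bc: str = "zeroflux"  # or "absorbing"
    F: float = 5.0  # activation constant of the default regulatory function
    K_s: float = 1.0  # inhibition scale of the default regulatory function
    f: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None  # override

    def __post_init__(self) -> None:
        if self.bc not in ("zeroflux", "absorbing"):
            raise ValueError("bc must be 'zeroflux' or 'absorbing'")
        if self.n_grid < 3:
            raise ValueError("need at least 3 grid nodes")
        for name in ("beta_r", "rho_r", "rho_s", "alpha_r", "alpha_s", "d", "L", "F", "K_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def regulatory(self, r: np.ndarray, s: np.ndarray) -> np.ndarray:
        if self.f is not None:
            return self.f(r, s)
        act = self.F * r**2
        return act / (1.0 + act + (s / self.K_s) ** 2)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_grid)


@dataclass
class ContinuumResult:
    x: np.ndarray
    r: np.ndarray
    s: np.ndarray
    converged: bool
    residual: float  # max |d/dt| at the final state
    t_reached: float


def _rhs(params: ContinuumParams, h: float):
    n = params.n_grid

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        r = y[:n]
        s = y[n:]
        f = params.regulatory(r, np.maximum(s, 0.0))
        dr = params.beta_r + f * params.rho_r - params.alpha_r * r
        lap = np.empty(n)
        lap[1:-1] = (s[:-2] - 2.0 * s[1:-1] + s[2:]) / h**2
        if params.bc == "zeroflux":
            # ghost nodes: s[-1] = s[1], s[n] = s[n-2]
            lap[0] = 2.0 * (s[1] - s[0]) / h**2
            lap[-1] = 2.0 * (s[-2] - s[-1]) / h**2
        else:
            lap[0] = lap[-1] = 0.0
        ds = f * params.rho_s - params.alpha_s * s + params.d * lap
        if params.bc == "absorbing":
            ds[0] = ds[-1] = 0.0  # pinned at s = 0
        return np.concatenate([dr, ds])

    return rhs


def integrate_to_steady_state(
    params: ContinuumParams,
    tol: float = 1e-8,
    t_max: float = 2000.0,
    r0: Optional[np.ndarray] = None,
    s0: Optional[np.ndarray] = None,
) -> ContinuumResult:
    """Integrate the boundary-value problem until max |d/dt| < tol.

    Integration proceeds in chunks (stiff LSODA) with the residual polled
    after each; failure to converge by ``t_max`` is reported through
    ``converged=False`` rather than raised, with the last profiles returned.
    """
    n = params.n_grid
    h = params.L / (n - 1)
    r = np.full(n, params.beta_r / params.alpha_r) if r0 is None else np.asarray(r0, float).copy()
    s = np.zeros(n) if s0 is None else np.asarray(s0, float).copy()
    if params.bc == "absorbing":
        s[0] = s[-1] = 0.0
    rhs = _rhs(params, h)
    y = np.concatenate([r, s])
    t = 0.0
    chunk = max(t_max / 100.0, 1.0)
    residual = float(np.max(np.abs(rhs(0.0, y))))
    while residual >= tol and t < t_max:
        sol = solve_ivp(
            rhs,
            (t, min(t + chunk, t_max)),
            y,
            method="LSODA",
            rtol=1e-9,
            atol=1e-11,
        )
        if not sol.success:
            raise RuntimeError(f"continuum integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = sol.t[-1]
        residual = float(np.max(np.abs(rhs(t, y))))
    return ContinuumResult(
        x=params.x,
        r=y[:n].copy(),
        s=np.maximum(y[n:], 0.0),
        converged=residual < tol,
        residual=residual,
        t_reached=t,
    )


def profiles_dataframe(result: ContinuumResult) -> pd.DataFrame:
    return pd.DataFrame({"x": result.x, "r": result.r, "s": result.s})
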