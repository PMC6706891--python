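"""Generalized Lotka-Volterra (gLV) model: parameter container and trajectory integration.

The gLV model couples the absolute densities ``x_i(t)`` of ``p`` species through

    dx_i/dt = mu_i * x_i + sum_j beta_ij * x_i * x_j,

where ``mu_i`` is the intrinsic growth rate of species ``i`` and ``beta_ij``
the effect of species ``j`` on the per-capita growth of species ``i``.
Negative diagonal entries ``beta_ii`` encode self-limitation (logistic
saturation) and are required for bounded dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class GLVIntegrationError(RuntimeError):
    """Raised when the ODE solver diverges (unstable parameter set)."""


@dataclass
class GLVParameters:
    """Growth-rate vector and interaction matrix defining a gLV community.

    Parameters
    ----------
    mu : (p,) array
        Intrinsic growth rates, per unit time.
    beta : (p, p) array
        Interaction matrix, per unit time per unit density. Diagonal entries
        must be strictly negative (self-limitation).
    species_ids : sequence of str, optional
        Labels; defaults to ``sp1..sp<p>``.
    """

    mu: np.ndarray
    beta: np.ndarray
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        p = self.mu.shape[0]
        if self.mu.ndim != 1 or self.beta.shape != (p, p):
            raise ValueError(
                f"dimension mismatch: mu has length {p}, beta has shape {self.beta.shape}"
            )
        if not self.species_ids:
            self.species_ids = [f"sp{i + 1}" for i in range(p)]
        if len(self.species_ids) != p:
            raise ValueError("species_ids length does not match mu/beta dimension")
        if np.any(np.diag(self.beta) >= 0):
            raise ValueError("beta diagonal entries must be strictly negative")

    @property
    def n_species(self) -> int:
        return self.mu.shape[0]

    def equilibrium(self) -> np.ndarray:
        """Interior fixed point solving ``mu + beta @ x = 0``.

        May contain non-positive components for communities without a feasible
        coexistence equilibrium; callers must check.
        """
        return np.linalg.solve(self.beta, -self.mu)


@dataclass
class StateVector:
    """Absolute species densities at a single time point."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("densities must be non-negative")


def glv_derivative(params: GLVParameters, state: StateVector | np.ndarray) -> np.ndarray:
    """Right-hand side ``mu_i x_i + sum_j beta_ij x_i x_j`` of the gLV system.

    Exactly zero for extinct species (``x_i = 0``).
    """
    x = state.x if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    if x.shape[0] != params.n_species:
        raise ValueError(
            f"state has {x.shape[0]} species but parameters define {params.n_species}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("state densities must be finite")
    return x * (params.mu + params.beta @ x)


def integrate_glv(
    params: GLVParameters,
    x0: StateVector | np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    blowup: float = 1e6,
) -> np.ndarray:
    """Integrate the gLV ODE on a grid of requested times.

    Uses an adaptive Dormand-Prince (RK45) solver with tight tolerances so
    that downstream gradient-matching tests see trajectories accurate well
    below the observation noise floor. Densities are clipped at zero after
    each output step; the exact dynamics preserve non-negativity, so any
    negative values are pure round-off.

    Returns
    -------
    (p, T) array of densities at ``times``.

    Raises
    ------
    GLVIntegrationError
        If any density exceeds ``blowup`` (unstable parameters), naming the
        first failing time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x0 = x0.x if isinstance(x0, StateVector) else np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)
        return xc * (params.mu + params.beta @ xc)

    def blew_up(_t: float, x: np.ndarray) -> float:
        return float(blowup - np.max(np.abs(x)))

    blew_up.terminal = True  # type: ignore[attr-defined]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=atol,
        events=blew_up,
    )
    if sol.status == 1 and sol.t_events[0].size:
        raise GLVIntegrationError(
            f"trajectory diverged (density > {blowup:g}) at t = {sol.t_events[0][0]:.4g}"
        )
    if not sol.success or sol.y.shape[1] != times.size:
        t_fail = times[sol.y.shape[1]] if sol.y.shape[1] < times.size else times[-1]
        raise GLVIntegrationError(f"ODE solver failed near t = {t_fail:.4g}: {sol.message}")
    traj = np.clip(sol.y, 0.0, None)
    # species that start extinct remain exactly extinct
    traj[x0 == 0.0, :] = 0.0
    return traj
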