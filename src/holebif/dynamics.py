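"""Master-equation propagation and bifurcation observables.

The transition-rate matrix K follows the column-generator convention:
entry (b, a) is the rate of the hop a -> b, and each diagonal entry is
minus its column sum, so d/dt P = K P conserves total probability and
P(t) = expm(K t) P(0) holds literally.

Terminus cofactors act as hole traps: hops out of a terminus are assigned
zero rate (``trap_termini=True``), reflecting the design intent that the
terminal acceptors capture their hole for the duration of a photocycle
(no refilling by sacrificial donors is modeled).  With reversible termini
the shallow 0.05-0.1 eV steps near the cold trap would re-thermalize a
noticeable fraction of the population at 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .landscape import Landscape
from .microstates import StateSpace, allowed_transitions, enumerate_states, state_energy
from .rates import jortner_rate

__all__ = [
    "RateMatrix",
    "Trajectory",
    "build_rate_matrix",
    "propagate",
    "propagate_ode",
    "initial_state_index",
    "target_state_index",
    "quantum_yield",
    "arrival_curves",
    "completion_time",
    "CompletionNotReached",
    "default_time_grid",
]


@dataclass(frozen=True)
class RateMatrix:
    space: StateSpace
    matrix: np.ndarray  # (n_states, n_states), column generator

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.space.n_states, self.space.n_states):
            raise ValueError("rate matrix shape does not match state space")


@dataclass(frozen=True)
class Trajectory:
    space: StateSpace
    times: np.ndarray  # s, strictly increasing
    probabilities: np.ndarray  # (n_times, n_states)

    def occupancy(self, cofactor_id: str) -> np.ndarray:
        """Marginal hole occupancy probability of one site over time."""
        col = self.space.landscape.site_index(cofactor_id)
        occ = self.space.occupancy_matrix()[:, col]
        return self.probabilities @ occ


def build_rate_matrix(space: StateSpace, trap_termini: bool = True) -> RateMatrix:
    """Assemble K from vibronic rates over all allowed transitions.

    For each hop a -> b, ``K[b, a] = jortner_rate(E_b - E_a, R_edge)``;
    diagonals are the negative column sums.  With ``trap_termini`` hops
    whose donor is a terminus-role cofactor are omitted.
    """
    landscape = space.landscape
    n = space.n_states
    energies = np.array([state_energy(s, landscape) for s in space.states])
    roles = {c.id: c.role for c in landscape.cofactors}
    k = np.zeros((n, n))
    for tr in allowed_transitions(space):
        if trap_termini and roles[tr.donor_id] == "terminus":
            continue
        delta_g = energies[tr.to_index] - energies[tr.from_index]
        k[tr.to_index, tr.from_index] += jortner_rate(
            delta_g, tr.edge.distance, landscape.rate_params
        )
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=0))
    return RateMatrix(space=space, matrix=k)


def _check_p0(p0: np.ndarray, n: int) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (n,):
        raise ValueError(f"P0 must have shape ({n},)")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("P0 must be non-negative and sum to 1")
    return p0


def propagate(rate_matrix: RateMatrix, p0, times) -> Trajectory:
    """Matrix-exponential action P(t) = expm(K t) P(0) at each time."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    p0 = _check_p0(p0, rate_matrix.space.n_states)
    k = rate_matrix.matrix
    probs = np.empty((times.size, p0.size))
    for row, t in enumerate(times):
        probs[row] = p0 if t == 0.0 else expm(k * t) @ p0
    return Trajectory(space=rate_matrix.space, times=times, probabilities=probs)


def propagate_ode(
    rate_matrix: RateMatrix, p0, times, rtol: float = 1e-10, atol: float = 1e-12
) -> Trajectory:
    """Stiff ODE integration of d/dt P = K P (independent back end)."""
    times = np.asarray(times, dtype=float)
    p0 = _check_p0(p0, rate_matrix.space.n_states)
    k = rate_matrix.matrix
    sol = solve_ivp(
        lambda _t, p: k @ p,
        (0.0, float(times[-1])),
        p0,
        t_eval=times,
        method="BDF",
        jac=lambda _t, _p: k,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(space=rate_matrix.space, times=times, probabilities=sol.y.T)


def default_time_grid(t_min: float = 1e-9, t_max: float = 1.0, n: int = 60) -> np.ndarray:
    """Logarithmic reporting grid, 60 points over [1e-9, 1] s by default."""
    return np.geomspace(t_min, t_max, n)


def initial_state_index(space: StateSpace) -> int:
    """State with one hole on each bifurcation-pair site (post-flash)."""
    pair = space.landscape.bifurcation_sites()
    if len(pair) != 2:
        raise ValueError("landscape must declare exactly two bifurcation sites")
    return space.state_of_sites([c.id for c in pair])


def target_state_index(space: StateSpace) -> int:
    """State with exactly one hole on each pathway terminus."""
    termini = space.landscape.termini()
    if set(termini) != {"hot", "cold"}:
        raise ValueError(
            "landscape must declare one hot and one cold terminus, "
            f"found pathways {sorted(termini)}"
        )
    return space.state_of_sites([c.id for c in termini.values()])


def quantum_yield(
    landscape: Landscape, t_final: float = 1.0, trap_termini: bool = True
) -> float:
    """Bifurcation quantum yield: probability of the two-termini state.

    Starting from the doubly occupied bifurcation pair, propagate the
    two-hole master equation to ``t_final`` (s) and return the probability
    of the microstate with one hole on each terminus.
    """
    space = enumerate_states(landscape, n_holes=2)
    k = build_rate_matrix(space, trap_termini=trap_termini)
    p0 = np.zeros(space.n_states)
    p0[initial_state_index(space)] = 1.0
    target = target_state_index(space)
    if t_final == 0.0:
        return float(p0[target])
    p = expm(k.matrix * t_final) @ p0
    return float(p[target])


def arrival_curves(
    landscape: Landscape, times=None, trap_termini: bool = True
) -> dict:
    """Terminus occupancy probabilities over time.

    Returns ``{"times": ndarray, "hot": ndarray, "cold": ndarray}`` for the
    two-hole kinetics started from the doubly occupied bifurcation pair.
    """
    if times is None:
        times = default_time_grid()
    space = enumerate_states(landscape, n_holes=2)
    k = build_rate_matrix(space, trap_termini=trap_termini)
    p0 = np.zeros(space.n_states)
    p0[initial_state_index(space)] = 1.0
    traj = propagate(k, p0, times)
    termini = landscape.termini()
    return {
        "times": traj.times,
        "hot": traj.occupancy(termini["hot"].id),
        "cold": traj.occupancy(termini["cold"].id),
        "trajectory": traj,
    }


class CompletionNotReached(RuntimeError):
    """The occupancy curve never crosses the requested threshold."""


def completion_time(
    landscape: Landscape,
    pathway: str,
    threshold: float = 0.5,
    t_min: float = 1e-12,
    t_max: float = 1.0,
    rel_tol: float = 1e-3,
    trap_termini: bool = True,
) -> float:
    """First time the terminus occupancy exceeds ``threshold`` (s).

    A coarse logarithmic scan brackets the crossing, then log-time
    bisection refines it to relative precision ``rel_tol``.  Raises
    :class:`CompletionNotReached` if the threshold is never exceeded
    within ``[t_min, t_max]``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    space = enumerate_states(landscape, n_holes=2)
    km = build_rate_matrix(space, trap_termini=trap_termini)
    p0 = np.zeros(space.n_states)
    p0[initial_state_index(space)] = 1.0
    terminus = landscape.termini()[pathway].id
    col = landscape.site_index(terminus)
    occ = space.occupancy_matrix()[:, col]

    def value(t: float) -> float:
        return float(occ @ (expm(km.matrix * t) @ p0))

    grid = np.geomspace(t_min, t_max, 40)
    vals = [value(t) for t in grid]
    above = [i for i, v in enumerate(vals) if v > threshold]
    if not above:
        raise CompletionNotReached(
            f"{pathway} terminus occupancy never exceeds {threshold} "
            f"within [{t_min:g}, {t_max:g}] s (max {max(vals):.4g})"
        )
    hi_idx = above[0]
    if hi_idx == 0:
        return float(grid[0])
    lo, hi = np.log(grid[hi_idx - 1]), np.log(grid[hi_idx])
    while hi - lo > rel_tol:
        mid = 0.5 * (lo + hi)
        if value(np.exp(mid)) > threshold:
            hi = mid
        else:
            lo = mid
    return float(np.exp(hi))
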