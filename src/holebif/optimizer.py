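"""Gaussian-process surrogate with UCB acquisition for landscape design.

A from-scratch Bayesian optimizer over cofactor potentials and edge
distances.  The surrogate is a zero-mean GP with an isotropic RBF kernel
evaluated on min-max scaled coordinates (distances in angstroms and
potentials in volts are incommensurate, so each coordinate is rescaled to
[0, 1] by its search bounds before entering the kernel).  The acquisition
is the upper confidence bound mu + kappa * sigma, maximized by seeded
candidate sampling followed by coordinate-wise golden-section refinement.

Design coordinates are named after the landscape fields they override:
``potential:<cofactor id>`` (V) and ``distance:<id_a>-<id_b>`` (angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .dynamics import quantum_yield
from .landscape import Landscape

__all__ = [
    "DesignVector",
    "GPModel",
    "rbf_kernel",
    "gp_posterior",
    "ucb",
    "propose_next",
    "apply_design",
    "optimize_landscape",
]

JITTER = 1e-10  # Gram-diagonal regularization; noiseless observations
                # make K exactly singular at duplicated points


@dataclass(frozen=True)
class DesignVector:
    """Named, bounded design coordinates."""

    coordinates: dict  # name -> value
    bounds: dict  # name -> (lo, hi)

    def __post_init__(self) -> None:
        if set(self.coordinates) != set(self.bounds):
            raise ValueError("coordinate names must match bound names")
        for name, value in self.coordinates.items():
            lo, hi = self.bounds[name]
            if not lo <= value <= hi:
                raise ValueError(
                    f"coordinate {name!r} = {value} outside bounds [{lo}, {hi}]"
                )

    def scaled(self, names) -> np.ndarray:
        """Min-max scaled coordinate array in the given name order."""
        out = np.empty(len(names))
        for k, name in enumerate(names):
            lo, hi = self.bounds[name]
            width = hi - lo if hi > lo else 1.0
            out[k] = (self.coordinates[name] - lo) / width
        return out


@dataclass
class GPModel:
    """Observed designs and GP hyperparameters.

    ``X`` holds scaled coordinates (rows), ``y`` the observed objective
    values (quantum yields).  ``sigma_n_sq`` defaults to 0: the master
    equation objective is deterministic, so observations are noiseless.
    """

    X: np.ndarray
    y: np.ndarray
    sigma_f_sq: float
    length_scale: float = 0.2
    sigma_n_sq: float = 0.0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same length")
        if not (self.sigma_f_sq > 0 and self.length_scale > 0):
            raise ValueError("sigma_f_sq and length_scale must be > 0")
        if self.sigma_n_sq < 0:
            raise ValueError("sigma_n_sq must be >= 0")


def rbf_kernel(x, x_star, sigma_f_sq: float, length_scale: float):
    """Squared-exponential covariance on (scaled) coordinates.

    ``k(x, x*) = sigma_f^2 exp(-||x - x*||^2 / (2 l^2))``; accepts single
    vectors or stacked rows and broadcasts to the full cross-covariance.
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    b = np.atleast_2d(np.asarray(x_star, dtype=float))
    sq = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    out = sigma_f_sq * np.exp(-sq / (2.0 * length_scale**2))
    if np.ndim(x) == 1 and np.ndim(x_star) == 1:
        return float(out[0, 0])
    return out


def _gram_cholesky(model: GPModel):
    gram = rbf_kernel(model.X, model.X, model.sigma_f_sq, model.length_scale)
    gram = gram + (model.sigma_n_sq + JITTER) * np.eye(len(model.X))
    try:
        return cho_factor(gram, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "Gram matrix singular even after jitter"
        ) from exc


def gp_posterior(model: GPModel, x_star):
    """Posterior mean and variance at query point(s).

    Zero prior mean; variance is clipped at 0 to absorb jitter-level
    negative round-off.  Returns floats for a single query vector.
    """
    factor = _gram_cholesky(model)
    alpha = cho_solve(factor, model.y)
    k_star = rbf_kernel(model.X, x_star, model.sigma_f_sq, model.length_scale)
    k_star = np.atleast_2d(k_star)
    mean = k_star.T @ alpha
    v = cho_solve(factor, k_star)
    var = model.sigma_f_sq - np.einsum("ij,ij->j", k_star, v)
    var = np.maximum(var, 0.0)
    if np.ndim(x_star) == 1:
        return float(mean[0]), float(var[0])
    return mean, var


def ucb(mean, std, kappa: float):
    """Upper confidence bound acquisition ``mu + kappa * sigma``."""
    std = np.asarray(std, dtype=float)
    if np.any(std < 0):
        raise ValueError("std must be >= 0")
    return mean + kappa * std


def propose_next(model: GPModel, bounds: dict, kappa: float, seed: int) -> dict:
    """Approximate argmax of the UCB over the bounded box.

    2048 seeded uniform candidates in scaled space, then a few sweeps of
    coordinate-wise golden-section refinement of the best candidate.
    Deterministic for a fixed seed.  Returns unscaled named coordinates.
    """
    names = sorted(bounds)
    rng = np.random.default_rng(seed)
    cand = rng.uniform(size=(2048, len(names)))

    def acq(points) -> np.ndarray:
        mean, var = gp_posterior(model, np.atleast_2d(points))
        return ucb(mean, np.sqrt(var), kappa)

    best = cand[int(np.argmax(acq(cand)))].copy()
    for _ in range(3):  # coordinate-descent sweeps
        for dim in range(len(names)):
            def negated(v: float, d=dim) -> float:
                point = best.copy()
                point[d] = v
                m, s2 = gp_posterior(model, point)
                return -ucb(m, np.sqrt(s2), kappa)

            res = minimize_scalar(negated, bounds=(0.0, 1.0), method="bounded")
            if -res.fun > acq(best[None, :])[0]:
                best[dim] = res.x
    coords = {}
    for k, name in enumerate(names):
        lo, hi = bounds[name]
        coords[name] = lo + best[k] * (hi - lo)
    return coords


# ---------------------------------------------------------------------------
# Landscape objective plumbing
# ---------------------------------------------------------------------------


def _parse_coordinate(name: str):
    kind, _, rest = name.partition(":")
    if kind == "potential" and rest:
        return ("potential", rest)
    if kind == "distance" and rest.count("-") == 1:
        return ("distance", frozenset(rest.split("-")))
    raise ValueError(
        f"bad coordinate name {name!r}; expected 'potential:<id>' or "
        "'distance:<id_a>-<id_b>'"
    )


def apply_design(base: Landscape, coordinates: dict) -> Landscape:
    """Override landscape potentials/distances with design coordinates."""
    potentials, distances = {}, {}
    for name, value in coordinates.items():
        kind, key = _parse_coordinate(name)
        (potentials if kind == "potential" else distances)[key] = value
    return base.with_overrides(potentials=potentials, distances=distances)


@dataclass
class OptimizationResult:
    best_design: DesignVector
    best_yield: float
    history: list = field(default_factory=list)  # (coordinates dict, yield)

    @property
    def incumbent_trace(self) -> np.ndarray:
        """Running best yield after each evaluation (non-decreasing)."""
        return np.maximum.accumulate([y for _, y in self.history])


def optimize_landscape(
    base: Landscape,
    tunables: dict,
    n_init: int = 8,
    n_iter: int = 30,
    kappa: float = 2.0,
    seed: int = 0,
    t_final: float = 1.0,
    objective=None,
) -> OptimizationResult:
    """Maximize the bifurcation quantum yield over the tunable box.

    ``tunables`` maps coordinate names to (lo, hi) bounds.  The first
    ``n_init`` designs are uniform random in the box (the initial GP data);
    each of the ``n_iter`` following designs maximizes the UCB acquisition.
    ``objective`` may replace the default yield evaluation (for testing on
    analytic functions); it receives a coordinate dict and returns a float.
    """
    if not tunables:
        raise ValueError("tunables must be non-empty")
    names = sorted(tunables)
    rng = np.random.default_rng(seed)

    if objective is None:
        def objective(coords: dict) -> float:
            return quantum_yield(apply_design(base, coords), t_final=t_final)

    history = []

    def evaluate(coords: dict) -> float:
        value = float(objective(coords))
        history.append((dict(coords), value))
        return value

    for _ in range(n_init):
        coords = {
            name: rng.uniform(*tunables[name]) for name in names
        }
        evaluate(coords)

    for it in range(n_iter):
        scaled = np.array(
            [
                DesignVector(c, {n: tuple(tunables[n]) for n in names}).scaled(names)
                for c, _ in history
            ]
        )
        y = np.array([v for _, v in history])
        model = GPModel(
            X=scaled,
            y=y - y.mean(),  # center so the zero prior mean is unbiased
            sigma_f_sq=max(float(np.var(y)), 1e-6),
            kappa=kappa,
        )
        proposal = propose_next(model, tunables, kappa, seed=seed + 1 + it)
        evaluate(proposal)

    best_coords, best_yield = max(history, key=lambda item: item[1])
    best = DesignVector(best_coords, {n: tuple(tunables[n]) for n in names})
    return OptimizationResult(best_design=best, best_yield=best_yield, history=history)
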