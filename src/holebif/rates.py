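"""Nonadiabatic hole-transfer rates.

Rates follow the single-quantum-mode Jortner expression: a classical
(outer-sphere) reorganization coordinate plus one effective high-frequency
vibrational mode, summed over vibronic channels weighted by a Poisson
(Huang-Rhys) distribution.  Electronic couplings decay exponentially with
the edge-to-edge donor-acceptor distance.

All energies are in eV, distances in angstroms, temperatures in kelvin and
rates in 1/s.  The eV-based physical constants used throughout:

* ``KB_EV``      Boltzmann constant, eV/K
* ``HBAR_EV_S``  reduced Planck constant, eV*s
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "KB_EV",
    "HBAR_EV_S",
    "RateParameters",
    "coupling_squared",
    "jortner_rate",
    "marcus_rate",
]

KB_EV = 8.617333e-5
HBAR_EV_S = 6.582120e-16


@dataclass(frozen=True)
class RateParameters:
    """Parameters of the vibronic rate expression.

    Attributes
    ----------
    lambda_outer : float
        Outer-sphere (classical) reorganization energy, eV.
    hbar_omega : float
        Quantum of the effective high-frequency vibrational mode, eV.
    huang_rhys : float
        Dimensionless electron-vibration coupling strength D; the
        inner-sphere reorganization energy is ``D * hbar_omega``.
    beta : float
        Tunneling decay constant of the electronic coupling, 1/angstrom.
    v0 : float
        Electronic coupling at zero edge-to-edge distance, eV.
    temperature : float
        Absolute temperature, K.
    n_max : int
        Truncation of the vibronic sum (number of quanta); the Poisson
        weights decay factorially so modest values converge.
    """

    lambda_outer: float = 0.9
    hbar_omega: float = 0.15
    huang_rhys: float = 0.5
    beta: float = 0.6
    v0: float = 0.01
    temperature: float = 300.0
    n_max: int = 100

    def __post_init__(self) -> None:
        if not (self.lambda_outer > 0):
            raise ValueError("lambda_outer must be > 0 eV")
        if not (self.hbar_omega > 0):
            raise ValueError("hbar_omega must be > 0 eV")
        if self.huang_rhys < 0:
            raise ValueError("huang_rhys must be >= 0")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0 1/A")
        if not (self.v0 > 0):
            raise ValueError("v0 must be > 0 eV")
        if not (self.temperature > 0):
            raise ValueError("temperature must be > 0 K")
        if int(self.n_max) < 1:
            raise ValueError("n_max must be >= 1")

    @property
    def lambda_inner(self) -> float:
        """Inner-sphere reorganization energy D * hbar_omega, eV."""
        return self.huang_rhys * self.hbar_omega

    def with_temperature(self, temperature: float) -> "RateParameters":
        return replace(self, temperature=temperature)


def coupling_squared(distance: float, params: RateParameters) -> float:
    """Mean-squared electronic coupling ``(V0 * exp(-beta * R))**2`` in eV^2.

    ``distance`` is the closest heavy-atom (edge-to-edge) separation in
    angstroms; negative distances are rejected.
    """
    if distance < 0:
        raise ValueError(f"distance must be >= 0 A, got {distance}")
    v = params.v0 * math.exp(-params.beta * distance)
    return v * v


def _franck_condon_sum(delta_g: float, params: RateParameters) -> float:
    """Vibronic (Franck-Condon weighted) sum of the rate expression."""
    lam = params.lambda_outer
    kbt = KB_EV * params.temperature
    d = params.huang_rhys
    denom = 4.0 * lam * kbt
    total = 0.0
    weight = math.exp(-d)  # e^-D * D^n / n!, built up iteratively
    for n in range(int(params.n_max) + 1):
        gap = delta_g + lam + n * params.hbar_omega
        total += weight * math.exp(-gap * gap / denom)
        weight *= d / (n + 1)
    return total


def jortner_rate(delta_g: float, distance: float, params: RateParameters) -> float:
    """Nonadiabatic transfer rate (1/s) with one quantized mode.

    ``k = (2 pi / hbar) <V^2> (4 pi lambda kB T)^(-1/2)
    sum_n e^-D D^n/n! exp[-(dG + lambda + n hbar w)^2 / (4 lambda kB T)]``

    The classical reorganization energy enters both the activation factor
    and the thermal prefactor; the high-frequency mode opens vibronically
    excited acceptor channels that dominate in the inverted region.
    """
    if not math.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    v_sq = coupling_squared(distance, params)
    kbt = KB_EV * params.temperature
    prefactor = (2.0 * math.pi / HBAR_EV_S) * v_sq
    thermal = 1.0 / math.sqrt(4.0 * math.pi * params.lambda_outer * kbt)
    return prefactor * thermal * _franck_condon_sum(delta_g, params)


def marcus_rate(delta_g: float, distance: float, params: RateParameters) -> float:
    """Classical single-Gaussian Marcus rate (1/s), the D -> 0 limit.

    Uses ``lambda_outer`` as the full reorganization energy; serves as a
    closed-form reference for the vibronic expression.
    """
    v_sq = coupling_squared(distance, params)
    lam = params.lambda_outer
    kbt = KB_EV * params.temperature
    gap = delta_g + lam
    return (
        (2.0 * math.pi / HBAR_EV_S)
        * v_sq
        / math.sqrt(4.0 * math.pi * lam * kbt)
        * math.exp(-gap * gap / (4.0 * lam * kbt))
    )
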