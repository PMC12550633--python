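"""Hole-occupancy microstates, state energies and allowed transitions.

A microstate is a 0/1 occupancy vector over the landscape's sites in its
declared site order.  The state space at fixed total hole count is the set
of all such vectors with that many ones, enumerated lexicographically.
State energies are sums of occupied-site potentials (unit hole charge, so
V maps to eV) plus any pairwise interaction terms whose partner sites are
both occupied; single-site occupancy therefore sees only the intrinsic
potential, which is what relaxes the second dimer hole after the first
departs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import NamedTuple

import numpy as np

from .landscape import Edge, Landscape

__all__ = ["Microstate", "StateSpace", "Transition", "enumerate_states",
           "state_energy", "allowed_transitions"]

Microstate = tuple  # 0/1 occupancy tuple in landscape site order


class Transition(NamedTuple):
    """A single-hole hop between two microstates along one edge."""

    from_index: int
    to_index: int
    donor_id: str
    acceptor_id: str
    edge: Edge


@dataclass(frozen=True)
class StateSpace:
    landscape: Landscape
    n_holes: int
    states: tuple  # lexicographically ordered occupancy tuples

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state) -> int:
        return self._index_map()[tuple(state)]

    def _index_map(self) -> dict:
        # cached lazily on the instance
        cache = self.__dict__.get("_idx")
        if cache is None:
            cache = {s: i for i, s in enumerate(self.states)}
            object.__setattr__(self, "_idx", cache)
        return cache

    def occupancy_matrix(self) -> np.ndarray:
        """(n_states, n_sites) 0/1 array in state-space order."""
        return np.array(self.states, dtype=float)

    def state_of_sites(self, occupied_ids) -> int:
        """Index of the state with holes on exactly the given cofactor ids."""
        occ = [0] * len(self.landscape.site_order)
        for cid in occupied_ids:
            occ[self.landscape.site_index(cid)] = 1
        return self.index(tuple(occ))


def enumerate_states(landscape: Landscape, n_holes: int) -> StateSpace:
    """All occupancy vectors with exactly ``n_holes`` holes, lex ordered."""
    n_sites = len(landscape.site_order)
    if not 0 <= n_holes <= n_sites:
        raise ValueError(
            f"n_holes must be in [0, {n_sites}], got {n_holes}"
        )
    states = sorted(
        tuple(1 if i in positions else 0 for i in range(n_sites))
        for positions in itertools.combinations(range(n_sites), n_holes)
    )
    assert len(states) == comb(n_sites, n_holes)
    return StateSpace(landscape=landscape, n_holes=n_holes, states=tuple(states))


def state_energy(state, landscape: Landscape) -> float:
    """Free energy of a microstate in eV.

    ``sum_i n_i * potential_i + sum_(a,b) epsilon_ab * n_a * n_b``.
    """
    order = landscape.site_order
    if len(state) != len(order):
        raise ValueError("state length does not match landscape site count")
    energy = sum(
        n * c.potential for n, c in zip(state, landscape.cofactors)
    )
    for term in landscape.interactions:
        ia = order.index(term.site_a)
        ib = order.index(term.site_b)
        energy += term.epsilon * state[ia] * state[ib]
    return energy


def allowed_transitions(space: StateSpace) -> list:
    """Single-hole hops across declared edges, both directions.

    Each transition moves exactly one hole from an occupied site to an
    empty site joined by a landscape edge; double occupancy can never be
    produced.  The result is symmetric: (a -> b) is listed iff (b -> a) is.
    """
    landscape = space.landscape
    transitions = []
    for i, state in enumerate(space.states):
        for edge in landscape.edges:
            for donor, acceptor in (
                (edge.donor_id, edge.acceptor_id),
                (edge.acceptor_id, edge.donor_id),
            ):
                di = landscape.site_index(donor)
                ai = landscape.site_index(acceptor)
                if state[di] == 1 and state[ai] == 0:
                    target = list(state)
                    target[di] = 0
                    target[ai] = 1
                    j = space.index(tuple(target))
                    transitions.append(Transition(i, j, donor, acceptor, edge))
    return transitions
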