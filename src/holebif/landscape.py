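"""Hole-hopping network data model and config I/O.

A :class:`Landscape` is an abstract weighted graph: redox cofactors (nodes)
carrying potentials in V, hop edges carrying edge-to-edge distances in
angstroms, and pairwise hole-hole interaction terms in eV that act only
when both partner sites are occupied.  Potentials are stored against the
network's internal reference (the cold terminus at 1.0 V); no conversion
to an electrochemical reference electrode is attempted.

The canonical fixture :func:`fig8_landscape` is an optimized two-pathway
bifurcation design: a tryptophan dimer (the bifurcation site) feeding a
three-cofactor "hot" chain and a three-cofactor "cold" chain.  Both dimer
sites sit at the intrinsic monomer potential of 1.1 V; a 1.6 eV repulsion
term raises the effective potential of the first departing hole to 2.7 V
while the remaining hole relaxes back to 1.1 V once its partner leaves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import yaml

from .rates import RateParameters

__all__ = [
    "ROLES",
    "PATHWAYS",
    "Cofactor",
    "Edge",
    "InteractionTerm",
    "Landscape",
    "LandscapeError",
    "load_landscape",
    "save_landscape",
    "fig8_landscape",
]

ROLES = ("bifurcation_site", "relay", "terminus")
PATHWAYS = ("hot", "cold", "bifurcation")


class LandscapeError(ValueError):
    """Raised when a landscape document or object fails validation."""


@dataclass(frozen=True)
class Cofactor:
    id: str
    role: str
    pathway: str
    potential: float  # V vs the network's internal reference

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LandscapeError(f"cofactor {self.id!r}: unknown role {self.role!r}")
        if self.pathway not in PATHWAYS:
            raise LandscapeError(
                f"cofactor {self.id!r}: unknown pathway {self.pathway!r}"
            )
        import math

        if not math.isfinite(self.potential):
            raise LandscapeError(f"cofactor {self.id!r}: potential must be finite")


@dataclass(frozen=True)
class Edge:
    donor_id: str
    acceptor_id: str
    distance: float  # angstrom, closest heavy atoms

    def __post_init__(self) -> None:
        if not (self.distance > 0):
            raise LandscapeError(
                f"edge {self.donor_id}-{self.acceptor_id}: "
                f"distance must be > 0 A, got {self.distance}"
            )
        if self.donor_id == self.acceptor_id:
            raise LandscapeError(f"edge {self.donor_id}: self-loop not allowed")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.donor_id, self.acceptor_id))


@dataclass(frozen=True)
class InteractionTerm:
    site_a: str
    site_b: str
    epsilon: float  # eV, added when both sites hold a hole

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise LandscapeError(
                f"interaction {self.site_a}-{self.site_b}: epsilon must be >= 0 eV"
            )
        if self.site_a == self.site_b:
            raise LandscapeError("interaction must couple two distinct sites")


@dataclass(frozen=True)
class Landscape:
    """Validated hole-hopping network.

    Site order is the declaration order of ``cofactors``; microstate
    occupancy vectors downstream use this ordering.
    """

    cofactors: tuple
    edges: tuple
    interactions: tuple = ()
    rate_params: RateParameters = field(default_factory=RateParameters)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cofactors", tuple(self.cofactors))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        self._validate()

    # -- lookups -----------------------------------------------------------
    @property
    def site_order(self) -> tuple:
        return tuple(c.id for c in self.cofactors)

    @property
    def temperature(self) -> float:
        return self.rate_params.temperature

    def site_index(self, cofactor_id: str) -> int:
        try:
            return self.site_order.index(cofactor_id)
        except ValueError:
            raise LandscapeError(f"unknown cofactor id {cofactor_id!r}") from None

    def cofactor(self, cofactor_id: str) -> Cofactor:
        return self.cofactors[self.site_index(cofactor_id)]

    def termini(self) -> dict:
        """Map pathway -> terminus cofactor for each declared terminus."""
        return {c.pathway: c for c in self.cofactors if c.role == "terminus"}

    def bifurcation_sites(self) -> tuple:
        return tuple(c for c in self.cofactors if c.role == "bifurcation_site")

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        ids = [c.id for c in self.cofactors]
        if not ids:
            raise LandscapeError("landscape has no cofactors")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise LandscapeError(f"duplicate cofactor id(s): {sorted(dupes)}")
        known = set(ids)
        pairs = set()
        for e in self.edges:
            for endpoint in (e.donor_id, e.acceptor_id):
                if endpoint not in known:
                    raise LandscapeError(
                        f"edge {e.donor_id}-{e.acceptor_id} references "
                        f"unknown cofactor id {endpoint!r}"
                    )
            if e.pair in pairs:
                raise LandscapeError(
                    f"duplicate edge for pair {sorted(e.pair)}; "
                    "edges are undirected, declare each pair once"
                )
            pairs.add(e.pair)
        for term in self.interactions:
            for endpoint in (term.site_a, term.site_b):
                if endpoint not in known:
                    raise LandscapeError(
                        f"interaction references unknown cofactor id {endpoint!r}"
                    )
        # Connectivity: sites linked by an interaction term form one physical
        # module (the bifurcating dimer), so interaction pairs count as links.
        g = nx.Graph()
        g.add_nodes_from(known)
        g.add_edges_from((e.donor_id, e.acceptor_id) for e in self.edges)
        g.add_edges_from((t.site_a, t.site_b) for t in self.interactions)
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise LandscapeError(f"hop graph is disconnected: components {comps}")

    # -- convenience -------------------------------------------------------
    def with_overrides(
        self,
        potentials: dict | None = None,
        distances: dict | None = None,
    ) -> "Landscape":
        """Return a copy with selected potentials / edge distances replaced.

        ``potentials`` maps cofactor id -> V; ``distances`` maps a frozenset
        (or 2-tuple) of endpoint ids -> angstroms.
        """
        potentials = dict(potentials or {})
        dist = {frozenset(k): v for k, v in (distances or {}).items()}
        cofs = []
        for c in self.cofactors:
            if c.id in potentials:
                c = Cofactor(c.id, c.role, c.pathway, float(potentials.pop(c.id)))
            cofs.append(c)
        if potentials:
            raise LandscapeError(
                f"potential override for unknown id(s): {sorted(potentials)}"
            )
        edges = []
        for e in self.edges:
            if e.pair in dist:
                e = Edge(e.donor_id, e.acceptor_id, float(dist.pop(e.pair)))
            edges.append(e)
        if dist:
            raise LandscapeError(
                f"distance override for unknown edge(s): "
                f"{[sorted(p) for p in dist]}"
            )
        return Landscape(cofs, edges, self.interactions, self.rate_params)


# ---------------------------------------------------------------------------
# Config I/O.  Keys carry explicit unit suffixes (V, A, eV, K) so that a
# document with bare, unit-less fields fails loudly.
# ---------------------------------------------------------------------------

_RATE_KEYS = {
    "lambda_outer_eV": "lambda_outer",
    "hbar_omega_eV": "hbar_omega",
    "huang_rhys": "huang_rhys",
    "beta_inv_A": "beta",
    "V0_eV": "v0",
    "n_max": "n_max",
}


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        bare = key.split("_")[0]
        hint = f" (unit-suffixed key required)" if bare in mapping else ""
        raise LandscapeError(f"{context}: missing required field {key!r}{hint}")
    return mapping[key]


def load_landscape(source) -> Landscape:
    """Parse a landscape config (YAML text, path, or open file).

    The document must supply cofactors, edges, interaction terms, the
    temperature and the rate parameters, all with explicit unit suffixes;
    see :func:`save_landscape` for the schema.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise LandscapeError("landscape config must be a mapping")

    temperature = float(_require(doc, "temperature_K", "landscape"))
    rp_doc = _require(doc, "rate_params", "landscape")
    rp_kwargs = {"temperature": temperature}
    for key, attr in _RATE_KEYS.items():
        rp_kwargs[attr] = _require(rp_doc, key, "rate_params")
    rp_kwargs["n_max"] = int(rp_kwargs["n_max"])
    rate_params = RateParameters(**rp_kwargs)

    cofactors = []
    for c in _require(doc, "cofactors", "landscape"):
        cofactors.append(
            Cofactor(
                id=str(_require(c, "id", "cofactor")),
                role=str(_require(c, "role", f"cofactor {c.get('id')}")),
                pathway=str(_require(c, "pathway", f"cofactor {c.get('id')}")),
                potential=float(_require(c, "potential_V", f"cofactor {c.get('id')}")),
            )
        )
    edges = []
    for e in _require(doc, "edges", "landscape"):
        edges.append(
            Edge(
                donor_id=str(_require(e, "donor", "edge")),
                acceptor_id=str(_require(e, "acceptor", "edge")),
                distance=float(
                    _require(e, "distance_A", f"edge {e.get('donor')}-{e.get('acceptor')}")
                ),
            )
        )
    interactions = []
    for t in doc.get("interactions", []) or []:
        interactions.append(
            InteractionTerm(
                site_a=str(_require(t, "site_a", "interaction")),
                site_b=str(_require(t, "site_b", "interaction")),
                epsilon=float(_require(t, "epsilon_eV", "interaction")),
            )
        )
    return Landscape(cofactors, edges, interactions, rate_params)


def save_landscape(landscape: Landscape, destination=None) -> str:
    """Serialize a landscape to the YAML config schema.

    Returns the YAML text; if ``destination`` (path or file) is given the
    text is also written there.
    """
    rp = landscape.rate_params
    doc = {
        "temperature_K": rp.temperature,
        "cofactors": [
            {
                "id": c.id,
                "role": c.role,
                "pathway": c.pathway,
                "potential_V": c.potential,
            }
            for c in landscape.cofactors
        ],
        "edges": [
            {"donor": e.donor_id, "acceptor": e.acceptor_id, "distance_A": e.distance}
            for e in landscape.edges
        ],
        "interactions": [
            {"site_a": t.site_a, "site_b": t.site_b, "epsilon_eV": t.epsilon}
            for t in landscape.interactions
        ],
        "rate_params": {
            "lambda_outer_eV": rp.lambda_outer,
            "hbar_omega_eV": rp.hbar_omega,
            "huang_rhys": rp.huang_rhys,
            "beta_inv_A": rp.beta,
            "V0_eV": rp.v0,
            "n_max": rp.n_max,
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


def fig8_landscape(epsilon: float = 1.6) -> Landscape:
    """Canonical optimized bifurcation design (8 sites, 6 edges).

    Site order: hot branch first (W1, WH1, WH2, T_hot), then cold branch
    (W2, WL1, WL2, T_cold).  Dimer sites W1 and W2 carry the intrinsic
    tryptophan potential 1.1 V; ``epsilon`` (eV) is the hole-hole repulsion
    active while both are occupied, making the first hole leave at an
    effective 2.7 V.  All edges are 5 A except the 10 A dimer-to-cold-chain
    edge, which biases the first (hot) hole onto the short hot chain.
    """
    cofactors = [
        Cofactor("W1", "bifurcation_site", "bifurcation", 1.1),
        Cofactor("WH1", "relay", "hot", 1.9),
        Cofactor("WH2", "relay", "hot", 1.75),
        Cofactor("T_hot", "terminus", "hot", 1.6),
        Cofactor("W2", "bifurcation_site", "bifurcation", 1.1),
        Cofactor("WL1", "relay", "cold", 1.1),
        Cofactor("WL2", "relay", "cold", 1.05),
        Cofactor("T_cold", "terminus", "cold", 1.0),
    ]
    edges = [
        Edge("W1", "WH1", 5.0),
        Edge("WH1", "WH2", 5.0),
        Edge("WH2", "T_hot", 5.0),
        Edge("W2", "WL1", 10.0),
        Edge("WL1", "WL2", 5.0),
        Edge("WL2", "T_cold", 5.0),
    ]
    interactions = [InteractionTerm("W1", "W2", epsilon)]
    return Landscape(cofactors, edges, interactions, RateParameters())
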