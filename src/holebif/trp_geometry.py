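"""Geometry statistics of a tryptophan pair.

Three descriptors of the mutual arrangement of two Trp side chains,
computed from atomic coordinates: the closest hydrogen-hydrogen contact
distance, the angle between the least-squares planes of the two indole
rings (folded to [0, 90] degrees), and the area of overlap of the two
ring outlines projected onto the mean plane of the first ring.

Conventions: the projection plane is the least-squares plane of ring A,
and each ring outline is the convex hull of its nine projected indole
atoms (indole is convex to good approximation, which sidesteps outline
ordering).  All three statistics are invariant under rigid-body motion
of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

__all__ = [
    "INDOLE_RING_ATOMS",
    "TrpPairGeometry",
    "closest_hh_distance",
    "interplane_angle",
    "ring_overlap_area",
    "load_trp_pair",
    "pair_statistics",
]

# The nine heavy atoms of the indole ring system, standard PDB names.
INDOLE_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass(frozen=True)
class TrpPairGeometry:
    """Labeled coordinates (angstrom) of two Trp residues.

    ``atoms_a`` / ``atoms_b`` map atom name -> length-3 coordinate array;
    hydrogens are any atoms whose name starts with "H".
    """

    atoms_a: dict
    atoms_b: dict

    def __post_init__(self) -> None:
        for tag, atoms in (("a", self.atoms_a), ("b", self.atoms_b)):
            missing = [n for n in INDOLE_RING_ATOMS if n not in atoms]
            if missing:
                raise ValueError(
                    f"residue {tag} is missing indole ring atom(s): {missing}"
                )

    def hydrogens(self, which: str) -> np.ndarray:
        atoms = self.atoms_a if which == "a" else self.atoms_b
        coords = [xyz for name, xyz in atoms.items() if name.startswith("H")]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def ring(self, which: str) -> np.ndarray:
        atoms = self.atoms_a if which == "a" else self.atoms_b
        return np.array([atoms[n] for n in INDOLE_RING_ATOMS], dtype=float)

    def transformed(self, rotation=None, translation=None) -> "TrpPairGeometry":
        """Apply one rigid-body transform to both residues."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        shift = np.zeros(3) if translation is None else np.asarray(translation, float)

        def apply(atoms: dict) -> dict:
            return {n: rot @ np.asarray(x, float) + shift for n, x in atoms.items()}

        return TrpPairGeometry(apply(self.atoms_a), apply(self.atoms_b))


def closest_hh_distance(pair: TrpPairGeometry) -> float:
    """Minimum hydrogen-hydrogen distance between the residues, angstrom."""
    ha, hb = pair.hydrogens("a"), pair.hydrogens("b")
    if ha.size == 0 or hb.size == 0:
        raise ValueError("both residues must contain at least one hydrogen")
    diff = ha[:, None, :] - hb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def _plane_basis(ring: np.ndarray):
    """Least-squares plane of ring atoms: (centroid, in-plane e1, e2, normal)."""
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    if singular[1] < 1e-8 * max(singular[0], 1.0):
        raise ValueError("ring atoms are degenerate (collinear); no plane defined")
    return centroid, vt[0], vt[1], vt[2]


def interplane_angle(pair: TrpPairGeometry) -> float:
    """Angle between the two indole best-fit planes, degrees in [0, 90]."""
    _, _, _, normal_a = _plane_basis(pair.ring("a"))
    _, _, _, normal_b = _plane_basis(pair.ring("b"))
    cosine = abs(float(np.dot(normal_a, normal_b)))
    return float(np.degrees(np.arccos(np.clip(cosine, 0.0, 1.0))))


def ring_overlap_area(pair: TrpPairGeometry) -> float:
    """Projected overlap area of the two ring outlines, angstrom^2.

    Both rings are projected onto the least-squares plane of ring A; each
    outline is the convex hull of its projected atoms and the returned
    value is the area of the polygon intersection (0 if disjoint).
    """
    centroid, e1, e2, _ = _plane_basis(pair.ring("a"))

    def project(ring: np.ndarray):
        centered = ring - centroid
        pts = np.column_stack([centered @ e1, centered @ e2])
        return MultiPoint(pts.tolist()).convex_hull

    poly_a, poly_b = project(pair.ring("a")), project(pair.ring("b"))
    if poly_a.geom_type != "Polygon" or poly_b.geom_type != "Polygon":
        # a ring seen edge-on projects to a segment: zero overlap area
        return 0.0
    return float(poly_a.intersection(poly_b).area)


def pair_statistics(pair: TrpPairGeometry) -> dict:
    """All three descriptors as a dict (distance_A, angle_deg, overlap_A2)."""
    return {
        "closest_hh_distance_A": closest_hh_distance(pair),
        "interplane_angle_deg": interplane_angle(pair),
        "ring_overlap_area_A2": ring_overlap_area(pair),
    }


def load_trp_pair(pdb_path, residue_a, residue_b, model_index: int = 0) -> TrpPairGeometry:
    """Read a Trp pair from a PDB file.

    ``residue_a`` / ``residue_b`` are (chain_id, resseq) tuples.  Multi-model
    files (e.g. trajectory frames written as MODEL records) are addressed
    with ``model_index``.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse synthetic PDBs
        structure = PDBParser(QUIET=True).get_structure("pair", str(pdb_path))
    models = list(structure)
    try:
        model = models[model_index]
    except IndexError:
        raise ValueError(
            f"model {model_index} not in file ({len(models)} model(s))"
        ) from None

    def residue_atoms(chain_id, resseq) -> dict:
        chain = model[chain_id]
        residue = chain[(" ", int(resseq), " ")]
        return {atom.get_name(): atom.get_coord().astype(float) for atom in residue}

    return TrpPairGeometry(
        atoms_a=residue_atoms(*residue_a), atoms_b=residue_atoms(*residue_b)
    )
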