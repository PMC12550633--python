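"""Hole-hole repulsion energetics of the bifurcating Trp pair.

The interaction energy between the two tryptophan radical cations is
estimated as the shift of one residue's HOMO energy when its partner is
charged versus neutral.  Snapshot values computed along an MD trajectory
(shipped here as a packaged CSV) average to 1.63 eV; the rounded 1.6 eV
sets the repulsion term of the canonical kinetic landscape.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "SnapshotEnergy",
    "interaction_energy",
    "mean_interaction",
    "read_snapshot_table",
    "write_snapshot_table",
    "packaged_snapshot_table",
]


@dataclass(frozen=True)
class SnapshotEnergy:
    label: str  # snapshot time tag, e.g. "1 ps"
    e_interaction: float  # eV

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.e_interaction):
            raise ValueError(f"snapshot {self.label!r}: energy must be finite")


def interaction_energy(e_homo_charged: float, e_homo_neutral: float) -> float:
    """Repulsion energy (eV) as the HOMO shift charged minus neutral."""
    return e_homo_charged - e_homo_neutral


def mean_interaction(snapshots) -> float:
    """Arithmetic mean interaction energy (eV) over snapshots."""
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("cannot average an empty snapshot list")
    return sum(s.e_interaction for s in snapshots) / len(snapshots)


def read_snapshot_table(source) -> list:
    """Parse a two-column CSV (label, energy_eV) into snapshot records.

    Accepts a path, CSV text, or an open file.  A header row is allowed.
    Malformed rows raise with their line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and source.endswith(".csv"):
        text = Path(source).read_text()
    else:
        text = source
    rows = list(csv.reader(io.StringIO(text)))
    rows = [(lineno, row) for lineno, row in enumerate(rows, start=1) if row]
    if not rows:
        raise ValueError("snapshot table is empty")
    snapshots = []
    for lineno, row in rows:
        if len(row) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(row)}")
        label, value = row[0].strip(), row[1].strip()
        try:
            energy = float(value)
        except ValueError:
            if lineno == 1 and not snapshots:
                continue  # header row
            raise ValueError(
                f"line {lineno}: energy {value!r} is not a number"
            ) from None
        snapshots.append(SnapshotEnergy(label=label, e_interaction=energy))
    if not snapshots:
        raise ValueError("snapshot table has no data rows")
    return snapshots


def write_snapshot_table(snapshots, destination=None) -> str:
    """Serialize snapshots back to the two-column CSV schema."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["snapshot", "e_interaction_eV"])
    for s in snapshots:
        writer.writerow([s.label, repr(s.e_interaction)])
    text = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


def packaged_snapshot_table() -> list:
    """The 11 MD-snapshot repulsion energies bundled with the package."""
    text = (
        resources.files("holebif")
        .joinpath("data/trp_repulsion_snapshots.csv")
        .read_text()
    )
    return read_snapshot_table(text)
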