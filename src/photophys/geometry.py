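"""Coordinate-geometry utilities for comparing crystallographic and modelled structures.

Torsion (dihedral) angles are reported as unsigned values in [0, 180]
degrees, matching the convention used when quoting, e.g., an alkyl-N-aryl
twist of 152.05 or 159.0 degrees; distances are plain Euclidean norms in
the input units (Angstrom for crystallographic coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AtomSet", "dihedral", "distance", "read_xyz", "read_cif_atoms"]


class CollinearError(ValueError):
    pass


@dataclass(frozen=True)
class AtomSet:
    """Labelled Cartesian coordinates (labels unique, coordinates finite)."""

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if coords.shape[0] != len(self.labels):
            raise ValueError("one label per coordinate triple required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atom labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def dihedral(self, a: str, b: str, c: str, d: str) -> float:
        return dihedral(self[a], self[b], self[c], self[d])

    def distance(self, a: str, b: str) -> float:
        return distance(self[a], self[b])


def distance(a, b) -> float:
    """Euclidean distance between two points."""
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, unsigned, in [0, 180].

    Standard definition: the angle between the half-planes spanned by
    (a, b, c) and (b, c, d) about the b-c axis. Three collinear consecutive
    points leave the angle undefined and raise ``CollinearError``.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if norm2 == 0 or np.linalg.norm(n1) < 1e-12 * max(1, np.linalg.norm(b1)) * norm2 \
            or np.linalg.norm(n2) < 1e-12 * max(1, np.linalg.norm(b3)) * norm2:
        raise CollinearError("three consecutive points are collinear; dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2 / norm2), n2))
    return float(abs(np.degrees(np.arctan2(y, x))))


def read_xyz(path: str | Path) -> AtomSet:
    """Read a standard XYZ file (count line, comment line, 'element x y z' rows).

    Duplicate element symbols are suffixed with a running index so labels
    stay unique (C, C2, C3, ...).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("not a valid XYZ file (needs count, comment, atom lines)")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("first XYZ line must be the atom count") from exc
    labels: list[str] = []
    coords: list[list[float]] = []
    seen: dict[str, int] = {}
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ atom line: {ln!r}")
        el = parts[0]
        seen[el] = seen.get(el, 0) + 1
        labels.append(el if seen[el] == 1 else f"{el}{seen[el]}")
        coords.append([float(x) for x in parts[1:4]])
    if len(labels) != n:
        raise ValueError(f"XYZ header declares {n} atoms, found {len(labels)}")
    return AtomSet(labels=tuple(labels), coords=np.asarray(coords))


def read_cif_atoms(path: str | Path) -> AtomSet:
    """Read labelled Cartesian coordinates from a small-molecule CIF (optional glue).

    Requires ``gemmi``; fractional coordinates are orthogonalised with the
    cell. Intended for checking deposited crystal structures, not for
    refinement.
    """
    import gemmi

    st = gemmi.SmallStructure.from_cif_block(gemmi.cif.read(str(path)).sole_block())
    labels: list[str] = []
    coords: list[list[float]] = []
    for site in st.sites:
        pos = st.cell.orthogonalize(site.fract)
        labels.append(site.label)
        coords.append([pos.x, pos.y, pos.z])
    return AtomSet(labels=tuple(labels), coords=np.asarray(coords))
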