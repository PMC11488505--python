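"""Molecular structure I/O and synthetic fixture generators.

XYZ is the canonical input format (count line, comment line, then
``element x y z`` rows, coordinates in Angstrom); a minimal PDB reader
extracts ATOM/HETATM coordinates.  The synthetic generators emulate the
two application scenarios at desk scale: a pair of closo-carborane-like
B7C2H9 isomers whose boron cages differ in geometry while the element
composition matches, and ABX3 perovskite-like units in cubic, tetragonal
and orthorhombic phases with halide-dependent lattice constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chain_complex import Simplex
from .persistence import PointCloud

__all__ = [
    "MolecularStructure",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "standard_simplex_complex",
    "synth_isomer_pair",
    "synth_perovskite_like",
]


class XYZParseError(ValueError):
    """Malformed XYZ (or PDB) input; carries the offending line number."""


@dataclass(frozen=True)
class MolecularStructure:
    points: PointCloud
    name: str = ""
    comment: str = ""

    def __len__(self) -> int:
        return len(self.points)


def read_xyz(path: str | Path) -> MolecularStructure:
    """Read a standard XYZ file; the declared atom count is cross-checked."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise XYZParseError(f"{path}: line 1: missing atom count")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}: line 1: atom count must be an integer") from None
    comment = lines[1] if len(lines) > 1 else ""
    rows = [l for l in lines[2:] if l.strip()]
    if len(rows) != count:
        raise XYZParseError(
            f"{path}: declared {count} atoms but found {len(rows)} coordinate rows"
        )
    labels, coords = [], []
    for lineno, row in enumerate(rows, start=3):
        parts = row.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected 'element x y z'")
        labels.append(parts[0])
        try:
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError:
            raise XYZParseError(
                f"{path}: line {lineno}: non-numeric coordinate in {row!r}"
            ) from None
    return MolecularStructure(
        points=PointCloud(np.asarray(coords, dtype=float).reshape(-1, 3), tuple(labels)),
        name=path.stem,
        comment=comment,
    )


def write_xyz(structure: MolecularStructure, path: str | Path) -> None:
    pts = structure.points
    lines = [str(len(pts)), structure.comment]
    for label, (x, y, z) in zip(pts.labels, pts.coordinates):
        lines.append(f"{label} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path) -> MolecularStructure:
    """Minimal PDB reader: ATOM/HETATM coordinate extraction only."""
    path = Path(path)
    labels, coords = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        except (ValueError, IndexError):
            raise XYZParseError(f"{path}: line {lineno}: bad coordinate fields") from None
        element = line[76:78].strip() or line[12:16].strip()[:1]
        labels.append(element)
        coords.append([x, y, z])
    if not labels:
        raise XYZParseError(f"{path}: no ATOM/HETATM records found")
    return MolecularStructure(
        points=PointCloud(np.asarray(coords).reshape(-1, 3), tuple(labels)),
        name=path.stem,
    )


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def standard_simplex_complex(n: int) -> list[Simplex]:
    """All 2^{n+1}-1 faces of the standard n-simplex on vertices 0..n."""
    if not 0 <= n <= 8:
        raise ValueError(f"n must be in [0, 8], got {n}")
    from itertools import combinations

    out = []
    for size in range(1, n + 2):
        out.extend(Simplex(c) for c in combinations(range(n + 1), size))
    return out


def _ring(count: int, radius: float, z: float) -> np.ndarray:
    ang = 2 * np.pi * np.arange(count) / count
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(count, z)])


def synth_isomer_pair(seed: int) -> tuple[MolecularStructure, MolecularStructure]:
    """Two synthetic B7C2H9 'isomers' with distinct boron-cage geometries.

    Both clouds share the element multiset (7 B, 2 C, 9 H).  Isomer A puts
    the borons on a pentagonal bipyramid; isomer B uses a capped trigonal
    arrangement (two stacked triangles plus an apex).  Bond-scale distances
    (~1.8 Angstrom B-B) mimic carborane cages; a small seeded jitter breaks
    exact symmetry deterministically.  Synthetic stand-ins: the published
    carborane coordinates are not available.
    """
    rng = np.random.default_rng(seed)

    # isomer A: pentagonal bipyramid (5-ring + 2 apices)
    b_a = np.vstack([
        _ring(5, 1.53, 0.0),
        [[0.0, 0.0, 1.25], [0.0, 0.0, -1.25]],
    ])
    # isomer B: two eclipsed triangles + one apex (capped prism-like cage)
    b_b = np.vstack([
        _ring(3, 1.05, 0.80),
        _ring(3, 1.05, -0.80),
        [[0.0, 0.0, 1.95]],
    ])

    def assemble(borons: np.ndarray) -> PointCloud:
        center = borons.mean(axis=0)
        # carbons cap the cage; hydrogens radiate from cage atoms
        carbons = np.array([center + [2.0, 0.0, 0.6], center + [-2.0, 0.0, -0.6]])
        cage = np.vstack([borons, carbons])
        dirs = cage - center
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        hydro = cage + 1.1 * dirs / norms
        jitter = rng.normal(scale=0.02, size=(len(cage) + len(hydro), 3))
        coords = np.vstack([cage, hydro]) + jitter
        labels = ("B",) * len(borons) + ("C",) * 2 + ("H",) * len(hydro)
        return PointCloud(coords, labels)

    a = MolecularStructure(assemble(b_a), name="isomer_A", comment="synthetic B7C2H9-like cage A")
    b = MolecularStructure(assemble(b_b), name="isomer_B", comment="synthetic B7C2H9-like cage B")
    return a, b


#: lattice constants (Angstrom) scaling with the halide radius
_HALIDE_A = {"Cl": 5.68, "Br": 5.93, "I": 6.28}
#: phase-dependent axial distortions of the ABX3 unit
_PHASE_AXES = {
    "cubic": (1.0, 1.0, 1.0),
    "tetragonal": (0.99, 0.99, 1.06),
    "orthorhombic": (0.97, 1.00, 1.08),
}


def synth_perovskite_like(
    phase: str,
    halide: str,
    jitter: float = 0.0,
    seed: int = 0,
) -> MolecularStructure:
    """One ABX3-like unit cell emulating a methylammonium lead halide.

    The B site (Pb) sits at the cell center, the A site (the organic
    cation, reduced to one point) at the origin corner, and the three X
    halides on the face centers adjacent to B, with periodic images of the
    corner and face sites within one cell.  Lattice constants grow
    Cl < Br < I; the phase distorts the axes; ``jitter`` adds seeded
    Gaussian displacement (thermal-sample emulation).
    """
    if phase not in _PHASE_AXES:
        raise ValueError(f"phase must be one of {sorted(_PHASE_AXES)}, got {phase!r}")
    if halide not in _HALIDE_A:
        raise ValueError(f"halide must be one of {sorted(_HALIDE_A)}, got {halide!r}")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    a0 = _HALIDE_A[halide]
    ax, ay, az = (a0 * f for f in _PHASE_AXES[phase])

    labels: list[str] = []
    coords: list[list[float]] = []
    # A-site cation images at the eight cell corners
    for cx in (0.0, 1.0):
        for cy in (0.0, 1.0):
            for cz in (0.0, 1.0):
                labels.append("C")
                coords.append([cx * ax, cy * ay, cz * az])
    # B site (Pb) at the body center
    labels.append("Pb")
    coords.append([0.5 * ax, 0.5 * ay, 0.5 * az])
    # X halides at the six face centers
    for fc in ([0.5, 0.5, 0.0], [0.5, 0.5, 1.0], [0.5, 0.0, 0.5],
               [0.5, 1.0, 0.5], [0.0, 0.5, 0.5], [1.0, 0.5, 0.5]):
        labels.append(halide)
        coords.append([fc[0] * ax, fc[1] * ay, fc[2] * az])

    pts = np.asarray(coords)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return MolecularStructure(
        points=PointCloud(pts, tuple(labels)),
        name=f"{phase}_{halide}",
        comment=f"synthetic ABX3-like unit, phase={phase}, X={halide}, jitter={jitter}",
    )
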