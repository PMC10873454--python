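"""Solvent-accessible surface area and charge profiling.

SASA is computed with a deterministic Shrake-Rupley scheme: each heavy atom
is sampled on a golden-spiral point lattice inflated to ``r_atom + probe``;
a point is accessible if it lies outside every neighbour's inflated sphere.
No random numbers are involved, so results are bit-stable across runs.

Because a fixed world-frame lattice is not rotation-invariant, coordinates
are first posed in a canonical frame (centroid at the origin, axes aligned
to the principal axes of the heavy-atom cloud, with a third-moment sign
convention).  SASA is then invariant under rigid motion of the input up to
eigendecomposition round-off.

Surface residues are defined by relative SASA: residue SASA divided by a
residue-type theoretical maximum (Tien et al. 2013 values), at a
configurable threshold (default 0.25).  Charge profiles count acidic (D, E)
and basic (R, K, H) residues over the whole protein and, given surface
flags, over surface residues only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from xynrin.structio import Residue, Structure, STANDARD_AA3

# solvent-exposure radii (A); hydrogens are ignored
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}

# theoretical maximum residue SASA (A^2), Tien et al. 2013
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

ACIDIC = set("DE")
BASIC = set("RKH")


@dataclass
class SasaResult:
    per_atom_sasa: list[list[float]]  # parallel to structure.residues[i].atoms
    per_residue_sasa: list[float]
    probe_radius: float
    n_sphere_points: int

    def residue_sasa(self, index: int) -> float:
        return self.per_residue_sasa[index]


@dataclass
class SurfaceChargeProfile:
    scope: str  # "whole" | "surface"
    n_acidic: int
    n_basic: int
    n_charged: int
    acidic_basic_ratio: float | None

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "n_acidic": self.n_acidic,
            "n_basic": self.n_basic,
            "n_charged": self.n_charged,
            "acidic_basic_ratio": self.acidic_basic_ratio,
        }


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def canonical_pose(coords: np.ndarray) -> np.ndarray:
    """Pose coordinates in a rigid-motion-invariant frame.

    Centroid to the origin; axes = principal axes of the coordinate cloud,
    each oriented so the third moment along it is non-negative; handedness
    fixed to a proper rotation.  Degenerate (symmetric) clouds fall back to
    the input axes, which is harmless for the single-atom case.
    """
    coords = np.asarray(coords, float)
    center = coords.mean(axis=0)
    x = coords - center
    if len(coords) < 3:
        return x
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    y = x @ vecs
    for k in range(3):
        if np.sum(y[:, k] ** 3) < 0:
            y[:, k] *= -1.0
    return y


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    canonical_frame: bool = True,
) -> SasaResult:
    """Per-atom and per-residue SASA by deterministic sphere sampling."""
    atoms = [(ri, ai, at) for ri, res in enumerate(structure.residues)
             for ai, at in enumerate(res.atoms) if at.element != "H"]
    if not atoms:
        raise ValueError("no heavy atoms")
    coords = np.array([at.coord for _, _, at in atoms])
    radii = np.empty(len(atoms))
    for k, (_, _, at) in enumerate(atoms):
        r = SASA_RADII.get(at.element)
        if r is None:
            raise ValueError(f"unknown element {at.element!r} for atom {at.name}")
        radii[k] = r
    if canonical_frame:
        coords = canonical_pose(coords)
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(len(atoms))
    for k in range(len(atoms)):
        pts = coords[k] + expanded[k] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[k], max_reach)
                     if j != k and np.linalg.norm(coords[j] - coords[k]) < expanded[j] + expanded[k]]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= expanded[j] ** 2
        frac = accessible.mean()
        per_atom[k] = frac * 4.0 * np.pi * expanded[k] ** 2

    per_atom_nested: list[list[float]] = [
        [0.0] * len(res.atoms) for res in structure.residues]
    per_residue = [0.0] * len(structure.residues)
    for k, (ri, ai, _) in enumerate(atoms):
        per_atom_nested[ri][ai] = float(per_atom[k])
        per_residue[ri] += float(per_atom[k])
    return SasaResult(per_atom_nested, per_residue, probe_radius, n_sphere_points)


def classify_surface(
    structure: Structure,
    sasa: SasaResult,
    rsasa_threshold: float = 0.25,
) -> list[bool]:
    """Flag residues as surface when relative SASA >= threshold."""
    flags = []
    for ri, res in enumerate(structure.residues):
        ref = MAX_SASA.get(res.res_name)
        if ref is None:
            raise ValueError(f"no reference max-SASA for residue type {res.res_name!r}")
        flags.append(sasa.per_residue_sasa[ri] / ref >= rsasa_threshold)
    return flags


def relative_sasa(structure: Structure, sasa: SasaResult) -> list[float]:
    out = []
    for ri, res in enumerate(structure.residues):
        ref = MAX_SASA.get(res.res_name)
        if ref is None:
            raise ValueError(f"no reference max-SASA for residue type {res.res_name!r}")
        out.append(sasa.per_residue_sasa[ri] / ref)
    return out


def charge_profile(
    sequence_or_structure: str | Structure,
    surface_flags: list[bool] | None = None,
) -> dict[str, SurfaceChargeProfile]:
    """Acidic/basic residue counts and ratio, whole protein and (optionally)
    surface-restricted.  Histidine counts as basic."""
    if isinstance(sequence_or_structure, Structure):
        seq = sequence_or_structure.sequence()
    else:
        seq = sequence_or_structure.upper()
    profiles = {"whole": _count_charges(seq, "whole")}
    if surface_flags is not None:
        if len(surface_flags) != len(seq):
            raise ValueError("surface_flags length does not match residue count")
        surf_seq = "".join(c for c, f in zip(seq, surface_flags) if f)
        profiles["surface"] = _count_charges(surf_seq, "surface")
    return profiles


def _count_charges(seq: str, scope: str) -> SurfaceChargeProfile:
    n_acidic = sum(1 for c in seq if c in ACIDIC)
    n_basic = sum(1 for c in seq if c in BASIC)
    ratio = n_acidic / n_basic if n_basic else None
    return SurfaceChargeProfile(scope, n_acidic, n_basic, n_acidic + n_basic, ratio)
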