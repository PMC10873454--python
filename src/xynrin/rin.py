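"""Residue interaction network (RIN) construction.

Six geometric interaction types are detected between residue pairs, each by
a distance rule on a fixed set of "corresponding atoms":

===========  =============================================================
type         rule (defaults)
===========  =============================================================
HBOND        donor-capable N/O heavy atom to acceptor-capable N/O heavy
             atom, d <= 3.5 A
VDW          side-chain heavy atoms (plus C-beta): d <= r_i + r_j + 0.5 A
SSBOND       cysteine SG to SG, d <= 2.5 A
IONIC        negative-group oxygen (Asp/Glu carboxylate, C-terminal OXT)
             to positive-group nitrogen (Lys NZ, Arg NE/NH1/NH2,
             His ND1/NE2, N-terminal backbone N), d <= 4.0 A
PIPI         aromatic ring centroid to ring centroid, d <= 6.5 A
PICATION     ring centroid to cation point (Lys NZ, Arg guanidinium
             centroid), d <= 5.0 A
===========  =============================================================

All criteria are heavy-atom, distance-only.  Residue pairs closer than
``sequence_separation_min`` in author numbering within a chain are excluded
(covalent neighbours).  One edge is kept per (residue pair, type), at the
minimal qualifying distance; a pair may carry several types.  Detection is
grid-accelerated with a k-d tree; tests hold it to an all-pairs oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from xynrin.structio import Residue, Structure, STANDARD_AA3

logger = logging.getLogger(__name__)


class IType(str, Enum):
    HBOND = "HBOND"
    VDW = "VDW"
    SSBOND = "SSBOND"
    IONIC = "IONIC"
    PIPI = "PIPI"
    PICATION = "PICATION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class InteractionConfig:
    hbond_cutoff: float = 3.5
    vdw_slack: float = 0.5
    disulfide_cutoff: float = 2.5
    ionic_cutoff: float = 4.0
    pipi_cutoff: float = 6.5
    pication_cutoff: float = 5.0
    sequence_separation_min: int = 2
    include_his_aromatic: bool = True
    his_as_cation: bool = False
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self) -> None:
        for name in ("hbond_cutoff", "vdw_slack", "disulfide_cutoff",
                     "ionic_cutoff", "pipi_cutoff", "pication_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sequence_separation_min < 0:
            raise ValueError("sequence_separation_min must be >= 0")


ResidueId = tuple[str, int, str, str]  # chain, seq_num, icode, res_name


def residue_id(res: Residue) -> ResidueId:
    return (res.chain_id, res.seq_num, res.insertion_code, res.res_name)


@dataclass(frozen=True)
class InteractionEdge:
    residue_a: ResidueId
    residue_b: ResidueId
    itype: IType
    distance: float
    atoms: tuple[str, str]
    pair_label: str = ""

    def __post_init__(self) -> None:
        if self.residue_a[:3] == self.residue_b[:3]:
            raise ValueError("self-edge")
        # canonical unordered form: (a, b) sorted by (chain, seq_num, icode)
        if self.residue_a[:3] > self.residue_b[:3]:
            a, b = self.residue_a, self.residue_b
            object.__setattr__(self, "residue_a", b)
            object.__setattr__(self, "residue_b", a)
            object.__setattr__(self, "atoms", (self.atoms[1], self.atoms[0]))

    @property
    def pair_key(self) -> tuple[tuple, tuple]:
        return (self.residue_a[:3], self.residue_b[:3])


@dataclass
class RINSummary:
    n_edges: int
    n_nodes: int
    edge_node_ratio: float | None
    per_type: dict[str, int]
    pipi_pairs: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "n_nodes": self.n_nodes,
            "edge_node_ratio": self.edge_node_ratio,
            "per_type": dict(self.per_type),
            "pipi_pairs": dict(self.pipi_pairs),
        }


# ---------------------------------------------------------------------------
# chemistry tables

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# side-chain hydrogen-bond capable N/O heavy atoms (standard chemistry)
_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
_SC_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

NEGATIVE_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

POSITIVE_ATOMS = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}}

AROMATIC_RINGS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "PHE": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "HIS": [("5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "TRP": [("5", ("CG", "CD1", "CD2", "NE1", "CE2")),
            ("6", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"))],
}


def _is_donor(res: Residue, atom_name: str, is_nterm: bool) -> bool:
    if atom_name == "N" and res.res_name != "PRO":
        return True
    if atom_name == "N" and res.res_name == "PRO" and is_nterm:
        return True
    return atom_name in _SC_DONORS.get(res.res_name, ())


def _is_acceptor(res: Residue, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in _SC_ACCEPTORS.get(res.res_name, ())


# ---------------------------------------------------------------------------
# pair iteration machinery

def _pair_allowed(res_i: Residue, res_j: Residue, sep_min: int) -> bool:
    if res_i.key == res_j.key:
        return False
    if res_i.chain_id != res_j.chain_id:
        return True
    return abs(res_i.seq_num - res_j.seq_num) >= sep_min


def _min_distance_edges(
    points_a: np.ndarray,
    meta_a: list[tuple[int, str]],  # (residue index, atom name)
    points_b: np.ndarray,
    meta_b: list[tuple[int, str]],
    cutoff: float,
    residues: list[Residue],
    sep_min: int,
    itype: IType,
    qualifies: Callable[[int, str, int, str, float], bool] | None = None,
    pair_label_fn: Callable[[Residue, Residue], str] | None = None,
) -> list[InteractionEdge]:
    """Grid-accelerated sweep: for every candidate point pair within
    ``cutoff``, keep the minimal qualifying distance per residue pair."""
    if len(points_a) == 0 or len(points_b) == 0:
        return []
    tree_b = cKDTree(points_b)
    pairs = cKDTree(points_a).query_ball_tree(tree_b, cutoff)
    best: dict[tuple[tuple, tuple], tuple[float, str, str, int, int]] = {}
    for ia, hits in enumerate(pairs):
        ri, name_i = meta_a[ia]
        for ib in hits:
            rj, name_j = meta_b[ib]
            if ri == rj:
                continue
            if not _pair_allowed(residues[ri], residues[rj], sep_min):
                continue
            d = float(np.linalg.norm(points_a[ia] - points_b[ib]))
            if d > cutoff:
                continue
            if qualifies is not None and not qualifies(ri, name_i, rj, name_j, d):
                continue
            key = tuple(sorted((ri, rj)))
            prev = best.get(key)
            if prev is None or d < prev[0]:
                if key[0] == ri:
                    best[key] = (d, name_i, name_j, ri, rj)
                else:
                    best[key] = (d, name_j, name_i, rj, ri)
    edges = []
    for (k0, k1), (d, an0, an1, *_) in sorted(best.items()):
        ra, rb = residues[k0], residues[k1]
        label = pair_label_fn(ra, rb) if pair_label_fn else ""
        edges.append(InteractionEdge(residue_id(ra), residue_id(rb), itype, d,
                                     (an0, an1), label))
    return edges


def _chain_terminals(structure: Structure) -> tuple[set[int], set[int]]:
    """Indices of first and last residues of each chain (polymer termini)."""
    first, last = set(), set()
    prev_chain = None
    for i, res in enumerate(structure.residues):
        if res.chain_id != prev_chain:
            first.add(i)
            if i > 0:
                last.add(i - 1)
            prev_chain = res.chain_id
    last.add(len(structure.residues) - 1)
    return first, last


# ---------------------------------------------------------------------------
# detectors

def detect_hbonds(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Hydrogen bonds: donor N/O to acceptor N/O within the cutoff."""
    config = config or InteractionConfig()
    residues = structure.residues
    nterm, _ = _chain_terminals(structure)
    donors, donor_meta, acceptors, acc_meta = [], [], [], []
    for ri, res in enumerate(residues):
        for at in res.atoms:
            if at.element not in ("N", "O"):
                continue
            if _is_donor(res, at.name, ri in nterm):
                donors.append(at.coord)
                donor_meta.append((ri, at.name))
            if _is_acceptor(res, at.name):
                acceptors.append(at.coord)
                acc_meta.append((ri, at.name))
    return _min_distance_edges(
        np.asarray(donors), donor_meta, np.asarray(acceptors), acc_meta,
        config.hbond_cutoff, residues, config.sequence_separation_min, IType.HBOND)


def detect_vdw(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Van der Waals contacts between side-chain heavy atoms (plus C-beta):
    d <= r_i + r_j + slack.  The pair with the smallest surface gap
    (d - r_i - r_j) is retained per residue pair."""
    config = config or InteractionConfig()
    residues = structure.residues
    radii = config.vdw_radii
    pts, meta, rads = [], [], []
    for ri, res in enumerate(residues):
        for at in res.atoms:
            if at.name in BACKBONE_NAMES or at.element == "H":
                continue
            r = radii.get(at.element)
            if r is None:
                raise ValueError(
                    f"unknown element {at.element!r} for atom {at.name} in {res.label()}")
            pts.append(at.coord)
            meta.append((ri, at.name))
            rads.append(r)
    if not pts:
        return []
    pts_arr = np.asarray(pts)
    rads_arr = np.asarray(rads)
    max_r = rads_arr.max()
    search = 2 * max_r + config.vdw_slack
    tree = cKDTree(pts_arr)
    candidate = tree.query_pairs(search, output_type="ndarray")
    best: dict[tuple[int, int], tuple[float, float, str, str]] = {}  # (gap, d, name_i, name_j)
    sep = config.sequence_separation_min
    for ia, ib in candidate:
        ri, name_i = meta[ia]
        rj, name_j = meta[ib]
        if ri == rj or not _pair_allowed(residues[ri], residues[rj], sep):
            continue
        d = float(np.linalg.norm(pts_arr[ia] - pts_arr[ib]))
        gap = d - rads_arr[ia] - rads_arr[ib]
        if gap > config.vdw_slack:
            continue
        key = (min(ri, rj), max(ri, rj))
        prev = best.get(key)
        if prev is None or gap < prev[0]:
            if key[0] == ri:
                best[key] = (gap, d, name_i, name_j)
            else:
                best[key] = (gap, d, name_j, name_i)
    edges = []
    for (k0, k1), (gap, d, an0, an1) in sorted(best.items()):
        edges.append(InteractionEdge(residue_id(residues[k0]), residue_id(residues[k1]),
                                     IType.VDW, d, (an0, an1)))
    return edges


def detect_ssbonds(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Disulfide bonds: cysteine SG-SG within the cutoff."""
    config = config or InteractionConfig()
    residues = structure.residues
    pts, meta = [], []
    for ri, res in enumerate(residues):
        if res.res_name != "CYS":
            continue
        sg = res.atom("SG")
        if sg is not None:
            pts.append(sg.coord)
            meta.append((ri, "SG"))
    pts_arr = np.asarray(pts) if pts else np.empty((0, 3))
    return _min_distance_edges(
        pts_arr, meta, pts_arr, meta,
        config.disulfide_cutoff, residues, config.sequence_separation_min, IType.SSBOND)


def detect_ionic(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Ionic bonds (salt bridges): opposite formal-charge group atoms within
    the cutoff.  Negative: Asp/Glu carboxylate oxygens and the C-terminal
    OXT; positive: Lys NZ, Arg guanidinium nitrogens, His imidazole
    nitrogens, and the N-terminal backbone N."""
    config = config or InteractionConfig()
    residues = structure.residues
    nterm, cterm = _chain_terminals(structure)
    neg, neg_meta, pos, pos_meta = [], [], [], []
    for ri, res in enumerate(residues):
        neg_names = set(NEGATIVE_ATOMS.get(res.res_name, ()))
        if ri in cterm:
            neg_names = neg_names | {"OXT"}
        pos_names = set(POSITIVE_ATOMS.get(res.res_name, ()))
        if ri in nterm:
            pos_names = pos_names | {"N"}
        for at in res.atoms:
            if at.name in neg_names:
                neg.append(at.coord)
                neg_meta.append((ri, at.name))
            if at.name in pos_names:
                pos.append(at.coord)
                pos_meta.append((ri, at.name))
    return _min_distance_edges(
        np.asarray(neg) if neg else np.empty((0, 3)), neg_meta,
        np.asarray(pos) if pos else np.empty((0, 3)), pos_meta,
        config.ionic_cutoff, residues, config.sequence_separation_min, IType.IONIC)


def aromatic_centroids(residue: Residue, include_his: bool = True) -> list[tuple[str, np.ndarray]]:
    """Ring centroids of an aromatic residue (Trp contributes two rings).
    A residue with a missing ring atom is skipped with a logged warning."""
    rings = AROMATIC_RINGS.get(residue.res_name)
    if rings is None:
        return []
    if residue.res_name == "HIS" and not include_his:
        return []
    out = []
    for label, names in rings:
        coords = []
        for n in names:
            at = residue.atom(n)
            if at is None:
                logger.warning("%s: missing ring atom %s; ring skipped", residue.label(), n)
                coords = None
                break
            coords.append(at.coord)
        if coords is not None:
            out.append((label, np.mean(coords, axis=0)))
    return out


def _pipi_label(ra: Residue, rb: Residue) -> str:
    a, b = sorted((STANDARD_AA3.get(ra.res_name, "X"), STANDARD_AA3.get(rb.res_name, "X")))
    return f"{a}-{b}"


def detect_pipi(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Pi-pi stacking: aromatic ring centroids within the cutoff
    (distance-only criterion).  Edges are tagged with an unordered
    one-letter pair label such as ``F-F`` or ``F-Y``."""
    config = config or InteractionConfig()
    residues = structure.residues
    pts, meta = [], []
    for ri, res in enumerate(residues):
        for label, c in aromatic_centroids(res, config.include_his_aromatic):
            pts.append(c)
            meta.append((ri, f"ring{label}"))
    pts_arr = np.asarray(pts) if pts else np.empty((0, 3))
    return _min_distance_edges(
        pts_arr, meta, pts_arr, meta,
        config.pipi_cutoff, residues, config.sequence_separation_min,
        IType.PIPI, pair_label_fn=_pipi_label)


def _cation_points(res: Residue, his_as_cation: bool) -> list[tuple[str, np.ndarray]]:
    if res.res_name == "LYS":
        nz = res.atom("NZ")
        return [("NZ", nz.coord)] if nz is not None else []
    if res.res_name == "ARG":
        atoms = [res.atom(n) for n in ("CZ", "NE", "NH1", "NH2")]
        if any(a is None for a in atoms):
            return []
        return [("GUA", np.mean([a.coord for a in atoms], axis=0))]
    if res.res_name == "HIS" and his_as_cation:
        pts = aromatic_centroids(res, include_his=True)
        return [("IMD", pts[0][1])] if pts else []
    return []


def detect_pication(structure: Structure, config: InteractionConfig | None = None) -> list[InteractionEdge]:
    """Pi-cation: aromatic ring centroid to cation point within the cutoff.
    His is a ring by default but not a cation (ambiguous protonation)."""
    config = config or InteractionConfig()
    residues = structure.residues
    rings, ring_meta, cats, cat_meta = [], [], [], []
    for ri, res in enumerate(residues):
        for label, c in aromatic_centroids(res, config.include_his_aromatic):
            rings.append(c)
            ring_meta.append((ri, f"ring{label}"))
        for label, c in _cation_points(res, config.his_as_cation):
            cats.append(c)
            cat_meta.append((ri, label))
    return _min_distance_edges(
        np.asarray(rings) if rings else np.empty((0, 3)), ring_meta,
        np.asarray(cats) if cats else np.empty((0, 3)), cat_meta,
        config.pication_cutoff, residues, config.sequence_separation_min, IType.PICATION)


DETECTORS: dict[IType, Callable[[Structure, InteractionConfig], list[InteractionEdge]]] = {
    IType.HBOND: detect_hbonds,
    IType.VDW: detect_vdw,
    IType.SSBOND: detect_ssbonds,
    IType.IONIC: detect_ionic,
    IType.PIPI: detect_pipi,
    IType.PICATION: detect_pication,
}


def summarize_edges(edges: list[InteractionEdge]) -> RINSummary:
    per_type = {t.value: 0 for t in IType}
    nodes: set[tuple] = set()
    pipi_pairs: dict[str, int] = {}
    for e in edges:
        per_type[e.itype.value] += 1
        nodes.add(e.residue_a[:3])
        nodes.add(e.residue_b[:3])
        if e.itype is IType.PIPI:
            pipi_pairs[e.pair_label] = pipi_pairs.get(e.pair_label, 0) + 1
    n_edges = len(edges)
    n_nodes = len(nodes)
    ratio = n_edges / n_nodes if n_nodes else None
    return RINSummary(n_edges, n_nodes, ratio, per_type, pipi_pairs)


def build_rin(structure: Structure, config: InteractionConfig | None = None
              ) -> tuple[list[InteractionEdge], RINSummary]:
    """Run all six detectors, deduplicate per (pair, type), and order edges
    deterministically by (chain, residue number, type)."""
    config = config or InteractionConfig()
    edges: list[InteractionEdge] = []
    seen: set[tuple] = set()
    for itype in IType:
        for e in DETECTORS[itype](structure, config):
            key = (e.pair_key, e.itype)
            if key not in seen:
                seen.add(key)
                edges.append(e)
    edges.sort(key=lambda e: (e.residue_a[:3], e.residue_b[:3], e.itype.value))
    return edges, summarize_edges(edges)
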