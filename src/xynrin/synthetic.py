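"""Synthetic fixtures with planted ground truth.

Every stage of the pipeline is testable without external downloads:

* :func:`make_structure_fixture` — toy structures in which each requested
  interaction is planted at ``cutoff - margin`` and each decoy at
  ``cutoff + margin``, with the planted units isolated on a coarse grid so
  no cross-unit contacts arise.
* :func:`make_random_structure` — unconstrained random placements for
  oracle-equivalence testing of the detectors.
* :func:`make_msa_fixture` — alignments with planted group A/B columns over
  a reference plus a homolog cluster.
* :func:`make_charge_fixture` — sequences with exact acidic/basic/neutral
  composition.
* :func:`make_tree_fixture` — trees whose clades have known generating mean
  branch lengths (one clade optionally accelerated).

Residue geometry uses idealized, rigid side-chain templates (literature
bond lengths to within a few hundredths of an Angstrom); physical realism
beyond what the distance detectors require is a non-goal.  All generators
are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from xynrin.rin import IType, InteractionEdge
from xynrin.structio import Atom, Residue, Structure, Alignment

# ---------------------------------------------------------------------------
# idealized residue templates
#
# Each "role" template is anchored with its functional tip (atom or ring
# centroid) at the origin and the rest of the residue in the z <= 0
# half-space, so two templates facing each other along +z realize a tip-tip
# distance exactly.

def _ring(names: tuple[str, ...], radius: float, start_deg: float = 180.0,
          clockwise: bool = False) -> list[tuple[str, str, tuple[float, float, float]]]:
    step = 360.0 / len(names) * (-1 if clockwise else 1)
    out = []
    for i, n in enumerate(names):
        a = math.radians(start_deg + i * step)
        elem = "N" if n.startswith("N") else "C"
        out.append((n, elem, (radius * math.cos(a), radius * math.sin(a), 0.0)))
    return out


_PHE_BACKBONE = [
    ("CB", "C", (-2.25, 0.0, -1.20)),
    ("CA", "C", (-1.90, -1.10, -2.15)),
    ("N", "N", (-2.60, -2.30, -2.00)),
    ("C", "C", (-0.65, -1.50, -2.90)),
    ("O", "O", (-0.70, -1.40, -4.10)),
]

ROLE_TEMPLATES: dict[tuple[str, str], list[tuple[str, str, tuple[float, float, float]]]] = {
    ("GLY", "donorN"): [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, -1.46)),
        ("C", "C", (1.20, 0.0, -2.30)),
        ("O", "O", (2.40, 0.0, -2.20)),
    ],
    ("GLY", "acceptorO"): [
        ("O", "O", (0.0, 0.0, 0.0)),
        ("C", "C", (0.0, 0.0, -1.23)),
        ("CA", "C", (1.30, 0.0, -2.00)),
        ("N", "N", (1.30, 0.0, -3.46)),
    ],
    ("ALA", "cb"): [
        ("CB", "C", (0.0, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, -1.52)),
        ("N", "N", (1.20, 0.60, -2.20)),
        ("C", "C", (-1.20, 0.50, -2.30)),
        ("O", "O", (-1.30, 0.70, -3.50)),
    ],
    ("CYS", "sg"): [
        ("SG", "S", (0.0, 0.0, 0.0)),
        ("CB", "C", (0.0, 0.0, -1.81)),
        ("CA", "C", (1.20, 0.40, -2.75)),
        ("N", "N", (2.45, 0.20, -2.20)),
        ("C", "C", (1.30, -0.50, -3.90)),
        ("O", "O", (2.20, -1.20, -4.30)),
    ],
    ("ASP", "od2"): [
        ("OD2", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (0.0, 0.0, -1.25)),
        ("OD1", "O", (1.09, 0.0, -1.85)),
        ("CB", "C", (-0.80, -1.00, -2.10)),
        ("CA", "C", (-0.20, -1.50, -3.40)),
        ("N", "N", (1.05, -2.20, -3.20)),
        ("C", "C", (-1.20, -2.40, -4.10)),
        ("O", "O", (-2.40, -2.20, -4.20)),
    ],
    ("LYS", "nz"): [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CE", "C", (0.0, 0.0, -1.49)),
        ("CD", "C", (0.95, 0.40, -2.55)),
        ("CG", "C", (0.35, 0.90, -3.80)),
        ("CB", "C", (1.30, 1.50, -4.75)),
        ("CA", "C", (0.75, 2.00, -6.05)),
        ("N", "N", (-0.40, 2.75, -5.80)),
        ("C", "C", (1.75, 2.90, -6.80)),
        ("O", "O", (1.50, 4.10, -6.90)),
    ],
    ("PHE", "ring"): _ring(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.39) + _PHE_BACKBONE,
    ("TYR", "ring"): (_ring(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.39)
                      + [("OH", "O", (2.75, 0.0, 0.0))] + _PHE_BACKBONE),
}


def _his_template() -> list[tuple[str, str, tuple[float, float, float]]]:
    return _ring(("CG", "ND1", "CE1", "NE2", "CD2"), 1.17) + [
        ("CB", "C", (-2.00, 0.0, -1.10)),
        ("CA", "C", (-1.70, -1.10, -2.10)),
        ("N", "N", (-2.50, -2.20, -1.90)),
        ("C", "C", (-0.45, -1.50, -2.85)),
        ("O", "O", (-0.50, -1.40, -4.05)),
    ]


def _trp_template() -> list[tuple[str, str, tuple[float, float, float]]]:
    # pentagon CG-CD1-NE1-CE2-CD2 and hexagon sharing the CD2-CE2 edge
    r5 = 1.20
    penta = _ring(("CG", "CD1", "NE1", "CE2", "CD2"), r5)
    by_name = {n: np.array(xyz) for n, _, xyz in penta}
    cd2, ce2 = by_name["CD2"], by_name["CE2"]
    side = float(np.linalg.norm(cd2 - ce2))
    mid = (cd2 + ce2) / 2.0
    u = mid / np.linalg.norm(mid)
    hex_center = mid + u * (side * math.cos(math.pi / 6))
    # remaining four hexagon vertices by stepping 60 deg around the center
    def rot60(v, k):
        a = math.radians(60 * k)
        c, s = math.cos(a), math.sin(a)
        x, y = v[0], v[1]
        return np.array([c * x - s * y, s * x + c * y, 0.0])
    v_cd2 = cd2 - hex_center
    names = ["CE3", "CZ3", "CH2", "CZ2"]
    # choose rotation direction that walks away from CE2
    step = 1 if np.linalg.norm(hex_center + rot60(v_cd2, 1) - ce2) > 1e-6 else -1
    hex_atoms = []
    for k, n in enumerate(names, start=1):
        hex_atoms.append((n, "C", tuple(hex_center + rot60(v_cd2, step * k))))
    return penta + hex_atoms + [
        ("CB", "C", (-2.05, 0.0, -1.10)),
        ("CA", "C", (-1.75, -1.10, -2.10)),
        ("N", "N", (-2.55, -2.20, -1.90)),
        ("C", "C", (-0.50, -1.50, -2.85)),
        ("O", "O", (-0.55, -1.40, -4.05)),
    ]


# templates for random (oracle-testing) fixtures
RANDOM_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": ROLE_TEMPLATES[("GLY", "donorN")],
    "ALA": ROLE_TEMPLATES[("ALA", "cb")],
    "CYS": ROLE_TEMPLATES[("CYS", "sg")],
    "ASP": ROLE_TEMPLATES[("ASP", "od2")],
    "LYS": ROLE_TEMPLATES[("LYS", "nz")],
    "PHE": ROLE_TEMPLATES[("PHE", "ring")],
    "TYR": ROLE_TEMPLATES[("TYR", "ring")],
    "HIS": _his_template(),
    "TRP": _trp_template(),
    "SER": [
        ("OG", "O", (0.0, 0.0, 0.0)),
        ("CB", "C", (0.0, 0.0, -1.41)),
        ("CA", "C", (1.20, 0.40, -2.35)),
        ("N", "N", (2.40, 0.10, -1.80)),
        ("C", "C", (1.30, -0.30, -3.70)),
        ("O", "O", (2.30, -0.90, -4.20)),
    ],
    "GLU": [
        ("OE2", "O", (0.0, 0.0, 0.0)),
        ("CD", "C", (0.0, 0.0, -1.25)),
        ("OE1", "O", (1.09, 0.0, -1.85)),
        ("CG", "C", (-0.80, -1.00, -2.10)),
        ("CB", "C", (-0.20, -1.50, -3.40)),
        ("CA", "C", (-1.10, -2.30, -4.20)),
        ("N", "N", (-2.30, -1.80, -4.60)),
        ("C", "C", (-0.50, -3.20, -5.20)),
        ("O", "O", (-1.00, -4.30, -5.30)),
    ],
    "ASN": [
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (0.0, 0.0, -1.23)),
        ("ND2", "N", (1.15, 0.0, -1.90)),
        ("CB", "C", (-0.80, -1.00, -2.10)),
        ("CA", "C", (-0.20, -1.50, -3.40)),
        ("N", "N", (1.05, -2.20, -3.20)),
        ("C", "C", (-1.20, -2.40, -4.10)),
        ("O", "O", (-2.40, -2.20, -4.20)),
    ],
    "ARG": [
        ("NH1", "N", (1.15, 0.0, 0.6325)),
        ("NH2", "N", (-1.15, 0.0, 0.6325)),
        ("CZ", "C", (0.0, 0.0, 0.0325)),
        ("NE", "N", (0.0, 0.0, -1.2975)),
        ("CD", "C", (0.90, 0.40, -2.3675)),
        ("CG", "C", (0.30, 1.00, -3.5675)),
        ("CB", "C", (1.20, 1.40, -4.6675)),
        ("CA", "C", (0.60, 2.00, -5.9675)),
        ("N", "N", (-0.60, 2.70, -5.6675)),
        ("C", "C", (1.60, 2.90, -6.6675)),
        ("O", "O", (1.40, 4.10, -6.7675)),
    ],
}


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _mirror_z(template):
    return [(n, e, (x, -y, -z)) for n, e, (x, y, z) in template]


def _make_residue(chain: str, seq_num: int, res_name: str, template,
                  rotation: np.ndarray, translation: np.ndarray) -> Residue:
    atoms = [Atom(n, e, rotation @ np.asarray(xyz) + translation)
             for n, e, xyz in template]
    return Residue(chain, seq_num, "", res_name, atoms)


# ---------------------------------------------------------------------------
# planted-interaction structure fixtures

# (itype) -> (role template a, role template b, cutoff name tip-tip)
_PLANT_ROLES = {
    IType.HBOND: (("GLY", "donorN"), ("GLY", "acceptorO")),
    IType.VDW: (("ALA", "cb"), ("ALA", "cb")),
    IType.SSBOND: (("CYS", "sg"), ("CYS", "sg")),
    IType.IONIC: (("ASP", "od2"), ("LYS", "nz")),
    IType.PIPI: (("PHE", "ring"), ("PHE", "ring")),
    IType.PICATION: (("PHE", "ring"), ("LYS", "nz")),
}

_TIP_ATOMS = {
    IType.HBOND: ("N", "O"),
    IType.VDW: ("CB", "CB"),
    IType.SSBOND: ("SG", "SG"),
    IType.IONIC: ("OD2", "NZ"),
    IType.PIPI: ("ring6", "ring6"),
    IType.PICATION: ("ring6", "NZ"),
}

_CUTOFFS = {
    IType.HBOND: 3.5,
    IType.VDW: 3.9,       # C-C: 1.7 + 1.7 + 0.5 slack
    IType.SSBOND: 2.5,
    IType.IONIC: 4.0,
    IType.PIPI: 6.5,
    IType.PICATION: 5.0,
}

_GRID_SPACING = 30.0  # A; isolates planted units (max cutoff is 6.5 A)


@dataclass
class PlantSpec:
    itype: IType
    margin: float = 0.3
    decoy: bool = False
    pair: tuple[tuple[str, str], tuple[str, str]] | None = None  # role keys

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        self.itype = IType(self.itype)


@dataclass
class FixtureSpec:
    seed: int
    planted: list[PlantSpec] = field(default_factory=list)
    n_decoys: int = 0          # per interaction type
    n_filler: int = 0          # isolated single residues
    decoy_margin: float = 0.3
    structure_id: str = "fixture"


@dataclass
class FixtureTruth:
    edges: list[InteractionEdge] = field(default_factory=list)
    surface_flags: list[bool] | None = None
    column_groups: dict[int, str] | None = None
    clade_rates: dict[str, float] | None = None


def _companion_edges(itype: IType, d: float, id_a, id_b) -> list[InteractionEdge]:
    """Edges unavoidably implied by a planted tip-tip geometry at distance d.

    A disulfide-range SG-SG contact is always also a Van der Waals contact
    (S-S surface threshold 4.1 A); a salt bridge tight enough also
    satisfies the donor-acceptor hydrogen-bond rule and, closer still, the
    O-N Van der Waals rule.
    """
    out = []
    if itype is IType.SSBOND and d <= 1.8 + 1.8 + 0.5:
        out.append(InteractionEdge(id_a, id_b, IType.VDW, d, ("SG", "SG")))
    if itype is IType.IONIC:
        if d <= 3.5:
            out.append(InteractionEdge(id_a, id_b, IType.HBOND, d, ("OD2", "NZ")))
        if d <= 1.52 + 1.55 + 0.5:
            out.append(InteractionEdge(id_a, id_b, IType.VDW, d, ("OD2", "NZ")))
    return out


def make_structure_fixture(spec: FixtureSpec) -> tuple[Structure, FixtureTruth]:
    """Build a structure realizing each planted interaction at
    ``cutoff - margin`` and each decoy at ``cutoff + margin``.

    Units (pairs or filler singles) are placed on a 30 A grid — beyond
    twice the largest cutoff — and randomly oriented, so the ground truth
    is exactly the within-unit qualifying contacts.
    """
    rng = np.random.default_rng(spec.seed)
    units: list[tuple[PlantSpec | None]] = [(p,) for p in spec.planted]
    for itype in IType:
        for _ in range(spec.n_decoys):
            units.append((PlantSpec(itype, margin=spec.decoy_margin, decoy=True),))
    for _ in range(spec.n_filler):
        units.append((None,))
    if not units:
        raise ValueError("empty fixture: nothing planted and no filler")

    n_units = len(units)
    dim = math.ceil(n_units ** (1.0 / 3.0))
    slots = [np.array([i, j, k], float) * _GRID_SPACING
             for i in range(dim) for j in range(dim) for k in range(dim)][:n_units]

    residues: list[Residue] = []
    truth_edges: list[InteractionEdge] = []
    filler_types = list(RANDOM_TEMPLATES)
    for u, ((plant,), center) in enumerate(zip(units, slots)):
        rot = random_rotation(rng)
        if plant is None:
            rtype = filler_types[rng.integers(len(filler_types))]
            residues.append(_make_residue(
                "A", 10 * u + 1, rtype, RANDOM_TEMPLATES[rtype], rot, center))
            continue
        roles = plant.pair or _PLANT_ROLES[plant.itype]
        cutoff = _CUTOFFS[plant.itype]
        d = cutoff + plant.margin if plant.decoy else cutoff - plant.margin
        if d <= 0:
            raise ValueError(f"margin {plant.margin} too large for {plant.itype}")
        t_a = ROLE_TEMPLATES[roles[0]]
        t_b = _mirror_z(ROLE_TEMPLATES[roles[1]])
        anchor_a = center + rot @ np.array([0.0, 0.0, -d / 2.0])
        anchor_b = center + rot @ np.array([0.0, 0.0, +d / 2.0])
        res_a = _make_residue("A", 10 * u + 1, roles[0][0], t_a, rot, anchor_a)
        res_b = _make_residue("A", 10 * u + 5, roles[1][0], t_b, rot, anchor_b)
        residues.extend([res_a, res_b])
        id_a = (res_a.chain_id, res_a.seq_num, "", res_a.res_name)
        id_b = (res_b.chain_id, res_b.seq_num, "", res_b.res_name)
        if not plant.decoy:
            tip_a, tip_b = _TIP_ATOMS[plant.itype]
            label = ""
            if plant.itype is IType.PIPI:
                one = {"PHE": "F", "TYR": "Y", "TRP": "W", "HIS": "H"}
                label = "-".join(sorted((one[roles[0][0]], one[roles[1][0]])))
            truth_edges.append(InteractionEdge(id_a, id_b, plant.itype, d,
                                               (tip_a, tip_b), label))
        truth_edges.extend(_companion_edges(plant.itype, d, id_a, id_b))

    structure = Structure(spec.structure_id, residues)
    truth_edges.sort(key=lambda e: (e.residue_a[:3], e.residue_b[:3], e.itype.value))
    return structure, FixtureTruth(edges=truth_edges)


def make_random_structure(n_residues: int, seed: int, box_size: float = 32.0,
                          structure_id: str = "random") -> Structure:
    """Residues of random type, position and orientation in a box — dense
    enough that arbitrary contacts of every kind arise.  For detector
    oracle-equivalence testing; carries no planted truth."""
    rng = np.random.default_rng(seed)
    types = list(RANDOM_TEMPLATES)
    residues = []
    for i in range(n_residues):
        rtype = types[rng.integers(len(types))]
        rot = random_rotation(rng)
        pos = rng.uniform(0.0, box_size, size=3)
        residues.append(_make_residue("A", 3 * i + 1, rtype,
                                      RANDOM_TEMPLATES[rtype], rot, pos))
    return Structure(structure_id, residues)


def make_cluster_study(
    out_dir,
    seed: int = 0,
    n_per_cluster: int = 5,
    extra_ff: int = 3,
    baseline_ff_max: int = 2,
) -> dict[str, list[str]]:
    """Write two clusters of structure fixtures to ``out_dir`` and return a
    {cluster: [pdb paths]} mapping.

    Both clusters carry a seed-varying baseline of 0..``baseline_ff_max``
    planted F-F stacking pairs per structure plus one contact of each other
    type; the "stable" cluster gets ``extra_ff`` additional F-F pairs per
    structure — a desk-scale analogue of an acid-stable clade enriched in
    Phe-Phe stacking.
    """
    from pathlib import Path
    from xynrin.structio import write_pdb

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    clusters: dict[str, list[str]] = {"labile": [], "stable": []}
    for cluster, bonus in (("labile", 0), ("stable", extra_ff)):
        for i in range(n_per_cluster):
            n_ff = int(rng.integers(0, baseline_ff_max + 1)) + bonus
            planted = [PlantSpec(IType.PIPI, margin=0.3) for _ in range(n_ff)]
            planted += [PlantSpec(t, margin=0.3) for t in
                        (IType.HBOND, IType.VDW, IType.IONIC, IType.PICATION)]
            spec = FixtureSpec(seed=int(rng.integers(2 ** 31)), planted=planted,
                               n_filler=3, structure_id=f"{cluster}_{i+1}")
            st, _ = make_structure_fixture(spec)
            path = out_dir / f"{cluster}_{i+1}.pdb"
            write_pdb(st, path)
            clusters[cluster].append(str(path))
    return clusters


# ---------------------------------------------------------------------------
# alignments with planted group A/B columns

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_msa_fixture(
    n_cluster: int = 5,
    length: int = 120,
    n_groupA: int = 10,
    n_groupB: int = 8,
    seed: int = 0,
    ref_id: str = "REF",
    query_id: str = "QUERY",
) -> tuple[Alignment, FixtureTruth, dict]:
    """Alignment of a reference row plus ``n_cluster`` cluster rows (query
    first) with planted group A and B columns.

    A columns: every cluster member differs from the reference.  B columns:
    the query differs and the total number of differing members (query
    included) is uniform in {1, ..., n_cluster - 1}.  All other columns are
    identical across rows.  Returns the alignment, the truth map
    (column -> "A"/"B"), and the id bookkeeping.
    """
    if n_cluster < 2:
        raise ValueError("n_cluster must be >= 2")
    if n_groupA + n_groupB > length:
        raise ValueError("more planted columns than alignment length")
    rng = np.random.default_rng(seed)
    member_ids = [query_id] + [f"M{i}" for i in range(1, n_cluster)]
    cols = rng.permutation(length)
    a_cols = sorted(cols[:n_groupA].tolist())
    b_cols = sorted(cols[n_groupA:n_groupA + n_groupB].tolist())

    aa = np.array(list(AA_ALPHABET))
    rows = {rid: [""] * length for rid in [ref_id] + member_ids}
    for col in range(length):
        ref_c = str(rng.choice(aa))
        rows[ref_id][col] = ref_c
        others = [c for c in AA_ALPHABET if c != ref_c]
        if col in a_cols:
            for rid in member_ids:
                rows[rid][col] = str(rng.choice(others))
        elif col in b_cols:
            n_diff = int(rng.integers(1, n_cluster))  # 1..n_cluster-1
            diff_ids = [query_id] + list(rng.choice(member_ids[1:], size=n_diff - 1,
                                                    replace=False))
            for rid in member_ids:
                rows[rid][col] = str(rng.choice(others)) if rid in diff_ids else ref_c
        else:
            for rid in member_ids:
                rows[rid][col] = ref_c

    ids = [ref_id] + member_ids
    aln = Alignment(ids, ["".join(rows[r]) for r in ids])
    truth = {c + 1: "A" for c in a_cols}
    truth.update({c + 1: "B" for c in b_cols})
    meta = {"ref_id": ref_id, "query_id": query_id, "cluster_ids": member_ids}
    return aln, FixtureTruth(column_groups=truth), meta


# ---------------------------------------------------------------------------
# charge-composition sequences

ACIDIC_AA = "DE"
BASIC_AA = "RKH"
NEUTRAL_AA = "ACFGILMNPQSTVWY"


def make_charge_fixture(n_acidic: int, n_basic: int, n_neutral: int, seed: int = 0) -> str:
    """Shuffled sequence with exactly the requested D/E, R/K/H and neutral
    residue counts."""
    if min(n_acidic, n_basic, n_neutral) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    letters = (
        list(rng.choice(list(ACIDIC_AA), size=n_acidic))
        + list(rng.choice(list(BASIC_AA), size=n_basic))
        + list(rng.choice(list(NEUTRAL_AA), size=n_neutral))
    )
    rng.shuffle(letters)
    return "".join(letters)


# ---------------------------------------------------------------------------
# trees with planted clade rate contrasts

def _random_clade_newick(labels: list[str], rng: np.random.Generator,
                         mean_length: float) -> str:
    """Random binary topology over ``labels`` with exponential edge lengths."""
    nodes = [f"{lab}:{rng.exponential(mean_length):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(mean_length):.6f}")
    # strip the root's own pending length; the caller adds the stem
    tail = nodes[0].rfind(":")
    return nodes[0][:tail] if nodes[0].startswith("(") else nodes[0]


def make_tree_fixture(
    clade_sizes: dict[str, int],
    base_rate: float = 0.15,
    fast_clade_multiplier: float = 1.0,
    fast_clade: str | None = None,
    seed: int = 0,
) -> tuple[dendropy.Tree, FixtureTruth, str]:
    """Random clade topologies joined on a backbone; edge lengths are
    exponential with mean ``base_rate`` (the fast clade's multiplied).
    Returns the tree, the truth (generating mean per clade), and the
    Newick string (byte-stable given the seed)."""
    if len(clade_sizes) < 2:
        raise ValueError("need at least 2 clades")
    rng = np.random.default_rng(seed)
    subtrees = []
    rates = {}
    for name, size in clade_sizes.items():
        mean = base_rate * (fast_clade_multiplier if name == fast_clade else 1.0)
        rates[name] = mean
        labels = [f"{name}_{i}" for i in range(1, size + 1)]
        nwk = _random_clade_newick(labels, rng, mean)
        stem = rng.exponential(base_rate)
        subtrees.append(f"{nwk}:{stem:.6f}" if nwk.startswith("(")
                        else f"{nwk.split(':')[0]}:{stem:.6f}")
    # caterpillar backbone
    newick = subtrees[0]
    for sub in subtrees[1:]:
        newick = f"({newick},{sub}):{rng.exponential(base_rate):.6f}"
    newick = newick[:newick.rfind(":")] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    leaf_sets = {name: {f"{name}_{i}" for i in range(1, size + 1)}
                 for name, size in clade_sizes.items()}
    truth = FixtureTruth(clade_rates=rates)
    truth.leaf_sets = leaf_sets  # type: ignore[attr-defined]
    return tree, truth, newick
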