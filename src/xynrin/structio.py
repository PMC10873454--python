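"""Structure, sequence and tree I/O.

The domain model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each holding its heavy (and, if present,
hydrogen) :class:`Atom` records.  Residue numbering follows the author
numbering in the PDB file, because mutant positions in the literature
("A113", "E244") are author-numbering references.  Sequence positions in all
sequence-level operations are 1-based.

PDB parsing goes through :mod:`gemmi`; FASTA through Biopython; Newick
through dendropy.  All readers accept gzipped input (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in STANDARD_AA3.items()}
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA3

    @property
    def one_letter(self) -> str:
        return STANDARD_AA3.get(self.res_name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{icode}"


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"structure {self.id!r}: at least one residue required")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"structure {self.id!r}: duplicate residue keys")

    def coords(self) -> np.ndarray:
        return np.vstack([a.coord for r in self.residues for a in r.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            atoms = [Atom(a.name, a.element, rotation @ a.coord + translation,
                          a.occupancy, a.altloc) for a in r.atoms]
            new_res.append(Residue(r.chain_id, r.seq_num, r.insertion_code, r.res_name, atoms))
        return Structure(self.id, new_res, self.source_path)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate alignment ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in alignment") from None


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# PDB

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(
    path: str | Path,
    model_policy: str = "first",
    model_index: int = 0,
    altloc_policy: str = "highest-occupancy",
    include_hetatm: bool = False,
    mse_as_met: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    HETATM records and waters are excluded by default (a count is logged).
    With ``mse_as_met`` selenomethionine is retained as methionine.  Missing
    occupancy is treated as 1.0 (gemmi's default).  Altloc handling: with
    ``highest-occupancy`` the best-occupancy conformer of each atom name is
    kept; with ``blank-only`` only blank-altloc atoms are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no ATOM records (empty structure)")
    if model_policy == "first":
        model = st[0]
    elif model_policy == "index":
        model = st[model_index]
    else:
        raise ValueError(f"unknown model_policy {model_policy!r}")

    residues: list[Residue] = []
    n_skipped_het = 0
    n_skipped_water = 0
    for chain in model:
        for res in chain:
            name = res.name
            if name in _WATER_NAMES:
                n_skipped_water += 1
                continue
            if mse_as_met and name == "MSE":
                name = "MET"
            elif name not in STANDARD_AA3 and not include_hetatm:
                n_skipped_het += 1
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                # gemmi encodes a blank altloc as '\x00'
                alt = at.altloc if at.altloc and at.altloc != "\x00" else ""
                if altloc_policy == "blank-only":
                    if alt:
                        continue
                    by_name[at.name] = at
                elif altloc_policy == "highest-occupancy":
                    prev = by_name.get(at.name)
                    if prev is None or at.occ > prev.occ:
                        by_name[at.name] = at
                else:
                    raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name if at.element.name else "X",
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc and at.altloc != "\x00" else "",
                )
                for at in by_name.values()
            ]
            if not atoms:
                continue
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            residues.append(Residue(chain.name, res.seqid.num, icode, name, atoms))
    if n_skipped_het or n_skipped_water:
        logger.info("read_pdb %s: skipped %d HETATM residues, %d waters",
                    path.name, n_skipped_het, n_skipped_water)
    if not residues:
        raise FormatError(f"{path}: no polymer ATOM records after filtering")
    return Structure(structure_id or path.stem, residues, source_path=str(path))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as minimal, legal PDB ATOM records."""
    path = Path(path)
    serial = 0
    lines = []
    for res in structure.residues:
        for at in res.atoms:
            serial += 1
            name = at.name
            # PDB atom-name column convention: 1-char elements start in col 14
            if len(name) < 4 and len(at.element) == 1:
                name = f" {name}"
            x, y, z = at.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{at.altloc or ' '}{res.res_name:>3s} "
                f"{res.chain_id[:1]:1s}{res.seq_num:4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{at.occupancy:6.2f}{0.0:6.2f}          "
                f"{at.element:>2s}  "
            )
    lines.append("END")
    with _open_maybe_gz(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)``; sequences are upper-cased
    and any ``*`` stop symbols are stripped with a warning."""
    with _open_maybe_gz(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate ids {dupes}")
    out = []
    for r in records:
        seq = str(r.seq).upper()
        if "*" in seq:
            warnings.warn(f"{r.id}: stripped '*' from sequence", stacklevel=2)
            seq = seq.replace("*", "")
        out.append((r.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with _open_maybe_gz(path, "wt") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_alignment(path: str | Path) -> Alignment:
    recs = read_fasta(path)
    return Alignment([r[0] for r in recs], [r[1] for r in recs])


# ---------------------------------------------------------------------------
# Newick

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree; every edge must carry a branch length
    (branch-length statistics would otherwise be undefined)."""
    with _open_maybe_gz(path) as fh:
        text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root has no parent edge length by convention
        if edge.length is None:
            leaf = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise FormatError(f"{path}: missing branch length on edge above {leaf!r}")
        if edge.length < 0:
            raise FormatError(f"{path}: negative branch length")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with _open_maybe_gz(path, "wt") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
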