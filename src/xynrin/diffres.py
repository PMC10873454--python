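"""Differential-residue classification, region enrichment and mutant design.

Given a multiple sequence alignment, a non-acid-stable *reference* enzyme,
an acid-stable *query* enzyme and the query's homolog *cluster*, every
alignment column where the query differs from the reference is classified:

* **group A** — every cluster member (query included) differs from the
  reference at that column;
* **group B** — the query differs but only a proper subset of the cluster
  does.

Substitution-set mutants rewrite selected query positions with the
reference residue (the "back-to-reference" design used to probe which
differential residues carry acid stability).  Spatially enriched regions of
a residue set are single-linkage connected components under a C-beta
distance cutoff.

Gap policy: a gap in the reference or in a cluster member counts as
"differing" for that member; a gap in the query yields a classified column
without a mutable query position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from xynrin.structio import Alignment, Structure, GAP

logger = logging.getLogger(__name__)


@dataclass
class ColumnClassification:
    column_index: int        # 1-based alignment column
    ref_residue: str
    query_residue: str
    n_cluster_diff: int
    n_cluster: int
    group: str               # "A" | "B"
    query_position: int | None  # 1-based ungapped position in query


@dataclass
class SubstitutionSet:
    name: str
    positions: frozenset[int]
    replacement_source: str = "ref"
    description: str = ""


@dataclass
class SpatialRegion:
    region_id: int
    members: list[tuple]          # residue ids (chain, seq_num, icode, res_name)
    centroid: np.ndarray
    diameter: float


def classify_columns(
    alignment: Alignment,
    ref_id: str,
    query_id: str,
    cluster_ids: list[str],
) -> list[ColumnClassification]:
    """Classify every column where the query differs from the reference.

    ``cluster_ids`` must include the query (the all/subset rule presumes the
    query is a cluster member).  Returns one record per differential column,
    in column order.
    """
    ref_row = alignment.row(ref_id)
    query_row = alignment.row(query_id)
    if query_id not in cluster_ids:
        raise ValueError(f"query {query_id!r} must be a member of cluster_ids")
    cluster_rows = [alignment.row(cid) for cid in cluster_ids]
    n_cluster = len(cluster_ids)

    records: list[ColumnClassification] = []
    qpos = 0
    for col in range(alignment.length):
        ref_c = ref_row[col]
        q_c = query_row[col]
        if q_c != GAP:
            qpos += 1
        if q_c == ref_c:
            continue  # group "none": no record
        n_diff = sum(1 for row in cluster_rows if row[col] != ref_c)
        group = "A" if n_diff == n_cluster else "B"
        records.append(ColumnClassification(
            column_index=col + 1,
            ref_residue=ref_c,
            query_residue=q_c,
            n_cluster_diff=n_diff,
            n_cluster=n_cluster,
            group=group,
            query_position=qpos if q_c != GAP else None,
        ))
        if q_c == GAP:
            logger.info("column %d: query gapped; no mutable position", col + 1)
    return records


def mutable_positions(classifications: list[ColumnClassification],
                      group: str | None = None) -> list[int]:
    """1-based query positions of classified columns (optionally one group)
    where both query and reference carry residues (mutable positions)."""
    out = []
    for c in classifications:
        if c.query_position is None or c.ref_residue == GAP:
            continue
        if group is None or c.group == group:
            out.append(c.query_position)
    return sorted(out)


def design_mutants(
    query_sequence: str,
    classifications: list[ColumnClassification],
    substitution_sets: list[SubstitutionSet],
) -> list[tuple[str, str]]:
    """Write the reference residue at each selected query position.

    Every selected position must map to a classified column with a non-gap
    reference residue; sequence length is preserved.
    """
    by_pos = {c.query_position: c for c in classifications
              if c.query_position is not None and c.ref_residue != GAP}
    results = []
    for sset in substitution_sets:
        seq = list(query_sequence)
        for pos in sorted(sset.positions):
            rec = by_pos.get(pos)
            if rec is None:
                raise ValueError(
                    f"{sset.name}: position {pos} is not a mutable classified position")
            # allow the already-substituted residue so re-application is a no-op
            if seq[pos - 1] not in (rec.query_residue, rec.ref_residue):
                raise ValueError(
                    f"{sset.name}: query sequence has {seq[pos - 1]!r} at {pos}, "
                    f"classification says {rec.query_residue!r}")
            seq[pos - 1] = rec.ref_residue
        results.append((sset.name, "".join(seq)))
    return results


def split_termini(
    positions: list[int],
    boundary_policy: str = "ceil",
    midpoint: int | None = None,
) -> tuple[list[int], list[int]]:
    """Split sorted positions into N- and C-terminal halves.

    ``ceil`` assigns the first ceil(k/2) positions to the N half;
    ``midpoint`` splits at a given sequence position instead.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    pos = sorted(positions)
    if boundary_policy == "ceil":
        k = math.ceil(len(pos) / 2)
        return pos[:k], pos[k:]
    if boundary_policy == "midpoint":
        if midpoint is None:
            raise ValueError("midpoint policy requires a midpoint")
        return [p for p in pos if p <= midpoint], [p for p in pos if p > midpoint]
    raise ValueError(f"unknown boundary_policy {boundary_policy!r}")


def _cb_coordinate(structure: Structure, seq_pos: int) -> np.ndarray:
    """C-beta coordinate (C-alpha for glycine) of the residue at 1-based
    sequence position ``seq_pos`` in the structure's residue order."""
    try:
        res = structure.residues[seq_pos - 1]
    except IndexError:
        raise ValueError(f"position {seq_pos} outside structure "
                         f"({len(structure.residues)} residues)") from None
    at = res.atom("CA") if res.res_name == "GLY" else res.atom("CB")
    if at is None:
        at = res.atom("CA")
    if at is None:
        raise ValueError(f"position {seq_pos} ({res.label()}): no CB/CA atom")
    return at.coord


def find_enriched_regions(
    structure: Structure,
    residue_positions: list[int],
    linkage_cutoff: float = 10.0,
    min_size: int = 3,
) -> list[SpatialRegion]:
    """Single-linkage spatial clusters of a residue set.

    Connected components of the graph joining residues whose C-beta atoms
    lie within ``linkage_cutoff``; components below ``min_size`` are
    discarded.  Regions are ordered by size (descending), then by first
    residue number.
    """
    positions = sorted(set(residue_positions))
    if not positions:
        return []
    coords = np.vstack([_cb_coordinate(structure, p) for p in positions])
    if len(positions) == 1:
        adj = np.zeros((1, 1), dtype=bool)
    else:
        adj = squareform(pdist(coords)) <= linkage_cutoff
        np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    regions = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < min_size:
            continue
        members_pos = [positions[i] for i in idx]
        member_ids = []
        for p in members_pos:
            r = structure.residues[p - 1]
            member_ids.append((r.chain_id, r.seq_num, r.insertion_code, r.res_name))
        sub = coords[idx]
        diameter = float(pdist(sub).max()) if len(idx) > 1 else 0.0
        regions.append(SpatialRegion(
            region_id=-1, members=member_ids,
            centroid=sub.mean(axis=0), diameter=diameter))
    regions.sort(key=lambda r: (-len(r.members), min(m[1] for m in r.members)))
    for i, r in enumerate(regions, start=1):
        r.region_id = i
    return regions


def align_pair(id_a: str, seq_a: str, id_b: str, seq_b: str) -> Alignment:
    """Global pairwise protein alignment (BLOSUM62, affine gaps -11/-1),
    returned as a two-row :class:`Alignment`."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    best = aligner.align(seq_a, seq_b)[0]
    # rebuild gapped rows from the aligned block coordinates
    a_row, b_row = [], []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*best.aligned):
        while ia < sa:
            a_row.append(seq_a[ia]); b_row.append(GAP); ia += 1
        while ib < sb:
            a_row.append(GAP); b_row.append(seq_b[ib]); ib += 1
        a_row.append(seq_a[sa:ea]); b_row.append(seq_b[sb:eb])
        ia, ib = ea, eb
    while ia < len(seq_a):
        a_row.append(seq_a[ia]); b_row.append(GAP); ia += 1
    while ib < len(seq_b):
        a_row.append(GAP); b_row.append(seq_b[ib]); ib += 1
    return Alignment([id_a, id_b], ["".join(a_row), "".join(b_row)])


def count_differential_columns(alignment: Alignment, ref_id: str, query_id: str) -> int:
    """Number of alignment columns where query and reference differ,
    ignoring columns gapped in both (the pairwise differential-residue
    count of the worked comparison between an acid-stable enzyme and its
    non-acid-stable relative)."""
    ref_row = alignment.row(ref_id)
    q_row = alignment.row(query_id)
    return sum(1 for a, b in zip(ref_row, q_row)
               if a != b and not (a == GAP and b == GAP))
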