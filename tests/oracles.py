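"""Independent brute-force oracles for the interaction detectors.

Deliberately naive: plain all-pairs loops over explicit atom tables, no
spatial indexing and no shared helpers with the package implementation.
Each function returns a set of (pair, itype, distance-rounded) triples for
direct comparison with detector output.
"""

from __future__ import annotations

import numpy as np

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"},
}
SC_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}
NEG = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
POS = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}}
BACKBONE = {"N", "CA", "C", "O", "OXT"}
RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}


def _dist(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def _allowed(res_i, res_j, sep=2):
    if res_i.chain_id != res_j.chain_id:
        return True
    return abs(res_i.seq_num - res_j.seq_num) >= sep


def _pair_key(res_i, res_j):
    a = (res_i.chain_id, res_i.seq_num, res_i.insertion_code)
    b = (res_j.chain_id, res_j.seq_num, res_j.insertion_code)
    return (a, b) if a < b else (b, a)


def _terminals(structure):
    first, last = set(), set()
    prev = None
    for i, r in enumerate(structure.residues):
        if r.chain_id != prev:
            first.add(i)
            if i:
                last.add(i - 1)
            prev = r.chain_id
    last.add(len(structure.residues) - 1)
    return first, last


def _min_over_pairs(structure, atoms_of_i, atoms_of_j, cutoff, symmetric=True):
    """Minimal qualifying distance per residue pair; returns
    {pair_key: distance}."""
    res = structure.residues
    best = {}
    for i in range(len(res)):
        for j in range(len(res)):
            if i == j or not _allowed(res[i], res[j]):
                continue
            for ca in atoms_of_i(i):
                for cb in atoms_of_j(j):
                    d = _dist(ca, cb)
                    if d <= cutoff:
                        k = _pair_key(res[i], res[j])
                        if k not in best or d < best[k]:
                            best[k] = d
    return best


def oracle_hbonds(structure, cutoff=3.5):
    res = structure.residues
    nterm, _ = _terminals(structure)

    def donors(i):
        out = []
        for at in res[i].atoms:
            if at.element not in ("N", "O"):
                continue
            if at.name == "N" and (res[i].res_name != "PRO" or i in nterm):
                out.append(at.coord)
            elif at.name in SC_DONORS.get(res[i].res_name, ()):
                out.append(at.coord)
        return out

    def acceptors(j):
        out = []
        for at in res[j].atoms:
            if at.element not in ("N", "O"):
                continue
            if at.name in ("O", "OXT") or at.name in SC_ACCEPTORS.get(res[j].res_name, ()):
                out.append(at.coord)
        return out

    return _min_over_pairs(structure, donors, acceptors, cutoff)


def oracle_vdw(structure, slack=0.5):
    res = structure.residues
    best_gap = {}
    best_d = {}
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            if not _allowed(res[i], res[j]):
                continue
            for ai in res[i].atoms:
                if ai.name in BACKBONE or ai.element == "H":
                    continue
                for aj in res[j].atoms:
                    if aj.name in BACKBONE or aj.element == "H":
                        continue
                    d = _dist(ai.coord, aj.coord)
                    gap = d - VDW_RADII[ai.element] - VDW_RADII[aj.element]
                    if gap <= slack:
                        k = _pair_key(res[i], res[j])
                        if k not in best_gap or gap < best_gap[k]:
                            best_gap[k] = gap
                            best_d[k] = d
    return best_d


def oracle_ssbonds(structure, cutoff=2.5):
    def sgs(i):
        r = structure.residues[i]
        if r.res_name != "CYS":
            return []
        return [a.coord for a in r.atoms if a.name == "SG"]
    return _min_over_pairs(structure, sgs, sgs, cutoff)


def oracle_ionic(structure, cutoff=4.0):
    nterm, cterm = _terminals(structure)
    res = structure.residues

    def negs(i):
        names = set(NEG.get(res[i].res_name, ()))
        if i in cterm:
            names.add("OXT")
        return [a.coord for a in res[i].atoms if a.name in names]

    def poss(j):
        names = set(POS.get(res[j].res_name, ()))
        if j in nterm:
            names.add("N")
        return [a.coord for a in res[j].atoms if a.name in names]

    return _min_over_pairs(structure, negs, poss, cutoff)


def _centroids(residue, include_his=True):
    rings = RINGS.get(residue.res_name, [])
    if residue.res_name == "HIS" and not include_his:
        return []
    out = []
    for names in rings:
        coords = [a.coord for n in names for a in residue.atoms if a.name == n]
        if len(coords) == len(names):
            out.append(np.mean(coords, axis=0))
    return out


def oracle_pipi(structure, cutoff=6.5, include_his=True):
    def rings(i):
        return _centroids(structure.residues[i], include_his)
    return _min_over_pairs(structure, rings, rings, cutoff)


def oracle_pication(structure, cutoff=5.0, include_his=True):
    res = structure.residues

    def rings(i):
        return _centroids(res[i], include_his)

    def cations(j):
        r = res[j]
        if r.res_name == "LYS":
            return [a.coord for a in r.atoms if a.name == "NZ"]
        if r.res_name == "ARG":
            coords = [a.coord for n in ("CZ", "NE", "NH1", "NH2")
                      for a in r.atoms if a.name == n]
            return [np.mean(coords, axis=0)] if len(coords) == 4 else []
        return []

    return _min_over_pairs(structure, rings, cations, cutoff)


ORACLES = {
    "HBOND": oracle_hbonds,
    "VDW": oracle_vdw,
    "SSBOND": oracle_ssbonds,
    "IONIC": oracle_ionic,
    "PIPI": oracle_pipi,
    "PICATION": oracle_pication,
}


def edge_set(edges):
    """Canonical comparison form for detector output."""
    return {((e.residue_a[:3]), (e.residue_b[:3]), e.itype.value, round(e.distance, 9))
            for e in edges}


def oracle_edge_set(structure, itype):
    return {(k[0], k[1], itype, round(d, 9))
            for k, d in ORACLES[itype](structure).items()}
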