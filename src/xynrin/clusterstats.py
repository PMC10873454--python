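"""Cluster-level statistics: F-test-then-t-test contrasts, compact letter
displays, and per-clade branch-length summaries.

The two-sample procedure mirrors the common "F-test followed by t-test"
scheme: a two-sided variance-ratio F-test decides between the pooled
(Student) and Welch forms of the two-sample t-test, both two-sided.  A
compact letter display labels >2 groups so that groups sharing a letter are
not significantly different pairwise.

Clade branch statistics locate each clade's most recent common ancestor
(MRCA) in a rooted tree and report the mean branch length over edges
strictly within the MRCA subtree (the MRCA's own parent edge excluded),
plus the mean tip-to-MRCA depth as an alternative convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    f_stat: float
    f_pvalue: float
    t_stat: float
    t_pvalue: float
    pooled: bool
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.t_pvalue < self.alpha

    def as_dict(self) -> dict:
        return {
            "groups": list(self.group_labels),
            "n": [self.n_a, self.n_b],
            "means": [self.mean_a, self.mean_b],
            "f_stat": self.f_stat, "f_pvalue": self.f_pvalue,
            "t_stat": self.t_stat, "t_pvalue": self.t_pvalue,
            "pooled": self.pooled, "alpha": self.alpha,
            "significant": self.significant,
        }


@dataclass
class CladeBranchStats:
    clade_name: str
    n_edges: int
    n_tips: int
    mean_branch_length: float
    alt_mean_tip_depth: float


def compare_groups(
    values_a,
    values_b,
    alpha: float = DEFAULT_ALPHA,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Variance-ratio F-test, then pooled or Welch two-sample t-test.

    F = larger sample variance / smaller, with a two-sided p-value from the
    F distribution.  If equal variances are not rejected at ``alpha`` the
    pooled t-test is used, otherwise Welch.  Degenerate case: both samples
    with zero variance and equal means gives t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a >= var_b:
        v_num, v_den, df_num, df_den = var_a, var_b, a.size - 1, b.size - 1
    else:
        v_num, v_den, df_num, df_den = var_b, var_a, b.size - 1, a.size - 1
    if v_den == 0.0:
        if v_num == 0.0:
            f_stat, f_pvalue = 0.0, 1.0
        else:
            f_stat, f_pvalue = float("inf"), 0.0
    else:
        f_stat = float(v_num / v_den)
        sf = stats.f.sf(f_stat, df_num, df_den)
        f_pvalue = float(min(1.0, 2.0 * min(sf, 1.0 - sf)))
    pooled = f_pvalue >= alpha

    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            t_stat, t_pvalue = 0.0, 1.0
        else:
            t_stat = float("inf") if a.mean() > b.mean() else float("-inf")
            t_pvalue = 0.0
    else:
        with warnings.catch_warnings():
            # count data with near-identical groups triggers a benign
            # precision-loss warning inside scipy's moment calculation
            warnings.filterwarnings("ignore", message="Precision loss",
                                    category=RuntimeWarning)
            t_stat, t_pvalue = stats.ttest_ind(a, b, equal_var=pooled)
        t_stat, t_pvalue = float(t_stat), float(t_pvalue)
    return GroupComparison(labels, int(a.size), int(b.size),
                           float(a.mean()), float(b.mean()),
                           f_stat, f_pvalue, t_stat, t_pvalue, pooled, alpha)


def letter_groups(samples: dict[str, list[float]], alpha: float = DEFAULT_ALPHA
                  ) -> dict[str, str]:
    """Compact letter display over all pairwise comparisons.

    Greedy insertion by descending mean: groups not significantly different
    share a letter.  No multiple-testing correction is applied (matching a
    plain pairwise p < alpha convention); apply Holm upstream if desired.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    different: set[tuple[str, str]] = set()
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            cmp = compare_groups(samples[gi], samples[gj], alpha=alpha, labels=(gi, gj))
            if cmp.significant:
                different.add((gi, gj))
                different.add((gj, gi))
    order = sorted(names, key=lambda g: -float(np.mean(samples[g])))
    letters: list[list[str]] = []  # letter index -> member groups
    assigned: dict[str, list[int]] = {g: [] for g in names}
    for g in order:
        placed = False
        for li, members in enumerate(letters):
            if all((g, m) not in different for m in members):
                members.append(g)
                assigned[g].append(li)
                placed = True
        if not placed:
            letters.append([g])
            assigned[g].append(len(letters) - 1)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {g: "".join(alphabet[i] for i in sorted(assigned[g])) for g in names}


def _mrca(nodes):
    """Most recent common ancestor by ancestor-path intersection (treats the
    seed node as the root, i.e. the tree as rooted)."""
    def path_to_root(n):
        path = [n]
        while n.parent_node is not None:
            n = n.parent_node
            path.append(n)
        return path[::-1]

    paths = [path_to_root(n) for n in nodes]
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidates = {id(p[depth]) for p in paths}
        if len(candidates) == 1:
            mrca = paths[0][depth]
        else:
            break
    return mrca


def clade_branch_stats(
    tree: dendropy.Tree,
    clade_leaf_sets: dict[str, set[str] | list[str]],
) -> list[CladeBranchStats]:
    """Per-clade mean branch length and mean tip depth.

    Each clade's leaf set must be monophyletic: the MRCA's subtree must
    contain exactly the given leaves.  The mean branch length averages all
    edge lengths strictly within the MRCA subtree (internal and terminal),
    excluding the MRCA's parent edge.
    """
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out = []
    for name, leaves in clade_leaf_sets.items():
        leaves = set(leaves)
        missing = leaves - set(leaf_by_label)
        if missing:
            raise ValueError(f"clade {name!r}: leaves not in tree: {sorted(missing)}")
        mrca = _mrca([leaf_by_label[l] for l in sorted(leaves)])
        subtree_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        if subtree_leaves != leaves:
            extra = sorted(subtree_leaves - leaves)
            raise ValueError(
                f"clade {name!r} is not monophyletic: MRCA subtree also contains {extra}")
        edge_lengths = []
        for node in mrca.preorder_iter():
            if node is mrca:
                continue
            if node.edge.length is None:
                raise ValueError(f"clade {name!r}: missing branch length")
            edge_lengths.append(node.edge.length)
        if not edge_lengths:
            raise ValueError(f"clade {name!r}: no edges within the MRCA subtree")
        depths = []
        for lf in mrca.leaf_iter():
            d = 0.0
            node = lf
            while node is not mrca:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        out.append(CladeBranchStats(
            clade_name=name,
            n_edges=len(edge_lengths),
            n_tips=len(depths),
            mean_branch_length=float(np.mean(edge_lengths)),
            alt_mean_tip_depth=float(np.mean(depths)),
        ))
    return out
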