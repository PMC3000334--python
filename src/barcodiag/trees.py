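"""Neighbour-joining trees, bootstrap supports, and species differentiation.

NJ follows the Saitou-Nei agglomeration: minimise the Q-criterion

    Q(i, j) = (m - 2) d(i, j) - r_i - r_j,   r_i = sum_k d(i, k)

join the minimising pair, assign branch lengths, reduce the matrix, and
finish with the three-taxon closed form, yielding an unrooted tree with a
trifurcating root node.  Determinism: ties in Q are broken by the lowest
(row, column) index pair in the current working order, where freshly joined
clusters are appended at the end.  Negative branch lengths are clamped to
zero with the deficit transferred to the sibling edge so the pair's path
length is preserved (the convention of mainstream distance-tree software);
the raw values are kept on the nodes as ``raw_length``.

Bootstrap supports resample alignment COLUMNS with replacement, recompute
the K2P matrix (pairwise deletion re-applied per replicate) and the NJ tree,
and score each internal bipartition of the reference tree by the percentage
of replicate trees containing it.

Species differentiation applies the two-part barcoding criterion: a species
with >= 2 members succeeds iff its sequences form a monophyletic cluster on
the (rooted) tree AND it shares no haplotype with another species; a
singleton species is only required not to share its haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .seqio import Haplotype, Library
from ._encoding import encode_many
from .distances import DistanceMatrix, distance_matrix_from_encoded

logger = logging.getLogger(__name__)


def _tip(name: str) -> TreeNode:
    return TreeNode(name=name)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a distance matrix (unrooted, trifurcating root)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 labels")
    bad = np.argwhere(np.triu(dm.undefined | dm.saturated, k=1))
    if bad.size:
        pairs = [(dm.labels[i], dm.labels[j]) for i, j in bad]
        raise ValueError(f"undefined/saturated distances for pairs: {pairs}")

    d = dm.values.astype(np.float64).copy()
    nodes: list[TreeNode] = [_tip(lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # first occurrence = lowest (i, j) lexicographically
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li[0], lj[0]
        nodes[i].raw_length, nodes[j].raw_length = li[1], lj[1]

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[x] for x in keep] + [parent]

    # closed form for the final three clusters
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01)]
    root = TreeNode(children=list(nodes))
    for node, raw in zip(nodes, lens):
        node.length = max(raw, 0.0)
        node.raw_length = raw
    return root


def _clamp_pair(li: float, lj: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Clamp a sibling pair's lengths at zero, moving the deficit to the sibling."""
    raw_i, raw_j = li, lj
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return (max(li, 0.0), raw_i), (max(lj, 0.0), raw_j)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions, canonicalised to the side NOT containing
    the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if len(s) < 2 or len(s) > len(leaves) - 2:
            continue
        if ref in s:
            s = leaves - s
        parts.add(s)
    return parts


def bootstrap_supports(
    lib: Library,
    replicates: int = 100,
    seed: Optional[int] = None,
    max_redraw_factor: int = 10,
) -> TreeNode:
    """Reference NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; replicates whose
    resampled matrix contains undefined/saturated pairs are redrawn, up to
    ``max_redraw_factor * replicates`` total draws.  Supports are stored as
    ``node.support`` (percent of replicates containing the node's
    bipartition) on every internal non-root node.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mat = encode_many([r.sequence for r in lib])
    ref_dm = distance_matrix_from_encoded(mat, lib.ids)
    ref_tree = nj(ref_dm)
    ref_parts = {p: 0 for p in bipartitions(ref_tree)}

    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    done = redrawn = 0
    budget = max_redraw_factor * replicates
    while done < replicates:
        cols = rng.integers(0, L, size=L)
        rep_dm = distance_matrix_from_encoded(mat[:, cols], lib.ids)
        if (np.triu(rep_dm.undefined | rep_dm.saturated, k=1)).any():
            redrawn += 1
            if redrawn > budget:
                raise RuntimeError("bootstrap redraw budget exhausted "
                                   f"({redrawn} invalid replicates)")
            continue
        rep_parts = bipartitions(nj(rep_dm))
        for p in ref_parts:
            if p in rep_parts:
                ref_parts[p] += 1
        done += 1
    if redrawn:
        logger.warning("bootstrap redrew %d invalid replicates", redrawn)

    leaves = frozenset(t.name for t in ref_tree.tips())
    ref_leaf = min(leaves)
    for node in ref_tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if len(s) < 2 or len(s) > len(leaves) - 2:
            node.support = None
            continue
        key = s if ref_leaf not in s else leaves - s
        node.support = 100.0 * ref_parts[key] / replicates
    return ref_tree


def write_newick(tree: TreeNode, path) -> None:
    """Newick export with integer bootstrap supports as internal node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        node.name = str(int(round(sup))) if sup is not None else None
    clone.write(str(path), format="newick")


def root_tree(tree: TreeNode, outgroup: Optional[str] = None) -> TreeNode:
    """Rooted copy of an NJ tree: at the outgroup tip's edge when given,
    otherwise at the midpoint of the longest tip-to-tip path."""
    clone = tree.copy()
    if outgroup is not None:
        tip = clone.find(outgroup)
        if not tip.is_tip():
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        return clone.root_at(tip, above=True, reset=True)
    return clone.root_at_midpoint(reset=True)


def is_monophyletic(tree: TreeNode, labels: Iterable[str], rooted: bool = False,
                    outgroup: Optional[str] = None) -> bool:
    """True iff ``labels`` form an exclusive clade on the rooted tree.

    ``tree`` may already be rooted (``rooted=True``); otherwise it is rooted
    at ``outgroup`` or, failing that, at the midpoint.
    """
    wanted = set(labels)
    t = tree if rooted else root_tree(tree, outgroup)
    tips = {x.name for x in t.tips()}
    unknown = wanted - tips
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if wanted == tips:
        return True
    if len(wanted) == 1:
        return True
    lca = t.lca([t.find(x) for x in wanted])
    return {x.name for x in lca.tips()} == wanted


@dataclass
class DifferentiationReport:
    """Outcome of the two-part species-differentiation criterion."""

    per_species: pd.DataFrame  # species, n, status, shared_haplotype, success
    n_species: int
    n_success: int

    @property
    def success_fraction(self) -> float:
        return self.n_success / self.n_species


def differentiation_report(
    tree: TreeNode,
    haplotypes: Sequence[Haplotype],
    species_of: Mapping[str, str],
    outgroup: Optional[str] = None,
) -> DifferentiationReport:
    """Tally which species the barcode library successfully differentiates.

    The outgroup record (if named) is used only for rooting and excluded
    from the tally.
    """
    rooted = root_tree(tree, outgroup)
    outgroup_species = species_of.get(outgroup) if outgroup else None

    members: dict[str, list[str]] = {}
    for rid, sp in species_of.items():
        if sp == outgroup_species:
            continue
        members.setdefault(sp, []).append(rid)

    shared_species = {sp for h in haplotypes if h.shared_between_species
                      for sp in h.species_set}

    rows = []
    for sp in sorted(members):
        ids = members[sp]
        shared = sp in shared_species
        if len(ids) == 1:
            status = "singleton"
            success = not shared
        else:
            mono = is_monophyletic(rooted, ids, rooted=True)
            status = "monophyletic" if mono else "non-monophyletic"
            success = mono and not shared
        rows.append({"species": sp, "n": len(ids), "status": status,
                     "shared_haplotype": shared, "success": success})
    df = pd.DataFrame(rows)
    return DifferentiationReport(df, len(df), int(df["success"].sum()))
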