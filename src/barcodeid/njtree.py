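"""Neighbour-Joining trees: construction, polytomy collapse, rooting,
bootstrap supports.

The agglomeration is the standard Saitou–Nei algorithm. Two behaviours
the downstream identification criteria depend on are pinned here rather
than delegated: ties on the Q criterion are broken by the lowest pair of
taxon indices in input order (creation order for merged nodes), making
the topology deterministic for any matrix; and negative branch lengths
are clamped to zero with the deficit moved to the sibling branch so that
the pair's summed length is preserved — zero-length branches then
collapse cleanly into polytomies.

Trees are :class:`dendropy.Tree` objects (newick IO, rooting and
bipartition machinery come from dendropy); leaves are labelled by
specimen id.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, encode
from .seqio import BarcodeDataset

__all__ = [
    "build_nj",
    "collapse_short_branches",
    "root_with_outgroup",
    "bootstrap_supports",
    "leaf_bipartitions",
    "write_newick",
    "read_newick",
]


def build_nj(m: DistanceMatrix, taxa: Sequence[str] | None = None) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Requires >=3 taxa and no undefined pairs among them. The returned
    tree's seed node is the final degree-3 join (dendropy's unrooted
    convention); all branch lengths are >= 0.
    """
    ids = list(taxa) if taxa is not None else list(m.ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"neighbour joining needs >=3 taxa, got {n}")
    bad = [
        tuple(sorted(p))
        for p in m.undefined_pairs
        if p <= set(ids)
    ]
    if bad:
        raise ValueError(f"undefined distances among taxa: {sorted(bad)}")

    idx = [m.index(i) for i in ids]
    d = m.d[np.ix_(idx, idx)].astype(float).copy()

    tns = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for sid in ids:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(sid)
        nodes.append(node)

    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin on the row-major flattened matrix → lowest (i, j) on ties
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, na)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to every other active node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    # final three-way join: closed-form star resolution
    a, b, c = active
    la = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = max(0.0, 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = max(0.0, 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    center = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = length

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    total = li + lj
    if li < 0.0:
        li, lj = 0.0, max(0.0, total)
    elif lj < 0.0:
        lj, li = 0.0, max(0.0, total)
    return li, lj


def collapse_short_branches(
    tree: dendropy.Tree, epsilon: float = 1e-9
) -> dendropy.Tree:
    """Contract every internal branch of length <= epsilon into a polytomy.

    Leaf branches are never contracted. Idempotent. Returns a new tree.
    """
    if epsilon < 0:
        raise ValueError(f"collapse epsilon must be >= 0, got {epsilon}")
    out = tree.clone(depth=1)
    to_collapse = [
        e
        for e in out.preorder_edge_iter()
        if e.tail_node is not None
        and not e.head_node.is_leaf()
        and (e.length or 0.0) <= epsilon
    ]
    for e in to_collapse:
        e.collapse()
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup's pendant branch.

    The ingroup topology is untouched; re-rooting on the same leaf is
    idempotent. Returns a new tree.
    """
    out = tree.clone(depth=1)
    leaf = _find_leaf(out, outgroup_id)
    root = out.seed_node
    if leaf.parent_node is root and len(root.child_nodes()) == 2:
        return out  # already rooted on this pendant branch
    pendant = leaf.edge.length or 0.0
    out.reroot_at_edge(leaf.edge, length1=pendant / 2.0, length2=pendant / 2.0)
    out.is_rooted = True
    return out


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise ValueError(f"no leaf labelled {label!r} in tree")


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, one per internal branch.

    Each split is normalised to the smaller side (ties: lexicographically
    smaller), so rooted and unrooted representations of the same topology
    compare equal.
    """
    all_leaves = frozenset(
        l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None
    )
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        other = all_leaves - below
        if len(below) < 2 or len(other) < 2:
            continue  # trivial split
        if len(below) < len(other) or (
            len(below) == len(other) and sorted(below) < sorted(other)
        ):
            splits.add(below)
        else:
            splits.add(other)
    return splits


def bootstrap_supports(
    dataset: BarcodeDataset,
    n_replicates: int = 1000,
    seed: int | None = None,
    tree: dendropy.Tree | None = None,
    column_index_lists: Iterable[Sequence[int]] | None = None,
) -> dendropy.Tree:
    """Attach bootstrap supports (percent of replicates) to an NJ tree.

    Each replicate resamples alignment columns with replacement, rebuilds
    the full distance + NJ pipeline, and a branch's support is the
    percentage of replicate trees containing the same bipartition.
    Replicates producing an undefined distance are dropped with a warning
    and excluded from the denominator. ``column_index_lists`` overrides
    the random resampling (one list of column indices per replicate) so
    an external oracle can drive identical replicates.

    Returns a (copy of the) tree with ``node.support`` (float, 0-100) and
    ``node.label`` set on internal nodes; supports reproducible given seed.
    """
    if n_replicates < 1 and column_index_lists is None:
        raise ValueError("n_replicates must be >= 1")
    from .distances import distance_matrix

    if tree is None:
        tree = build_nj(distance_matrix(dataset))
    out = tree.clone(depth=1)

    L = dataset.alignment_length
    enc = np.stack([encode(r.sequence) for r in dataset.records])
    ids = dataset.specimen_ids

    if column_index_lists is None:
        rng = np.random.default_rng(seed)
        column_index_lists = (
            rng.integers(0, L, size=L) for _ in range(n_replicates)
        )

    counts: dict[frozenset[str], int] = {}
    n_ok = 0
    n_dropped = 0
    for cols in column_index_lists:
        cols = np.asarray(cols, dtype=int)
        rep = _replicate_matrix(enc[:, cols], ids)
        if rep is None:
            n_dropped += 1
            continue
        n_ok += 1
        for split in leaf_bipartitions(build_nj(rep)):
            counts[split] = counts.get(split, 0) + 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped} bootstrap replicate(s) dropped due to undefined "
            "distances",
            stacklevel=2,
        )
    if n_ok == 0:
        raise ValueError("all bootstrap replicates were dropped")

    all_leaves = frozenset(ids)
    for node in out.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        other = all_leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        key = below if (
            len(below) < len(other)
            or (len(below) == len(other) and sorted(below) < sorted(other))
        ) else other
        support = 100.0 * counts.get(key, 0) / n_ok
        node.support = support
        node.label = f"{support:g}"
    return out


def _replicate_matrix(enc: np.ndarray, ids: list[str]) -> DistanceMatrix | None:
    """Distance matrix from an encoded resampled alignment; None if any
    pair is undefined."""
    n = enc.shape[0]
    valid = enc != 255
    parity = enc & 1
    d = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        ts = diff & (parity[i] == parity[i + 1 :])
        n_comp = both.sum(axis=1).astype(float)
        n_ts = ts.sum(axis=1).astype(float)
        n_tv = diff.sum(axis=1).astype(float) - n_ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = n_ts / n_comp
            Q = n_tv / n_comp
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where(
                (n_comp > 0) & (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.abs(w1) * np.sqrt(np.abs(w2))),
                np.nan,
            )
        if np.isnan(row).any():
            return None
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(ids=list(ids), d=d, undefined_pairs=set())


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
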