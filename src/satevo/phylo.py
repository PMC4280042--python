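"""Indel-aware distances, neighbor joining, bootstrap and topology queries.

Distances treat each maximal run of adjacent gap columns (gap in exactly
one of the two rows) as a single fifth-state event — one insertion/deletion
of any length counts once — so indel-rich satellite alignments are not
over-weighted.  Trees are classic Saitou–Nei neighbor joining (consistent
on additive distances), unrooted, with optional column-bootstrap supports.
Tree containers are :mod:`dendropy` trees, so Newick round-trips and
standard tree arithmetic come for free.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.matrix).all() or (self.matrix < 0).any():
            raise ValueError("entries must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab.ljust(12) + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _pair_indel_block_distance(a: str, b: str) -> float:
    mismatch = 0
    compared = 0
    events = 0
    run_side = 0  # 0 = not in a single-gap run, 1 = gap in a, 2 = gap in b
    for ca, cb in zip(a, b):
        ga, gb = ca == "-", cb == "-"
        if ga and gb:
            continue  # both-gap columns carry no information for this pair
        if ga or gb:
            side = 1 if ga else 2
            if side != run_side:
                events += 1
                run_side = side
            continue
        run_side = 0
        compared += 1
        if ca != cb or ca == "N":
            mismatch += 1
    denom = compared + events
    return (mismatch + events) / denom if denom else 0.0


def indel_block_distance(msa: dict[str, str] | list[str], labels=None) -> DistanceMatrix:
    """Pairwise distances over an alignment with indel runs as 5th-state sites.

    For each pair: columns gapped in both rows are skipped; each maximal
    run of columns gapped in exactly one row collapses to one "indel"
    pseudo-site scored as a difference; distance = (mismatched nucleotide
    sites + indel events) / (compared nucleotide sites + indel events).
    Run-length invariant: a gap of length 10 counts the same as length 1.
    """
    if isinstance(msa, dict):
        labels = list(msa.keys())
        rows = [msa[k] for k in labels]
    else:
        rows = list(msa)
        labels = list(labels) if labels is not None else [f"seq{i}" for i in range(len(rows))]
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("aligned sequences must have equal length")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_indel_block_distance(rows[i], rows[j])
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei neighbor joining; unrooted dendropy tree.

    Deterministic: ties in the Q-matrix are broken by the label order of
    the joined pair.  Negative branch-length estimates are clamped to zero
    with the deficit transferred to the sister branch of the same join.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    keys = []  # deterministic tie-break keys (smallest leaf label in subtree)
    for lab in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
        keys.append(lab)
    D = dm.matrix.copy()
    active = list(range(n))

    def set_edge(node: dendropy.Node, parent_length: float) -> None:
        node.edge.length = max(parent_length, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = [
            (keys[active[i]], keys[active[j]], i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + 1e-12
        ]
        _, _, i, j = min(cand)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = max(vi, 0.0)
        nodes[aj].edge.length = max(vj, 0.0)
        new_row = 0.5 * (D[ai, active] + D[aj, active] - dij)
        u = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, active] = new_row
        D[active, u] = new_row
        D[u, u] = 0.0
        nodes.append(parent)
        keys.append(min(keys[ai], keys[aj]))
        active = [a for a in active if a not in (ai, aj)] + [u]

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def leafset_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _internal_bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Map each non-trivial bipartition (canonical smaller side) to its node."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = leafset_below(node)
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            continue
        other = all_leaves - below
        canon = min(below, other, key=lambda s: (len(s), sorted(s)))
        out[canon] = node
    return out


def is_monophyletic(tree: dendropy.Tree, leaves) -> tuple[bool, dendropy.Node | None]:
    """Does some edge separate exactly ``leaves`` from the rest (unrooted)?

    Singleton sets are monophyletic by their pendant edge.  Returns the
    witness node (child side of the separating edge) when true.
    """
    target = frozenset(leaves)
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not target or target == all_leaves:
        raise ValueError("leaf set must be a non-empty proper subset")
    if not target <= all_leaves:
        raise ValueError("unknown leaf labels: %s" % sorted(target - all_leaves))
    if len(target) == 1:
        (lab,) = target
        node = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == lab)
        return True, node
    other = all_leaves - target
    canon = min(target, other, key=lambda s: (len(s), sorted(s)))
    node = _internal_bipartitions(tree).get(canon)
    return (node is not None), node


def bootstrap_support(
    msa: dict[str, str],
    B: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with column-bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement B times; the
    indel-block distance and NJ tree are recomputed per replicate, and the
    support of each internal edge of the original tree is the percentage
    of replicates containing the same bipartition (stored as the internal
    node label, integer percent).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = list(msa.keys())
    if len(labels) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    rows = [msa[k] for k in labels]
    length = len(rows[0])
    tree = neighbor_joining(indel_block_distance(msa))
    original = _internal_bipartitions(tree)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, length, size=length)
        resampled = {
            lab: "".join(row[c] for c in cols) for lab, row in zip(labels, rows)
        }
        try:
            rep = neighbor_joining(indel_block_distance(resampled))
        except ValueError:  # pragma: no cover - degenerate resample
            continue
        rep_bps = _internal_bipartitions(rep)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in original.items():
        node.label = str(round(100.0 * counts[bp] / B))
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted symmetric (Robinson–Foulds) distance between two trees."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def root_at_outgroup_ancestor(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root post hoc on the edge above the ancestor of the outgroup leaves."""
    mono, node = is_monophyletic(tree, outgroup)
    if not mono:
        raise ValueError("outgroup is not monophyletic; cannot root on its ancestor")
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree
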