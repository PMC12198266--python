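"""Distance-based phylogeny: p-distances, neighbor joining, rooting, monophyly.

Neighbor joining (Saitou–Nei, Studier–Keppler Q-criterion) is implemented
in-package because its contracts here are load-bearing: deterministic
tie-breaking by lowest (row, column) index, exact recovery of additive
matrices, and clamping of negative branch-length estimates with the deficit
transferred to the sibling branch.  Trees are dendropy objects throughout,
so Newick round-tripping, rerooting and MRCA queries use a battle-tested
container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from aaokit.alignment import Msa


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("matrix must be symmetric within 1e-12")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be zero")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def p_distance_matrix(msa: Msa, correction: str = "none") -> DistanceMatrix:
    """Pairwise p-distances over mutually ungapped columns.

    ``correction='poisson'`` applies d = -ln(1 - p); p = 1 is then an error.
    """
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(msa.rows) < 3:
        raise ValueError("need at least 3 sequences")
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    gap = np.bytes_("-")
    n = len(arrs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arrs[i] != gap) & (arrs[j] != gap)
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = float((arrs[i][shared] != arrs[j][shared]).sum()) / n_shared
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1 between {msa.ids[i]!r} and {msa.ids[j]!r}: "
                        "Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            D[i, j] = D[j, i] = p
    return DistanceMatrix(list(msa.ids), D)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei agglomeration; returns an unrooted tree (trifurcating seed).

    Ties in the Q-criterion are broken by the lowest (row, column) index pair
    of the current matrix.  Negative branch-length estimates are clamped to 0
    with the deficit moved to the sibling branch so pair sums are preserved.
    """
    m = len(D.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(lab)) for lab in D.labels]
    d = D.values.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while m > 3:
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: first minimum = lowest (i, j)
        i, j = divmod(flat, m)
        if i > j:  # argmin lands on the upper triangle first, but be safe
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, : m - 2] = d2[: m - 2, m - 2] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2
        m -= 1

    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    seed = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        seed.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def _leafset_below(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The separating branch length is split equally between the two root
    children.  Fails if no single edge separates outgroup from ingroup.
    """
    og = frozenset(outgroup_ids)
    tree = tree.clone(depth=1)
    leaves = _leafset_below(tree.seed_node)
    if not og or not og.issubset(leaves):
        raise ValueError("outgroup ids must be a non-empty subset of the leaf labels")
    if og == leaves:
        raise ValueError("outgroup cannot contain every leaf")
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = _leafset_below(node)
        if below == og or below == leaves - og:
            target = node
            break
    if target is None:
        raise ValueError("outgroup not monophyletic in unrooted tree")
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, update_bipartitions=False)
    children = tree.seed_node.child_nodes()
    for child in children:
        child.edge.length = length / 2.0
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class MonophylyResult:
    label: str
    is_monophyletic: bool
    clade_purity: float
    clade_size: int


def monophyly_report(
    tree: dendropy.Tree, labels: dict[str, str]
) -> dict[str, MonophylyResult]:
    """Per-label monophyly of the smallest clade containing all its leaves.

    A label's clade is the MRCA subtree of its leaves; purity is the fraction
    of clade leaves carrying that label.  Single-member labels are
    monophyletic by convention.
    """
    if not tree.is_rooted:
        raise ValueError("monophyly assessment requires a rooted tree")
    leaf_labels = _leafset_below(tree.seed_node)
    missing = leaf_labels - set(labels)
    if missing:
        raise ValueError(f"unlabeled leaves: {sorted(missing)}")
    by_type: dict[str, set[str]] = {}
    for leaf, lab in labels.items():
        if leaf in leaf_labels:
            by_type.setdefault(lab, set()).add(leaf)
    results = {}
    for lab, members in sorted(by_type.items()):
        taxa = [t for t in tree.taxon_namespace if t.label in members]
        if len(taxa) == 1:
            results[lab] = MonophylyResult(lab, True, 1.0, 1)
            continue
        mrca = tree.mrca(taxa=taxa)
        clade = _leafset_below(mrca)
        purity = len(members) / len(clade)
        results[lab] = MonophylyResult(lab, clade == frozenset(members), purity, len(clade))
    return results


def bootstrap_support(
    msa: Msa,
    reference_tree: dendropy.Tree,
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "none",
) -> dict[frozenset[str], float]:
    """Nonparametric column-resampling bootstrap support for the reference
    tree's internal bipartitions (fraction of replicates containing each)."""
    rng = np.random.default_rng(seed)
    leaves = _leafset_below(reference_tree.seed_node)

    def bipartitions(tree) -> set[frozenset[str]]:
        out = set()
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            below = _leafset_below(node)
            side = min(below, leaves - below, key=lambda s: (len(s), sorted(s)))
            if len(side) >= 2:
                out.add(frozenset(side))
        return out

    ref_bips = bipartitions(reference_tree)
    counts = {b: 0 for b in ref_bips}
    n_cols = msa.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep_tree = neighbor_joining(p_distance_matrix(Msa(list(msa.ids), rows)))
        rep_bips = bipartitions(rep_tree)
        for b in ref_bips:
            if b in rep_bips:
                counts[b] += 1
    return {b: c / n_replicates for b, c in counts.items()}
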