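"""Gene-tree construction and scoring.

The native tree builder is distance-based neighbor-joining (raw p-distance
or Jukes-Cantor-corrected) with nonparametric bootstrap support; Fitch
small parsimony with gaps as a fifth character provides the parsimony
criterion; trees built elsewhere (e.g. ML searches) can be imported via
:func:`gcpsr.seqio.read_newick` and flow through the same downstream
analyses.  Trees are :class:`dendropy.Tree` objects with sample ids as
taxon labels and a float ``support`` attribute (bootstrap percent) on
internal nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from gcpsr.seqio import LocusAlignment

logger = logging.getLogger(__name__)

_BASES = np.array([b"A", b"C", b"G", b"T"])


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site), zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix not symmetric")
        if (self.matrix < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("nonzero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def _mismatch_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(diffs, comparable) pair-count matrices with pairwise deletion."""
    valid = np.isin(matrix, _BASES)
    comparable = valid.astype(np.int64) @ valid.astype(np.int64).T
    matches = np.zeros_like(comparable)
    for b in _BASES:
        x = (matrix == b).astype(np.int64)
        matches += x @ x.T
    return comparable - matches, comparable


def p_distance(
    aln: LocusAlignment, correction: str = "raw"
) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gaps/N.

    ``raw`` is the per-pair mismatch proportion; ``JC69`` applies the
    Jukes-Cantor correction -(3/4) ln(1 - (4/3) p) and raises for
    saturated pairs (p >= 0.75), naming the offending pair.
    """
    if correction not in {"raw", "JC69"}:
        raise ValueError(f"unknown correction {correction!r}")
    diffs, comparable = _mismatch_counts(aln.matrix)
    np.fill_diagonal(comparable, 1)  # diagonal p is 0 regardless
    if (comparable == 0).any():
        i, j = np.argwhere(comparable == 0)[0]
        raise ValueError(
            f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
        )
    p = diffs / comparable
    if correction == "JC69":
        if (p >= 0.75).any():
            i, j = np.argwhere(p >= 0.75)[0]
            raise ValueError(
                f"saturated pair under JC69: {aln.ids[i]} vs {aln.ids[j]} "
                f"(p = {p[i, j]:.3f} >= 0.75)"
            )
        p = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    np.fill_diagonal(p, 0.0)
    return DistanceMatrix(list(aln.ids), p)


# ---------------------------------------------------------------------------
# neighbor-joining


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; returns an unrooted tree.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge.  All argmin ties break lexicographically by the
    smallest leaf label contained in each cluster, making output
    deterministic for any input.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor-joining requires >= 3 taxa")
    tns = dendropy.TaxonNamespace(list(dist.ids))
    nodes: dict[str, dendropy.Node] = {}
    for label in dist.ids:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes[label] = nd

    # active clusters keyed by their lexicographically smallest leaf label
    d: dict[tuple[str, str], float] = {}
    active = sorted(dist.ids)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            d[(a, b)] = dist.value(a, b)

    def dget(a: str, b: str) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    def dset(a: str, b: str, v: float) -> None:
        d[(min(a, b), max(a, b))] = v

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best: tuple[str, str] | None = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dget(a, b) - r[a] - r[b]
                if q < best_q:
                    best_q, best = q, (a, b)
        assert best is not None
        a, b = best
        dab = dget(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            lb, la = dab, 0.0
        if lb < 0:
            la, lb = dab, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dset(new_key, c, 0.5 * (dget(a, c) + dget(b, c) - dab))
        active = sorted(set(active) - {a, b} | {new_key})
        nodes[new_key] = parent

    a, b, c = active
    la = 0.5 * (dget(a, b) + dget(a, c) - dget(b, c))
    lb = 0.5 * (dget(a, b) + dget(b, c) - dget(a, c))
    lc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
    root = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[label])
        nodes[label].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


# ---------------------------------------------------------------------------
# splits


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _canonical_split(
    side: frozenset[str], all_labels: frozenset[str]
) -> frozenset[str]:
    """Canonical representation of the unrooted split side|rest: the side
    not containing the lexicographically smallest leaf label."""
    ref = min(all_labels)
    return frozenset(all_labels - side) if ref in side else side


def nontrivial_splits(
    tree: dendropy.Tree, with_nodes: bool = False
):
    """Canonical nontrivial splits; optionally with their defining node."""
    labels = leaf_labels(tree)
    n = len(labels)
    out = []
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(clade) < 2 or len(clade) > n - 2:
            continue
        split = _canonical_split(clade, labels)
        out.append((split, nd) if with_nodes else split)
    return out


def supports_by_split(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    return {
        split: nd.support
        for split, nd in nontrivial_splits(tree, with_nodes=True)
        if getattr(nd, "support", None) is not None
    }


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapConfig:
    """Nonparametric bootstrap settings.

    ``n_replicates`` defaults to 1000 replicates; ``seed`` is mandatory so
    supports are bit-reproducible; ``support_display_threshold`` is the
    conventional percent below which figures omit the value (70).
    """

    seed: int
    n_replicates: int = 1000
    support_display_threshold: float = 70.0
    correction: str = "raw"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.support_display_threshold <= 100:
            raise ValueError("support_display_threshold outside [0, 100]")


def bootstrap_support(
    aln: LocusAlignment, cfg: BootstrapConfig
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement (seeded), NJ is
    rebuilt per replicate, and each internal split of the full-data tree
    receives the percentage of replicates containing it.  Replicates whose
    distance matrix is degenerate (incomparable or JC-saturated pairs) are
    skipped with a logged warning and the denominator adjusted.
    """
    if aln.n_seqs < 4:
        raise ValueError("bootstrap support requires >= 4 sequences")
    full = nj_tree(p_distance(aln, cfg.correction))
    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset[str], int] = {}
    valid_reps = 0
    for rep in range(cfg.n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        sub = LocusAlignment(aln.locus_name, list(aln.ids), aln.matrix[:, cols])
        try:
            rep_tree = nj_tree(p_distance(sub, cfg.correction))
        except ValueError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", rep, exc)
            continue
        valid_reps += 1
        for split in set(nontrivial_splits(rep_tree)):
            counts[split] = counts.get(split, 0) + 1
    if valid_reps == 0:
        raise ValueError("all bootstrap replicates degenerate")
    for split, nd in nontrivial_splits(full, with_nodes=True):
        nd.support = 100.0 * counts.get(split, 0) / valid_reps
    return full


# ---------------------------------------------------------------------------
# Fitch parsimony, gaps as a fifth state


_STATE_MASK = {b"A": 1, b"C": 2, b"G": 4, b"T": 8, b"-": 16, b"N": 31}


def fitch_score(tree: dendropy.Tree, aln: LocusAlignment) -> int:
    """Fitch small-parsimony length over the state set {A, C, G, T, -}.

    N is treated as missing data (the union of all five states, so it
    never forces a step).  The tree is evaluated as a rooted binary tree;
    an unrooted basal trifurcation is handled by rooting along a terminal
    edge, which leaves the parsimony length unchanged.  At genuine
    multifurcations children are folded sequentially (the usual
    generalization).
    """
    seqs = {}
    index = {sid: i for i, sid in enumerate(aln.ids)}
    for lf in tree.leaf_node_iter():
        label = lf.taxon.label
        if label not in index:
            raise ValueError(f"leaf {label!r} has no sequence in alignment")
        row = aln.matrix[index[label]]
        seqs[label] = np.array([_STATE_MASK[bytes(b)] for b in row], dtype=np.uint8)

    work = tree
    if len(tree.seed_node.child_nodes()) > 2:
        work = tree.clone(depth=1)
        first_leaf = next(work.leaf_node_iter())
        work.reroot_at_edge(first_leaf.edge)

    steps = np.zeros(aln.length, dtype=np.int64)

    def down(node) -> np.ndarray:
        if node.is_leaf():
            return seqs[node.taxon.label]
        children = [down(c) for c in node.child_nodes()]
        cur = children[0]
        for nxt in children[1:]:
            inter = cur & nxt
            disjoint = inter == 0
            cur = np.where(disjoint, cur | nxt, inter).astype(np.uint8)
            steps[disjoint] += 1
        return cur

    down(work.seed_node)
    return int(steps.sum())


# ---------------------------------------------------------------------------
# rooting


def root_tree(
    tree: dendropy.Tree,
    mode: str = "midpoint",
    outgroup: set[str] | None = None,
) -> dendropy.Tree:
    """Root a tree by outgroup or at the midpoint of the longest path.

    Outgroup mode roots on the edge separating the outgroup samples from
    the rest; if the outgroup is not clade-compatible, the edge maximizing
    outgroup/ingroup separation is used with a warning.  Supports are
    carried over split-wise, so the rooted tree shows the same bootstrap
    value for each preserved bipartition.
    """
    labels = leaf_labels(tree)
    saved = supports_by_split(tree)
    rooted = tree.clone(depth=1)
    if mode == "midpoint":
        rooted.reroot_at_midpoint(update_bipartitions=False)
    elif mode == "outgroup":
        if not outgroup:
            raise ValueError("outgroup mode requires a non-empty outgroup set")
        outgroup = set(outgroup)
        missing = outgroup - labels
        if missing:
            raise ValueError(f"outgroup samples absent from tree: {sorted(missing)}")
        edge = _outgroup_edge(rooted, outgroup, labels)
        if len(outgroup) == len(labels):
            raise ValueError("outgroup cannot contain every leaf")
        length = edge.length or 0.0
        rooted.reroot_at_edge(
            edge, length1=length / 2.0, length2=length / 2.0,
            update_bipartitions=False,
        )
    else:
        raise ValueError(f"unknown rooting mode {mode!r}")
    rooted.is_rooted = True
    for nd in rooted.preorder_node_iter():
        nd.support = None
    for nd in rooted.preorder_internal_node_iter():
        if nd is rooted.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(clade) <= len(labels) - 2:
            nd.support = saved.get(_canonical_split(clade, labels))
    return rooted


def _outgroup_edge(tree, outgroup: set[str], labels: frozenset[str]):
    """Edge whose removal best separates outgroup from ingroup leaves."""
    best_edge = None
    best_score = -1
    exact = False
    n_out = len(outgroup)
    n_in = len(labels) - n_out
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        clade = {lf.taxon.label for lf in nd.leaf_iter()}
        for side in (clade, set(labels) - clade):
            # correctly classified leaves when `side` is the outgroup side
            score = len(side & outgroup) + (n_in - len(side - outgroup))
            if score > best_score:
                best_score, best_edge = score, nd.edge
                exact = side == outgroup
    if not exact:
        logger.warning(
            "outgroup %s is not monophyletic; rooting on the edge "
            "maximizing outgroup/ingroup separation", sorted(outgroup),
        )
    return best_edge
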