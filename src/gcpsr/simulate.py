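"""Synthetic multilocus datasets with planted gene flow and exact truth.

The generator emulates the statistical shape of a multilocus survey of
closely related fungal species: a Yule species tree scaled to a chosen
root-to-tip height (expected substitutions/site), per-locus gene trees in
which each species tip is replaced by a shallow within-species subtree,
HKY85 sequence evolution along the branches, per-(sample, locus)
amplification dropout, and two kinds of planted discordance events:

* :class:`TipTransfer` — one sample is moved, at one locus only, onto the
  stem of a donor species (sister to the donor's crown), emulating an
  introgressed/hybrid individual.  The recipient species stops being
  monophyletic at that locus; the donor stays monophyletic.
* :class:`CladeMerge` — two species share a single interleaved subtree at
  one locus, emulating recently diverged species whose sequences have not
  sorted.  Neither species is monophyletic there, their union is.

Everything is deterministic given the config seed, and the expected
conflict matrix is derived from events + dropout alone, independently of
the analysis code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from gcpsr.concord import (
    CONFLICT,
    NO_CONFLICT,
    NO_DATA,
    SINGLE_SAMPLE,
    ConflictMatrix,
)
from gcpsr.seqio import (
    AMPLIFIED,
    FAILED,
    LocusAlignment,
    SampleTable,
    write_alignment,
    write_sample_table,
)

import pandas as pd


# ---------------------------------------------------------------------------
# internal tree representation (ultrametric, depth-annotated)


class _SimNode:
    __slots__ = ("label", "depth", "children")

    def __init__(self, depth: float, label: str | None = None,
                 children: list["_SimNode"] | None = None):
        self.label = label
        self.depth = depth
        self.children = children or []

    def leaves(self) -> list["_SimNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def copy(self) -> "_SimNode":
        return _SimNode(
            self.depth, self.label, [c.copy() for c in self.children]
        )


def _to_dendropy(root: _SimNode, rooted: bool = True) -> dendropy.Tree:
    labels = sorted(lf.label for lf in root.leaves())
    tns = dendropy.TaxonNamespace(labels)

    def convert(node: _SimNode) -> dendropy.Node:
        nd = dendropy.Node()
        if not node.children:
            nd.taxon = tns.get_taxon(node.label)
        for c in node.children:
            child = convert(c)
            nd.add_child(child)
            child.edge.length = max(c.depth - node.depth, 0.0)
        return nd

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=convert(root))
    tree.is_rooted = rooted
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def _from_dendropy(tree: dendropy.Tree) -> _SimNode:
    """Depth-annotated copy of a rooted tree (depths = root distances)."""

    def convert(nd, depth: float) -> _SimNode:
        out = _SimNode(depth, nd.taxon.label if nd.is_leaf() else None)
        for c in nd.child_nodes():
            out.children.append(convert(c, depth + (c.edge.length or 0.0)))
        return out

    return convert(tree.seed_node, 0.0)


def _prune(root: _SimNode, drop: set[str]) -> _SimNode | None:
    """Remove the named leaves; suppress single-child internals."""
    if not root.children:
        return None if root.label in drop else root
    kept = [c for c in (_prune(c, drop) for c in root.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    root.children = kept
    return root


# ---------------------------------------------------------------------------
# species tree


def sim_species_tree(
    n_species: int,
    height: float,
    seed: int | np.random.Generator,
    depth_fraction: float = 1.0,
) -> dendropy.Tree:
    """Ultrametric species tree with Yule topology, root-to-tip = height.

    ``depth_fraction`` < 1 compresses all speciation events into the top
    fraction of the height, guaranteeing every between-species divergence
    is at least ``2 * (1 - depth_fraction) * height`` (a strong-signal
    radiation); 1.0 leaves the natural profile, under which the youngest
    sister species may be arbitrarily weakly separated.
    """
    root = _yule(n_species, height, _rng(seed), depth_fraction=depth_fraction)
    return _to_dendropy(root)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _yule(n: int, height: float, rng: np.random.Generator,
          labels: Sequence[str] | None = None,
          depth_fraction: float = 1.0) -> _SimNode:
    """Yule (uniform random splitting) topology; split depths follow the
    expected-waiting-time (harmonic) profile, a documented internal
    choice that keeps the tree ultrametric and deterministic."""
    if n < 2:
        raise ValueError("need >= 2 species")
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must be in (0, 1]")
    if labels is None:
        width = len(str(n))
        labels = [f"sp{i + 1:0{width}d}" for i in range(n)]
    harmonics = np.cumsum(1.0 / np.arange(1, n + 1))  # H_1 .. H_n
    depth_of_event = (
        depth_fraction * height * (harmonics - 1.0) / (harmonics[-1] - 1.0)
    )
    # event k (1-based) splits one active lineage at depth_of_event[k-1];
    # event 1 is the root.
    root = _SimNode(depth_of_event[0], children=[_SimNode(0.0), _SimNode(0.0)])
    active = list(root.children)
    for k in range(2, n):
        nd = active.pop(int(rng.integers(len(active))))
        nd.depth = depth_of_event[k - 1]
        nd.children = [_SimNode(0.0), _SimNode(0.0)]
        active.extend(nd.children)
    order = rng.permutation(len(active))
    for lbl, idx in zip(labels, order):
        active[idx].label = lbl
        active[idx].depth = height
    return root


# ---------------------------------------------------------------------------
# config / truth


@dataclass
class TipTransfer:
    sample_id: str
    locus: str
    donor_species: str


@dataclass
class CladeMerge:
    species_a: str
    species_b: str
    locus: str


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``species_tree_height`` is the expected substitutions/site from root
    to tip; ``within_species_scale`` sets within-species subtree depth as
    a fraction of that height.  ``dropout_prob`` may be a scalar or a
    per-locus mapping of Bernoulli failure probabilities.
    """

    n_species: int = 22
    samples_per_species: int | Sequence[int] = 4
    loci: Sequence[tuple[str, int]] = (("locus1", 800),)
    species_tree_height: float = 0.02
    within_species_scale: float = 0.02
    species_depth_fraction: float = 1.0
    kappa: float = 2.0
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    dropout_prob: float | Mapping[str, float] = 0.0
    events: Sequence[TipTransfer | CladeMerge] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if isinstance(self.samples_per_species, int):
            self.samples_per_species = [self.samples_per_species] * self.n_species
        if len(self.samples_per_species) != self.n_species:
            raise ValueError("samples_per_species length != n_species")
        probs = (
            list(dict(self.dropout_prob).values())
            if isinstance(self.dropout_prob, Mapping)
            else [self.dropout_prob]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("dropout probabilities must be in [0, 1]")

    @property
    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]

    def samples_of(self, species: str) -> list[str]:
        i = self.species_ids.index(species)
        return [f"{species}_{j + 1}" for j in range(self.samples_per_species[i])]

    def locus_dropout(self, locus: str) -> float:
        if isinstance(self.dropout_prob, Mapping):
            return float(self.dropout_prob.get(locus, 0.0))
        return float(self.dropout_prob)


#: Conditions mirroring the published survey: 22 species, 1-9 samples
#: each (83 in total), four loci at the published aligned lengths, full
#: amplification success at the two mating-type loci, and dropout rates at
#: the two non-reproductive loci matching the published 14/83 and 15/83
#: failure counts.  Interspecific diversity ~0.02, intraspecific <= ~0.01.
SURVEY_SAMPLE_COUNTS = (5, 2, 4, 5, 4, 2, 1, 9, 3, 4, 4, 2, 5, 6, 5, 5, 4, 6, 1, 2, 2, 2)


def survey_config(seed: int = 0, events: Sequence = ()) -> SimConfig:
    return SimConfig(
        n_species=22,
        samples_per_species=list(SURVEY_SAMPLE_COUNTS),
        loci=(
            ("MAT1-1-1", 654),
            ("MAT1-2-1", 827),
            ("F1", 755),
            ("IGS", 909),
        ),
        species_tree_height=0.02,
        within_species_scale=0.02,
        kappa=2.0,
        dropout_prob={"F1": 14 / 83, "IGS": 15 / 83},
        events=list(events),
        seed=seed,
    )


@dataclass
class SimTruth:
    """Ground truth for one synthetic dataset."""

    species_tree: str  # newick over species ids
    gene_trees: dict[str, str]  # locus -> newick over sample ids
    events: list[TipTransfer | CladeMerge]
    dropout: dict[str, list[str]]  # sample -> loci that failed
    expected_conflicts: ConflictMatrix
    sample_species: dict[str, str]

    def to_json(self) -> str:
        def enc(e):
            if isinstance(e, TipTransfer):
                return {"type": "tip_transfer", "sample_id": e.sample_id,
                        "locus": e.locus, "donor_species": e.donor_species}
            return {"type": "clade_merge", "species_a": e.species_a,
                    "species_b": e.species_b, "locus": e.locus}

        m = self.expected_conflicts
        return json.dumps(
            {
                "species_tree": self.species_tree,
                "gene_trees": self.gene_trees,
                "events": [enc(e) for e in self.events],
                "dropout": self.dropout,
                "expected_conflicts": {
                    sp: {loc: m.states[(sp, loc)] for loc in m.loci}
                    for sp in m.species
                },
                "sample_species": self.sample_species,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# gene trees


def _coalescent_subtree(
    samples: Sequence[str], top_depth: float, tip_depth: float,
    rng: np.random.Generator,
) -> _SimNode:
    """Random-topology ultrametric subtree over the samples; join depths
    evenly spaced between tip_depth and top_depth."""
    nodes = [_SimNode(tip_depth, label=s) for s in samples]
    m = len(nodes)
    if m == 1:
        return nodes[0]
    join_depths = [
        tip_depth - (tip_depth - top_depth) * (j + 1) / (m - 1)
        for j in range(m - 1)
    ]
    for d in join_depths:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(_SimNode(d, children=[a, b]))
    return nodes[0]


def _interleaved_caterpillar(
    group_a: Sequence[str], group_b: Sequence[str],
    top_depth: float, tip_depth: float,
) -> _SimNode:
    """Caterpillar alternating the two groups' samples, so that neither
    group alone is monophyletic while their union is."""
    order: list[str] = []
    for x, y in zip(group_a, group_b):
        order.extend([x, y])
    longer = group_a if len(group_a) > len(group_b) else group_b
    order.extend(longer[min(len(group_a), len(group_b)):])
    m = len(order)
    join_depths = [
        tip_depth - (tip_depth - top_depth) * (j + 1) / (m - 1)
        for j in range(m - 1)
    ]
    node = _SimNode(tip_depth, label=order[0])
    for j, lbl in enumerate(order[1:]):
        node = _SimNode(
            join_depths[j], children=[node, _SimNode(tip_depth, label=lbl)]
        )
    return node


def _species_crown(root: _SimNode, species: str) -> tuple[_SimNode, _SimNode]:
    """(parent, crown) where crown is the subtree holding exactly the
    samples of `species` (identified by the `species_` label prefix)."""
    prefix = f"{species}_"

    def find(node: _SimNode, parent: _SimNode | None):
        labels = [lf.label for lf in node.leaves()]
        if all(l.startswith(prefix) for l in labels):
            return parent, node
        for c in node.children:
            child_labels = [lf.label for lf in c.leaves()]
            if any(l.startswith(prefix) for l in child_labels):
                return find(c, node)
        raise ValueError(f"species {species} not found as a clade")

    parent, crown = find(root, None)
    if parent is None:
        raise ValueError(f"species {species} spans the whole tree")
    return parent, crown


def sim_gene_trees(
    species_root: _SimNode | dendropy.Tree,
    config: SimConfig,
) -> tuple[dict[str, dendropy.Tree], SimTruth]:
    """Per-locus gene trees plus ground truth.

    Baseline: the species tree with each species tip replaced by a
    within-species subtree of depth height * within_species_scale.
    Dropout is drawn first; an event referencing a sample dropped at the
    same locus raises.  Events then reshape the named locus only.
    """
    if isinstance(species_root, dendropy.Tree):
        species_root = _from_dendropy(species_root)
    height = config.species_tree_height
    d_within = height * config.within_species_scale
    rng_topo = np.random.default_rng([config.seed, 1])
    rng_drop = np.random.default_rng([config.seed, 2])

    sample_species = {
        s: sp for sp in config.species_ids for s in config.samples_of(sp)
    }

    # dropout ledger
    dropout: dict[str, list[str]] = {s: [] for s in sample_species}
    dropped_at: dict[str, set[str]] = {loc: set() for loc, _ in config.loci}
    for locus, _ in config.loci:
        p = config.locus_dropout(locus)
        for s in sample_species:
            if p > 0 and rng_drop.random() < p:
                dropout[s].append(locus)
                dropped_at[locus].add(s)

    events_by_locus: dict[str, list] = {loc: [] for loc, _ in config.loci}
    for ev in config.events:
        if ev.locus not in events_by_locus:
            raise ValueError(f"event references unknown locus {ev.locus!r}")
        events_by_locus[ev.locus].append(ev)
        if isinstance(ev, TipTransfer):
            if ev.sample_id not in sample_species:
                raise ValueError(f"unknown sample {ev.sample_id!r} in event")
            if ev.donor_species not in config.species_ids:
                raise ValueError(f"unknown donor {ev.donor_species!r} in event")
            if ev.sample_id in dropped_at[ev.locus]:
                raise ValueError(
                    f"event references sample {ev.sample_id} dropped at "
                    f"locus {ev.locus}"
                )
        else:
            for sp in (ev.species_a, ev.species_b):
                if sp not in config.species_ids:
                    raise ValueError(f"unknown species {sp!r} in event")

    gene_trees: dict[str, dendropy.Tree] = {}
    gene_newicks: dict[str, str] = {}
    for locus, _length in config.loci:
        root = species_root.copy()
        # per-species crown subtrees over surviving samples
        surviving: dict[str, list[str]] = {}
        for leaf in root.leaves():
            sp = leaf.label
            keep = [
                s for s in config.samples_of(sp)
                if s not in dropped_at[locus]
            ]
            surviving[sp] = keep
        merged_species: set[str] = set()
        for ev in events_by_locus[locus]:
            if isinstance(ev, CladeMerge):
                merged_species.update([ev.species_a, ev.species_b])
        transferred = {
            ev.sample_id: ev
            for ev in events_by_locus[locus]
            if isinstance(ev, TipTransfer)
        }
        root = _attach_crowns(
            root, config, surviving, transferred, d_within, rng_topo
        )
        for ev in events_by_locus[locus]:
            if isinstance(ev, TipTransfer):
                root = _apply_transfer(root, ev, surviving, d_within, height)
            else:
                root = _apply_merge(root, ev, surviving, d_within, height)
        if root is None or len(root.leaves()) == 0:
            gene_trees[locus] = None
            gene_newicks[locus] = ""
            continue
        tree = _to_dendropy(root)
        gene_trees[locus] = tree
        gene_newicks[locus] = tree.as_string(schema="newick").strip()

    expected = _expected_conflicts(config, sample_species, dropped_at)
    truth = SimTruth(
        species_tree=_to_dendropy(species_root).as_string(schema="newick").strip(),
        gene_trees=gene_newicks,
        events=list(config.events),
        dropout={s: sorted(l) for s, l in dropout.items() if l},
        expected_conflicts=expected,
        sample_species=sample_species,
    )
    return gene_trees, truth


def _attach_crowns(root, config, surviving, transferred, d_within, rng):
    """Replace each species tip with its within-species subtree (samples
    slated for transfer at this locus are excluded here)."""
    height = config.species_tree_height
    drop_all: set[str] = set()
    for leaf in root.leaves():
        sp = leaf.label
        keep = [s for s in surviving[sp] if s not in transferred]
        if not keep:
            drop_all.add(sp)
            continue
        crown = _coalescent_subtree(keep, height - d_within, height, rng)
        leaf.label = None
        leaf.depth = crown.depth
        leaf.children = crown.children
        if not crown.children:  # single sample
            leaf.label = crown.label
    return _prune(root, drop_all)


def _apply_transfer(root, ev: TipTransfer, surviving, d_within, height):
    """Attach the transferred sample on the donor's stem, sister to the
    donor crown (donor stays monophyletic; recipient does not)."""
    parent, crown = _species_crown(root, ev.donor_species)
    attach_depth = (parent.depth + crown.depth) / 2.0
    new = _SimNode(attach_depth, children=[crown, _SimNode(height, label=ev.sample_id)])
    parent.children[parent.children.index(crown)] = new
    return root


def _apply_merge(root, ev: CladeMerge, surviving, d_within, height):
    """Replace both species' crowns with one interleaved caterpillar at
    the position of species_a; species_b's crown is pruned."""
    a = sorted(surviving[ev.species_a])
    b = sorted(surviving[ev.species_b])
    if not a or not b:
        raise ValueError(
            f"clade merge {ev.species_a}/{ev.species_b} at {ev.locus}: "
            "a species has no surviving samples"
        )
    _, crown_b = _species_crown(root, ev.species_b)
    root = _prune(root, {lf.label for lf in crown_b.leaves()})
    parent, crown_a = _species_crown(root, ev.species_a)
    merged = _interleaved_caterpillar(a, b, height - d_within, height)
    parent.children[parent.children.index(crown_a)] = merged
    return root


def _expected_conflicts(config, sample_species, dropped_at) -> ConflictMatrix:
    """Derived from events + dropout alone (no tree inspection)."""
    loci = [loc for loc, _ in config.loci]
    states = {}
    for sp in config.species_ids:
        for locus in loci:
            amplified = [
                s for s in config.samples_of(sp) if s not in dropped_at[locus]
            ]
            if len(amplified) == 0:
                states[(sp, locus)] = NO_DATA
                continue
            if len(amplified) == 1:
                states[(sp, locus)] = SINGLE_SAMPLE
                continue
            conflict = False
            for ev in config.events:
                if ev.locus != locus:
                    continue
                if isinstance(ev, TipTransfer):
                    if sample_species[ev.sample_id] == sp and ev.sample_id in amplified:
                        conflict = True
                else:
                    partner = {ev.species_a: ev.species_b,
                               ev.species_b: ev.species_a}.get(sp)
                    if partner is not None:
                        partner_alive = any(
                            s not in dropped_at[locus]
                            for s in config.samples_of(partner)
                        )
                        conflict = conflict or partner_alive
            states[(sp, locus)] = CONFLICT if conflict else NO_CONFLICT
    return ConflictMatrix(list(config.species_ids), loci, states)


# ---------------------------------------------------------------------------
# sequence evolution (HKY85)


def hky_rate_matrix(kappa: float, base_freqs: Sequence[float]) -> np.ndarray:
    """HKY85 generator (rows A, C, G, T), scaled to mean rate 1."""
    pi = np.asarray(base_freqs, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    kappa: float = 2.0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
) -> LocusAlignment:
    """Simulate an alignment down the tree under HKY85.

    Root states are drawn from ``base_freqs``; each branch applies the
    transition matrix expm(Q * t).  Branch lengths are substitutions/site;
    negative lengths raise.  Deterministic under the seed.
    """
    rng = _rng(seed)
    q = hky_rate_matrix(kappa, base_freqs)
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            p = expm(q * t)
            p = np.clip(p, 0.0, None)
            pmat_cache[t] = p / p.sum(axis=1, keepdims=True)
        return pmat_cache[t]

    pi = np.asarray(base_freqs, dtype=float)
    states: dict[int, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    bases = np.array([b"A", b"C", b"G", b"T"])
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[id(nd)] = rng.choice(4, size=length, p=pi)
        else:
            t = nd.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            parent_states = states[id(nd.parent_node)]
            p = pmat(t)
            child = np.empty(length, dtype=np.int64)
            for a in range(4):
                idx = np.nonzero(parent_states == a)[0]
                if idx.size:
                    child[idx] = rng.choice(4, size=idx.size, p=p[a])
            states[id(nd)] = child
        if nd.is_leaf():
            rows[nd.taxon.label] = bases[states[id(nd)]]
    ids = sorted(rows)
    matrix = np.stack([rows[s] for s in ids])
    locus = getattr(tree, "locus_name", "sim")
    return LocusAlignment(locus, ids, matrix)


# ---------------------------------------------------------------------------
# dataset assembly


def make_dataset(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[dict[str, LocusAlignment], SampleTable, SimTruth]:
    """Simulate alignments + metadata + truth; optionally write them out.

    Writes one FASTA per locus, a metadata TSV (dropout marked FAILED) and
    ``truth.json`` when ``outdir`` is given.  Byte-identical for identical
    configs.
    """
    species_root = _yule(
        config.n_species,
        config.species_tree_height,
        np.random.default_rng([config.seed, 0]),
        labels=config.species_ids,
        depth_fraction=config.species_depth_fraction,
    )
    gene_trees, truth = sim_gene_trees(species_root, config)

    alignments: dict[str, LocusAlignment] = {}
    for i, (locus, length) in enumerate(config.loci):
        tree = gene_trees[locus]
        if tree is None:
            alignments[locus] = None
            continue
        tree.locus_name = locus
        alignments[locus] = evolve_sequences(
            tree, length, config.kappa, config.base_freqs,
            np.random.default_rng([config.seed, 10 + i]),
        )

    frame = pd.DataFrame(
        {
            "species_id": [
                truth.sample_species[s] for s in sorted(truth.sample_species)
            ],
            "voucher": [f"SYN-{s}" for s in sorted(truth.sample_species)],
        },
        index=pd.Index(sorted(truth.sample_species), name="sample_id"),
    )
    status = {
        s: {
            locus: FAILED if locus in truth.dropout.get(s, []) else AMPLIFIED
            for locus, _ in config.loci
        }
        for s in sorted(truth.sample_species)
    }
    table = SampleTable(frame, status)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus, aln in alignments.items():
            if aln is not None:
                write_alignment(aln, outdir / f"{locus}.fasta")
        write_sample_table(table, outdir / "samples.tsv")
        (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return alignments, table, truth
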