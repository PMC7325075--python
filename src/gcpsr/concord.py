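"""Genealogical concordance: monophyly scoring, the species x locus
conflict matrix, hybrid flagging, and pairwise genealogy comparison.

The unit of inference is a species whose samples form a clade in the
species phylogeny: if the same samples fail to form a clade in a gene
genealogy, that (species, locus) cell is a CONFLICT.  Species with one
amplified sample (SINGLE_SAMPLE) or none (NO_DATA) are excluded from the
per-locus conflict percentage.  Sample-level hybrid flagging looks for a
sample nesting, with strong bootstrap support, inside another species'
clade (FOREIGN_NESTING) and for pairs of species collapsing into a single
supported clade with no supported internal resolution (SPECIES_MERGE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import dendropy

from gcpsr.divstats import round_half_up
from gcpsr.phylo import leaf_labels, nontrivial_splits, supports_by_split
from gcpsr.seqio import AMPLIFIED, SampleTable

logger = logging.getLogger(__name__)

CONFLICT = "CONFLICT"
NO_CONFLICT = "NO_CONFLICT"
SINGLE_SAMPLE = "SINGLE_SAMPLE"
NO_DATA = "NO_DATA"

FOREIGN_NESTING = "FOREIGN_NESTING"
SPECIES_MERGE = "SPECIES_MERGE"


class MonophylyStatus(NamedTuple):
    is_monophyletic: bool
    support: float | None  # bootstrap percent of the exact clade, if any


def _clades(tree: dendropy.Tree) -> list[tuple[frozenset[str], float | None]]:
    """Leaf sets of every node (leaves included), with supports."""
    out = []
    for nd in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        out.append((leaves, getattr(nd, "support", None)))
    return out


def monophyly_status(
    tree: dendropy.Tree, samples: Iterable[str], threshold: float = 70.0
) -> MonophylyStatus:
    """Is the sample set an exact clade of the (rooted) tree?

    Returns the clade's bootstrap support when monophyletic (absent for a
    single sample or an unsupported node).  ``threshold`` is the display
    convention and does not affect the boolean.
    """
    target = frozenset(samples)
    if not target:
        raise ValueError("empty sample set")
    labels = leaf_labels(tree)
    missing = target - labels
    if missing:
        raise ValueError(f"samples not in tree: {sorted(missing)}")
    for leaves, support in _clades(tree):
        if leaves == target:
            return MonophylyStatus(True, support if len(target) > 1 else None)
    return MonophylyStatus(False, None)


@dataclass
class ConflictMatrix:
    """Species x locus conflict states plus per-locus percentages."""

    species: list[str]
    loci: list[str]
    states: dict[tuple[str, str], str]
    species_tree_violations: list[str] = field(default_factory=list)

    def state(self, species: str, locus: str) -> str:
        return self.states[(species, locus)]

    def percentages(self) -> dict[str, float | None]:
        return conflict_percentages(self)


def conflict_percentages(matrix: ConflictMatrix) -> dict[str, float | None]:
    """Per locus, 100 * CONFLICT / (CONFLICT + NO_CONFLICT), one decimal
    (half-up); None where no species is evaluable."""
    out: dict[str, float | None] = {}
    for locus in matrix.loci:
        states = [matrix.states[(sp, locus)] for sp in matrix.species]
        n_conf = states.count(CONFLICT)
        n_eval = n_conf + states.count(NO_CONFLICT)
        out[locus] = round_half_up(100.0 * n_conf / n_eval, 1) if n_eval else None
    return out


def build_conflict_matrix(
    species_tree: dendropy.Tree,
    gene_trees: Mapping[str, dendropy.Tree],
    table: SampleTable,
) -> ConflictMatrix:
    """Score every species' monophyly in every gene tree.

    Cell states: NO_DATA (0 amplified samples), SINGLE_SAMPLE (1),
    CONFLICT (>= 2 amplified samples not monophyletic in the gene tree),
    NO_CONFLICT otherwise.  A gene tree containing a sample whose
    amplification is marked FAILED for that locus is a metadata
    inconsistency and raises.  Species that are not monophyletic in the
    species tree are recorded as violations (the matrix is still built).
    """
    violations = []
    for species in table.species_ids:
        members = [
            s for s in table.samples_of(species)
            if s in leaf_labels(species_tree)
        ]
        if len(members) >= 2 and not monophyly_status(
            species_tree, members
        ).is_monophyletic:
            violations.append(species)
    if violations:
        logger.warning(
            "species not monophyletic in the species tree: %s", violations
        )

    states: dict[tuple[str, str], str] = {}
    loci = list(gene_trees)
    for locus, gtree in gene_trees.items():
        tree_leaves = leaf_labels(gtree)
        failed_in_tree = [
            s for s in tree_leaves
            if table.locus_status.get(s, {}).get(locus) != AMPLIFIED
        ]
        if failed_in_tree:
            raise ValueError(
                f"gene tree for {locus} contains samples marked FAILED "
                f"(metadata inconsistency): {sorted(failed_in_tree)}"
            )
        for species in table.species_ids:
            amplified = table.amplified_samples(species, locus)
            present = [s for s in amplified if s in tree_leaves]
            if len(present) < len(amplified):
                logger.warning(
                    "%s: %d amplified sample(s) of %s absent from gene tree",
                    locus, len(amplified) - len(present), species,
                )
            if len(present) == 0:
                states[(species, locus)] = NO_DATA
            elif len(present) == 1:
                states[(species, locus)] = SINGLE_SAMPLE
            else:
                mono = monophyly_status(gtree, present).is_monophyletic
                states[(species, locus)] = NO_CONFLICT if mono else CONFLICT
    return ConflictMatrix(list(table.species_ids), loci, states, violations)


@dataclass
class HybridCall:
    """One sample-level (or species-pair) discordance call at one locus."""

    sample_id: str | None  # None for SPECIES_MERGE
    own_species: str
    locus_name: str
    host_species: tuple[str, ...]
    support: float
    evidence: str  # FOREIGN_NESTING | SPECIES_MERGE


def _species_in_tree(
    table: SampleTable, tree_leaves: frozenset[str]
) -> dict[str, frozenset[str]]:
    return {
        sp: frozenset(set(table.samples_of(sp)) & tree_leaves)
        for sp in table.species_ids
        if set(table.samples_of(sp)) & tree_leaves
    }


def flag_hybrids(
    species_tree: dendropy.Tree,
    gene_tree: dendropy.Tree,
    table: SampleTable,
    locus_name: str,
    support_min: float = 95.0,
    resolution_threshold: float = 70.0,
) -> list[HybridCall]:
    """Flag putative hybrid samples and merged species pairs at one locus.

    FOREIGN_NESTING — sample ``s`` of species X is called when the gene
    tree has a clade with support >= ``support_min`` in which ``s`` is the
    only X member and every other member belongs to other species, and
    pruning ``s`` would restore the monophyly of X and of every host
    species.  The restoration requirement distinguishes the intruding
    sample from the host-side samples it nests among.

    SPECIES_MERGE — species pair (X, Y) is called when the union of their
    samples is a clade with support >= ``support_min`` while no clade with
    support >= ``resolution_threshold`` equals either species alone (the
    near-identical-sequences pattern, where two recently diverged species
    share one gene pool at this locus).
    """
    tree_leaves = leaf_labels(gene_tree)
    by_species = _species_in_tree(table, tree_leaves)
    clades = _clades(gene_tree)
    supported = [
        (leaves, sup) for leaves, sup in clades
        if sup is not None and sup >= support_min and len(leaves) >= 2
    ]
    clade_sets = {leaves for leaves, _ in clades}

    def mono_without(species_samples: frozenset[str], s: str) -> bool:
        rest = species_samples - {s}
        if len(rest) <= 1:
            return True
        return any(leaves - {s} == rest for leaves in clade_sets)

    calls: list[HybridCall] = []
    for sp_x, x_samples in by_species.items():
        if len(x_samples) < 2:
            continue
        for s in sorted(x_samples):
            candidates = [
                (leaves, sup) for leaves, sup in supported
                if s in leaves and leaves & x_samples == {s}
            ]
            if not candidates:
                continue
            leaves, sup = min(candidates, key=lambda c: len(c[0]))
            # clades containing s form a chain, so the smallest clade in
            # which s is the only X member (any support) is nested inside
            # the supported one and names the immediate host(s)
            nearest = min(
                (
                    c for c, _ in clades
                    if s in c and len(c) >= 2 and c & x_samples == {s}
                ),
                key=len,
            )
            hosts = sorted({table.species_of(m) for m in nearest - {s}})
            if not mono_without(x_samples, s):
                continue
            if not all(
                mono_without(by_species[h], s) for h in hosts if h in by_species
            ):
                continue
            calls.append(
                HybridCall(s, sp_x, locus_name, tuple(hosts), sup, FOREIGN_NESTING)
            )

    species_list = sorted(sp for sp, ss in by_species.items() if len(ss) >= 2)
    for i, sp_a in enumerate(species_list):
        for sp_b in species_list[i + 1 :]:
            a, b = by_species[sp_a], by_species[sp_b]
            union = a | b
            union_sup = next(
                (sup for leaves, sup in supported if leaves == union), None
            )
            if union_sup is None:
                continue

            def separated(side: frozenset[str]) -> bool:
                return any(
                    leaves == side
                    and sup is not None
                    and sup >= resolution_threshold
                    for leaves, sup in clades
                )

            if separated(a) or separated(b):
                continue
            calls.append(
                HybridCall(
                    None, sp_a, locus_name, (sp_b,), union_sup, SPECIES_MERGE
                )
            )
    return calls


class GenealogyComparison(NamedTuple):
    shared: set[frozenset[str]]
    conflicting: set[tuple[frozenset[str], frozenset[str]]]


def splits_compatible(
    a: frozenset[str], b: frozenset[str], labels: frozenset[str]
) -> bool:
    """Two unrooted splits (given as one side each) can coexist in a tree
    iff one of the four side intersections is empty."""
    a2, b2 = labels - a, labels - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def compare_genealogies(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    threshold: float = 70.0,
) -> GenealogyComparison:
    """Shared and conflicting well-supported bipartitions of two trees.

    Both trees are restricted to their common leaves (error if fewer than
    4); a bipartition counts when its support is >= ``threshold`` in its
    own tree; two bipartitions conflict when they cannot coexist in any
    single tree on the common leaf set.
    """
    common = leaf_labels(tree_a) & leaf_labels(tree_b)
    if len(common) < 4:
        raise ValueError(
            f"leaf intersection has {len(common)} taxa; need >= 4"
        )
    ref = min(common)

    def restricted_supported(tree) -> set[frozenset[str]]:
        out = set()
        for split, nd in nontrivial_splits(tree, with_nodes=True):
            sup = getattr(nd, "support", None)
            if sup is None or sup < threshold:
                continue
            side = split & common
            if len(side) < 2 or len(common - side) < 2:
                continue
            out.add(frozenset(common - side) if ref in side else side)
        return out

    splits_a = restricted_supported(tree_a)
    splits_b = restricted_supported(tree_b)
    shared = splits_a & splits_b
    conflicting = {
        (sa, sb)
        for sa in splits_a
        for sb in splits_b
        if not splits_compatible(sa, sb, common)
    }
    return GenealogyComparison(shared, conflicting)
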