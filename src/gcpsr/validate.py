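"""End-to-end validation experiments on synthetic data.

These run the full inference chain — simulate, build NJ bootstrap gene
trees, build the species tree from the concatenated loci, score
conflicts, flag hybrids — against the generator's planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gcpsr import concord, phylo, simulate
from gcpsr.cli import _concatenate
from gcpsr.mating import segregation_test


def _planted_config(seed: int, with_events: bool) -> simulate.SimConfig:
    """Strong-signal planted-event conditions: 8 species x 4 samples,
    four 800-site loci, root-to-tip height 0.05 with every speciation in
    the deep half (between-species divergence >= 0.05), two tip transfers
    and one species merge."""
    events = []
    if with_events:
        events = [
            simulate.TipTransfer("sp1_2", "locus1", "sp5"),
            simulate.TipTransfer("sp3_1", "locus2", "sp7"),
            simulate.CladeMerge("sp2", "sp4", "locus3"),
        ]
    return simulate.SimConfig(
        n_species=8,
        samples_per_species=4,
        loci=[(f"locus{i + 1}", 800) for i in range(4)],
        species_tree_height=0.05,
        species_depth_fraction=0.5,
        events=events,
        seed=seed,
    )


def _infer_trees(alignments, seed: int, n_replicates: int):
    gene_trees = {}
    for i, (locus, aln) in enumerate(alignments.items()):
        cfg = phylo.BootstrapConfig(
            seed=(seed * 131 + i) % 2**31, n_replicates=n_replicates
        )
        gene_trees[locus] = phylo.root_tree(
            phylo.bootstrap_support(aln, cfg), "midpoint"
        )
    concat = _concatenate(list(alignments.values()))
    cfg = phylo.BootstrapConfig(seed=(seed * 131 + 99) % 2**31,
                                n_replicates=n_replicates)
    species_tree = phylo.root_tree(
        phylo.bootstrap_support(concat, cfg), "midpoint"
    )
    return gene_trees, species_tree


@dataclass
class PlantedRecovery:
    precision: float
    recall: float
    n_calls: int
    n_events: int
    null_conflict_cells: int
    null_evaluable_cells: int


def planted_recovery(
    seed: int, n_replicates: int = 100, support_min: float = 95.0
) -> PlantedRecovery:
    """Recover planted hybridization events with the full pipeline.

    Precision counts a call as correct when it names the planted sample
    and locus with the donor among its hosts (tip transfers), or the
    planted species pair at the planted locus (merges).  The event-free
    control reruns identical conditions without events and counts
    conflict cells (which should be zero).
    """
    cfg = _planted_config(seed, with_events=True)
    alns, table, truth = simulate.make_dataset(cfg)
    gene_trees, species_tree = _infer_trees(alns, seed, n_replicates)

    calls = []
    for locus, gtree in gene_trees.items():
        calls.extend(
            concord.flag_hybrids(
                species_tree, gtree, table, locus, support_min=support_min
            )
        )

    def matches(event, call) -> bool:
        if isinstance(event, simulate.TipTransfer):
            return (
                call.evidence == concord.FOREIGN_NESTING
                and call.sample_id == event.sample_id
                and call.locus_name == event.locus
                and event.donor_species in call.host_species
            )
        return (
            call.evidence == concord.SPECIES_MERGE
            and call.locus_name == event.locus
            and {call.own_species, *call.host_species}
            == {event.species_a, event.species_b}
        )

    matched_calls = sum(
        1 for c in calls if any(matches(e, c) for e in cfg.events)
    )
    matched_events = sum(
        1 for e in cfg.events if any(matches(e, c) for c in calls)
    )
    precision = matched_calls / len(calls) if calls else 0.0
    recall = matched_events / len(cfg.events)

    null_cfg = _planted_config(seed, with_events=False)
    alns0, table0, _ = simulate.make_dataset(null_cfg)
    gene_trees0, species_tree0 = _infer_trees(alns0, seed + 1, n_replicates)
    matrix = concord.build_conflict_matrix(species_tree0, gene_trees0, table0)
    states = list(matrix.states.values())
    return PlantedRecovery(
        precision=precision,
        recall=recall,
        n_calls=len(calls),
        n_events=len(cfg.events),
        null_conflict_cells=states.count(concord.CONFLICT),
        null_evaluable_cells=states.count(concord.CONFLICT)
        + states.count(concord.NO_CONFLICT),
    )


def segregation_type1_rate(
    seed: int, trials: int = 10_000, n_spores: int = 20, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the exact 1:1 test under a true 1:1."""
    rng = np.random.default_rng(seed)
    p_by_k = {k: segregation_test(k, n_spores - k) for k in range(n_spores + 1)}
    ks = rng.binomial(n_spores, 0.5, size=trials)
    return float(np.mean([p_by_k[int(k)] < alpha for k in ks]))
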