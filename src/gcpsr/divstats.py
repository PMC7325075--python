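"""Per-locus and per-species alignment summary statistics.

Site classification (constant / singleton-variable / parsimony-informative /
other-variable) and nucleotide diversity (pi, the mean per-site proportion
of differences over all unordered sequence pairs, with pairwise deletion of
gaps and ambiguous bases).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from gcpsr.seqio import LocusAlignment, SampleTable

CONSTANT = "CONSTANT"
SINGLETON_VARIABLE = "SINGLETON_VARIABLE"
PARSIMONY_INFORMATIVE = "PARSIMONY_INFORMATIVE"
OTHER_VARIABLE = "OTHER_VARIABLE"

ALL_SAMPLES = "ALL_SAMPLES"

_BASES = np.array([b"A", b"C", b"G", b"T"])


def _base_counts(aln: LocusAlignment) -> np.ndarray:
    """(4, length) counts of unambiguous bases per column."""
    return np.stack([(aln.matrix == b).sum(axis=0) for b in _BASES])


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding, matching printed-table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SiteClassification:
    """Per-column categories for one alignment.

    Only unambiguous bases (A, C, G, T) enter the classification; gaps and
    N are excluded per column.  Categories are disjoint:

    * ``CONSTANT`` — at most one distinct base observed;
    * ``PARSIMONY_INFORMATIVE`` — >= 2 distinct bases, every observed base
      present in >= 2 sequences;
    * ``SINGLETON_VARIABLE`` — >= 2 distinct bases, every minority base
      present exactly once;
    * ``OTHER_VARIABLE`` — remaining variable columns (a minority base with
      count >= 2 alongside a singleton base).
    """

    categories: list[str]
    n_sites: int

    @property
    def counts(self) -> dict[str, int]:
        return {
            cat: self.categories.count(cat)
            for cat in (
                CONSTANT,
                SINGLETON_VARIABLE,
                PARSIMONY_INFORMATIVE,
                OTHER_VARIABLE,
            )
        }

    @property
    def n_variable(self) -> int:
        return self.n_sites - self.categories.count(CONSTANT)


def _classify_column(counts: np.ndarray) -> str:
    present = counts[counts > 0]
    if len(present) <= 1:
        return CONSTANT
    if (present >= 2).all():
        return PARSIMONY_INFORMATIVE
    # minority states = all but one maximal-count state
    minority = np.sort(present)[:-1]
    if (minority == 1).all():
        return SINGLETON_VARIABLE
    return OTHER_VARIABLE


def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Classify every column of the alignment.

    Raises ``ValueError`` for single-sequence alignments, where variability
    is undefined.
    """
    if aln.n_seqs < 2:
        raise ValueError("site classification requires >= 2 sequences")
    counts = _base_counts(aln)
    categories = [_classify_column(counts[:, j]) for j in range(aln.length)]
    return SiteClassification(categories, aln.length)


class PiEstimate(NamedTuple):
    pi: float
    n_pairs: int


def nucleotide_diversity(
    aln: LocusAlignment, sample_ids: Iterable[str] | None = None
) -> PiEstimate:
    """Nucleotide diversity over all unordered pairs of the selected rows.

    For each pair only columns where both sequences carry an unambiguous
    base are compared (pairwise deletion); the pair contributes its
    proportion of differing compared sites, and pi is the mean over pairs.
    A pair with zero comparable columns raises ``ValueError`` naming it.
    """
    sub = aln if sample_ids is None else aln.subset(sample_ids)
    if sub.n_seqs < 2:
        raise ValueError("nucleotide diversity requires >= 2 sequences")
    valid = np.isin(sub.matrix, _BASES)
    total = 0.0
    n_pairs = 0
    for i in range(sub.n_seqs):
        for j in range(i + 1, sub.n_seqs):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {sub.ids[i]} and {sub.ids[j]}"
                )
            diffs = int((both & (sub.matrix[i] != sub.matrix[j])).sum())
            total += diffs / comparable
            n_pairs += 1
    return PiEstimate(total / n_pairs, n_pairs)


@dataclass
class DiversitySummary:
    """Summary for one (locus, scope); scope is ALL_SAMPLES or a species id.

    ``pi`` is None when fewer than two sequences are available for the
    scope (not computable); ``pct_variable`` is the variable-site
    percentage rounded half-up to two decimals, matching printed-table
    formatting.
    """

    locus_name: str
    scope: str
    n_seqs: int
    n_sites: int
    n_variable: int | None
    n_parsimony_informative: int | None
    n_singleton: int | None
    pct_variable: float | None
    pi: float | None

    @staticmethod
    def percent_variable(n_variable: int, n_sites: int) -> float:
        return round_half_up(100.0 * n_variable / n_sites, 2)


def _summary_for(
    aln: LocusAlignment, scope: str, sample_ids: list[str]
) -> DiversitySummary:
    if len(sample_ids) < 2:
        return DiversitySummary(
            aln.locus_name, scope, len(sample_ids), aln.length,
            None, None, None, None, None,
        )
    sub = aln.subset(sample_ids)
    cls = classify_sites(sub)
    counts = cls.counts
    return DiversitySummary(
        aln.locus_name,
        scope,
        sub.n_seqs,
        sub.length,
        cls.n_variable,
        counts[PARSIMONY_INFORMATIVE],
        counts[SINGLETON_VARIABLE],
        DiversitySummary.percent_variable(cls.n_variable, sub.length),
        nucleotide_diversity(sub).pi,
    )


def summarize_locus(
    aln: LocusAlignment, table: SampleTable
) -> list[DiversitySummary]:
    """One ALL_SAMPLES summary plus one summary per species.

    Species are scoped to their amplified samples present in the alignment;
    species with fewer than two such samples are reported with pi marked
    not computable (None).  Alignment rows must all be known to the table.
    """
    unknown = [s for s in aln.ids if s not in set(table.sample_ids)]
    if unknown:
        raise ValueError(f"alignment samples absent from metadata: {unknown}")
    in_aln = set(aln.ids)
    summaries = [_summary_for(aln, ALL_SAMPLES, aln.ids)]
    for species in table.species_ids:
        members = [
            s
            for s in table.amplified_samples(species, aln.locus_name)
            if s in in_aln
        ]
        summaries.append(_summary_for(aln, species, members))
    return summaries


def write_diversity_report(
    summaries: Iterable[DiversitySummary], path: str | Path
) -> None:
    """TSV report: one row per (locus, scope)."""
    cols = [
        "locus", "scope", "n_seqs", "n_sites", "n_variable",
        "pct_variable", "n_PI", "n_singleton", "pi",
    ]

    def fmt(v: object) -> str:
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.4f}".rstrip("0").rstrip(".") if v else "0"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            pi = "NA" if s.pi is None else f"{s.pi:.4f}"
            pct = "NA" if s.pct_variable is None else f"{s.pct_variable:.2f}"
            fh.write(
                "\t".join(
                    [
                        s.locus_name, s.scope, str(s.n_seqs), str(s.n_sites),
                        fmt(s.n_variable), pct,
                        fmt(s.n_parsimony_informative), fmt(s.n_singleton), pi,
                    ]
                )
                + "\n"
            )
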