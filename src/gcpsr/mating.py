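"""Mating-type idiomorph calling, 1:1 segregation testing, and
reproductive-mode classification.

In heterothallic ascomycetes each haploid individual carries exactly one
of two idiomorphs (MAT1-1 vs MAT1-2) at the mating-type locus, and the two
types segregate 1:1 among single-ascospore isolates.  A single spore
carrying both idiomorphs instead indicates secondary homothallism.  The
two idiomorphs amplify at characteristically different lengths (708 bp
for MAT1-1-1, 869-880 bp for MAT1-2-1), so a gel-based length read
suffices for calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binom

MAT1_1_ONLY = "MAT1_1_ONLY"
MAT1_2_ONLY = "MAT1_2_ONLY"
BOTH = "BOTH"
NONE = "NONE"

HETEROTHALLIC = "HETEROTHALLIC"
PUTATIVE_SECONDARY_HOMOTHALLIC = "PUTATIVE_SECONDARY_HOMOTHALLIC"
PRESUMED_HETEROTHALLIC = "PRESUMED_HETEROTHALLIC"
INDETERMINATE = "INDETERMINATE"

#: Expected amplicon lengths (bp).
MAT11_LENGTH = 708
MAT12_RANGE = (869, 880)


@dataclass
class IdiomorphCall:
    """Mating-type call for one isolate from its amplicon evidence."""

    isolate_id: str
    call: str  # MAT1_1_ONLY | MAT1_2_ONLY | BOTH | NONE
    evidence: tuple = field(default_factory=tuple)


def call_idiomorph(
    isolate_id: str,
    amplicons: Sequence[tuple[str, int]],
    tol: int = 15,
) -> IdiomorphCall:
    """Call the idiomorph(s) of an isolate from amplicon lengths.

    A length within ``708 +/- tol`` is MAT1-1 evidence; within
    ``[869 - tol, 880 + tol]`` MAT1-2 evidence.  The default 15 bp
    tolerance reflects gel-based length reading and keeps the two windows
    disjoint; a length falling in both windows (impossible at the default)
    raises.
    """
    lo11, hi11 = MAT11_LENGTH - tol, MAT11_LENGTH + tol
    lo12, hi12 = MAT12_RANGE[0] - tol, MAT12_RANGE[1] + tol
    has11 = has12 = False
    for assay, length in amplicons:
        if length <= 0:
            raise ValueError(f"non-positive amplicon length {length}")
        in11 = lo11 <= length <= hi11
        in12 = lo12 <= length <= hi12
        if in11 and in12:
            raise ValueError(
                f"amplicon length {length} matches both idiomorph windows "
                f"(tol={tol}); windows must not overlap"
            )
        has11 |= in11
        has12 |= in12
    if has11 and has12:
        call = BOTH
    elif has11:
        call = MAT1_1_ONLY
    elif has12:
        call = MAT1_2_ONLY
    else:
        call = NONE
    return IdiomorphCall(isolate_id, call, tuple(amplicons))


def segregation_test(n11: int, n12: int) -> float:
    """Exact two-sided binomial test of a 1:1 idiomorph ratio.

    P(|X - n/2| >= |n11 - n/2|) with X ~ Binomial(n, 1/2), by direct
    summation of the point probabilities.
    """
    if n11 < 0 or n12 < 0:
        raise ValueError("counts must be non-negative")
    n = n11 + n12
    if n < 1:
        raise ValueError("need at least one spore")
    dev = abs(n11 - n / 2.0)
    k = range(n + 1)
    pmf = binom.pmf(list(k), n, 0.5)
    p = float(sum(pmf[i] for i in k if abs(i - n / 2.0) >= dev - 1e-12))
    return min(p, 1.0)


@dataclass
class SegregationResult:
    """Per-species segregation counts, p-value and reproductive-mode call."""

    species_id: str
    n_mat11: int
    n_mat12: int
    p_value: float | None
    mode_call: str
    reason: str = ""


def classify_reproductive_mode(
    species_id: str,
    strain_calls: Iterable[IdiomorphCall],
    spore_calls: Iterable[IdiomorphCall],
    alpha: float = 0.05,
) -> SegregationResult:
    """Classify a species' reproductive mode from parent-tissue and
    single-ascospore idiomorph calls.

    Any spore carrying both idiomorphs -> PUTATIVE_SECONDARY_HOMOTHALLIC.
    Spores all single-type with both types present and a segregation ratio
    consistent with 1:1 (p >= alpha) -> HETEROTHALLIC.  No spores but
    parent tissue carrying both idiomorphs -> PRESUMED_HETEROTHALLIC (the
    handling for species from which no ascospores could be obtained).
    Anything else -> INDETERMINATE with a reason.
    """
    strains = list(strain_calls)
    spores = list(spore_calls)
    if not strains and not spores:
        raise ValueError("no idiomorph calls given")

    n11 = sum(1 for c in spores if c.call == MAT1_1_ONLY)
    n12 = sum(1 for c in spores if c.call == MAT1_2_ONLY)

    if any(c.call == BOTH for c in spores):
        return SegregationResult(
            species_id, n11, n12, None, PUTATIVE_SECONDARY_HOMOTHALLIC,
            "at least one single spore carries both idiomorphs",
        )
    if spores:
        if n11 == 0 or n12 == 0:
            return SegregationResult(
                species_id, n11, n12,
                segregation_test(n11, n12) if n11 + n12 else None,
                INDETERMINATE,
                "only one mating type among single spores",
            )
        p = segregation_test(n11, n12)
        if p >= alpha:
            return SegregationResult(species_id, n11, n12, p, HETEROTHALLIC)
        return SegregationResult(
            species_id, n11, n12, p, INDETERMINATE,
            f"segregation deviates from 1:1 (p = {p:.4g} < {alpha})",
        )
    if any(c.call == BOTH for c in strains):
        return SegregationResult(
            species_id, 0, 0, None, PRESUMED_HETEROTHALLIC,
            "no spores; both idiomorphs present in parent tissue",
        )
    return SegregationResult(
        species_id, 0, 0, None, INDETERMINATE,
        "no spores and parent tissue lacks one or both idiomorphs",
    )
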