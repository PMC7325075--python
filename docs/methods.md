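# Methods

`gcpsr` implements a multilocus genealogical-concordance workflow for
species recognition in fungi (GCPSR): per-locus diversity statistics,
distance-based gene-tree construction with nonparametric bootstrap,
per-species monophyly scoring against a species phylogeny, sample-level
hybrid flagging, and mating-type segregation analysis.  This note records
the models, conventions, numerical choices and known limitations.

## Diversity statistics

Nucleotide diversity is the mean, over all unordered sequence pairs, of
the proportion of differing sites among the sites where both sequences
carry an unambiguous base (pairwise deletion of gaps and N, the
DnaSP-style convention; robust to ragged amplicon ends).  No multiple-hit
correction is applied to the reported values — the magnitudes involved
(about 0.02 between species) make the correction negligible and raw
values match how such surveys typically report the statistic.  A pair
with no comparable columns is an error naming the pair rather than a
silent NaN.

Site classification excludes gaps and N per column and uses four
disjoint categories: constant (at most one base observed);
parsimony-informative (at least two bases, each observed base in at least
two sequences); singleton-variable (every minority base exactly once);
other-variable (the remainder: a repeated minority base alongside a
singleton, e.g. the column pattern A,A,T,T,C).  This carving is stricter
than the classical PAUP definition of parsimony-informative (which would
accept A,A,T,T,C); it was chosen so the three variable categories are
disjoint, exhaustive, and individually testable.  The reported
variable-site count is unaffected by the choice.

Variable-site percentages are rounded half-up to two decimals and
conflict percentages half-up to one decimal, matching how the survey
tables print them.  One published value cannot be reproduced by any
formatting rule: 100·158/827 = 19.1052, which every nearest-rounding rule
renders 19.11, while the survey prints 19.10 (its companion value
100·120/654 = 18.3486 → 18.35 rules out truncation).  The package
reports 19.11; the discrepancy is a one-unit-in-the-last-digit
inconsistency internal to the published numbers.

## Trees

The native builder is Saitou–Nei neighbor-joining on raw p-distances
(optionally Jukes–Cantor corrected; saturated pairs with p ≥ 0.75 raise
an error naming the pair).  Raw distances are the default: at the
within-genus divergences this package targets, the correction changes
distances by well under 1% while saturating pairs in bootstrap
pseudo-replicates of noisy data would abort replicates needlessly.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sister edge; all argmin ties break lexicographically by the smallest
leaf label in each cluster, so trees are deterministic functions of the
distance matrix.  Trees built by other programs (e.g. ML searches) can be
imported from newick, with internal node labels read as bootstrap
percentages, and flow through the same downstream analyses — the
concordance layer is tree-source-agnostic.

Bootstrap support resamples alignment columns with replacement (seeded
generator; bit-reproducible), rebuilds NJ per replicate, and maps the
frequency of each internal bipartition of the full-data tree.  Replicates
with degenerate distances are skipped with a logged warning and the
denominator adjusted.  The conventional display threshold is 70%;
defaults are 1000 replicates with a mandatory seed.

Parsimony tree length uses Fitch small parsimony over the five-state set
{A, C, G, T, gap} — gaps are a fifth character — with N as missing data
(the union state, never forcing a step).  Unrooted basal trifurcations
are rooted along a terminal edge before scoring, which leaves the
parsimony length unchanged; genuine multifurcations fold children
sequentially.

Rooting is by outgroup (root on the edge separating the outgroup from
the rest, splitting that branch length evenly) or by midpoint.  A
non-monophyletic outgroup roots on the edge maximizing outgroup/ingroup
separation, with a warning.  Supports are carried across rerooting by
bipartition identity, not node identity.

## Conflict scoring

The unit of inference is the species: a (species, locus) cell is a
CONFLICT exactly when the species' amplified samples fail to form a clade
in that gene genealogy while forming one in the species phylogeny.  A
differing *placement* of an intact monophyletic species is not a
conflict.  Species with one amplified sample (SINGLE_SAMPLE) or none
(NO_DATA) at a locus are excluded from that locus's percentage, whose
denominator is the CONFLICT + NO_CONFLICT count only.

The transcribed published state table (`gcpsr.datasets`) reproduces the
survey's printed totals for MAT1-1-1 (6/20 = 30.0%), MAT1-2-1
(7/20 = 35.0%) and IGS (13/16 = 81.25 → 81.3%).  The printed F1 total
(66.7%) does not follow from the printed F1 states under any obvious
denominator (a strict tally gives 11/17 = 64.7%), and the survey's
narrative describes a species merge in a genealogy whose cell is printed
as no-conflict; the package computes percentages from state matrices
exactly and does not special-case this column.

## Hybrid flagging

Two discordance patterns are called, both requiring bootstrap support at
or above a threshold (default 95%, following the convention that only
very strongly supported foreign placements justify a hybrid hypothesis):

* **Foreign nesting** — sample *s* of species X when some clade with
  support ≥ 95 contains *s* as its only X member, with every other
  member from other species, and pruning *s* would restore the monophyly
  of X and of every host species.  The restoration requirement
  disambiguates the intruding sample from the host-side samples it nests
  among (without it, a host sample adjacent to the intruder could be
  flagged symmetrically).  Hosts are named from the smallest clade in
  which *s* is the only X member — clades containing a fixed leaf are
  nested, so this is well defined; a clade mixing several host species
  yields a single call listing them all.
* **Species merge** — species pair (X, Y) when the union of their
  samples is a clade with support ≥ 95 and no clade with support ≥ 70
  equals either species alone.  "Neither species separately supported"
  rather than "neither topologically monophyletic" is deliberate: inside
  a merged clade of near-identical sequences the estimated topology is
  arbitrary, and a chance zero-length resolution of one species must not
  defeat detection, while an ordinary well-supported sister pair is
  excluded by its own within-pair resolution.

Pairwise genealogy comparison restricts both trees to their common
leaves, collects bipartitions supported at ≥ 70% in each, and reports
incompatible pairs (two splits conflict when all four side intersections
are non-empty).

## Mating types

Idiomorph calls use amplicon length windows: 708 ± 15 bp for MAT1-1-1
and [869 − 15, 880 + 15] bp for MAT1-2-1, reflecting gel-based length
reading; the tolerance is configurable but must keep the windows
disjoint.  Segregation against 1:1 uses the exact two-sided binomial
test, P(|X − n/2| ≥ |observed − n/2|) with X ~ Binomial(n, ½) by direct
summation — exact rather than chi-square because spore counts are small
(n ≈ 20), and the tail-distance definition of two-sided is stated
explicitly to avoid cross-ecosystem ambiguity (at p = ½ it coincides
with the minimum-likelihood definition).  Reproductive-mode calls: any
spore with both idiomorphs → putative secondary homothallism; spores all
single-type, both types present, p ≥ α → heterothallic; no spores but
parent tissue carrying both idiomorphs → presumed heterothallic;
otherwise indeterminate with a reason.

## Synthetic data

The generator emulates the statistical shape of a 22-species survey: a
Yule-topology ultrametric species tree scaled to a root-to-tip height in
expected substitutions/site (default 0.02, giving between-species
diversity near 0.02–0.03); within-species subtrees of relative depth
0.02 (keeping within-species diversity an order of magnitude lower, as
observed); HKY85 substitution (κ = 2 by default — the minimal model with
a transition/transversion knob; the analysis layer never assumes the
generating model); per-(sample, locus) Bernoulli dropout; and planted
events that operate on gene-tree topology, giving exact ground truth:

* a **tip transfer** moves one sample, at one locus, onto the donor
  species' stem as sister to the donor crown — the recipient species
  stops being monophyletic there, the donor does not;
* a **clade merge** replaces two species' subtrees at one locus with a
  single caterpillar alternating their samples, so neither is
  monophyletic while their union is.

Internal choices, documented as such rather than scientific claims:
split depths follow the expected-waiting-time (harmonic) profile of the
Yule process instead of sampled exponentials, and within-species join
depths are evenly spaced — both keep trees ultrametric and byte-level
deterministic under the config seed while leaving the Yule topology
distribution intact.  `species_depth_fraction` compresses all speciation
into the top fraction of the height; the planted-event validation uses
0.5 at height 0.05 so every between-species divergence is at least 0.05
substitutions/site (a strong-signal radiation), while the survey preset
keeps the natural profile, under which recently diverged sister pairs —
a real feature of the emulated system — may be only weakly separated.

The survey preset uses 22 species with 1–9 samples (83 in total), four
loci at 654/827/755/909 aligned sites, full amplification success at the
two mating-type loci and dropout rates of 14/83 and 15/83 at the two
non-reproductive loci, mirroring the published sampling design.

What the generator does **not** emulate: indels (alignments are gap-free;
gap handling is exercised by hand-built fixtures), rate variation across
sites or loci, coalescent-with-migration gene flow (events are
topological grafts), base-composition heterogeneity, and sequencing
error.  Passing the planted-event tests therefore demonstrates that the
inference chain recovers topological signals of the planted kind at
realistic divergences — not that it would be equally powered against
incomplete lineage sorting or low-support introgression in real data.

## Validation experiment sizes

The planted-recovery experiment runs 8 species × 4 samples, four 800-site
loci, 100 bootstrap replicates, two tip transfers and one merge, plus an
event-free control under identical conditions; it completes in well under
a minute.  The segregation type-I experiment draws 10,000 species of 20
spores at a true 1:1 ratio.  Diversity calibration is checked over six
generator seeds of the full survey preset.

## Known limitations

* No ML or MP heuristic tree search: NJ with bootstrap is the native
  builder, and externally built trees are first-class imports.  Support
  thresholds tuned for ML/MP bootstrap values are applied unchanged to NJ
  bootstrap values.
* Monophyly scoring is purely topological; very short internal edges can
  flip cells between CONFLICT and NO_CONFLICT on weak data (the
  bootstrap values are reported but deliberately not used to filter the
  matrix, matching how such tables are conventionally scored).
* The hybrid rules detect single-sample foreign nesting and two-species
  merges; a jointly transferred pair of samples, or a three-species
  merge, would need the rules' natural generalizations.
* No formal network inference or ILS-vs-hybridization model testing; the
  calls are descriptive flags, not likelihood-based hypothesis tests.
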