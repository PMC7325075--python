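"""Input/output for the formats the pipeline touches.

Three kinds of objects come in from disk: per-locus FASTA alignments
(:class:`LocusAlignment`), the sample metadata table mapping samples to
species and recording per-locus amplification status (:class:`SampleTable`),
and newick trees whose internal node labels carry bootstrap support
percentages (read into :class:`dendropy.Tree` with a float ``support``
attribute on internal nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Allowed residue states.  Anything else on input is mapped to N.
ALPHABET = ("A", "C", "G", "T", "N", "-")

AMPLIFIED = "AMPLIFIED"
FAILED = "FAILED"


class UnalignedInputError(ValueError):
    """Rows of a FASTA file meant to be an alignment have unequal lengths."""


@dataclass
class LocusAlignment:
    """An aligned set of sequences for a single locus.

    Parameters
    ----------
    locus_name:
        Identifier of the locus (e.g. ``"MAT1-1-1"``).
    ids:
        Sample identifiers, one per row, unique, order preserved.
    matrix:
        ``(n_seqs, length)`` array of single-character byte strings over
        ``{A,C,G,T,N,-}`` (uppercase).
    """

    locus_name: str
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of sample ids")
        if self.matrix.shape[1] < 1:
            raise ValueError("alignment must have at least one column")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({s for s in self.ids if self.ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids in alignment: {dupes}")
        allowed = {c.encode() for c in ALPHABET}
        present = set(np.unique(self.matrix).tolist())
        if not present <= allowed:
            bad = sorted(b.decode() for b in present - allowed)
            raise ValueError(f"characters outside alphabet: {bad}")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        """Number of columns (sites)."""
        return self.matrix.shape[1]

    @property
    def rows(self) -> dict[str, str]:
        """Ordered mapping sample id -> sequence string."""
        return {
            sid: self.matrix[i].tobytes().decode()
            for i, sid in enumerate(self.ids)
        }

    def sequence(self, sample_id: str) -> str:
        return self.matrix[self.ids.index(sample_id)].tobytes().decode()

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        """Row subset in the requested order; unknown ids raise KeyError."""
        wanted = list(sample_ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment {self.locus_name}: {missing}")
        rows = [index[s] for s in wanted]
        return LocusAlignment(self.locus_name, wanted, self.matrix[rows])

    @classmethod
    def from_dict(
        cls, locus_name: str, rows: Mapping[str, str]
    ) -> "LocusAlignment":
        ids = list(rows)
        seqs = [rows[s] for s in ids]
        return cls(locus_name, ids, _to_matrix(seqs, locus_name))


def _to_matrix(seqs: list[str], locus_name: str) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise UnalignedInputError(
            f"unaligned input for locus {locus_name}: "
            f"row lengths {sorted(lengths)}"
        )
    arr = np.array([list(s.upper()) for s in seqs], dtype="S1")
    allowed = np.isin(arr, [c.encode() for c in ALPHABET])
    if not allowed.all():
        bad = sorted(set(arr[~allowed].tolist()))
        logger.warning(
            "locus %s: %d characters outside {A,C,G,T,N,-} mapped to N (%s)",
            locus_name,
            int((~allowed).sum()),
            ",".join(b.decode() for b in bad),
        )
        arr = np.where(allowed, arr, b"N")
    return arr


def read_alignment(path: str | Path, locus_name: str) -> LocusAlignment:
    """Read an aligned FASTA file into a validated :class:`LocusAlignment`.

    Characters outside the alphabet (IUPAC ambiguity codes etc.) are mapped
    to ``N`` with a logged warning.  Unequal row lengths raise
    :class:`UnalignedInputError`; duplicate record ids raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate record ids in {path}: {dupes}")
    matrix = _to_matrix([str(r.seq) for r in records], locus_name)
    return LocusAlignment(locus_name, ids, matrix)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.rows.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# sample metadata


@dataclass
class SampleTable:
    """Sample -> species mapping plus per-locus amplification status.

    ``locus_status[sample_id][locus]`` is ``"AMPLIFIED"`` or ``"FAILED"``;
    a failed cell corresponds to a sample for which no amplicon of that
    locus could be obtained (the published tables mark these with a cross),
    and is kept as an explicit state so that per-species bookkeeping of
    no-data and single-sample cells stays computable downstream.
    """

    frame: pd.DataFrame  # index sample_id; columns species_id, voucher
    locus_status: dict[str, dict[str, str]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = sorted(self.frame.index[self.frame.index.duplicated()])
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.frame["species_id"].isna().any() or (
            self.frame["species_id"].astype(str).str.strip() == ""
        ).any():
            bad = sorted(
                self.frame.index[
                    self.frame["species_id"].isna()
                    | (self.frame["species_id"].astype(str).str.strip() == "")
                ]
            )
            raise ValueError(f"missing species_id for samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def species_ids(self) -> list[str]:
        """Species in first-appearance order."""
        seen: dict[str, None] = {}
        for sp in self.frame["species_id"]:
            seen.setdefault(sp, None)
        return list(seen)

    @property
    def loci(self) -> list[str]:
        first = next(iter(self.locus_status.values()), {})
        return list(first)

    def species_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "species_id"])

    def samples_of(self, species_id: str) -> list[str]:
        return list(self.frame.index[self.frame["species_id"] == species_id])

    def amplified_samples(self, species_id: str, locus: str) -> list[str]:
        return [
            s
            for s in self.samples_of(species_id)
            if self.locus_status[s].get(locus) == AMPLIFIED
        ]

    def status(self, sample_id: str, locus: str) -> str:
        return self.locus_status[sample_id][locus]


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the sample metadata TSV.

    Expected columns: ``sample_id``, ``species_id``, ``voucher``, then one
    column per locus holding ``1`` (amplified) or ``0`` (failed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species_id", "voucher"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    loci = [c for c in df.columns if c not in required]
    df = df.set_index("sample_id")
    status: dict[str, dict[str, str]] = {}
    for sid, row in df.iterrows():
        per_locus = {}
        for locus in loci:
            val = str(row[locus]).strip()
            if val not in {"0", "1"}:
                raise ValueError(
                    f"bad amplification flag {val!r} for sample {sid}, "
                    f"locus {locus} (expected 0 or 1)"
                )
            per_locus[locus] = AMPLIFIED if val == "1" else FAILED
        status[str(sid)] = per_locus
    return SampleTable(df[["species_id", "voucher"]], status)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    loci = table.loci
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "species_id", "voucher"] + loci) + "\n")
    df = table.frame.copy()
    for locus in loci:
        df[locus] = [
            "1" if table.locus_status[s][locus] == AMPLIFIED else "0"
            for s in df.index
        ]
    df.to_csv(path, sep="\t", mode="a", header=False)


# ---------------------------------------------------------------------------
# newick trees


def read_newick(
    path_or_string: str | Path, *, labels_are_support: bool = True
) -> dendropy.Tree:
    """Parse a newick tree; internal node labels become support percentages.

    With ``labels_are_support=True`` (the default, matching common RAxML
    output) every internal node label must parse as a number in [0, 100]
    and is stored as ``node.support`` (float).  With ``False`` labels are
    kept verbatim as clade names.
    """
    src = str(path_or_string)
    if "(" in src:  # a newick string rather than a path
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        if labels_are_support:
            try:
                support = float(node.label)
            except ValueError as exc:
                raise ValueError(
                    f"internal node label {node.label!r} is not a support value"
                ) from exc
            if not 0.0 <= support <= 100.0:
                raise ValueError(
                    f"support {support} outside [0, 100] in {path_or_string}"
                )
            node.support = support
            node.label = None
    return tree


def _format_support(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else f"{value:g}"


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree, supports as internal node labels.

    Returns the newick string; also writes it to ``path`` when given.
    Round-trip through :func:`read_newick` preserves topology, branch
    lengths and supports.
    """
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        support = getattr(node, "support", None)
        if not node.is_leaf() and support is not None:
            node.label = _format_support(support)
    text = clone.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
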