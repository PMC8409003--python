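"""Reference multiple-sequence-alignment handling.

An aligned set of complete mitochondrial genomes is ingested as a
rectangular character matrix with a designated rCRS (revised Cambridge
Reference Sequence) row.  Projection onto rCRS coordinates drops every
column in which the rCRS carries a gap, so that column *i* of the
projected alignment is rCRS position *i* (1-based) and the standard
mtDNA site-numbering convention is preserved.  Gaps in non-rCRS rows are
retained.  Sequence-level quality control removes rows with too many
ambiguous characters or too many gaps; the rCRS row is exempt because it
is a coordinate anchor, not a population sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Characters that count as fully specified nucleotide states.
UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"

DEFAULT_AMBIGUOUS_THRESHOLD = 5
DEFAULT_GAP_THRESHOLD = 8


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass
class ReferenceAlignment:
    """Rectangular alignment with a designated rCRS reference row.

    Attributes
    ----------
    sequence_ids : list of str
        Unique row labels.
    matrix : ndarray of shape (n_sequences, n_columns), dtype '<U1'
        Upper-case characters over {A, C, G, T, IUPAC codes, N, -}.
    rcrs_id : str
        Label of the reference (rCRS) row.
    column_positions : ndarray or None
        1-based rCRS position of each column; set by
        :func:`project_to_rcrs` (strictly increasing, starting at 1).
    """

    sequence_ids: list[str]
    matrix: np.ndarray
    rcrs_id: str
    column_positions: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.sequence_ids) != self.matrix.shape[0]:
            raise AlignmentError("sequence_ids and matrix row count differ")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        if self.rcrs_id not in self.sequence_ids:
            raise AlignmentError(f"rCRS id {self.rcrs_id!r} not in alignment")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def rcrs_index(self) -> int:
        return self.sequence_ids.index(self.rcrs_id)

    @property
    def rcrs_row(self) -> np.ndarray:
        return self.matrix[self.rcrs_index]

    def row(self, sequence_id: str) -> np.ndarray:
        return self.matrix[self.sequence_ids.index(sequence_id)]

    def is_projected(self) -> bool:
        return self.column_positions is not None

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.sequence_ids, self.matrix):
                fh.write(f">{sid}\n")
                seq = "".join(row)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class SequenceQCReport:
    """Per-sequence ambiguity/gap counts and removal flags.

    ``table`` has one row per input sequence with columns
    ``sequence_id``, ``n_ambiguous``, ``n_gaps``, ``removed``.
    """

    table: pd.DataFrame
    ambiguous_threshold: int
    gap_threshold: int

    @property
    def removed_ids(self) -> list[str]:
        return list(self.table.loc[self.table["removed"], "sequence_id"])

    @property
    def n_removed(self) -> int:
        return int(self.table["removed"].sum())


def read_msa(fasta_source, rcrs_id: str) -> ReferenceAlignment:
    """Read an aligned FASTA file into a :class:`ReferenceAlignment`.

    Characters are upper-cased and ``.`` is normalised to ``-``.  All
    records must have equal length and unique ids, and ``rcrs_id`` must
    name one of them.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    if not rows:
        raise AlignmentError("no sequences found in FASTA input")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths in alignment: {sorted(lengths)}")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate sequence ids: {dupes}")
    if rcrs_id not in ids:
        raise AlignmentError(f"rCRS id {rcrs_id!r} not found among {len(ids)} records")
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return ReferenceAlignment(sequence_ids=ids, matrix=matrix, rcrs_id=rcrs_id)


def project_to_rcrs(aln: ReferenceAlignment) -> ReferenceAlignment:
    """Drop every column where the rCRS row holds a gap.

    Insertion columns relative to the rCRS are discarded so that the
    projected alignment uses rCRS coordinates 1..L; gaps in all other
    rows are retained.  Idempotent.
    """
    keep = aln.rcrs_row != GAP
    if not keep.any():
        raise AlignmentError("rCRS row is entirely gaps; cannot project")
    matrix = aln.matrix[:, keep]
    positions = np.arange(1, matrix.shape[1] + 1, dtype=np.int64)
    return ReferenceAlignment(
        sequence_ids=list(aln.sequence_ids),
        matrix=matrix,
        rcrs_id=aln.rcrs_id,
        column_positions=positions,
    )


def qc_filter(
    aln: ReferenceAlignment,
    ambiguous_threshold: int = DEFAULT_AMBIGUOUS_THRESHOLD,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> tuple[ReferenceAlignment, SequenceQCReport]:
    """Remove sequences with too many ambiguous characters or gaps.

    A sequence is removed iff it has ``>= ambiguous_threshold``
    ambiguous characters (anything outside {A, C, G, T, -}) or
    ``>= gap_threshold`` gap characters.  The rCRS row is never removed.
    """
    if ambiguous_threshold < 1 or gap_threshold < 1:
        raise ValueError("QC thresholds must be >= 1")
    is_gap = aln.matrix == GAP
    is_specified = np.isin(aln.matrix, sorted(UNAMBIGUOUS))
    n_gaps = is_gap.sum(axis=1)
    n_ambiguous = (~is_gap & ~is_specified).sum(axis=1)
    removed = (n_ambiguous >= ambiguous_threshold) | (n_gaps >= gap_threshold)
    removed[aln.rcrs_index] = False
    report = SequenceQCReport(
        table=pd.DataFrame(
            {
                "sequence_id": aln.sequence_ids,
                "n_ambiguous": n_ambiguous,
                "n_gaps": n_gaps,
                "removed": removed,
            }
        ),
        ambiguous_threshold=ambiguous_threshold,
        gap_threshold=gap_threshold,
    )
    keep = ~removed
    filtered = replace(
        aln,
        sequence_ids=[s for s, k in zip(aln.sequence_ids, keep) if k],
        matrix=aln.matrix[keep],
    )
    return filtered, report
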