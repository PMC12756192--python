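"""Global pairwise alignment and percent identity — the sequence baseline.

Percent identity is the fraction of identical amino-acid positions in the
aligned sequences.  Alignments are optimal global (Needleman-Wunsch, affine
gaps) alignments computed with Biopython's ``PairwiseAligner`` under
EMBOSS-needle-style defaults: BLOSUM62, gap open 10, gap extend 0.5, end
gaps free.  All parameters are exposed via :class:`AlignmentParams`.

Denominator convention: by default identity divides by the full alignment
length including gap columns; dividing by non-gap columns only is available
via ``denominator="nongap"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "IdentityRecord",
    "global_align",
    "percent_identity",
    "pairwise_identity",
    "identity_table",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment parameters (EMBOSS-needle-style defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.penalize_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _prepare(seq: str, alphabet: str) -> str:
    """Uppercase and map residues absent from the matrix (e.g. U, O) to X."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return "".join(c if c in alphabet else "X" for c in seq)


def global_align(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> tuple[str, str, float]:
    """Optimal global alignment; returns (gapped_a, gapped_b, score).

    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic for fixed inputs.
    """
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    a = _prepare(seq_a, alphabet)
    b = _prepare(seq_b, alphabet)
    alignment = aligner.align(a, b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    return gapped_a, gapped_b, float(alignment.score)


@dataclass(frozen=True)
class IdentityRecord:
    """Identity of one aligned pair: n_identical / n_columns."""

    id_a: str
    id_b: str
    identity: float
    n_identical: int
    n_columns: int

    @property
    def percent(self) -> float:
        return 100.0 * self.identity


def percent_identity(
    gapped_a: str,
    gapped_b: str,
    *,
    id_a: str = "A",
    id_b: str = "B",
    denominator: str = "alignment",
) -> IdentityRecord:
    """Fraction of identical positions in an alignment.

    A column counts as identical only when both symbols are equal and
    neither is a gap.  ``denominator="alignment"`` divides by the full
    alignment length including gap columns; ``"nongap"`` divides by the
    columns where both sequences have a residue.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings must have equal length")
    if len(gapped_a) == 0:
        raise ValueError("empty alignment")
    n_identical = sum(
        1 for x, y in zip(gapped_a, gapped_b) if x == y and x != GAP
    )
    if denominator == "alignment":
        n_columns = len(gapped_a)
    elif denominator == "nongap":
        n_columns = sum(1 for x, y in zip(gapped_a, gapped_b) if x != GAP and y != GAP)
        if n_columns == 0:
            raise ValueError("alignment has no residue-residue columns")
    else:
        raise ValueError("denominator must be 'alignment' or 'nongap'")
    return IdentityRecord(
        id_a=id_a,
        id_b=id_b,
        identity=n_identical / n_columns,
        n_identical=n_identical,
        n_columns=n_columns,
    )


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams = AlignmentParams(),
    *,
    id_a: str = "A",
    id_b: str = "B",
    denominator: str = "alignment",
) -> IdentityRecord:
    """Align two sequences and return their identity record.

    The pair is aligned in a canonical order (lexicographic by sequence) so
    the result is symmetric in (a, b) regardless of tie-breaking inside the
    aligner.
    """
    if seq_a <= seq_b:
        ga, gb, _ = global_align(seq_a, seq_b, params)
    else:
        gb, ga, _ = global_align(seq_b, seq_a, params)
    return percent_identity(ga, gb, id_a=id_a, id_b=id_b, denominator=denominator)


def identity_table(
    sequences: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    *,
    denominator: str = "alignment",
) -> pd.DataFrame:
    """Identity records for a list of id pairs, as a DataFrame (percent scale)."""
    rows = []
    for id_a, id_b in pairs:
        rec = pairwise_identity(
            sequences[id_a], sequences[id_b], params, id_a=id_a, id_b=id_b,
            denominator=denominator,
        )
        rows.append(
            {
                "id_a": rec.id_a,
                "id_b": rec.id_b,
                "identity_pct": rec.percent,
                "n_identical": rec.n_identical,
                "n_columns": rec.n_columns,
            }
        )
    return pd.DataFrame(rows)


def write_identity_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
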