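"""Pairwise and center-star multiple alignment with affine gap penalties.

Global (Needleman–Wunsch/Gotoh) and local (Smith–Waterman) alignment are
delegated to :class:`Bio.Align.PairwiseAligner`; this module fixes the
scoring conventions, extracts percent identity / similarity / coverage the
way the rest of the pipeline expects them, and builds a center-star
multiple alignment for distance estimation and bootstrapping.

Scoring convention: a gap run of length L costs
``gap_open + (L - 1) * gap_extend``; terminal gaps are penalised in global
mode. Percent identity and similarity use the full alignment length (gap
columns included) as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

from .seqio import SeqRecord, SequenceError


class AlignmentError(ValueError):
    """Raised on invalid alignment input (alphabet mismatch, empty seqs)."""


def _dna_matrix(match: float = 5.0, mismatch: float = -4.0):
    """Nucleotide scoring matrix over ACGTN; N is neutral (score 0)."""
    alphabet = "ACGTN"
    mat = _submat.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == "N" or y == "N":
                mat[x, y] = 0.0
            else:
                mat[x, y] = match if x == y else mismatch
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both non-negative)."""

    matrix: object
    gap_open: float = 10.0
    gap_extend: float = 0.5
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise AlignmentError("gap_extend must not exceed gap_open")

    def pair_score(self, x: str, y: str) -> float:
        return float(self.matrix[x, y])


def default_scheme(alphabet: str = "protein") -> ScoringScheme:
    """BLOSUM62 with gap open 10 / extend 0.5 for protein; +5/−4 with the
    same gap costs for DNA."""
    if alphabet == "protein":
        return ScoringScheme(_submat.load("BLOSUM62"), 10.0, 0.5, "protein")
    if alphabet == "dna":
        return ScoringScheme(_dna_matrix(), 10.0, 0.5, "dna")
    raise AlignmentError(f"no default scheme for alphabet {alphabet!r}")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows plus the derived alignment statistics.

    For global alignments, ungapping each row recovers the full input
    sequence; for local alignments the rows cover only the best-scoring
    segment pair (segment offsets in ``start_a``/``start_b``, 0-based).
    """

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float
    identity_pct: float
    similarity_pct: Optional[float]
    coverage_a_pct: float
    coverage_b_pct: float
    start_a: int = 0
    start_b: int = 0

    @property
    def ncol(self) -> int:
        return len(self.row_a)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over an ordered id list."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("MSA rows have unequal lengths")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _make_aligner(scheme: ScoringScheme, mode: str) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _check_pair(a: SeqRecord, b: SeqRecord) -> None:
    if a.alphabet != b.alphabet:
        raise AlignmentError(
            f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}"
        )
    if not a.residues or not b.residues:
        raise AlignmentError("cannot align an empty sequence")


def _column_stats(row_a: str, row_b: str, scheme: ScoringScheme):
    ncol = len(row_a)
    ident = 0
    similar = 0
    paired = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        paired += 1
        if x == y:
            ident += 1
        if scheme.pair_score(x, y) > 0:
            similar += 1
    return ncol, ident, similar, paired


def _build_alignment(
    a: SeqRecord,
    b: SeqRecord,
    scheme: ScoringScheme,
    row_a: str,
    row_b: str,
    score: float,
    start_a: int = 0,
    start_b: int = 0,
) -> PairwiseAlignment:
    ncol, ident, similar, paired = _column_stats(row_a, row_b, scheme)
    identity = 100.0 * ident / ncol if ncol else 0.0
    similarity = 100.0 * similar / ncol if scheme.alphabet == "protein" and ncol else None
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        row_a=row_a,
        row_b=row_b,
        score=score,
        identity_pct=identity,
        similarity_pct=similarity,
        coverage_a_pct=100.0 * paired / len(a),
        coverage_b_pct=100.0 * paired / len(b),
        start_a=start_a,
        start_b=start_b,
    )


def global_align(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two same-alphabet sequences.

    Ties between equally optimal traces are broken by the aligner's
    canonical enumeration order, so output is deterministic.
    """
    _check_pair(a, b)
    if scheme is None:
        scheme = default_scheme(a.alphabet)
    aligner = _make_aligner(scheme, "global")
    aln = aligner.align(a.residues, b.residues)[0]
    return _build_alignment(a, b, scheme, aln[0], aln[1], float(aln.score))


def local_align(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None) -> Optional[PairwiseAlignment]:
    """Optimal local affine-gap alignment; ``None`` when the best score ≤ 0."""
    _check_pair(a, b)
    if scheme is None:
        scheme = default_scheme(a.alphabet)
    aligner = _make_aligner(scheme, "local")
    alignments = aligner.align(a.residues, b.residues)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    start_a = int(aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
    start_b = int(aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
    return _build_alignment(a, b, scheme, aln[0], aln[1], float(aln.score), start_a, start_b)


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 × identical columns / alignment columns (gap columns included)."""
    ident = sum(1 for x, y in zip(aln.row_a, aln.row_b) if x == y and x != "-")
    return 100.0 * ident / aln.ncol


def percent_similarity(aln: PairwiseAlignment, scheme: ScoringScheme | None = None) -> float:
    """100 × positively-scoring residue pairs / alignment columns.

    Defined for protein alignments only (raises on a DNA scheme).
    """
    if scheme is None:
        scheme = default_scheme("protein")
    if scheme.alphabet != "protein":
        raise AlignmentError("percent similarity is undefined for DNA alignments")
    similar = sum(
        1
        for x, y in zip(aln.row_a, aln.row_b)
        if x != "-" and y != "-" and scheme.pair_score(x, y) > 0
    )
    return 100.0 * similar / aln.ncol


def dna_identity_detectable(
    a: SeqRecord,
    b: SeqRecord,
    scheme: ScoringScheme | None = None,
    min_segment_frac: float = 0.2,
) -> bool:
    """Whether two DNA sequences share detectable identity.

    Operationalised as: the best local alignment has positive score AND its
    aligned segment covers at least ``min_segment_frac`` of the shorter
    sequence. Mirrors a BLAST-style "hit vs no hit" call.
    """
    if a.alphabet != "dna" or b.alphabet != "dna":
        raise AlignmentError("dna_identity_detectable requires DNA records")
    if scheme is None:
        scheme = default_scheme("dna")
    aln = local_align(a, b, scheme)
    if aln is None:
        return False
    shorter = min(len(a), len(b))
    covered = min(
        sum(1 for c in aln.row_a if c != "-"),
        sum(1 for c in aln.row_b if c != "-"),
    )
    return covered / shorter >= min_segment_frac


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def _center_insertions(center_row: str) -> list[int]:
    """Number of gap columns in the center row before each center residue.

    Returns ``len(center) + 1`` slot counts; slot i counts insertion
    columns between center residue i-1 and i (slot 0 = before the first,
    slot len = after the last).
    """
    counts = [0]
    for c in center_row:
        if c == "-":
            counts[-1] += 1
        else:
            counts.append(0)
    return counts


def star_msa(
    records: Sequence[SeqRecord],
    center_id: str,
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Center-star multiple alignment.

    Every sequence is globally aligned to the center; gaps are merged under
    the once-a-gap-always-a-gap rule, with each insertion block left-packed.
    """
    records = list(records)
    if len(records) < 2:
        raise AlignmentError("star_msa needs at least two sequences")
    ids = [r.id for r in records]
    if center_id not in ids:
        raise AlignmentError(f"center id {center_id!r} not among the records")
    center = records[ids.index(center_id)]
    if scheme is None:
        scheme = default_scheme(center.alphabet)

    others = [r for r in records if r.id != center_id]
    pair_alns = {r.id: global_align(center, r, scheme) for r in others}

    n_slots = len(center) + 1
    slot_width = [0] * n_slots
    for aln in pair_alns.values():
        for i, w in enumerate(_center_insertions(aln.row_a)):
            slot_width[i] = max(slot_width[i], w)

    def rebuild(aln: PairwiseAlignment) -> str:
        out: list[str] = []
        slot = 0
        pending: list[str] = []  # other-row chars inside the current insertion block

        def flush() -> None:
            out.extend(pending)
            out.append("-" * (slot_width[slot] - len(pending)))
            pending.clear()

        for cc, oc in zip(aln.row_a, aln.row_b):
            if cc == "-":
                pending.append(oc)
            else:
                flush()
                slot += 1
                out.append(oc)
        flush()
        return "".join(out)

    center_chars: list[str] = []
    for i, residue in enumerate(center.residues):
        center_chars.append("-" * slot_width[i])
        center_chars.append(residue)
    center_chars.append("-" * slot_width[len(center)])
    merged_center = "".join(center_chars)

    rows = []
    for r in records:
        rows.append(merged_center if r.id == center_id else rebuild(pair_alns[r.id]))
    return MultipleAlignment(ids=list(ids), rows=rows)


def choose_center(records: Sequence[SeqRecord], scheme: ScoringScheme | None = None) -> str:
    """Pick the center sequence maximising the summed global score to all others."""
    records = list(records)
    if len(records) < 2:
        raise AlignmentError("need at least two sequences")
    if scheme is None:
        scheme = default_scheme(records[0].alphabet)
    n = len(records)
    scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = global_align(records[i], records[j], scheme).score
            scores[i] += s
            scores[j] += s
    return records[int(np.argmax(scores))].id
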