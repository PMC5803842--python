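"""Protein local alignment and BLAST-style coverage/identity orthologue ranking.

The database search itself is out of scope; given a query (e.g. potato
StPTB1) and candidate orthologue sequences, this module recomputes the
scoring step: an optimal Smith-Waterman local alignment under BLOSUM62 with
affine gaps, then query coverage (percent of the query spanned by the best
local alignment) and percent identity (identical residues over alignment
columns, gaps included — the BLAST convention), both rounded to integers as
survey tables print them.  Only the single best-scoring local alignment is
used; multi-HSP tiling is deliberately not reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ptbscan.errors import MoltypeError, ParameterError
from ptbscan.seq_io import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class LocalAlignment:
    """A traceback-resolved local alignment of query ``a`` against subject ``b``.

    ``a_blocks``/``b_blocks`` are parallel lists of (start, end) half-open
    runs of aligned (gapless) columns; gaps fall between consecutive blocks.
    ``n_identical`` counts identical aligned residue pairs; ``n_columns`` is
    the alignment length including gap columns.
    """

    score: float
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    a_blocks: tuple[tuple[int, int], ...]
    b_blocks: tuple[tuple[int, int], ...]
    n_identical: int
    n_columns: int

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@dataclass(frozen=True)
class OrthoScore:
    """Coverage%/identity% of one candidate against the query, plus raw score."""

    query_id: str
    subject_id: str
    coverage_pct: int
    identity_pct: int
    score: float
    best: bool = False


def make_aligner(
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAligner:
    """A local affine-gap protein aligner (first gap position costs open+extend)."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: SeqRecord,
    b: SeqRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> LocalAlignment:
    """Optimal local alignment of two protein records.

    Deterministic: Biopython's traceback order is fixed, and the
    first-reported optimal alignment is used.  If no positive-scoring local
    alignment exists the result is empty with score 0.
    """
    for rec in (a, b):
        if rec.moltype != "protein":
            raise MoltypeError(f"local_align expects protein records, got {rec.moltype} {rec.id!r}")
        if not rec.residues:
            raise ParameterError(f"empty sequence {rec.id!r}")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a.residues, b.residues)
    try:
        best = alignments[0]
    except IndexError:
        return LocalAlignment(0.0, (0, 0), (0, 0), (), (), 0, 0)
    if best.score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), (), (), 0, 0)
    a_blocks = tuple((int(s), int(e)) for s, e in best.aligned[0])
    b_blocks = tuple((int(s), int(e)) for s, e in best.aligned[1])
    n_ident = 0
    n_aligned = 0
    for (as_, ae), (bs, _be) in zip(a_blocks, b_blocks):
        for k in range(ae - as_):
            n_aligned += 1
            if a.residues[as_ + k] == b.residues[bs + k]:
                n_ident += 1
    a_span = (a_blocks[0][0], a_blocks[-1][1])
    b_span = (b_blocks[0][0], b_blocks[-1][1])
    # alignment length = aligned columns + gap columns inside the local region
    n_gap_cols = (a_span[1] - a_span[0] - n_aligned) + (b_span[1] - b_span[0] - n_aligned)
    return LocalAlignment(
        score=float(best.score),
        a_span=a_span,
        b_span=b_span,
        a_blocks=a_blocks,
        b_blocks=b_blocks,
        n_identical=n_ident,
        n_columns=n_aligned + n_gap_cols,
    )


def ortho_score(
    query: SeqRecord,
    subject: SeqRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> OrthoScore:
    """Integer coverage%/identity% of ``subject`` against ``query``.

    Coverage is query-relative (BLAST "query coverage"): the aligned query
    span as a percentage of query length.
    """
    aln = local_align(query, subject, matrix, gap_open, gap_extend)
    if aln.is_empty:
        return OrthoScore(query.id, subject.id, 0, 0, 0.0)
    coverage = round(100 * (aln.a_span[1] - aln.a_span[0]) / len(query))
    identity = round(100 * aln.n_identical / aln.n_columns)
    return OrthoScore(query.id, subject.id, int(coverage), int(identity), aln.score)


def rank_orthologues(
    query: SeqRecord,
    candidates: list[SeqRecord],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[OrthoScore]:
    """Score all candidates and sort by (coverage, identity, score) descending.

    The first entry is flagged ``best`` — the orthologue a survey would
    carry forward.  Full ties keep input order (stable sort) and log a
    warning.
    """
    if not candidates:
        raise ParameterError("rank_orthologues needs at least one candidate")
    scores = [ortho_score(query, c, matrix, gap_open, gap_extend) for c in candidates]
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i].coverage_pct, -scores[i].identity_pct, -scores[i].score, i),
    )
    ranked = [scores[i] for i in order]
    if len(ranked) > 1:
        a, b = ranked[0], ranked[1]
        if (a.coverage_pct, a.identity_pct, a.score) == (b.coverage_pct, b.identity_pct, b.score):
            logger.warning(
                "tie on all ranking keys between %s and %s; input order kept", a.subject_id, b.subject_id
            )
    ranked[0] = OrthoScore(
        ranked[0].query_id,
        ranked[0].subject_id,
        ranked[0].coverage_pct,
        ranked[0].identity_pct,
        ranked[0].score,
        best=True,
    )
    return ranked
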