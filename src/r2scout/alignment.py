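"""Pairwise alignment primitives shared across the toolkit.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` providing BLAST-like
scoring conventions: integer match/mismatch (nucleotide) or a 20x20 half-bit
substitution table (protein, BLOSUM62 by default), with affine gap costs
``gap_open + L * gap_extend`` for a gap of length ``L``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class AlignmentInputError(ValueError):
    """Raised on empty input or characters outside the declared alphabet."""


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for pairwise alignment.

    mode
        ``"nucleotide"`` (match/mismatch over ACGT, N mismatches everything
        including itself) or ``"protein"`` (substitution table in half-bits).
    """

    mode: str = "nucleotide"
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    def substitution_matrix(self):
        if self.mode == "nucleotide":
            m = substitution_matrices.Array(NT_ALPHABET, dims=2)
            for a in NT_ALPHABET:
                for b in NT_ALPHABET:
                    if a == b and a != "N":
                        m[a, b] = self.match
                    else:
                        m[a, b] = self.mismatch
            return m
        base = substitution_matrices.load(self.matrix_name)
        return base


DEFAULT_NT = ScoringScheme()
DEFAULT_AA = ScoringScheme(mode="protein", gap_open=10, gap_extend=1)


@dataclass
class PairwiseResult:
    """Best pairwise alignment of a query ``a`` against a subject ``b``."""

    score: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    aligned_a: str = ""
    aligned_b: str = ""
    identity: float = 0.0
    _empty: bool = field(default=False, repr=False)

    @property
    def empty(self) -> bool:
        return self._empty


def _validate(seq: str, scheme: ScoringScheme) -> str:
    if not seq:
        raise AlignmentInputError("empty sequence")
    seq = seq.upper()
    if scheme.mode == "nucleotide":
        bad = set(seq) - set(NT_ALPHABET)
        if bad:
            raise AlignmentInputError(f"invalid nucleotide characters {sorted(bad)}")
    else:
        allowed = set(AA_ALPHABET) | {"X", "B", "Z", "*"}
        bad = set(seq) - allowed
        if bad:
            raise AlignmentInputError(f"invalid protein characters {sorted(bad)}")
    return seq


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.substitution_matrix()
    # Biopython charges open_gap_score on the first gap base and
    # extend_gap_score thereafter; convert from open+L*extend convention.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if mode == "local":
        aligner.end_gap_score = 0.0
    return aligner


def _columns(aln) -> tuple[str, str]:
    lines = str(aln).splitlines()
    # Alignment.__getitem__ gives the gapped rows directly.
    return aln[0], aln[1]


def _result_from(aln, a: str, b: str) -> PairwiseResult:
    blocks_a, blocks_b = aln.aligned
    q_start, q_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    s_start, s_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    row_a, row_b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    ncols = sum(1 for x, y in zip(row_a, row_b) if not (x == "-" and y == "-"))
    return PairwiseResult(
        score=float(aln.score),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        aligned_a=row_a,
        aligned_b=row_b,
        identity=matches / ncols if ncols else 0.0,
    )


def local_align(
    a: str, b: str, scoring: ScoringScheme | None = None, max_tie_enum: int = 32
) -> PairwiseResult:
    """Optimal affine-gap local alignment of query ``a`` against subject ``b``.

    Ties among co-optimal alignments are broken by the smallest
    ``(s_start, q_start)``.  A best score <= 0 yields an empty result with
    score 0 (no positive-scoring local alignment exists).
    """
    scheme = scoring or DEFAULT_NT
    a = _validate(a, scheme)
    b = _validate(b, scheme)
    aligner = _make_aligner(scheme, "local")
    # Aligner signature is (target, query); feed a first so row 0 is a.
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return PairwiseResult(score=0.0, _empty=True)
    best = None
    best_key = None
    for aln in itertools.islice(alns, max_tie_enum):
        res = _result_from(aln, a, b)
        key = (res.s_start, res.q_start)
        if best is None or key < best_key:
            best, best_key = res, key
    return best


def global_align(a: str, b: str, scoring: ScoringScheme | None = None) -> PairwiseResult:
    """Needleman-Wunsch global alignment under the same scoring conventions."""
    scheme = scoring or DEFAULT_NT
    a = _validate(a, scheme)
    b = _validate(b, scheme)
    aligner = _make_aligner(scheme, "global")
    aln = next(iter(aligner.align(a, b)))
    res = _result_from(aln, a, b)
    res.score = float(aln.score)
    return res


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
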