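"""Smith-Waterman based local search producing tabular-style HSPs.

A deliberately small stand-in for an external database search tool: exact
affine-gap local alignment (via Bio.Align.PairwiseAligner) with optional
exact k-mer seeding to skip unrelated pairs, iterated with query masking to
recover multiple HSPs per query-subject pair.  E-values follow the
Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)`` with documented
approximate constants for the default scoring schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import HSP, Orientation, ValidationError
from .seqs import revcomp

NUC_ALPHABET = "ACGTN"
MASK_SCORE = -1000.0


@dataclass(frozen=True)
class SearchScoring:
    """Scoring scheme plus Karlin-Altschul constants for E-values.

    The default nucleotide scheme is match +2 / mismatch -3 with affine
    gaps (open 5, extend 2); ``lam``/``k`` are the ungapped constants for
    that scheme (lambda solves sum p_ij exp(lambda s_ij) = 1 at uniform
    base composition).  Peptide mode uses BLOSUM62 with gap open 11 /
    extend 1 and the widely quoted gapped constants.
    """

    mode: str  # "nucleotide" | "peptide"
    gap_open: float
    gap_extend: float
    lam: float
    k: float
    match: float = 2.0
    mismatch: float = -3.0
    min_score: float = 40.0


NUCLEOTIDE_SCORING = SearchScoring(
    mode="nucleotide", gap_open=5.0, gap_extend=2.0, lam=0.625, k=0.2
)
PEPTIDE_SCORING = SearchScoring(
    mode="peptide", gap_open=11.0, gap_extend=1.0, lam=0.267, k=0.041
)


def _nucleotide_matrix(scoring: SearchScoring) -> substitution_matrices.Array:
    mat = substitution_matrices.Array(NUC_ALPHABET, dims=2)
    for a in NUC_ALPHABET:
        for b in NUC_ALPHABET:
            if "N" in (a, b):
                mat[a, b] = MASK_SCORE
            else:
                mat[a, b] = scoring.match if a == b else scoring.mismatch
    return mat


def _peptide_matrix() -> substitution_matrices.Array:
    base = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(str(base.alphabet), dims=2)
    for a in str(base.alphabet):
        for b in str(base.alphabet):
            if "X" in (a, b) or "*" in (a, b):
                mat[a, b] = MASK_SCORE
            else:
                mat[a, b] = base[a, b]
    return mat


def make_aligner(scoring: SearchScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.mode == "nucleotide":
        aligner.substitution_matrix = _nucleotide_matrix(scoring)
    elif scoring.mode == "peptide":
        aligner.substitution_matrix = _peptide_matrix()
    else:
        raise ValidationError(f"unknown search mode {scoring.mode!r}")
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _validate_alphabet(seqs: dict[str, str], mode: str) -> None:
    allowed = set("ACGTN") if mode == "nucleotide" else set(
        "ARNDCQEGHILKMFPSTWYVBZX"
    )
    for name, seq in seqs.items():
        bad = set(seq.upper()) - allowed
        if bad:
            raise ValidationError(
                f"sequence {name!r} contains characters {sorted(bad)} invalid "
                f"for {mode} search"
            )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _evalue(score: float, m: int, n: int, scoring: SearchScoring) -> float:
    return float(scoring.k * m * n * np.exp(-scoring.lam * score))


def _hsps_for_pair(
    aligner: Align.PairwiseAligner,
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    orientation: Orientation,
    scoring: SearchScoring,
    db_len: int,
    max_evalue: float,
    max_hsps: int,
    subject_offset: int = 0,
    subject_full_len: int | None = None,
) -> list[HSP]:
    """Iterated SW with query masking; coordinates mapped to the plus strand."""
    mask_char = "N" if scoring.mode == "nucleotide" else "X"
    work = list(query)
    full_len = subject_full_len if subject_full_len is not None else len(subject)
    hsps: list[HSP] = []
    for _ in range(max_hsps):
        alignments = aligner.align("".join(work), subject)
        if alignments.score < scoring.min_score:
            break
        aln = alignments[0]
        blocks_q = aln.aligned[0]
        blocks_s = aln.aligned[1]
        q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
        s_lo, s_hi = int(blocks_s[0][0]), int(blocks_s[-1][1])
        counts = aln.counts()
        n_columns = counts.gaps + counts.identities + counts.mismatches
        pident = 100.0 * counts.identities / n_columns if n_columns else 0.0
        if orientation is Orientation.INVERTED:
            s_start = subject_offset + (len(subject) - s_hi)
            s_end = subject_offset + (len(subject) - s_lo)
        else:
            s_start = subject_offset + s_lo
            s_end = subject_offset + s_hi
        evalue = _evalue(alignments.score, len(query), db_len, scoring)
        if evalue <= max_evalue:
            hsps.append(
                HSP(
                    query_id=query_id,
                    subject_id=subject_id,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    orientation=orientation,
                    percent_identity=round(pident, 2),
                    score=float(alignments.score),
                    e_value=evalue,
                    n_columns=int(n_columns),
                )
            )
        for i in range(q_start, q_end):
            work[i] = mask_char
    _ = full_len  # windowed scans keep full subject length via offsets only
    return hsps


#: Subjects longer than this are scanned via seed windows, not whole-sequence SW.
WINDOW_SUBJECT_LEN = 20000
WINDOW_PAD = 400


def _seed_windows(
    query: str,
    subject: str,
    word: int,
    pad: int,
    index: dict[str, list[int]] | None = None,
) -> list[tuple[int, int]]:
    """Cluster exact k-mer seed positions on the subject into scan windows."""
    if index is None:
        index = _kmer_positions(subject, word)
    positions = sorted(
        pos
        for i in range(len(query) - word + 1)
        for pos in index.get(query[i : i + word], ())
    )
    if not positions:
        return []
    windows: list[tuple[int, int]] = []
    gap = len(query) + pad
    run_start = positions[0]
    prev = positions[0]
    for pos in positions[1:]:
        if pos - prev > gap:
            windows.append((run_start, prev + word))
            run_start = pos
        prev = pos
    windows.append((run_start, prev + word))
    return [
        (max(0, lo - len(query) - pad), min(len(subject), hi + len(query) + pad))
        for lo, hi in windows
    ]


def toy_search(
    queries: dict[str, str],
    subjects: dict[str, str],
    mode: str = "nucleotide",
    scoring: SearchScoring | None = None,
    max_evalue: float = 10.0,
    max_hsps_per_pair: int = 8,
    seed_word_size: int | None = None,
    exclude_self: bool = True,
) -> list[HSP]:
    """Search every query against every subject, returning HSPs.

    Nucleotide mode searches both strands; minus-strand hits are reported
    with ``orientation=INVERTED`` and subject coordinates on the plus
    strand.  With ``seed_word_size`` set, pairs sharing no exact word are
    skipped (and long subjects are scanned window-wise around seeds); with
    it unset the search is exact Smith-Waterman on every pair.
    """
    if scoring is None:
        scoring = NUCLEOTIDE_SCORING if mode == "nucleotide" else PEPTIDE_SCORING
    if scoring.mode != mode:
        raise ValidationError("scoring.mode disagrees with requested mode")
    queries = {k: v.upper() for k, v in queries.items()}
    subjects = {k: v.upper() for k, v in subjects.items()}
    _validate_alphabet(queries, mode)
    _validate_alphabet(subjects, mode)
    aligner = make_aligner(scoring)
    db_len = sum(len(s) for s in subjects.values()) or 1

    hsps: list[HSP] = []
    subject_kmers: dict[tuple[str, str], set[str]] = {}
    window_index: dict[tuple[str, str], dict[str, list[int]]] = {}
    for subject_id, subject in subjects.items():
        strands = [(Orientation.FORWARD, subject)]
        if mode == "nucleotide":
            strands.append((Orientation.INVERTED, revcomp(subject)))
        for orientation, sseq in strands:
            if seed_word_size is None:
                continue
            key = (subject_id, orientation.value)
            if len(sseq) <= WINDOW_SUBJECT_LEN:
                subject_kmers[key] = _kmer_set(sseq, seed_word_size)
            else:
                window_index[key] = _kmer_positions(sseq, seed_word_size)
        for query_id, query in queries.items():
            if exclude_self and query_id == subject_id:
                continue
            for orientation, sseq in strands:
                if seed_word_size is not None:
                    if len(sseq) > WINDOW_SUBJECT_LEN:
                        for lo, hi in _seed_windows(
                            query,
                            sseq,
                            seed_word_size,
                            WINDOW_PAD,
                            index=window_index[(subject_id, orientation.value)],
                        ):
                            window = sseq[lo:hi]
                            offset = (
                                lo
                                if orientation is Orientation.FORWARD
                                else len(sseq) - hi
                            )
                            hsps.extend(
                                _hsps_for_pair(
                                    aligner,
                                    query_id,
                                    query,
                                    subject_id,
                                    window,
                                    orientation,
                                    scoring,
                                    db_len,
                                    max_evalue,
                                    max_hsps_per_pair,
                                    subject_offset=offset,
                                    subject_full_len=len(sseq),
                                )
                            )
                        continue
                    kmers = subject_kmers[(subject_id, orientation.value)]
                    qwords = _kmer_set(query, seed_word_size)
                    if kmers.isdisjoint(qwords):
                        continue
                hsps.extend(
                    _hsps_for_pair(
                        aligner,
                        query_id,
                        query,
                        subject_id,
                        sseq,
                        orientation,
                        scoring,
                        db_len,
                        max_evalue,
                        max_hsps_per_pair,
                    )
                )
    return hsps


def top_hit(hits: Iterable[HSP]) -> HSP | None:
    """Best hit by lowest E-value, then highest score, then subject id."""
    best = None
    for hsp in hits:
        key = (hsp.e_value, -hsp.score, hsp.subject_id)
        if best is None or key < (best.e_value, -best.score, best.subject_id):
            best = hsp
    return best
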