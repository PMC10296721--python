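"""Competitive junction-read classification against a two-isoform reference.

Each read is aligned (or its pre-computed primary alignment ingested) against
both the canonical and the exon-skipped transcript, and called:

* ``ALPHA`` — junction evidence for the canonical isoform,
* ``DELTA2`` — junction evidence for the exon-skipped isoform,
* ``AMBIGUOUS`` — both references satisfy the junction rule with equal score,
* ``NON_JUNCTION`` — no alignment crosses the diagnostic window usefully.

A reference *satisfies the junction rule* when its alignment (i) covers the
diagnostic window (fully, by default), (ii) is gapless inside the window,
(iii) has at least ``min_anchor`` aligned bases on each side of that
reference's junction position, and (iv) has at most
``max_mismatch_in_window`` mismatches inside the window.  Among satisfying
references the strictly higher alignment score wins; ties are never broken
arbitrarily.

Alignments come from either an internal affine local aligner (both strands
tried, better kept) or from SAM/BAM produced by an external mapper, in which
case only mapped primary records are used (FLAG bits 0x4 and 0x100 unset,
i.e. the ``samtools view -F 256`` convention) and per-window mismatches are
recomputed against the in-memory reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import Align
from Bio.Align import substitution_matrices

from .references import IsoformPair
from .simulate import read_fastq, reverse_complement

__all__ = [
    "ClassifierParams",
    "AlignmentRecord",
    "JunctionCall",
    "SampleCounts",
    "local_align",
    "align_read",
    "classify_read",
    "classify_sample",
    "ingest_sam",
    "write_sam",
]

CALL_ALPHA = "ALPHA"
CALL_DELTA2 = "DELTA2"
CALL_AMBIGUOUS = "AMBIGUOUS"
CALL_NON_JUNCTION = "NON_JUNCTION"


@dataclass(frozen=True)
class ClassifierParams:
    """Alignment scoring and junction-rule thresholds.

    Defaults: match +2 / mismatch −3 / gap open −5 / gap extend −2 (short-read
    local-alignment scale); ``min_anchor=5`` and ``max_mismatch_in_window=1``
    so that a single sequencing error cannot flip a call to the other isoform
    (a flip would require matching the other junction k-mer, at least
    ``min_anchor`` mismatches away).  ``overlap_mode`` is ``full_window`` by
    default: the alignment must cover the whole diagnostic window, which
    guarantees it crosses the junction; ``any_overlap`` is kept for fidelity
    experiments with the looser reading of window overlap.
    """

    match_score: float = 2.0
    mismatch_penalty: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_anchor: int = 5
    max_mismatch_in_window: int = 1
    overlap_mode: str = "full_window"
    try_reverse_complement: bool = True
    use_fast_path: bool = True

    def __post_init__(self) -> None:
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.overlap_mode not in {"full_window", "any_overlap"}:
            raise ValueError("overlap_mode must be 'full_window' or 'any_overlap'")
        if self.max_mismatch_in_window < 0:
            raise ValueError("max_mismatch_in_window must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a read against one reference.

    ``blocks`` are maximal gapless runs ``(ref_start, ref_end, read_start)``
    in 0-based half-open reference coordinates; ``read_start`` is on the
    aligned (possibly reverse-complemented) query.  ``mismatch_positions``
    are reference coordinates of mismatched or N-containing columns.
    """

    read_id: str
    reference: str  # 'canonical' | 'skipped'
    ref_start: int
    ref_end: int
    score: float
    n_mismatch: int
    n_gap: int
    blocks: tuple[tuple[int, int, int], ...]
    mismatch_positions: tuple[int, ...] = ()
    strand: str = "+"
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.blocks and not self.ref_start < self.ref_end:
            raise ValueError("ref_start must precede ref_end")


@dataclass(frozen=True)
class JunctionCall:
    """Per-read classification outcome.

    ``margin`` is the score gap to the runner-up among references satisfying
    the junction rule; when only one reference satisfies it there is no
    competing junction evidence and the margin equals the winning score.
    """

    read_id: str
    call: str
    winning_score: float = 0.0
    margin: float = 0.0


@dataclass(frozen=True)
class SampleCounts:
    """Call-class tallies for one sample; the four classes sum to n_total."""

    sample_id: str
    n_alpha: int = 0
    n_delta2: int = 0
    n_ambiguous: int = 0
    n_nonjunction: int = 0

    def __post_init__(self) -> None:
        if min(self.n_alpha, self.n_delta2, self.n_ambiguous, self.n_nonjunction) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_alpha + self.n_delta2 + self.n_ambiguous + self.n_nonjunction

    @classmethod
    def from_calls(cls, sample_id: str, calls: Iterable[JunctionCall]) -> "SampleCounts":
        tally = {CALL_ALPHA: 0, CALL_DELTA2: 0, CALL_AMBIGUOUS: 0, CALL_NON_JUNCTION: 0}
        for c in calls:
            tally[c.call] += 1
        return cls(
            sample_id=sample_id,
            n_alpha=tally[CALL_ALPHA],
            n_delta2=tally[CALL_DELTA2],
            n_ambiguous=tally[CALL_AMBIGUOUS],
            n_nonjunction=tally[CALL_NON_JUNCTION],
        )


# --- internal aligner --------------------------------------------------------

_ALIGNER_CACHE: dict[tuple[float, float, float, float], Align.PairwiseAligner] = {}


def _aligner(params: ClassifierParams) -> Align.PairwiseAligner:
    key = (params.match_score, params.mismatch_penalty, params.gap_open, params.gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        matrix = substitution_matrices.Array("ACGTN", dims=2)
        for x in "ACGTN":
            for y in "ACGTN":
                # N never scores as a match, even against another N
                matrix[x, y] = (
                    params.match_score if (x == y and x != "N") else params.mismatch_penalty
                )
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = params.gap_open
        aligner.extend_gap_score = params.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def _mismatches_in_blocks(
    blocks: Sequence[tuple[int, int, int]], ref: str, query: str
) -> tuple[int, ...]:
    pos = []
    for rs, re_, qs in blocks:
        for off in range(re_ - rs):
            a = ref[rs + off]
            b = query[qs + off]
            if a != b or a == "N":
                pos.append(rs + off)
    return tuple(pos)


def _empty_record(read_id: str, reference: str, strand: str = "+") -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read_id, reference=reference, ref_start=0, ref_end=0,
        score=0.0, n_mismatch=0, n_gap=0, blocks=(), strand=strand,
    )


def local_align(
    read_sequence: str,
    reference_sequence: str,
    params: Optional[ClassifierParams] = None,
    *,
    read_id: str = "",
    reference: str = "canonical",
    strand: str = "+",
) -> AlignmentRecord:
    """Optimal affine-gap local alignment of one read against one reference.

    Uses a deterministic traceback (the first co-optimal alignment in
    Biopython's canonical enumeration order), so repeated runs give identical
    records.  An empty or unalignable read yields a score-0 record with no
    aligned blocks.
    """
    params = params or ClassifierParams()
    read = _sanitize(read_sequence)
    ref = _sanitize(reference_sequence)
    if not read or not ref:
        return _empty_record(read_id, reference, strand)
    aligner = _aligner(params)
    try:
        aln = aligner.align(ref, read)[0]
    except IndexError:
        return _empty_record(read_id, reference, strand)
    if aln.score <= 0 or len(aln.aligned[0]) == 0:
        return _empty_record(read_id, reference, strand)
    ref_blocks, read_blocks = aln.aligned
    blocks = tuple(
        (int(rs), int(re_), int(qs))
        for (rs, re_), (qs, _qe) in zip(ref_blocks, read_blocks)
    )
    mism = _mismatches_in_blocks(blocks, ref, read)
    n_gap = 0
    for (prs, pre, _pq), (rs, _re, qs) in zip(blocks, blocks[1:]):
        prev_qe = _pq + (pre - prs)
        n_gap += (rs - pre) + (qs - prev_qe)
    return AlignmentRecord(
        read_id=read_id,
        reference=reference,
        ref_start=blocks[0][0],
        ref_end=blocks[-1][1],
        score=float(aln.score),
        n_mismatch=len(mism),
        n_gap=n_gap,
        blocks=blocks,
        mismatch_positions=mism,
        strand=strand,
    )


def _best_gapless(
    read: str, ref: str, params: ClassifierParams,
    window: Optional[tuple[int, int]],
) -> Optional[tuple[float, int, int, int, tuple[int, ...]]]:
    """Best gapless local alignment (optimal end-clipping) of read vs ref.

    Returns ``(score, ref_start, ref_end, read_start, mismatch_positions)``
    or None when the read is longer than the reference.  Vectorized over all
    placements; the clipped segment per placement is the maximum-sum run of
    match/mismatch scores (prefix-sum trick).  Deterministic choice among
    co-optimal placements: prefer one covering the diagnostic window, then
    the leftmost; within a placement the widest co-optimal segment.
    """
    L, R = len(read), len(ref)
    n_off = R - L + 1
    if n_off <= 0:
        return None
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    n_code = ord("N")
    refw = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    match = (refw == read_arr) & (read_arr != n_code) & (refw != n_code)
    vals = np.where(
        match,
        np.float32(params.match_score),
        np.float32(params.mismatch_penalty),
    )
    s = np.zeros((n_off, L + 1), dtype=np.float32)
    np.cumsum(vals, axis=1, out=s[:, 1:])
    prefix_min = np.minimum.accumulate(s, axis=1)
    d = s[:, 1:] - prefix_min[:, :-1]
    best_per_off = d.max(axis=1)
    best = float(best_per_off.max())
    if best <= 0:
        return (0.0, 0, 0, 0, ())
    candidates = np.flatnonzero(best_per_off == best)[:8]

    def _segment(off: int) -> tuple[int, int]:
        row = d[off]
        j = int(np.flatnonzero(row == best)[-1]) + 1
        i = int(np.flatnonzero(s[off, :j] == prefix_min[off, j - 1])[0])
        return i, j

    chosen = int(candidates[0])
    seg = _segment(chosen)
    if window is not None:
        for off in candidates:
            i, j = _segment(int(off))
            if off + i <= window[0] and off + j >= window[1]:
                chosen, seg = int(off), (i, j)
                break
    i, j = seg
    mism = tuple(int(chosen + k) for k in range(i, j) if not match[chosen, k])
    return (best, chosen + i, chosen + j, i, mism)


def _gapless_record(
    read: str, ref: str, params: ClassifierParams, read_id: str,
    reference: str, strand: str,
    result: tuple[float, int, int, int, tuple[int, ...]],
) -> AlignmentRecord:
    score, rs, re_, qs, mism = result
    if score <= 0:
        return _empty_record(read_id, reference, strand)
    return AlignmentRecord(
        read_id=read_id, reference=reference, ref_start=rs, ref_end=re_,
        score=score, n_mismatch=len(mism), n_gap=0,
        blocks=((rs, re_, qs),), mismatch_positions=mism, strand=strand,
    )


def _exact_record(
    read: str, ref: str, params: ClassifierParams, read_id: str,
    reference: str, strand: str, window: Optional[tuple[int, int]],
) -> Optional[AlignmentRecord]:
    """Fast path: the read occurs verbatim in the reference.

    Such a hit is a guaranteed optimal local alignment (full-length, all
    matches).  Among multiple occurrences the first one covering the
    diagnostic window is preferred, so the record is maximally informative.
    """
    if "N" in read:
        return None
    first = ref.find(read)
    if first < 0:
        return None
    start = first
    if window is not None:
        p = first
        while p >= 0:
            if p <= window[0] and p + len(read) >= window[1]:
                start = p
                break
            p = ref.find(read, p + 1)
    return AlignmentRecord(
        read_id=read_id,
        reference=reference,
        ref_start=start,
        ref_end=start + len(read),
        score=params.match_score * len(read),
        n_mismatch=0,
        n_gap=0,
        blocks=((start, start + len(read), 0),),
        strand=strand,
    )


def align_read(
    read_sequence: str,
    pair: IsoformPair,
    params: Optional[ClassifierParams] = None,
    *,
    read_id: str = "",
) -> dict[str, AlignmentRecord]:
    """Align one read against both references, trying both orientations.

    For each reference the better-scoring orientation is kept (forward wins
    ties).  Error-free reads short-circuit through an exact-substring check
    before the dynamic-programming aligner is invoked.
    """
    params = params or ClassifierParams()
    read = _sanitize(read_sequence)
    out: dict[str, AlignmentRecord] = {}
    for refname in ("canonical", "skipped"):
        rec, _certain, g_scores = _fast_candidate(read, pair, refname, params, read_id)
        if not _certain:
            rec = _dp_record(read, pair, refname, params, read_id, g_scores)
        out[refname] = rec
    return out


def _gap_bound(read: str, params: ClassifierParams) -> float:
    """Upper bound on the score of any alignment containing >= 1 gap.

    At most ``len(read)`` match columns plus at least one gap run, so a
    gapless alignment scoring at or above this bound is the global
    affine-gap optimum.
    """
    return params.match_score * len(read) + params.gap_open


def _fast_candidate(
    read: str, pair: IsoformPair, refname: str,
    params: ClassifierParams, read_id: str,
) -> tuple[AlignmentRecord, bool, Optional[tuple[float, float]]]:
    """Exact-substring / gapless-scan alignment for one reference.

    Returns ``(record, certain, gapless_scores)``; ``certain`` means the
    record is provably the optimal affine-gap local alignment (its score
    reaches the gapless certainty bound).  ``gapless_scores`` are the
    forward/reverse gapless optima, reusable by the DP fallback.  With the
    fast path disabled, certainty is never claimed and the caller falls
    through to dynamic programming.
    """
    ref = pair.model(refname).sequence
    if not read:
        return _empty_record(read_id, refname), True, None
    if not params.use_fast_path:
        return _empty_record(read_id, refname), False, None
    rc = reverse_complement(read) if params.try_reverse_complement else None
    rec = _exact_record(read, ref, params, read_id, refname, "+", pair.window)
    if rec is None and rc is not None:
        rec = _exact_record(rc, ref, params, read_id, refname, "-", pair.window)
    if rec is not None:
        return rec, True, None
    fwd = _best_gapless(read, ref, params, pair.window)
    rev = _best_gapless(rc, ref, params, pair.window) if rc is not None else None
    cand: list[tuple[float, int, str, object]] = []
    if fwd is not None:
        cand.append((fwd[0], 1, "+", fwd))
    if rev is not None:
        cand.append((rev[0], 0, "-", rev))
    if not cand:
        return _empty_record(read_id, refname), False, None
    score, _, strand, result = max(cand, key=lambda c: (c[0], c[1]))
    rec = _gapless_record(
        read if strand == "+" else rc,  # type: ignore[arg-type]
        ref, params, read_id, refname, strand, result,
    )
    g_scores = (
        fwd[0] if fwd is not None else 0.0,
        rev[0] if rev is not None else 0.0,
    )
    return rec, score >= _gap_bound(read, params), g_scores


def _dp_record(
    read: str, pair: IsoformPair, refname: str,
    params: ClassifierParams, read_id: str,
    gapless_scores: Optional[tuple[float, float]] = None,
) -> AlignmentRecord:
    """Full affine local alignment of one read vs one reference.

    Orientation handling: the orientation with the better gapless score is
    aligned first; the other orientation's optimum is bounded by
    ``max(its gapless score, gap bound)``, so a second traceback runs only
    when that bound could still win.  Forward wins exact ties.
    """
    ref = pair.model(refname).sequence
    if not read:
        return _empty_record(read_id, refname)
    if not params.try_reverse_complement:
        return local_align(read, ref, params, read_id=read_id, reference=refname, strand="+")
    rc = reverse_complement(read)
    if gapless_scores is None:
        g_fwd = _best_gapless(read, ref, params, None)
        g_rev = _best_gapless(rc, ref, params, None)
        s_fwd = g_fwd[0] if g_fwd else 0.0
        s_rev = g_rev[0] if g_rev else 0.0
    else:
        s_fwd, s_rev = gapless_scores
    bound = _gap_bound(read, params)
    if s_fwd >= s_rev:
        rec_f = local_align(read, ref, params, read_id=read_id, reference=refname, strand="+")
        if rec_f.score >= max(s_rev, bound):
            return rec_f
        rec_r = local_align(rc, ref, params, read_id=read_id, reference=refname, strand="-")
        return rec_f if rec_f.score >= rec_r.score else rec_r
    rec_r = local_align(rc, ref, params, read_id=read_id, reference=refname, strand="-")
    if rec_r.score > max(s_fwd, bound):
        return rec_r
    rec_f = local_align(read, ref, params, read_id=read_id, reference=refname, strand="+")
    return rec_f if rec_f.score >= rec_r.score else rec_r


def _call_one_read(
    read_sequence: str,
    pair: IsoformPair,
    params: ClassifierParams,
    read_id: str,
) -> JunctionCall:
    """Classify one read, skipping provably irrelevant alignment work.

    Each reference is first resolved by the exact/gapless fast path.  A
    reference left uncertain (its optimum might involve gaps) is refined by
    dynamic programming only when the outcome could depend on it: if some
    other reference already satisfies the junction rule with a certain score
    strictly above the gap bound, no gapped alignment on the uncertain
    reference can win or tie, so its fast-path record stands.
    """
    read = _sanitize(read_sequence)
    recs: dict[str, AlignmentRecord] = {}
    certain: dict[str, bool] = {}
    gapless: dict[str, Optional[tuple[float, float]]] = {}
    for refname in ("canonical", "skipped"):
        recs[refname], certain[refname], gapless[refname] = _fast_candidate(
            read, pair, refname, params, read_id
        )
    if not all(certain.values()):
        bound = _gap_bound(read, params)
        dominated = any(
            certain[other]
            and recs[other].score > bound
            and _satisfies_junction_rule(
                recs[other], pair.junction_pos(other), pair.window, params
            )
            for other in ("canonical", "skipped")
        )
        if not dominated:
            for refname in ("canonical", "skipped"):
                if not certain[refname]:
                    recs[refname] = _dp_record(
                        read, pair, refname, params, read_id, gapless[refname]
                    )
    return classify_read(recs, pair, params, read_id=read_id)


# --- junction rule and per-read call ----------------------------------------


def _satisfies_junction_rule(
    rec: Optional[AlignmentRecord],
    junction_pos: int,
    window: tuple[int, int],
    params: ClassifierParams,
) -> bool:
    if rec is None or not rec.blocks or rec.score <= 0:
        return False
    w0, w1 = window
    if params.overlap_mode == "full_window":
        span = (w0, w1)
    else:  # any_overlap: the aligned part of the window must be gapless
        span = (max(w0, rec.ref_start), min(w1, rec.ref_end))
        if span[0] >= span[1]:
            return False
    # window portion must lie inside a single gapless block
    if not any(rs <= span[0] and re_ >= span[1] for rs, re_, _ in rec.blocks):
        return False
    left = sum(
        max(0, min(re_, junction_pos) - rs) for rs, re_, _ in rec.blocks
    )
    right = sum(
        max(0, re_ - max(rs, junction_pos)) for rs, re_, _ in rec.blocks
    )
    if left < params.min_anchor or right < params.min_anchor:
        return False
    n_window_mismatch = sum(1 for p in rec.mismatch_positions if w0 <= p < w1)
    return n_window_mismatch <= params.max_mismatch_in_window


def classify_read(
    read_alignments: dict[str, Optional[AlignmentRecord]],
    pair: IsoformPair,
    params: Optional[ClassifierParams] = None,
    *,
    read_id: Optional[str] = None,
) -> JunctionCall:
    """Call one read from its per-reference primary alignments.

    Competitive assignment: among references satisfying the junction rule the
    strictly higher alignment score wins; an exact tie between both is
    ``AMBIGUOUS``; no satisfying reference is ``NON_JUNCTION``.
    """
    params = params or ClassifierParams()
    if pair.window is None:
        raise ValueError("isoform pair has no diagnostic window set")
    if read_id is None:
        read_id = next(
            (r.read_id for r in read_alignments.values() if r is not None), ""
        )
    satisfied: dict[str, float] = {}
    for refname in ("canonical", "skipped"):
        rec = read_alignments.get(refname)
        if _satisfies_junction_rule(rec, pair.junction_pos(refname), pair.window, params):
            satisfied[refname] = rec.score  # type: ignore[union-attr]
    if not satisfied:
        return JunctionCall(read_id, CALL_NON_JUNCTION)
    if len(satisfied) == 2:
        s_can, s_skip = satisfied["canonical"], satisfied["skipped"]
        if s_can == s_skip:
            return JunctionCall(read_id, CALL_AMBIGUOUS, s_can, 0.0)
        if s_can > s_skip:
            return JunctionCall(read_id, CALL_ALPHA, s_can, s_can - s_skip)
        return JunctionCall(read_id, CALL_DELTA2, s_skip, s_skip - s_can)
    (refname, score), = satisfied.items()
    call = CALL_ALPHA if refname == "canonical" else CALL_DELTA2
    return JunctionCall(read_id, call, score, score)


# --- SAM/BAM ingestion -------------------------------------------------------

_BLOCK_OPS = {0, 7, 8}  # M, =, X
_QUERY_OPS = {1, 4}  # I, S consume query
_REF_OPS = {2, 3}  # D, N consume reference


def _segment_blocks(seg: pysam.AlignedSegment) -> tuple[tuple[int, int, int], ...]:
    blocks = []
    rpos = seg.reference_start
    qpos = 0
    for op, length in seg.cigartuples or ():
        if op in _BLOCK_OPS:
            blocks.append((rpos, rpos + length, qpos))
            rpos += length
            qpos += length
        elif op in _QUERY_OPS:
            qpos += length
        elif op in _REF_OPS:
            rpos += length
    return tuple(blocks)


def _score_from_runs(
    n_match: int, n_mismatch: int, gap_runs: Sequence[int], params: ClassifierParams
) -> float:
    score = n_match * params.match_score + n_mismatch * params.mismatch_penalty
    for g in gap_runs:
        score += params.gap_open + (g - 1) * params.gap_extend
    return score


def ingest_sam(
    sam_or_bam_path: str | Path,
    pair: IsoformPair,
    params: Optional[ClassifierParams] = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped primary alignments from SAM/BAM against the pair.

    Secondary records (FLAG 0x100) and unmapped records (FLAG 0x4) are
    dropped — the ``samtools view -F 256`` filter.  Mismatches are recomputed
    by comparing the aligned query to the reference sequence, and the
    alignment score is re-derived under the classifier's scoring scheme so
    that externally mapped and internally aligned reads are comparable.
    """
    params = params or ClassifierParams()
    names = pair.reference_names()
    with pysam.AlignmentFile(str(sam_or_bam_path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary:
                continue
            if seg.reference_name not in names:
                raise ValueError(
                    f"unknown reference {seg.reference_name!r}; expected one of "
                    f"{sorted(names)}"
                )
            refname = names[seg.reference_name]
            ref = pair.model(refname).sequence
            query = _sanitize(seg.query_sequence or "")
            blocks = _segment_blocks(seg)
            if not blocks or not query:
                continue
            mism = _mismatches_in_blocks(blocks, ref, query)
            n_aligned = sum(re_ - rs for rs, re_, _ in blocks)
            gap_runs = [
                length
                for op, length in (seg.cigartuples or ())
                if op in {1, 2, 3}
            ]
            read_id = seg.query_name or ""
            if seg.is_paired:
                read_id += "/2" if seg.is_read2 else "/1"
            yield AlignmentRecord(
                read_id=read_id,
                reference=refname,
                ref_start=blocks[0][0],
                ref_end=blocks[-1][1],
                score=_score_from_runs(n_aligned - len(mism), len(mism), gap_runs, params),
                n_mismatch=len(mism),
                n_gap=sum(gap_runs),
                blocks=blocks,
                mismatch_positions=mism,
                strand="-" if seg.is_reverse else "+",
            )


def _merge_mate_calls(calls: Sequence[JunctionCall], fragment_id: str) -> JunctionCall:
    """A fragment counts once; conflicting mate calls become AMBIGUOUS."""
    informative = [c for c in calls if c.call != CALL_NON_JUNCTION]
    if not informative:
        return JunctionCall(fragment_id, CALL_NON_JUNCTION)
    kinds = {c.call for c in informative}
    best = max(informative, key=lambda c: c.winning_score)
    if kinds <= {CALL_ALPHA} or kinds <= {CALL_DELTA2}:
        return JunctionCall(fragment_id, best.call, best.winning_score, best.margin)
    return JunctionCall(fragment_id, CALL_AMBIGUOUS, best.winning_score, 0.0)


def _fragment_id(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


ReadsSource = Union[str, Path, Iterable[tuple[str, str]]]


def classify_sample(
    reads_source: ReadsSource,
    pair: IsoformPair,
    params: Optional[ClassifierParams] = None,
    *,
    sample_id: str = "",
    calls_out: Optional[str | Path] = None,
) -> tuple[SampleCounts, list[JunctionCall]]:
    """Classify every read of a sample and tally call classes.

    ``reads_source`` may be a FASTQ path (internal aligner route), a SAM/BAM
    path (ingest route), or an in-memory iterable of ``(read_id, sequence)``.
    Mate pairs (read IDs suffixed ``/1``/``/2``, or SAM mate flags) are merged
    so each fragment is counted once.  Optionally writes a per-read audit TSV.
    """
    params = params or ClassifierParams()
    if pair.window is None:
        raise ValueError("isoform pair has no diagnostic window set")
    raw_calls: list[JunctionCall] = []
    if isinstance(reads_source, (str, Path)):
        path = Path(reads_source)
        suffix = path.suffix.lower()
        if suffix in {".sam", ".bam", ".cram"}:
            grouped: dict[str, dict[str, AlignmentRecord]] = {}
            for rec in ingest_sam(path, pair, params):
                slot = grouped.setdefault(rec.read_id, {})
                # at most one primary per reference; keep the better on dupes
                if rec.reference not in slot or rec.score > slot[rec.reference].score:
                    slot[rec.reference] = rec
            for rid in grouped:
                raw_calls.append(
                    classify_read(grouped[rid], pair, params, read_id=rid)
                )
        else:
            for rid, seq in read_fastq(path):
                raw_calls.append(_call_one_read(seq, pair, params, rid))
    else:
        for rid, seq in reads_source:
            raw_calls.append(_call_one_read(seq, pair, params, rid))

    # merge mates into fragments, preserving first-seen order
    by_fragment: dict[str, list[JunctionCall]] = {}
    frag_order: list[str] = []
    for c in raw_calls:
        fid = _fragment_id(c.read_id)
        if fid not in by_fragment:
            by_fragment[fid] = []
            frag_order.append(fid)
        by_fragment[fid].append(c)
    calls = [
        by_fragment[fid][0]
        if len(by_fragment[fid]) == 1
        else _merge_mate_calls(by_fragment[fid], fid)
        for fid in frag_order
    ]
    counts = SampleCounts.from_calls(sample_id, calls)
    if calls_out is not None:
        with open(calls_out, "w", newline="\n") as fh:
            fh.write("read_id\tcall\tscore\tmargin\n")
            for c in calls:
                fh.write(f"{c.read_id}\t{c.call}\t{c.winning_score:g}\t{c.margin:g}\n")
    return counts, calls


# --- SAM export (for interoperability and ingest-route testing) --------------


def _cigar_from_blocks(
    blocks: Sequence[tuple[int, int, int]], read_length: int
) -> str:
    ops: list[str] = []
    lead = blocks[0][2]
    if lead:
        ops.append(f"{lead}S")
    qpos = lead
    prev = None
    for rs, re_, qs in blocks:
        if prev is not None:
            prs, pre, pqs = prev
            ref_gap = rs - pre
            read_gap = qs - (pqs + (pre - prs))
            if ref_gap:
                ops.append(f"{ref_gap}D")
            if read_gap:
                ops.append(f"{read_gap}I")
        ops.append(f"{re_ - rs}M")
        qpos = qs + (re_ - rs)
        prev = (rs, re_, qs)
    tail = read_length - qpos
    if tail:
        ops.append(f"{tail}S")
    return "".join(ops)


def write_sam(
    path: str | Path,
    pair: IsoformPair,
    records: Iterable[tuple[AlignmentRecord, str]],
    *,
    sample_id: str = "sample",
) -> None:
    """Write primary alignment records as plain-text SAM.

    ``records`` pairs each :class:`AlignmentRecord` with the original read
    sequence (as sequenced); minus-strand records store the reverse
    complement, following SAM convention.
    """
    id_by_ref = {v: k for k, v in pair.reference_names().items()}
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for refname in ("canonical", "skipped"):
            model = pair.model(refname)
            fh.write(f"@SQ\tSN:{model.transcript_id}\tLN:{len(model)}\n")
        fh.write(f"@RG\tID:{sample_id}\n")
        for rec, read_seq in records:
            if not rec.blocks:
                continue
            seq = (
                reverse_complement(_sanitize(read_seq))
                if rec.strand == "-"
                else _sanitize(read_seq)
            )
            flag = 16 if rec.strand == "-" else 0
            cigar = _cigar_from_blocks(rec.blocks, len(seq))
            nm = rec.n_mismatch + rec.n_gap
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        str(flag),
                        id_by_ref[rec.reference],
                        str(rec.ref_start + 1),
                        "60",
                        cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "I" * len(seq),
                        f"NM:i:{nm}",
                    ]
                )
                + "\n"
            )
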