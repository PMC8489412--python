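"""Seed-and-extend local alignment for repeat, MTPT, exon and synteny searches.

A deterministic BLASTN-like engine: exact k-mer seeding (k = 11), ungapped
X-drop extension, then merging of collinear segments separated by short
gaps.  Scoring is match +1, mismatch -2, gap open -5, gap extend -2.  No
E-value is computed; a minimum-score noise floor implied by the length and
identity thresholds replaces it (at toy database sizes the length/identity
filters dominate anyway).

Circular sequences are handled by extending them past the origin before
the search; coordinates of reported hits may then exceed the sequence
length, in which case the interval accessors wrap them back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from mitoshift.genome import CircularSequence, FeatureInterval, revcomp

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2
XDROP = 20
DEFAULT_K = 11
DEFAULT_WRAP_PAD = 5000
_MAX_JOIN_GAP = 50
_MAX_JOIN_SHIFT = 30

_ENC = np.full(256, 4, dtype=np.uint8)
for i, c in enumerate("ACGT"):
    _ENC[ord(c)] = i


@dataclass
class LocalAlignment:
    """One local alignment between a query and a subject.

    Coordinates are 1-based inclusive on the forward strands of both
    sequences (``s_start <= s_end`` even for minus-strand hits; ``strand``
    carries the subject orientation).  On circular sequences an end
    coordinate may exceed the sequence length, denoting origin wrap.
    """

    q_id: str
    s_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int
    mismatches: int
    gap_columns: int
    gap_opens: int
    score: int

    @property
    def aln_len(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aln_len

    def q_interval(self, seq_len: int | None = None, kind: str = "other") -> FeatureInterval:
        return _wrap_interval(self.q_id, self.q_start, self.q_end, seq_len, kind)

    def s_interval(self, seq_len: int | None = None, kind: str = "other") -> FeatureInterval:
        return _wrap_interval(self.s_id, self.s_start, self.s_end, seq_len, kind)


def _wrap_interval(seq_id: str, start: int, end: int, seq_len: int | None, kind: str) -> FeatureInterval:
    if seq_len is not None and end > seq_len:
        start = ((start - 1) % seq_len) + 1
        end = ((end - 1) % seq_len) + 1
    return FeatureInterval(seq_id=seq_id, start=start, end=end, strand="+", kind=kind)


@dataclass(frozen=True)
class RepeatPair:
    """Two disjoint copies of an interspersed repeat (direct or inverted)."""

    id: str
    copyA: FeatureInterval
    copyB: FeatureInterval
    orientation: str  # direct | inverted
    rep_len: int
    identity: float

    def __post_init__(self) -> None:
        if self.orientation not in {"direct", "inverted"}:
            raise ValueError(f"bad orientation {self.orientation!r}")


def _encode(s: str) -> np.ndarray:
    return _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each k-mer; -1 where the window contains N."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    invalid = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        col = arr[j : n - k + 1 + j]
        codes = codes * 4 + col
        invalid |= col == 4
    codes[invalid] = -1
    return codes


def _seed_matches(qc: np.ndarray, sc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, subject_pos) pairs with equal valid k-mer codes."""
    sc = sc.copy()
    sc[sc < 0] = -2  # never matches a query code (-1 marks invalid query k-mers)
    order = np.argsort(sc, kind="stable")
    ssorted = sc[order]
    left = np.searchsorted(ssorted, qc, side="left")
    right = np.searchsorted(ssorted, qc, side="right")
    counts = right - left
    counts[qc < 0] = 0
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    starts = np.cumsum(counts) - counts
    within = np.arange(total) - np.repeat(starts, counts)
    spos = order[np.repeat(left, counts) + within]
    qpos = np.repeat(np.arange(len(qc)), counts)
    return qpos, spos


def _extend(qb: bytes, sb: bytes, qs: int, qe: int, diag: int, run_matches: int):
    """Ungapped X-drop extension of an exact run [qs, qe] on one diagonal.

    Returns (qs, qe, matches, score) for the best-scoring extension; bases
    involving N count as mismatches.
    """
    nq, ns = len(qb), len(sb)
    score = run_matches * MATCH
    best = score
    best_right = qe
    m_right = 0
    m_best_right = 0
    i = qe + 1
    while i < nq and i - diag < ns:
        a, b = qb[i], sb[i - diag]
        if a == b and a != 4:
            score += MATCH
            m_right += 1
        else:
            score += MISMATCH
        if score > best:
            best = score
            best_right = i
            m_best_right = m_right
        elif score <= best - XDROP:
            break
        i += 1
    score = best
    best_left = qs
    m_left = 0
    m_best_left = 0
    i = qs - 1
    while i >= 0 and i - diag >= 0:
        a, b = qb[i], sb[i - diag]
        if a == b and a != 4:
            score += MATCH
            m_left += 1
        else:
            score += MISMATCH
        if score > best:
            best = score
            best_left = i
            m_best_left = m_left
        elif score <= best - XDROP:
            break
        i -= 1
    matches = run_matches + m_best_left + m_best_right
    return best_left, best_right, matches, best


@dataclass
class _RawHit:
    qs: int
    qe: int
    ss: int
    se: int
    matches: int
    mismatches: int
    gap_columns: int
    gap_opens: int
    score: int


def _ungapped_hits(qb: bytes, sb: bytes, qpos: np.ndarray, spos: np.ndarray, k: int) -> list[_RawHit]:
    if len(qpos) == 0:
        return []
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    diag = diag[order]
    qpos = qpos[order]
    hits: list[_RawHit] = []
    n = len(qpos)
    i = 0
    while i < n:
        d = int(diag[i])
        j = i
        covered_until = -1
        while j < n and diag[j] == d:
            q0 = int(qpos[j])
            # merge overlapping/contiguous seeds into one exact run
            q1 = q0
            j += 1
            while j < n and diag[j] == d and int(qpos[j]) - q1 <= k:
                q1 = int(qpos[j])
                j += 1
            run_s, run_e = q0, q1 + k - 1
            if run_e <= covered_until:
                continue
            run_matches = run_e - run_s + 1
            qs, qe, matches, score = _extend(qb, sb, run_s, run_e, d, run_matches)
            covered_until = qe
            aln_len = qe - qs + 1
            hits.append(
                _RawHit(qs=qs, qe=qe, ss=qs - d, se=qe - d,
                        matches=matches, mismatches=aln_len - matches,
                        gap_columns=0, gap_opens=0, score=score)
            )
        i = j
    return hits


def _merge_collinear(hits: list[_RawHit]) -> list[_RawHit]:
    """Join pairs of collinear hits separated by short gaps (banded gapped join)."""
    hits = sorted(hits, key=lambda h: (h.qs, h.ss))
    merged = True
    while merged:
        merged = False
        for i in range(len(hits) - 1):
            a = hits[i]
            for j in range(i + 1, len(hits)):
                b = hits[j]
                if b.qs > a.qe + _MAX_JOIN_GAP + 1:
                    break
                qgap = b.qs - a.qe - 1
                sgap = b.ss - a.se - 1
                if qgap < 0 or sgap < 0 or sgap > _MAX_JOIN_GAP:
                    continue
                shift = abs(qgap - sgap)
                if shift > _MAX_JOIN_SHIFT:
                    continue
                middle = min(qgap, sgap)
                gap_pen = (GAP_OPEN + GAP_EXTEND * (shift - 1)) if shift else 0
                new_score = a.score + b.score + MISMATCH * middle + gap_pen
                if new_score <= max(a.score, b.score):
                    continue
                hits[i] = _RawHit(
                    qs=a.qs, qe=b.qe, ss=a.ss, se=b.se,
                    matches=a.matches + b.matches,
                    mismatches=a.mismatches + b.mismatches + middle,
                    gap_columns=a.gap_columns + b.gap_columns + shift,
                    gap_opens=a.gap_opens + b.gap_opens + (1 if shift else 0),
                    score=new_score,
                )
                del hits[j]
                merged = True
                break
            if merged:
                break
    return hits


def _overlap_frac(a: FeatureInterval, b: FeatureInterval, seq_len: int | None) -> float:
    arcs_a = [(a.start, a.end)] if a.start <= a.end else [(a.start, seq_len), (1, a.end)]
    arcs_b = [(b.start, b.end)] if b.start <= b.end else [(b.start, seq_len), (1, b.end)]
    ov = 0
    for s1, e1 in arcs_a:
        for s2, e2 in arcs_b:
            ov += max(0, min(e1, e2) - max(s1, s2) + 1)
    la = sum(e - s + 1 for s, e in arcs_a)
    lb = sum(e - s + 1 for s, e in arcs_b)
    return ov / min(la, lb)


def local_align_all(
    query: CircularSequence,
    subject: CircularSequence,
    min_len: int = 50,
    min_ident: float = 80.0,
    k: int = DEFAULT_K,
    wrap_pad: int = DEFAULT_WRAP_PAD,
    _self_mode: bool = False,
) -> list[LocalAlignment]:
    """All maximal local alignments of query vs subject, both subject strands.

    Hits are filtered to alignment span >= ``min_len`` and identity >=
    ``min_ident`` (plus the implied minimum-score floor), then reduced to a
    non-overlapping-optimal set by greedy score-ordered selection.
    Deterministic given its inputs.
    """
    if not query.residues or not subject.residues:
        raise ValueError("empty sequence")
    if min_len < 1 or not (0 < min_ident <= 100):
        raise ValueError("min_len >= 1 and 0 < min_ident <= 100 required")
    Lq, Ls = query.length, subject.length
    qpad = min(Lq, wrap_pad) if query.circular else 0
    spad = min(Ls, wrap_pad) if subject.circular else 0
    qx = query.residues + query.residues[:qpad]
    sx = subject.residues + subject.residues[:spad]
    q_arr = _encode(qx)
    qb = q_arr.tobytes()
    qc = _kmer_codes(q_arr, k)

    # score floor implied by (min_len, min_ident): an ungapped hit at the
    # identity threshold scores (3*ident - 2) per column
    floor = max(k, math.floor((3 * min_ident / 100.0 - 2.0) * min_len))

    selected: list[LocalAlignment] = []
    candidates: list[LocalAlignment] = []
    for strand in "+-":
        s_str = sx if strand == "+" else revcomp(sx)
        s_arr = _encode(s_str)
        sb = s_arr.tobytes()
        sc = _kmer_codes(s_arr, k)
        qpos, spos = _seed_matches(qc, sc)
        if _self_mode and strand == "+":
            keep = (qpos - spos) % Lq != 0
            qpos, spos = qpos[keep], spos[keep]
        raw = _ungapped_hits(qb, sb, qpos, spos, k)
        raw = _merge_collinear(raw)
        SXL = len(s_str)
        for h in raw:
            if strand == "+":
                ss_f, se_f = h.ss + 1, h.se + 1
            else:
                ss_f, se_f = SXL - (h.se + 1) + 1, SXL - (h.ss + 1) + 1
            aln = LocalAlignment(
                q_id=query.id, s_id=subject.id,
                q_start=h.qs + 1, q_end=h.qe + 1,
                s_start=ss_f, s_end=se_f, strand=strand,
                matches=h.matches, mismatches=h.mismatches,
                gap_columns=h.gap_columns, gap_opens=h.gap_opens,
                score=h.score,
            )
            # drop pad duplicates: same alignment shifted by one full turn
            if aln.q_start > Lq or aln.s_start > Ls:
                continue
            if aln.aln_len < min_len or aln.identity < min_ident or aln.score < floor:
                continue
            candidates.append(aln)

    candidates.sort(key=lambda a: (-a.score, a.q_start, a.s_start, a.strand))
    for aln in candidates:
        qi = aln.q_interval(Lq if query.circular else None)
        si = aln.s_interval(Ls if subject.circular else None)
        redundant = False
        for kept in selected:
            if kept.strand != aln.strand:
                continue
            kqi = kept.q_interval(Lq if query.circular else None)
            ksi = kept.s_interval(Ls if subject.circular else None)
            if (_overlap_frac(qi, kqi, Lq) > 0.5 and _overlap_frac(si, ksi, Ls) > 0.5):
                redundant = True
                break
        if not redundant:
            selected.append(aln)
    selected.sort(key=lambda a: (a.q_start, a.s_start, a.strand))
    return selected


def self_repeats(
    genome: CircularSequence, min_len: int = 50, min_ident: float = 80.0
) -> list[RepeatPair]:
    """Interspersed repeat pairs from a self-vs-self search.

    The trivial full-length identity diagonal is removed, symmetric
    (A,B)/(B,A) duplicates collapsed, and self-overlapping hits (tandem or
    palindromic, whose two copies would not be disjoint) discarded.  Pairs
    are labeled direct (+) or inverted (-).
    """
    if genome.length <= 2 * min_len:
        raise ValueError("genome too short for repeat search")
    alns = local_align_all(genome, genome, min_len, min_ident, _self_mode=True)
    L = genome.length if genome.circular else None
    seen = set()
    pairs = []
    for aln in alns:
        qi = aln.q_interval(L, kind="repeat")
        si = aln.s_interval(L, kind="repeat")
        if (qi.start, qi.end) == (si.start, si.end):
            continue
        if qi.overlaps(si, genome.length):
            continue
        a, b = sorted([qi, si], key=lambda iv: (iv.start, iv.end))
        key = (a.start, a.end, b.start, b.end, aln.strand)
        if key in seen:
            continue
        seen.add(key)
        orientation = "direct" if aln.strand == "+" else "inverted"
        pairs.append((a, b, orientation, aln))
    pairs.sort(key=lambda t: (t[0].start, t[0].end, t[1].start, t[1].end))
    out = []
    for i, (a, b, orientation, aln) in enumerate(pairs, start=1):
        out.append(
            RepeatPair(
                id=f"rep{i:03d}", copyA=a, copyB=b, orientation=orientation,
                rep_len=a.span_length(genome.length),
                identity=aln.identity,
            )
        )
    return out


def repeat_span_stats(genome: CircularSequence, pairs: Iterable[RepeatPair]) -> tuple[int, float]:
    """Union length of all repeat-copy intervals and its percent of the genome.

    The union (not the sum) is used so overlapping copies are not double
    counted.
    """
    covered = np.zeros(genome.length, dtype=bool)
    for p in pairs:
        for iv in (p.copyA, p.copyB):
            if iv.wraps:
                covered[iv.start - 1 :] = True
                covered[: iv.end] = True
            else:
                covered[iv.start - 1 : iv.end] = True
    union_bp = int(covered.sum())
    return union_bp, 100.0 * union_bp / genome.length


def repeat_fraction_percent(union_bp: int, genome_len: int, digits: int = 2) -> float:
    """Percent of a genome occupied by repeats, from the two totals."""
    return round(100.0 * union_bp / genome_len, digits)


def alignments_to_table(alns: Iterable[LocalAlignment]) -> pd.DataFrame:
    """BLAST outfmt-6-style table (sstart > send encodes minus-strand hits)."""
    rows = []
    for a in alns:
        ss, se = (a.s_start, a.s_end) if a.strand == "+" else (a.s_end, a.s_start)
        rows.append(
            dict(qseqid=a.q_id, sseqid=a.s_id, pident=round(a.identity, 2),
                 length=a.aln_len, mismatch=a.mismatches, gapopen=a.gap_opens,
                 qstart=a.q_start, qend=a.q_end, sstart=ss, send=se, score=a.score)
        )
    return pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "pident", "length", "mismatch",
                       "gapopen", "qstart", "qend", "sstart", "send", "score"]
    )
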