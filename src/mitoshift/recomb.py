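"""Read-pair support for repeat-mediated recombination.

For every repeat pair shorter than the library insert size, two principal
references (each copy with its own flanks) and two alternative-conformation
references (the flank arrangements produced by homologous exchange between
the copies) are built.  Read pairs are placed end-to-end, ungapped, with a
mismatch cap; a pair supports an alternative conformation when it places
there, fails on both principal references, and anchors in both flanks
across the repeat (junction-spanning evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mitoshift.genome import CircularSequence, extract, revcomp
from mitoshift.homology import RepeatPair

DEFAULT_FLANK = 300
DEFAULT_INSERT_CAP = 350
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_ANCHOR = 5

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


@dataclass(frozen=True)
class ReadPair:
    id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"read pair {self.id!r} has an empty mate")


@dataclass
class ConformationSet:
    """Principal and alternative junction references for one repeat pair.

    ``junctions[ref_name]`` is the 1-based inclusive span of the repeat core
    within that reference; the flanks are everything outside it.
    """

    repeat_id: str
    flank: int
    principalA: str
    principalB: str
    alt1: str
    alt2: str
    junctions: dict = field(default_factory=dict)
    truncated: bool = False


@dataclass
class Placement:
    fwd_start: int  # 1-based start of the forward-oriented mate
    fwd_end: int
    rev_start: int  # 1-based start of the reverse-complemented mate
    rev_end: int
    mismatches: int
    mate1_forward: bool

    @property
    def frag_start(self) -> int:
        return self.fwd_start

    @property
    def frag_end(self) -> int:
        return self.rev_end


@dataclass
class RecombSupport:
    repeat_id: str
    n_alt1: int = 0
    n_alt2: int = 0
    supporting_ids: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_alt1 + self.n_alt2


def _slice_circ(genome: CircularSequence, start: int, end: int) -> tuple[str, bool]:
    """Residues start..end (1-based, may run off either end).

    On a circular genome the coordinates wrap; on a linear one they are
    clamped and the second return value flags the truncation.
    """
    L = genome.length
    if start >= 1 and end <= L:
        return genome.residues[start - 1 : end], False
    if genome.circular:
        idx = [((p - 1) % L) for p in range(start, end + 1)]
        return "".join(genome.residues[i] for i in idx), False
    s, e = max(start, 1), min(end, L)
    return (genome.residues[s - 1 : e] if s <= e else ""), True


def build_conformations(
    genome: CircularSequence, pair: RepeatPair, flank: int = DEFAULT_FLANK
) -> ConformationSet:
    """Build principal and alternative junction references for a repeat pair.

    With copyA context A_L·R·A_R and copyB context B_L·R_B·B_R (forward
    strand), the recombined arrangements are

    * direct repeats:   alt1 = A_L·R·B_R   alt2 = B_L·R·A_R
    * inverted repeats: alt1 = A_L·R·revcomp(B_L)   alt2 = revcomp(B_R)·R·A_R

    where R is copyA's own repeat sequence (the copies may diverge up to
    the repeat-identity threshold; the mismatch cap of the read placement
    absorbs that divergence).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    a, b = pair.copyA, pair.copyB
    L = genome.length
    ra = extract(genome, a)
    rb = extract(genome, b)
    a_end = a.end if not a.wraps else a.end + L
    b_end = b.end if not b.wraps else b.end + L
    al, t1 = _slice_circ(genome, a.start - flank, a.start - 1)
    ar, t2 = _slice_circ(genome, a_end + 1, a_end + flank)
    bl, t3 = _slice_circ(genome, b.start - flank, b.start - 1)
    br, t4 = _slice_circ(genome, b_end + 1, b_end + flank)
    if pair.orientation == "direct":
        alt1 = al + ra + br
        alt2 = bl + ra + ar
        j_alt2 = (len(bl) + 1, len(bl) + len(ra))
    else:
        alt1 = al + ra + revcomp(bl)
        alt2 = revcomp(br) + ra + ar
        j_alt2 = (len(br) + 1, len(br) + len(ra))
    return ConformationSet(
        repeat_id=pair.id,
        flank=flank,
        principalA=al + ra + ar,
        principalB=bl + rb + br,
        alt1=alt1,
        alt2=alt2,
        junctions={
            "principalA": (len(al) + 1, len(al) + len(ra)),
            "principalB": (len(bl) + 1, len(bl) + len(rb)),
            "alt1": (len(al) + 1, len(al) + len(ra)),
            "alt2": j_alt2,
        },
        truncated=t1 or t2 or t3 or t4,
    )


def _mismatch_profile(mate: str, ref_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of ``mate`` at every end-to-end offset of the reference."""
    m = _ENC[np.frombuffer(mate.encode(), dtype=np.uint8)]
    n = len(ref_arr) - len(m) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, len(m))
    return np.asarray((windows != m).sum(axis=1), dtype=np.int64)


def place_pair(
    rp: ReadPair, ref: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> Placement | None:
    """Best unique end-to-end ungapped placement of a read pair, or None.

    Both mates must align full-length with at most ``max_mismatch``
    mismatches each, in forward-reverse orientation with ordered mate
    intervals.  Ties for the best total mismatch count yield None.
    """
    if len(rp.mate1) > len(ref) or len(rp.mate2) > len(ref):
        return None
    ref_arr = _ENC[np.frombuffer(ref.encode(), dtype=np.uint8)]
    candidates: list[Placement] = []
    for mate1_forward in (True, False):
        fwd = rp.mate1 if mate1_forward else rp.mate2
        rev = rp.mate2 if mate1_forward else rp.mate1
        mm_f = _mismatch_profile(fwd, ref_arr)
        mm_r = _mismatch_profile(revcomp(rev), ref_arr)
        off_f = np.nonzero(mm_f <= max_mismatch)[0]
        off_r = np.nonzero(mm_r <= max_mismatch)[0]
        for i in off_f:
            for j in off_r:
                if j < i:
                    continue
                candidates.append(
                    Placement(
                        fwd_start=int(i) + 1,
                        fwd_end=int(i) + len(fwd),
                        rev_start=int(j) + 1,
                        rev_end=int(j) + len(rev),
                        mismatches=int(mm_f[i] + mm_r[j]),
                        mate1_forward=mate1_forward,
                    )
                )
    if not candidates:
        return None
    best = min(c.mismatches for c in candidates)
    winners = [c for c in candidates if c.mismatches == best]
    if len(winners) > 1:
        return None
    return winners[0]


def _supports(
    placement: Placement, junction: tuple[int, int], min_anchor: int
) -> bool:
    rs, re = junction
    return (rs - placement.frag_start) >= min_anchor and (
        placement.frag_end - re
    ) >= min_anchor


def count_support(
    reads: Sequence[ReadPair],
    conf: ConformationSet,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> RecombSupport:
    """Count read pairs supporting either alternative conformation.

    A pair supports alt_k iff it places on alt_k, fails on BOTH principal
    references, and its fragment extends at least ``min_anchor`` nt into
    each of alt_k's flanks.  Each read id is counted at most once.
    """
    ids = [rp.id for rp in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in input")
    support = RecombSupport(repeat_id=conf.repeat_id)
    for rp in reads:
        if place_pair(rp, conf.principalA, max_mismatch) is not None:
            continue
        if place_pair(rp, conf.principalB, max_mismatch) is not None:
            continue
        p1 = place_pair(rp, conf.alt1, max_mismatch)
        if p1 is not None and _supports(p1, conf.junctions["alt1"], min_anchor):
            support.n_alt1 += 1
            support.supporting_ids.append(rp.id)
            continue
        p2 = place_pair(rp, conf.alt2, max_mismatch)
        if p2 is not None and _supports(p2, conf.junctions["alt2"], min_anchor):
            support.n_alt2 += 1
            support.supporting_ids.append(rp.id)
    return support


def screen_all(
    genome: CircularSequence,
    repeats: Sequence[RepeatPair],
    reads: Sequence[ReadPair],
    insert_cap: int = DEFAULT_INSERT_CAP,
    flank: int = DEFAULT_FLANK,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[tuple[RepeatPair, RecombSupport]]:
    """Assess recombination activity for all repeat pairs < ``insert_cap``."""
    out = []
    for pair in repeats:
        if pair.rep_len >= insert_cap:
            continue
        conf = build_conformations(genome, pair, flank=flank)
        out.append((pair, count_support(reads, conf, max_mismatch, min_anchor)))
    return out


def support_table(results: Iterable[tuple[RepeatPair, RecombSupport]]) -> pd.DataFrame:
    rows = []
    for pair, sup in results:
        rows.append(
            dict(
                repeat_id=pair.id,
                copyA=f"{pair.copyA.start}..{pair.copyA.end}",
                copyB=f"{pair.copyB.start}..{pair.copyB.end}",
                orientation=pair.orientation,
                rep_len=pair.rep_len,
                identity=round(pair.identity, 2),
                n_alt1=sup.n_alt1,
                n_alt2=sup.n_alt2,
                n_total=sup.n_total,
            )
        )
    return pd.DataFrame(
        rows, columns=["repeat_id", "copyA", "copyB", "orientation", "rep_len",
                       "identity", "n_alt1", "n_alt2", "n_total"]
    )


def write_paired_fastq(
    pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    """Write mates to two FASTQ files with constant quality."""
    for path, attr in ((path1, "mate1"), (path2, "mate2")):
        records = []
        for rp in pairs:
            seq = getattr(rp, attr)
            rec = SeqRecord(Seq(seq), id=rp.id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read paired FASTQ files (qualities are read but unused)."""
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files have different read counts")
    pairs = []
    for a, b in zip(r1, r2):
        if a.id != b.id:
            raise ValueError(f"mate id mismatch: {a.id} vs {b.id}")
        pairs.append(ReadPair(id=a.id, mate1=str(a.seq).upper(), mate2=str(b.seq).upper()))
    return pairs
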