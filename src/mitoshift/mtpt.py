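"""Mitochondrial plastid insertions (MTPTs) and the fate of their genes.

Plant mitogenomes routinely carry stretches of plastid-derived DNA.  These
are found here by local alignment of the mitogenome against its plastome
(length > 100 bp, identity >= 80%); hits overlapping on mitochondrial
coordinates are merged into regions.  Plastid genes contained in a region
are called intact only when the transferred copy covers >= 95% of the
gene, implies no net frame-shifting indel, and translates without an
internal stop; otherwise the first failing rule names the pseudogene class
(pseudo_truncated, pseudo_frameshift, pseudo_internal_stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from mitoshift.genome import CircularSequence, FeatureInterval, GeneModel, extract
from mitoshift.homology import local_align_all

DEFAULT_MIN_LEN = 101  # "> 100 bp" as a strict inequality
DEFAULT_MIN_IDENT = 80.0
DEFAULT_INTACT_COVERAGE = 0.95


@dataclass
class MtptRegion:
    mito_iv: FeatureInterval
    plastid_iv: FeatureInterval
    strand: str
    identity: float
    length: int
    genes: list = field(default_factory=list)  # (gene name, status)


def find_mtpt(
    mito: CircularSequence,
    plastome: CircularSequence,
    min_len: int = DEFAULT_MIN_LEN,
    min_ident: float = DEFAULT_MIN_IDENT,
) -> list[MtptRegion]:
    """Plastid-derived regions of the mitogenome, merged and sorted.

    Hits overlapping on mitochondrial coordinates are merged into one
    region (union interval, length-weighted mean identity, the plastid
    interval of the longest component); regions are sorted by mito
    position.  Merging is idempotent because merged regions are disjoint.
    """
    alns = local_align_all(mito, plastome, min_len=min_len, min_ident=min_ident)
    hits = []
    for a in alns:
        if a.aln_len < min_len or a.identity < min_ident:
            continue
        # extended (unwrapped) mito coordinates keep the merge arithmetic linear
        hits.append((a.q_start, a.q_end, a))
    hits.sort()
    regions: list[MtptRegion] = []
    i = 0
    L = mito.length
    while i < len(hits):
        s, e, a = hits[i]
        comps = [a]
        j = i + 1
        while j < len(hits) and hits[j][0] <= e:
            e = max(e, hits[j][1])
            comps.append(hits[j][2])
            j += 1
        i = j
        longest = max(comps, key=lambda c: c.aln_len)
        w = np.array([c.aln_len for c in comps], dtype=float)
        ident = float(np.average([c.identity for c in comps], weights=w))
        mito_iv = FeatureInterval(
            seq_id=mito.id,
            start=((s - 1) % L) + 1 if e > L else s,
            end=((e - 1) % L) + 1 if e > L else e,
            strand="+",
            kind="MTPT",
        )
        regions.append(
            MtptRegion(
                mito_iv=mito_iv,
                plastid_iv=longest.s_interval(plastome.length if plastome.circular else None, kind="MTPT"),
                strand=longest.strand,
                identity=ident,
                length=e - s + 1,
            )
        )
    regions.sort(key=lambda r: (r.mito_iv.start, r.mito_iv.end))
    return regions


def mtpt_summary(regions: Sequence[MtptRegion], genome_len: int) -> dict:
    """Region count, length range, identity range and percent genome covered."""
    if not regions:
        return dict(count=0, min_len=0, max_len=0, min_identity=0.0,
                    max_identity=0.0, coverage_pct=0.0)
    covered = np.zeros(genome_len, dtype=bool)
    for r in regions:
        iv = r.mito_iv
        if iv.wraps:
            covered[iv.start - 1 :] = True
            covered[: iv.end] = True
        else:
            covered[iv.start - 1 : iv.end] = True
    return dict(
        count=len(regions),
        min_len=min(r.length for r in regions),
        max_len=max(r.length for r in regions),
        min_identity=round(min(r.identity for r in regions), 1),
        max_identity=round(max(r.identity for r in regions), 1),
        coverage_pct=round(100.0 * covered.sum() / genome_len, 1),
    )


def _gene_status(
    cds: str,
    region_seq: str,
    product_kind: str,
    intact_coverage: float,
) -> str:
    query = CircularSequence(id="cds", residues=cds)
    subject = CircularSequence(id="region", residues=region_seq)
    try:
        hits = local_align_all(query, subject, min_len=30, min_ident=75.0)
    except ValueError:
        hits = []
    if not hits:
        return "pseudo_truncated"
    covered = np.zeros(len(cds), dtype=bool)
    for h in hits:
        covered[h.q_start - 1 : h.q_end] = True
    if covered.sum() < intact_coverage * len(cds):
        return "pseudo_truncated"
    if product_kind != "protein":
        return "intact"
    hits = sorted(hits, key=lambda h: h.q_start)
    # net indel within any hit, or between consecutive colinear hits
    strand = hits[0].strand
    for h in hits:
        shift = (h.s_end - h.s_start) - (h.q_end - h.q_start)
        if shift % 3 != 0:
            return "pseudo_frameshift"
    for a, b in zip(hits, hits[1:]):
        if b.strand != strand:
            continue
        if strand == "+":
            step = (b.s_start - a.s_end) - (b.q_start - a.q_end)
        else:
            step = (a.s_start - b.s_end) - (b.q_start - a.q_end)
        if step % 3 != 0:
            return "pseudo_frameshift"
    # reconstruct the transferred copy in CDS order and translate in frame
    parts = []
    first_q = hits[0].q_start
    for h in hits:
        seg = region_seq[h.s_start - 1 : h.s_end]
        if h.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    merged = "".join(parts)
    lead = (3 - (first_q - 1) % 3) % 3
    merged = merged[lead:]
    merged = merged[: len(merged) - len(merged) % 3]
    if not merged:
        return "pseudo_truncated"
    protein = str(Seq(merged).translate())
    if "*" in protein[:-1]:
        return "pseudo_internal_stop"
    return "intact"


def call_mtpt_genes(
    regions: Sequence[MtptRegion],
    plastid_genes: Sequence[GeneModel],
    mito: CircularSequence,
    plastome: CircularSequence,
    intact_coverage: float = DEFAULT_INTACT_COVERAGE,
) -> list[MtptRegion]:
    """Annotate each region with the plastid genes it contains and their status."""
    for gm in plastid_genes:
        for ex in gm.exons:
            if ex.seq_id != plastome.id:
                raise ValueError(
                    f"gene {gm.gene!r} is not annotated on plastome {plastome.id!r}"
                )
    for region in regions:
        region.genes = []
        region_seq = extract(mito, region.mito_iv)
        for gm in plastid_genes:
            if not any(ex.overlaps(region.plastid_iv, plastome.length) for ex in gm.exons):
                continue
            cds = "".join(extract(plastome, ex) for ex in gm.exons)
            status = _gene_status(cds, region_seq, gm.product_kind, intact_coverage)
            region.genes.append((gm.gene, status))
    return list(regions)


def mtpt_table(regions: Sequence[MtptRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            dict(
                mito_start=r.mito_iv.start,
                mito_end=r.mito_iv.end,
                plastid_start=r.plastid_iv.start,
                plastid_end=r.plastid_iv.end,
                strand=r.strand,
                length=r.length,
                identity=round(r.identity, 1),
                genes=";".join(f"{g}({s})" for g, s in r.genes) or ".",
            )
        )
    return pd.DataFrame(
        rows, columns=["mito_start", "mito_end", "plastid_start", "plastid_end",
                       "strand", "length", "identity", "genes"]
    )
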