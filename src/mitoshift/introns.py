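"""Cis/trans classification of mitochondrial introns and breakpoint synteny.

Plant mitochondrial group II introns are spliced in cis when their flanking
exons sit on one contiguous precursor transcript, and in trans when a
genomic rearrangement has broken the intron so the exons are transcribed
from separate loci.  Introns are named gene + "i" + the reference-CDS
nucleotide after which they are inserted (nad1i728 = after nt 728 of the
nad1 CDS).  Classification is purely positional: consecutive exons (in CDS
order) that are on the same strand, colinear in transcription direction and
separated by at most ``max_intron_len`` are contiguous; anything else is a
raw trans split.  Five introns known to be trans-spliced in the common
ancestor of seed plants are forced to trans even when their exons happen to
be contiguous (the ancestral-trans override), because a reversal from trans
back to cis splicing is considered implausible.

For a trans intron, ``map_breakpoints`` aligns the homologous intron of a
cis-spliced reference genome against the regions flanking the two split
exons, measuring how much of each intron end is retained and how much of
the middle was lost in the rearrangement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from mitoshift.genome import CircularSequence, FeatureInterval
from mitoshift.homology import LocalAlignment, local_align_all


class GeneNotFoundError(ValueError):
    pass


class MalformedAnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class IntronRecord:
    name: str
    gene: str
    insertion_pos: int
    group: str = "II"
    ancestral_trans: bool = False

    def __post_init__(self) -> None:
        if self.insertion_pos < 1:
            raise ValueError(f"{self.name}: insertion_pos must be >= 1")
        if self.group not in {"I", "II"}:
            raise ValueError(f"{self.name}: group must be I or II")


#: Canonical intron registry. Only introns with established published names
#: are shipped; further canonical angiosperm introns can be supplied via a
#: registry TSV. The five ancestral-trans introns are flagged.
DEFAULT_REGISTRY: tuple[IntronRecord, ...] = (
    IntronRecord("cox1i729", "cox1", 729, group="I"),
    IntronRecord("cox2i373", "cox2", 373),
    IntronRecord("nad1i394", "nad1", 394, ancestral_trans=True),
    IntronRecord("nad1i669", "nad1", 669, ancestral_trans=True),
    IntronRecord("nad1i728", "nad1", 728),
    IntronRecord("nad2i156", "nad2", 156),
    IntronRecord("nad2i542", "nad2", 542, ancestral_trans=True),
    IntronRecord("nad2i709", "nad2", 709),
    IntronRecord("nad4i976", "nad4", 976),
    IntronRecord("nad5i1455", "nad5", 1455, ancestral_trans=True),
    IntronRecord("nad5i1477", "nad5", 1477, ancestral_trans=True),
    IntronRecord("rps3i74", "rps3", 74),
)

_REGISTRY_FIELDS = ["name", "gene", "insertion_pos", "group", "ancestral_trans"]


def read_registry(path: str | Path) -> list[IntronRecord]:
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                IntronRecord(
                    name=row["name"],
                    gene=row["gene"],
                    insertion_pos=int(row["insertion_pos"]),
                    group=row["group"],
                    ancestral_trans=row["ancestral_trans"].lower() in {"true", "1", "yes"},
                )
            )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate intron names in registry")
    return records


def write_registry(records: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_REGISTRY_FIELDS)
        for r in records:
            w.writerow([r.name, r.gene, r.insertion_pos, r.group, str(r.ancestral_trans).lower()])


@dataclass
class ExonPlacement:
    """Placement of one CDS segment (exon) on the genome."""

    gene: str
    exon_index: int
    genome_iv: FeatureInterval
    cds_start: int
    cds_end: int
    identity: float

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start must be <= cds_end")


@dataclass
class IntronCall:
    intron: IntronRecord
    mode: str  # cis | trans
    raw_adjacency: str  # contiguous | split
    override_applied: bool
    upstream_exon: ExonPlacement
    downstream_exon: ExonPlacement
    genome_gap: int | None


@dataclass
class SyntenyBlock:
    """Retained/lost portions of a reference cis intron around a trans break."""

    intron_name: str
    retained5_len: int
    retained3_len: int
    lost_mid_len: int
    mito5: FeatureInterval | None
    mito3: FeatureInterval | None
    ref5: tuple[int, int] | None
    ref3: tuple[int, int] | None
    warning: bool = False


def locate_exons(
    gene_cds: str,
    genome: CircularSequence,
    gene: str = "gene",
    min_exon_len: int = 25,
    min_ident: float = 85.0,
) -> list[ExonPlacement]:
    """Place a gene's CDS on the genome as a set of colinear-in-CDS exons.

    Local hits of the CDS against both genome strands are chained greedily
    by score so that every CDS position is covered at most once (overlapping
    hit ends are trimmed).  Raises GeneNotFoundError when less than half of
    the CDS can be placed.
    """
    if len(gene_cds) < 60:
        raise ValueError(f"{gene}: CDS shorter than 60 nt")
    query = CircularSequence(id=f"{gene}_cds", residues=gene_cds)
    alns = local_align_all(query, genome, min_len=min_exon_len, min_ident=min_ident)
    covered = np.zeros(len(gene_cds), dtype=bool)
    placed: list[tuple[int, int, LocalAlignment, int, int]] = []
    for aln in sorted(alns, key=lambda a: (-a.score, a.q_start, a.s_start)):
        a1, a2 = aln.q_start, aln.q_end
        free = ~covered[a1 - 1 : a2]
        if free.sum() < max(15, min_exon_len // 2):
            continue
        # largest contiguous free run within the hit's CDS span
        runs, start = [], None
        for off, f in enumerate(free):
            if f and start is None:
                start = off
            elif not f and start is not None:
                runs.append((start, off - 1))
                start = None
        if start is not None:
            runs.append((start, len(free) - 1))
        r0, r1 = max(runs, key=lambda r: r[1] - r[0])
        left_trim = r0
        right_trim = (a2 - a1) - r1
        c1, c2 = a1 + r0, a1 + r1  # cds span after trimming to the free run
        if aln.strand == "+":
            s1 = aln.s_start + left_trim
            s2 = aln.s_end - right_trim
        else:
            s1 = aln.s_start + right_trim
            s2 = aln.s_end - left_trim
        covered[c1 - 1 : c2] = True
        placed.append((c1, c2, aln, s1, s2))
    if covered.sum() < 0.5 * len(gene_cds):
        raise GeneNotFoundError(
            f"gene {gene!r} not found: only {int(covered.sum())}/{len(gene_cds)} "
            "CDS nt could be placed"
        )
    placed.sort(key=lambda t: t[0])
    L = genome.length if genome.circular else None
    out = []
    for idx, (c1, c2, aln, s1, s2) in enumerate(placed, start=1):
        if L is not None and s2 > genome.length:
            s1 = ((s1 - 1) % genome.length) + 1
            s2 = ((s2 - 1) % genome.length) + 1
        iv = FeatureInterval(
            seq_id=genome.id, start=s1, end=s2, strand=aln.strand,
            kind="exon", attributes={"gene": gene},
        )
        out.append(
            ExonPlacement(gene=gene, exon_index=idx, genome_iv=iv,
                          cds_start=c1, cds_end=c2, identity=aln.identity)
        )
    return out


def name_intron(gene: str, upstream_exon: ExonPlacement) -> str:
    """nad1 + upstream exon ending at CDS nt 728 -> "nad1i728"."""
    return f"{gene}i{upstream_exon.cds_end}"


def _transcription_gap(
    up: ExonPlacement, down: ExonPlacement, genome_len: int | None, circular: bool
) -> int | None:
    """Gap (nt) between two exons in transcription direction, or None if
    they are on different strands / not colinear."""
    ui, di = up.genome_iv, down.genome_iv
    if ui.strand != di.strand:
        return None
    if ui.strand == "+":
        gap = di.start - ui.end - 1
    else:
        gap = ui.start - di.end - 1
    if gap < 0 and circular and genome_len is not None:
        gap += genome_len
    return gap if gap >= 0 else None


def classify_introns(
    placements: Sequence[ExonPlacement],
    registry: Sequence[IntronRecord] = DEFAULT_REGISTRY,
    max_intron_len: int = 10000,
    genome_len: int | None = None,
    circular: bool = True,
    snap_tol: int = 15,
) -> list[IntronCall]:
    """Call cis/trans for every intron implied by consecutive exon placements.

    contiguous = same strand, colinear in the transcription direction of the
    upstream exon, and 0 <= gap <= max_intron_len (a circular wrap counts as
    contiguous when the wrapped gap satisfies the length rule).  mode =
    trans when the adjacency is split or when the registry marks the intron
    ancestral-trans (override_applied in the latter, contiguous case).
    """
    by_name = {r.name: r for r in registry}
    by_gene: dict[str, list[ExonPlacement]] = {}
    for p in placements:
        by_gene.setdefault(p.gene, []).append(p)
    calls = []
    for gene_name in sorted(by_gene):
        pls = sorted(by_gene[gene_name], key=lambda p: p.cds_start)
        for up, down in zip(pls, pls[1:]):
            if up.genome_iv.overlaps(down.genome_iv, genome_len):
                raise MalformedAnnotationError(
                    f"gene {gene_name!r}: consecutive exons have overlapping "
                    f"genome intervals ({up.genome_iv.start}..{up.genome_iv.end} vs "
                    f"{down.genome_iv.start}..{down.genome_iv.end})"
                )
            gap = _transcription_gap(up, down, genome_len, circular)
            contiguous = gap is not None and gap <= max_intron_len
            name = name_intron(gene_name, up)
            rec = by_name.get(name)
            if rec is None:
                # local-alignment ends can overrun a splice boundary by a
                # couple of bases; snap to the nearest canonical site
                near = [
                    r for r in registry
                    if r.gene == gene_name
                    and abs(r.insertion_pos - up.cds_end) <= snap_tol
                ]
                if near:
                    rec = min(near, key=lambda r: abs(r.insertion_pos - up.cds_end))
            if rec is None:
                rec = IntronRecord(name=name, gene=gene_name, insertion_pos=up.cds_end)
            if not contiguous:
                mode, raw, override = "trans", "split", False
            elif rec.ancestral_trans:
                mode, raw, override = "trans", "contiguous", True
            else:
                mode, raw, override = "cis", "contiguous", False
            calls.append(
                IntronCall(
                    intron=rec, mode=mode, raw_adjacency=raw,
                    override_applied=override, upstream_exon=up,
                    downstream_exon=down,
                    genome_gap=gap if contiguous else None,
                )
            )
    return calls


def _circ_dist(a: int, b: int, L: int | None) -> int:
    d = abs(a - b)
    if L is None:
        return d
    return min(d, L - d)


def map_breakpoints(
    call: IntronCall,
    ref_intron: str,
    genome: CircularSequence,
    min_ident: float = 80.0,
    tol: int = 15,
    window_pad: int = 2000,
) -> SyntenyBlock:
    """Map a trans intron's breakpoints against the homologous cis intron.

    The reference intron is aligned to the genome; a hit containing the
    reference's first base and lying next to the upstream split exon gives
    the retained 5' length, a hit containing the last base next to the
    downstream exon gives the retained 3' length, and the unmatched middle
    is reported as lost.
    """
    if call.mode != "trans":
        raise ValueError("breakpoint mapping is defined for trans introns only")
    L_ref = len(ref_intron)
    ref = CircularSequence(id=f"{call.intron.name}_ref", residues=ref_intron)
    alns = local_align_all(ref, genome, min_len=30, min_ident=min_ident)
    GL = genome.length if genome.circular else None
    reach = L_ref + window_pad

    up_iv = call.upstream_exon.genome_iv
    down_iv = call.downstream_exon.genome_iv
    # genomic point where each retained intron end should start, in the
    # transcription direction of its exon
    up_anchor = up_iv.end if up_iv.strand == "+" else up_iv.start
    down_anchor = down_iv.start if down_iv.strand == "+" else down_iv.end

    retained5 = retained3 = 0
    hit5 = hit3 = None
    for aln in alns:
        si = aln.s_interval(genome.length if genome.circular else None)
        near_up = min(
            _circ_dist(si.start, up_anchor, GL), _circ_dist(si.end, up_anchor, GL)
        ) <= reach
        near_down = min(
            _circ_dist(si.start, down_anchor, GL), _circ_dist(si.end, down_anchor, GL)
        ) <= reach
        if aln.q_start <= 1 + tol and near_up and aln.q_end > retained5:
            retained5 = aln.q_end
            hit5 = (si, (aln.q_start, aln.q_end))
        if aln.q_end >= L_ref - tol and near_down and (L_ref - aln.q_start + 1) > retained3:
            retained3 = L_ref - aln.q_start + 1
            hit3 = (si, (aln.q_start, aln.q_end))
    lost = max(L_ref - retained5 - retained3, 0)
    return SyntenyBlock(
        intron_name=call.intron.name,
        retained5_len=retained5,
        retained3_len=retained3,
        lost_mid_len=lost,
        mito5=hit5[0] if hit5 else None,
        mito3=hit3[0] if hit3 else None,
        ref5=hit5[1] if hit5 else None,
        ref3=hit3[1] if hit3 else None,
        warning=(hit5 is None and hit3 is None),
    )
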