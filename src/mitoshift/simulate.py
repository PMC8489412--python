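"""Synthetic mitogenomes, plastomes, reads and clade alignments with truth.

Every input the pipeline consumes can be generated here with planted ground
truth: a circular toy mitogenome carrying genes with cis and trans introns
(trans splits relocate one intron half, optionally inverted, optionally
deleting a middle portion of the ancestral intron), interspersed repeat
pairs, plastid-derived insertions copied from a generated toy plastome,
paired-end reads with a truncated-normal insert-size distribution, and a
multi-clade gene alignment with an optional planted conversion segment.

All randomness flows from a single integer seed per generator call; the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mitoshift.chimera import MultipleAlignment
from mitoshift.genome import (
    CircularSequence,
    FeatureInterval,
    GeneModel,
    revcomp,
)
from mitoshift.homology import RepeatPair
from mitoshift.introns import DEFAULT_REGISTRY
from mitoshift.recomb import ReadPair

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


class PlacementError(RuntimeError):
    """Feature placement failed after the retry budget (config too dense)."""


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.44) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def random_cds(rng: np.random.Generator, n: int) -> str:
    """A translatable CDS: ATG then sense codons (no internal stop)."""
    if n % 3:
        raise ValueError("CDS length must be a multiple of 3")
    codons = rng.choice(len(_SENSE_CODONS), size=n // 3 - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in codons)


def mutate(rng: np.random.Generator, s: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (to a different base)."""
    arr = np.array(list(s))
    hit = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def mutate_n(rng: np.random.Generator, s: str, n_subs: int) -> str:
    arr = np.array(list(s))
    for i in rng.choice(len(s), size=min(n_subs, len(s)), replace=False):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# --- configuration ---------------------------------------------------------


@dataclass(frozen=True)
class IntronSpec:
    """One intron of a gene: CDS insertion position and planted mode."""

    position: int
    length: int = 1200
    mode: str = "cis"  # planted arrangement: cis | trans
    invert: bool = False  # trans: place the downstream fragment inverted
    distance: int | None = None  # trans: genomic separation of the fragments
    middle_loss: int = 0  # trans: nt of the ancestral intron deleted at the break


@dataclass(frozen=True)
class GeneSpec:
    name: str
    cds_len: int
    introns: tuple[IntronSpec, ...] = ()


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    identity: float = 100.0
    orientation: str = "direct"


@dataclass(frozen=True)
class MtptSpec:
    count: int = 10
    min_len: int = 150
    max_len: int = 2500
    max_divergence: float = 0.05


@dataclass(frozen=True)
class ReadConfig:
    n_pairs: int = 2000
    read_len: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.001


def default_genes() -> tuple[GeneSpec, ...]:
    """Gene set echoing the intron inventory of a rearranged mitogenome.

    Arrangements mirror the observed pattern: cox1i729 and nad2i156 are
    cis, nad1i394 is planted cis but called trans through the
    ancestral-trans override, and the rest are genuine genomic splits
    (nad1i728 broken 14 kb away with an 866 nt middle loss).
    """
    return (
        GeneSpec("cox1", 1584, (IntronSpec(729, length=1100, mode="cis"),)),
        GeneSpec("cox2", 783, (IntronSpec(373, 1300, "trans", invert=True, middle_loss=400),)),
        GeneSpec("nad1", 978, (
            IntronSpec(394, 1500, "cis"),
            IntronSpec(669, 1400, "trans"),
            IntronSpec(728, 1700, "trans", distance=14000, middle_loss=866),
        )),
        GeneSpec("nad2", 1467, (
            IntronSpec(156, 1200, "cis"),
            IntronSpec(542, 1500, "trans", invert=True),
            IntronSpec(709, 1300, "trans"),
        )),
        GeneSpec("nad4", 1488, (IntronSpec(976, 1250, "trans"),)),
        GeneSpec("nad5", 2013, (IntronSpec(1455, 1350, "trans"),)),
        GeneSpec("rps3", 1674, (IntronSpec(74, 1100, "trans"),)),
    )


def default_repeats() -> tuple[RepeatSpec, ...]:
    return (
        RepeatSpec(100, 100.0, "direct"),
        RepeatSpec(60, 100.0, "direct"),
        RepeatSpec(150, 96.0, "direct"),
        RepeatSpec(200, 100.0, "inverted"),
        RepeatSpec(300, 100.0, "direct"),
        RepeatSpec(420, 100.0, "direct"),  # above the insert cap: never assessed
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_len: int = 60000
    gc: float = 0.44
    genes: tuple[GeneSpec, ...] = field(default_factory=default_genes)
    repeats: tuple[RepeatSpec, ...] = field(default_factory=default_repeats)
    recombined_fraction: float = 0.1
    active_repeat: int | None = 0  # index into repeats; None = no recombination
    mtpt: MtptSpec | None = field(default_factory=MtptSpec)
    plastome_len: int = 30000
    reads: ReadConfig = field(default_factory=ReadConfig)
    min_feature_gap: int = 120
    max_intron_len: int = 10000  # classification rule the trans placements must defeat


@dataclass
class TruthTable:
    gene_models: list[GeneModel]
    cds: dict
    intron_arrangement: dict  # name -> planted cis/trans
    expected_calls: dict  # name -> call expected under the default registry
    intron_refs: dict  # name -> ancestral (cis) intron sequence
    intron_losses: dict  # name -> (retained5, retained3, middle_loss)
    repeat_pairs: list
    active_repeat_id: str | None
    mtpt_regions: list  # (mito_iv, plastid_iv, strand, divergence)
    plastome: CircularSequence | None
    plastid_genes: list


# --- mitogenome assembly ---------------------------------------------------


@dataclass
class _Fragment:
    name: str
    seq: str
    inverted: bool = False
    distance_from_prev: int | None = None
    prev: "_Fragment | None" = None
    trans_no_invert: bool = False  # must land far from prev to stay a split
    segments: list = field(default_factory=list)  # (kind, label, offset, length)
    start: int | None = None  # assigned 1-based placement

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _gene_fragments(rng, spec: GeneSpec, truth: TruthTable) -> list[_Fragment]:
    cds = random_cds(rng, spec.cds_len)
    truth.cds[spec.name] = cds
    positions = [i.position for i in spec.introns]
    if positions != sorted(positions) or positions and positions[-1] >= spec.cds_len:
        raise ValueError(f"{spec.name}: intron positions must be increasing and inside the CDS")
    bounds = [0] + positions + [spec.cds_len]
    exons = [cds[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    ancestral = {r.name for r in DEFAULT_REGISTRY if r.ancestral_trans}

    frags: list[_Fragment] = []
    cur = _Fragment(name=f"{spec.name}_f1", seq="", segments=[])
    exon_no = 0

    def push(kind, label, seq):
        cur.segments.append((kind, label, len(cur.seq), len(seq)))
        cur.seq += seq

    push("exon", f"{spec.name}.e1", exons[0])
    exon_no = 1
    for ispec, exon in zip(spec.introns, exons[1:]):
        name = f"{spec.name}i{ispec.position}"
        intron_full = random_dna(rng, ispec.length)
        truth.intron_refs[name] = intron_full
        truth.intron_arrangement[name] = ispec.mode
        truth.expected_calls[name] = (
            "trans" if ispec.mode == "trans" or name in ancestral else "cis"
        )
        if ispec.mode == "cis":
            truth.intron_losses[name] = (ispec.length, 0, 0)
            push("intron", name, intron_full)
        else:
            if ispec.middle_loss >= ispec.length:
                raise ValueError(f"{name}: middle_loss >= intron length")
            r5 = (ispec.length - ispec.middle_loss) // 2
            r3 = ispec.length - ispec.middle_loss - r5
            truth.intron_losses[name] = (r5, r3, ispec.middle_loss)
            push("intron5", name, intron_full[:r5])
            frags.append(cur)
            nxt = _Fragment(
                name=f"{spec.name}_f{len(frags) + 1}",
                seq="",
                inverted=ispec.invert,
                distance_from_prev=ispec.distance,
                trans_no_invert=not ispec.invert and ispec.distance is None,
                segments=[],
            )
            cur = nxt
            push("intron3", name, intron_full[ispec.length - r3 :])
        exon_no += 1
        push("exon", f"{spec.name}.e{exon_no}", exon)
    frags.append(cur)
    return frags


def _valid_start_ranges(
    frag_len: int, occupied: list[tuple[int, int]], genome_len: int, gap: int
) -> list[tuple[int, int]]:
    """Ranges of start positions keeping >= gap distance from placed features."""
    merged: list[list[int]] = []
    for s, e in sorted(occupied):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    free = []
    pos = 1
    for s, e in merged:
        if s > pos:
            free.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= genome_len:
        free.append((pos, genome_len))
    ranges = []
    for s, e in free:
        lo = s if s == 1 else s + gap
        hi = (e if e == genome_len else e - gap) - frag_len + 1
        if hi >= lo:
            ranges.append((lo, hi))
    return ranges


def _place(
    rng,
    frag_len: int,
    occupied: list[tuple[int, int]],
    genome_len: int,
    gap: int,
    target: int | None = None,
    constraint=None,
    retries: int = 1000,
) -> int:
    ranges = _valid_start_ranges(frag_len, occupied, genome_len, gap)
    if not ranges:
        raise PlacementError("no room left for feature; config too dense")
    if target is not None:
        # admissible starts nearest the requested position, honoring any
        # placement constraint
        cands = set()
        for lo, hi in ranges:
            cands.update({min(max(target, lo), hi), lo, hi})
        for start in sorted(cands, key=lambda s: abs(s - target)):
            if constraint is None or constraint(start, start + frag_len - 1):
                occupied.append((start, start + frag_len - 1))
                return start
        raise PlacementError("could not satisfy placement constraint near target")
    total = sum(hi - lo + 1 for lo, hi in ranges)
    for _ in range(retries):
        pick = int(rng.integers(0, total))
        for lo, hi in ranges:
            n = hi - lo + 1
            if pick < n:
                start = lo + pick
                break
            pick -= n
        if constraint is not None and not constraint(start, start + frag_len - 1):
            continue
        occupied.append((start, start + frag_len - 1))
        return start
    raise PlacementError("could not satisfy placement constraint; config too dense")


def make_mitogenome(cfg: SimConfig) -> tuple[CircularSequence, list[GeneModel], TruthTable]:
    """Generate a circular mitogenome, its gene models and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTable(
        gene_models=[], cds={}, intron_arrangement={}, expected_calls={},
        intron_refs={}, intron_losses={}, repeat_pairs=[], active_repeat_id=None,
        mtpt_regions=[], plastome=None, plastid_genes=[],
    )
    background = list(random_dna(rng, cfg.genome_len, cfg.gc))
    occupied: list[tuple[int, int]] = []

    # genes: fragments placed in order; trans fragments must defeat the
    # contiguity rule (inverted, explicitly distant, or forced far away)
    gene_frag_lists = [(spec, _gene_fragments(rng, spec, truth)) for spec in cfg.genes]
    for spec, frags in gene_frag_lists:
        prev: _Fragment | None = None
        for frag in frags:
            target = None
            constraint = None
            if frag.distance_from_prev is not None and prev is not None:
                target = prev.start + frag.distance_from_prev
                if target + frag.length - 1 > cfg.genome_len:
                    target = max(target - cfg.genome_len, 1)  # wrap on the circle
                far = cfg.max_intron_len + 2000
                p_end = prev.end
                L = cfg.genome_len

                def constraint(s, e, p_end=p_end, far=far, L=L):
                    return (s - p_end - 1) % L > far
            elif frag.trans_no_invert and prev is not None:
                # keep the downstream fragment out of contiguity range of the
                # upstream one, including the circular wrap-around gap
                far = cfg.max_intron_len + 2000
                p_end = prev.end
                L = cfg.genome_len

                def constraint(s, e, p_end=p_end, far=far, L=L):
                    return (s - p_end - 1) % L > far

            frag.start = _place(
                rng, frag.length, occupied, cfg.genome_len, cfg.min_feature_gap,
                target=target, constraint=constraint,
            )
            prev = frag
        # write fragments and collect exon intervals
        exon_ivs: list[tuple[str, FeatureInterval]] = []
        for frag in frags:
            seq = revcomp(frag.seq) if frag.inverted else frag.seq
            background[frag.start - 1 : frag.end] = list(seq)
            for kind, label, off, ln in frag.segments:
                if kind != "exon":
                    continue
                if frag.inverted:
                    s = frag.start + (frag.length - off - ln)
                    e = frag.start + frag.length - off - 1
                    strand = "-"
                else:
                    s = frag.start + off
                    e = frag.start + off + ln - 1
                    strand = "+"
                exon_ivs.append(
                    (label, FeatureInterval(seq_id="mito", start=s, end=e,
                                            strand=strand, kind="exon",
                                            attributes={"gene": spec.name}))
                )
        exon_ivs.sort(key=lambda t: int(t[0].split(".e")[1]))
        truth.gene_models.append(
            GeneModel(gene=spec.name, product_kind="protein",
                      exons=[iv for _, iv in exon_ivs])
        )

    # plastome and MTPT insertions
    if cfg.mtpt is not None and cfg.mtpt.count > 0:
        ptruth_genes = (
            ("psbA", 1062, "protein"), ("rbcL", 1428, "protein"), ("rrn23", 2400, "rRNA"),
        )
        p_background = list(random_dna(rng, cfg.plastome_len, 0.37))
        p_occupied: list[tuple[int, int]] = []
        for gname, glen, gkind in ptruth_genes:
            gseq = random_cds(rng, glen) if gkind == "protein" else random_dna(rng, glen)
            gs = _place(rng, glen, p_occupied, cfg.plastome_len, 60)
            p_background[gs - 1 : gs + glen - 1] = list(gseq)
            truth.plastid_genes.append(
                GeneModel(gene=gname, product_kind=gkind,
                          exons=[FeatureInterval("plastome", gs, gs + glen - 1,
                                                 "+", "exon", {"gene": gname})])
            )
        plastome = CircularSequence("plastome", "".join(p_background), circular=True)
        truth.plastome = plastome
        p_windows: list[tuple[int, int]] = []
        # draw the insertion lengths jointly under a total-space budget so a
        # dense draw cannot exhaust the mitogenome
        budget = int(0.27 * cfg.genome_len)
        for _ in range(100):
            lengths = rng.integers(
                cfg.mtpt.min_len, cfg.mtpt.max_len + 1, size=cfg.mtpt.count
            )
            if lengths.sum() <= budget:
                break
        else:
            raise PlacementError("MTPT specs exceed the genome-space budget")
        for ln in sorted((int(x) for x in lengths), reverse=True):
            ps = _place(rng, ln, p_windows, cfg.plastome_len, 1)
            div = float(rng.uniform(0.0, cfg.mtpt.max_divergence))
            seg = plastome.residues[ps - 1 : ps + ln - 1]
            seg = mutate(rng, seg, div)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seg = revcomp(seg)
            ms = _place(rng, ln, occupied, cfg.genome_len, cfg.min_feature_gap)
            background[ms - 1 : ms + ln - 1] = list(seg)
            truth.mtpt_regions.append(
                (FeatureInterval("mito", ms, ms + ln - 1, "+", "MTPT"),
                 FeatureInterval("plastome", ps, ps + ln - 1, "+", "MTPT"),
                 strand, div)
            )
        truth.mtpt_regions.sort(key=lambda t: t[0].start)

    # repeats
    for i, rspec in enumerate(cfg.repeats, start=1):
        core = random_dna(rng, rspec.length)
        n_sub = int(round((1 - rspec.identity / 100.0) * rspec.length))
        copy_b = mutate_n(rng, core, n_sub) if n_sub else core
        if rspec.orientation == "inverted":
            copy_b = revcomp(copy_b)
        sa = _place(rng, rspec.length, occupied, cfg.genome_len, cfg.min_feature_gap)
        sb = _place(rng, rspec.length, occupied, cfg.genome_len, cfg.min_feature_gap)
        background[sa - 1 : sa + rspec.length - 1] = list(core)
        background[sb - 1 : sb + rspec.length - 1] = list(copy_b)
        iva = FeatureInterval("mito", sa, sa + rspec.length - 1, "+", "repeat")
        ivb = FeatureInterval("mito", sb, sb + rspec.length - 1, "+", "repeat")
        if ivb.start < iva.start:
            iva, ivb = ivb, iva
        pair = RepeatPair(id=f"planted{i:02d}", copyA=iva, copyB=ivb,
                          orientation=rspec.orientation, rep_len=rspec.length,
                          identity=rspec.identity)
        truth.repeat_pairs.append(pair)
    if cfg.active_repeat is not None and cfg.repeats:
        truth.active_repeat_id = truth.repeat_pairs[cfg.active_repeat].id

    genome = CircularSequence("mito", "".join(background), circular=True)
    return genome, truth.gene_models, truth


def make_recombined_genome(
    genome: CircularSequence, pair: RepeatPair
) -> list[CircularSequence]:
    """The molecule(s) produced by homologous exchange at a repeat pair.

    Inverted repeats yield a single circle with the intervening segment
    inverted; direct repeats split the circle into two subcircles, each
    carrying one repeat copy and one of the novel junctions.  Applying the
    inverted-repeat operation twice restores the genome; fusing the two
    direct-repeat subcircles at the repeat restores it likewise.
    """
    a, b = pair.copyA, pair.copyB
    if a.seq_id != genome.id:
        raise ValueError(f"repeat pair {pair.id!r} is not on genome {genome.id!r}")
    if a.wraps or b.wraps:
        raise ValueError("recombination across the origin-wrapped copy is unsupported")
    res = genome.residues
    if pair.orientation == "inverted":
        inner = res[a.end : b.start - 1]
        seq = res[: a.end] + revcomp(inner) + res[b.start - 1 :]
        return [CircularSequence(f"{genome.id}_rec", seq, circular=True)]
    c1 = res[a.start - 1 : b.start - 1]  # copyA + segment between the copies
    c2 = res[b.start - 1 :] + res[: a.start - 1]  # copyB + the rest (wraps)
    return [
        CircularSequence(f"{genome.id}_recA", c1, circular=True),
        CircularSequence(f"{genome.id}_recB", c2, circular=True),
    ]


def simulate_reads(
    genomes: Sequence[tuple[CircularSequence, float]],
    cfg: ReadConfig,
    seed: int,
) -> tuple[list[ReadPair], list[dict]]:
    """Paired-end reads from a weighted genome mixture, with per-read truth.

    Fragment counts follow a multinomial on the weights; positions are
    uniform on each circle; insert sizes are Normal(mean, sd) truncated to
    at least twice the read length; mates are the fragment ends with mate2
    reverse-complemented; substitution errors are applied per base.
    """
    weights = np.array([w for _, w in genomes], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("genome weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(cfg.n_pairs, weights)
    pairs: list[ReadPair] = []
    truth: list[dict] = []
    for (genome, _), n in zip(genomes, counts):
        L = genome.length
        doubled = genome.residues * 2 if genome.circular else genome.residues
        for i in range(n):
            insert = 0
            while insert < 2 * cfg.read_len:
                insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            if insert > L:
                raise ValueError(
                    f"insert {insert} longer than genome {genome.id!r} ({L} nt)"
                )
            if genome.circular:
                start = int(rng.integers(0, L))
            else:
                start = int(rng.integers(0, L - insert + 1))
            frag = doubled[start : start + insert]
            m1 = frag[: cfg.read_len]
            m2 = revcomp(frag[insert - cfg.read_len :])
            if cfg.error_rate > 0:
                m1 = mutate(rng, m1, cfg.error_rate)
                m2 = mutate(rng, m2, cfg.error_rate)
            rid = f"{genome.id}_p{i}"
            pairs.append(ReadPair(id=rid, mate1=m1, mate2=m2))
            truth.append(dict(id=rid, genome=genome.id, start=start + 1, insert=insert))
    return pairs, truth


def truth_to_dict(truth: TruthTable) -> dict:
    """JSON-serializable view of a truth table (sequences omitted)."""
    def iv(x: FeatureInterval) -> dict:
        return dict(seq_id=x.seq_id, start=x.start, end=x.end, strand=x.strand)

    return dict(
        genes={
            gm.gene: [iv(e) for e in gm.exons] for gm in truth.gene_models
        },
        intron_arrangement=dict(truth.intron_arrangement),
        expected_calls=dict(truth.expected_calls),
        intron_losses={k: list(v) for k, v in truth.intron_losses.items()},
        repeat_pairs=[
            dict(id=p.id, copyA=iv(p.copyA), copyB=iv(p.copyB),
                 orientation=p.orientation, rep_len=p.rep_len, identity=p.identity)
            for p in truth.repeat_pairs
        ],
        active_repeat_id=truth.active_repeat_id,
        mtpt_regions=[
            dict(mito=iv(m), plastid=iv(p), strand=s, divergence=round(d, 4))
            for m, p, s, d in truth.mtpt_regions
        ],
    )


def recombined_mixture(
    genome: CircularSequence, pair: RepeatPair, fraction: float
) -> list[tuple[CircularSequence, float]]:
    """Weighted genome mixture with a fraction of recombined molecules.

    The recombined fraction is split across the recombination products in
    proportion to their lengths, so read coverage is uniform per base on
    both the principal and the recombined state.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    mix: list[tuple[CircularSequence, float]] = [(genome, 1.0 - fraction)]
    if fraction > 0:
        products = make_recombined_genome(genome, pair)
        total = sum(p.length for p in products)
        mix += [(p, fraction * p.length / total) for p in products]
    return mix


# --- clade evolution for the chimera screen --------------------------------


@dataclass(frozen=True)
class CladeConfig:
    """Three-clade tree (outgroup, native clade with the focal taxon, a
    foreign donor clade) with per-branch substitution probabilities.

    Defaults are calibrated so that post-conversion donor-recipient
    divergence is about 2% (the segment is copied from the donor tip and
    drifted) while background pairwise divergence is roughly 6-12%,
    echoing the identity contrasts seen in a real chimeric atp1: inside
    the converted region the focal taxon is ~88% identical to its native
    relatives but far closer to the donor lineage.
    """

    seed: int = 0
    gene_len: int = 1506
    focal: str = "focal_sp"
    native: tuple = ("native_1", "native_2", "native_3")
    foreign: tuple = ("donor_sp", "foreign_2", "foreign_3")
    outgroup: str = "outgroup"
    stem_sub: float = 0.02
    tip_sub: float = 0.04
    outgroup_sub: float = 0.10
    conversion: tuple | None = (1138, 1493)
    post_transfer_sub: float = 0.02


def evolve_clades(cfg: CladeConfig) -> tuple[MultipleAlignment, dict]:
    """Evolve a gap-free alignment down the three-clade topology.

    The conversion segment (when enabled) is copied from the first
    foreign-clade taxon (the donor) into the focal taxon and then drifted,
    so the focal taxon is chimeric: native outside the segment, donor-like
    inside it.
    """
    rng = np.random.default_rng(cfg.seed)
    root = random_dna(rng, cfg.gene_len)
    native_anc = mutate(rng, root, cfg.stem_sub)
    foreign_anc = mutate(rng, root, cfg.stem_sub)
    seqs = {cfg.outgroup: mutate(rng, root, cfg.outgroup_sub)}
    seqs[cfg.focal] = mutate(rng, native_anc, cfg.tip_sub)
    for t in cfg.native:
        seqs[t] = mutate(rng, native_anc, cfg.tip_sub)
    for t in cfg.foreign:
        seqs[t] = mutate(rng, foreign_anc, cfg.tip_sub)
    truth = dict(conversion=None, donor_clade=list(cfg.foreign))
    if cfg.conversion is not None:
        s, e = cfg.conversion
        if not (1 <= s <= e <= cfg.gene_len):
            raise ValueError("conversion segment outside gene")
        donor = cfg.foreign[0]
        seg = mutate(rng, seqs[donor][s - 1 : e], cfg.post_transfer_sub)
        f = seqs[cfg.focal]
        seqs[cfg.focal] = f[: s - 1] + seg + f[e:]
        truth["conversion"] = (s, e)
        truth["donor"] = donor
    taxa = [cfg.outgroup, cfg.focal, *cfg.native, *cfg.foreign]
    return MultipleAlignment(taxa=taxa, seqs=seqs), truth
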