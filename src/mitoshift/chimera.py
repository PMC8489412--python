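"""Chimeric-gene (gene-conversion / HGT) screening on multi-taxon alignments.

The screen condenses an alignment to its polymorphic columns and, for every
taxon pair, scores columns +1 where the pair agrees and -P where it
disagrees, with P = scale * ceil((1 - p)/p) for pair disagreement fraction
p.  Candidate converted fragments are the maximal non-overlapping
positive-scoring segments; significance comes from permuting the
polymorphic-column order, with the null statistic taken as the maximum
segment score across ALL pairs per permutation (family-wise control).
This is a declared approximation in the GENECONV family of statistics, not
a re-derivation of GENECONV's inner-fragment formulas.

Per-region phylogenetic origin is then assigned with bootstrap
neighbor-joining trees on Jukes-Cantor distances: if the focal taxon's
smallest containing clade is made of native relatives at bootstrap support
>= 70% the region is native; if it is nested among a declared foreign
lineage at that support the region is foreign; otherwise unresolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

GAP = ord("-")


@dataclass
class MultipleAlignment:
    """Aligned sequences with bookkeeping of removed (masked) columns.

    ``col_map[i]`` is the original 1-based alignment column of current
    column i (0-based), so fragment coordinates can always be reported in
    original-alignment space after masking.
    """

    taxa: list[str]
    seqs: dict[str, str]
    col_map: list[int] = field(default_factory=list)
    masked_cols: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        lengths = {len(self.seqs[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if not self.col_map:
            self.col_map = list(range(1, self.n_cols + 1))

    @property
    def n_cols(self) -> int:
        return len(self.seqs[self.taxa[0]]) if self.taxa else 0

    def row(self, taxon: str) -> str:
        return self.seqs[taxon]

    def matrix(self) -> np.ndarray:
        return np.array(
            [np.frombuffer(self.seqs[t].encode(), dtype=np.uint8) for t in self.taxa]
        )

    def ungapped_to_columns(self, taxon: str, start: int, end: int) -> np.ndarray:
        """0-based current-column indices covering ungapped positions start..end."""
        row = np.frombuffer(self.seqs[taxon].encode(), dtype=np.uint8)
        nongap = np.nonzero(row != GAP)[0]
        if end > len(nongap) or start < 1:
            raise ValueError(
                f"span {start}..{end} beyond {taxon!r} sequence of "
                f"{len(nongap)} ungapped nt"
            )
        return nongap[start - 1 : end]


def read_alignment(path: str | Path) -> MultipleAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty alignment")
    taxa = [r.id for r in records]
    return MultipleAlignment(taxa=taxa, seqs={r.id: str(r.seq).upper() for r in records})


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(msa.seqs[t]), id=t, description="") for t in msa.taxa],
        str(path),
        "fasta",
    )


def read_edit_sites(path: str | Path) -> list[tuple[str, int]]:
    """C-to-U edit-site list as TSV rows (taxon, ungapped position)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
                continue
            taxon, pos = line.split("\t")[:2]
            sites.append((taxon, int(pos)))
    return sites


def mask_sites(
    msa: MultipleAlignment, sites: Sequence[tuple[str, int]]
) -> MultipleAlignment:
    """Remove every alignment column containing a listed edit site.

    Positions are ungapped per-taxon coordinates; the affected columns are
    dropped for all taxa and recorded in ``masked_cols`` (original-column
    numbering), while ``col_map`` keeps the back-mapping round-trippable.
    """
    drop: set[int] = set()
    for taxon, pos in sites:
        cols = msa.ungapped_to_columns(taxon, pos, pos)
        drop.add(int(cols[0]))
    keep = [i for i in range(msa.n_cols) if i not in drop]
    new_seqs = {t: "".join(msa.seqs[t][i] for i in keep) for t in msa.taxa}
    return MultipleAlignment(
        taxa=list(msa.taxa),
        seqs=new_seqs,
        col_map=[msa.col_map[i] for i in keep],
        masked_cols=set(msa.masked_cols) | {msa.col_map[i] for i in drop},
    )


def filter_short(
    msas: Mapping[str, MultipleAlignment], min_len: int = 300
) -> tuple[dict, list[tuple[str, int]]]:
    """Drop genes whose post-masking alignment length is below ``min_len``."""
    kept, excluded = {}, []
    for gene, msa in msas.items():
        if msa.n_cols < min_len:
            excluded.append((gene, msa.n_cols))
        else:
            kept[gene] = msa
    return kept, sorted(excluded)


# --- conversion-fragment detection ----------------------------------------


@dataclass
class ConversionFragment:
    pair: tuple[str, str]
    start_col: int  # 1-based inclusive, original alignment columns
    end_col: int
    n_poly_sites: int
    score: float
    p_value: float


def _positive_segments(x: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal non-overlapping positive-scoring segments (recursive Kadane)."""
    out: list[tuple[int, int, float]] = []

    def kadane(lo: int, hi: int) -> None:
        if lo > hi:
            return
        best = -math.inf
        best_span = (lo, lo)
        cur = 0.0
        cur_start = lo
        for i in range(lo, hi + 1):
            if cur <= 0:
                cur = x[i]
                cur_start = i
            else:
                cur += x[i]
            if cur > best:
                best = cur
                best_span = (cur_start, i)
        if best <= 0:
            return
        s, e = best_span
        out.append((s, e, best))
        kadane(lo, s - 1)
        kadane(e + 1, hi)

    kadane(0, len(x) - 1)
    out.sort()
    return out


def _pair_scores(mat: np.ndarray, poly: np.ndarray, penalty_scale: float):
    """Per-pair score vectors over polymorphic columns; identical pairs skipped."""
    n = mat.shape[0]
    pairs, scores = [], []
    sub = mat[:, poly]
    for i in range(n):
        for j in range(i + 1, n):
            agree = sub[i] == sub[j]
            p_hat = 1.0 - agree.mean()
            if p_hat == 0.0:
                continue
            P = penalty_scale * math.ceil((1.0 - p_hat) / p_hat)
            scores.append(np.where(agree, 1.0, -float(P)))
            pairs.append((i, j))
    return pairs, scores


def detect_fragments(
    msa: MultipleAlignment,
    penalty_scale: float = 1.0,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[ConversionFragment]:
    """Detect putative gene-conversion fragments between taxon pairs.

    Returns fragments with permutation p-value below ``alpha``; p-values
    are computed against the across-pairs maximum segment score under
    random permutation of polymorphic-column order, so they are
    family-wise controlled over taxon pairs.
    """
    if len(msa.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    mat = msa.matrix()
    nongap = (mat != GAP).all(axis=0)
    variable = ~(mat == mat[0]).all(axis=0)
    poly = np.nonzero(nongap & variable)[0]
    if len(poly) < 2:
        return []  # (near-)identical sequences carry no conversion signal
    pairs, scores = _pair_scores(mat, poly, penalty_scale)
    if not pairs:
        return []
    S = np.array(scores)  # (n_pairs, n_poly)
    n_pairs, n_poly = S.shape

    observed: list[tuple[int, int, int, float]] = []  # (pair_idx, s, e, score)
    for pi in range(n_pairs):
        for s, e, sc in _positive_segments(S[pi]):
            observed.append((pi, s, e, sc))

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    chunk = max(1, min(n_perm, 64_000_000 // (8 * n_pairs * n_poly) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n_poly)), axis=1)
        # gather permuted columns: shape (m, n_pairs, n_poly)
        Sp = np.take(S, perms, axis=1).transpose(1, 0, 2)
        cur = np.full((m, n_pairs), -np.inf)
        best = np.full((m, n_pairs), -np.inf)
        for c in range(n_poly):
            col = Sp[:, :, c]
            cur = np.where(cur > 0, cur + col, col)
            best = np.maximum(best, cur)
        null_max[done : done + m] = best.max(axis=1)
        done += m

    frags = []
    for pi, s, e, sc in observed:
        p = (1.0 + float((null_max >= sc).sum())) / (n_perm + 1.0)
        if p >= alpha:
            continue
        i, j = pairs[pi]
        frags.append(
            ConversionFragment(
                pair=(msa.taxa[i], msa.taxa[j]),
                start_col=msa.col_map[int(poly[s])],
                end_col=msa.col_map[int(poly[e])],
                n_poly_sites=e - s + 1,
                score=float(sc),
                p_value=p,
            )
        )
    frags.sort(key=lambda f: (-f.score, f.start_col))
    return frags


def max_segment_statistic(
    msa: MultipleAlignment, penalty_scale: float = 1.0
) -> float:
    """The across-pairs maximum segment score of an alignment (test statistic)."""
    mat = msa.matrix()
    nongap = (mat != GAP).all(axis=0)
    variable = ~(mat == mat[0]).all(axis=0)
    poly = np.nonzero(nongap & variable)[0]
    if len(poly) < 2:
        raise ValueError("need at least 2 polymorphic columns")
    pairs, scores = _pair_scores(mat, poly, penalty_scale)
    if not pairs:
        return 0.0
    best = 0.0
    for sc in scores:
        segs = _positive_segments(np.asarray(sc))
        if segs:
            best = max(best, max(s for _, _, s in segs))
    return best


def null_p_value(
    msa: MultipleAlignment,
    penalty_scale: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value of the alignment's maximum segment score.

    Used for null calibration: under no conversion these p-values are
    approximately uniform.
    """
    mat = msa.matrix()
    nongap = (mat != GAP).all(axis=0)
    variable = ~(mat == mat[0]).all(axis=0)
    poly = np.nonzero(nongap & variable)[0]
    pairs, scores = _pair_scores(mat, poly, penalty_scale)
    if not pairs:
        return 1.0
    S = np.array(scores)
    n_pairs, n_poly = S.shape
    obs = 0.0
    for pi in range(n_pairs):
        segs = _positive_segments(S[pi])
        if segs:
            obs = max(obs, max(s for _, _, s in segs))
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n_poly)), axis=1)
    Sp = np.take(S, perms, axis=1).transpose(1, 0, 2)
    cur = np.full((n_perm, n_pairs), -np.inf)
    best = np.full((n_perm, n_pairs), -np.inf)
    for c in range(n_poly):
        col = Sp[:, :, c]
        cur = np.where(cur > 0, cur + col, col)
        best = np.maximum(best, cur)
    null = best.max(axis=1)
    return (1.0 + float((null >= obs).sum())) / (n_perm + 1.0)


# --- region splitting ------------------------------------------------------


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class RegionPartition:
    gene: str
    regions: list[tuple[str, int, int]]  # (label, start, end) 1-based inclusive


def split_regions(
    gene_len: int, breakpoints: Sequence[int], gene: str = "gene"
) -> RegionPartition:
    """Split 1..gene_len into contiguous regions at the given breakpoints.

    k breakpoints produce k+1 regions labeled I, II, ...; each breakpoint b
    ends its region at b, with the next region starting at b+1.
    """
    bps = list(breakpoints)
    if bps != sorted(set(bps)):
        raise ValueError("breakpoints must be strictly increasing")
    if bps and (bps[0] < 1 or bps[-1] >= gene_len):
        raise ValueError("breakpoints must lie inside 1..gene_len-1")
    bounds = [0] + bps + [gene_len]
    regions = []
    for i in range(len(bounds) - 1):
        label = _ROMAN[i] if i < len(_ROMAN) else str(i + 1)
        regions.append((label, bounds[i] + 1, bounds[i + 1]))
    return RegionPartition(gene=gene, regions=regions)


def split_even(
    region: tuple[int, int], k: int = 3, comparand_len: int | None = None
) -> list[tuple[int, int]]:
    """Split a region into k contiguous subregions.

    The first k-1 spans get the comparand length when one is provided
    (e.g., the length of a shorter region they will be compared against),
    otherwise floor(length/k); the remainder goes to the last span.
    """
    start, end = region
    length = end - start + 1
    if k < 1 or length < k:
        raise ValueError("region too short to split")
    step = comparand_len if comparand_len is not None else length // k
    if step < 1 or step * (k - 1) >= length:
        raise ValueError("comparand length does not fit k-1 spans in the region")
    spans = []
    s = start
    for i in range(k - 1):
        spans.append((s, s + step - 1))
        s += step
    spans.append((s, end))
    return spans


def pairwise_identity(
    msa: MultipleAlignment,
    span: tuple[int, int],
    focal: str,
    group: Iterable[str],
) -> tuple[float, float]:
    """Identity range (min%, max%) of focal vs group members over a span.

    The span is in ungapped focal coordinates; columns where either member
    of a comparison has a gap are excluded pairwise.
    """
    group = list(group)
    if not group:
        raise ValueError("empty comparison group")
    cols = msa.ungapped_to_columns(focal, span[0], span[1])
    frow = np.frombuffer(msa.seqs[focal].encode(), dtype=np.uint8)[cols]
    idents = []
    for taxon in group:
        row = np.frombuffer(msa.seqs[taxon].encode(), dtype=np.uint8)[cols]
        valid = (frow != GAP) & (row != GAP)
        if valid.sum() == 0:
            continue
        idents.append(100.0 * float((frow[valid] == row[valid]).mean()))
    if not idents:
        raise ValueError("no comparable columns in span")
    return (min(idents), max(idents))


# --- bootstrap NJ and origin assignment ------------------------------------


@dataclass
class BootstrapTree:
    """NJ tree with bootstrap supports per bipartition.

    Bipartitions are keyed by the frozenset of tip names on the side NOT
    containing the first taxon of the alignment.
    """

    tree: object  # skbio TreeNode
    supports: dict
    taxa: list[str]
    jc_fallback_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_newick(self) -> str:
        t = self.tree.copy()
        for node in t.non_tips():
            tips = frozenset(x.name for x in node.tips())
            key = self._key(tips)
            if key in self.supports:
                node.name = str(int(round(self.supports[key])))
        return str(t)

    def _key(self, side: frozenset) -> frozenset:
        return side if self.taxa[0] not in side else frozenset(self.taxa) - side


def _jc_distance_matrix(
    rows: np.ndarray, taxa: list[str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    n = len(taxa)
    d = np.zeros((n, n))
    fallback = []
    for i in range(n):
        for j in range(i + 1, n):
            valid = (rows[i] != GAP) & (rows[j] != GAP)
            if valid.sum() == 0:
                p = 0.0
            else:
                p = float((rows[i][valid] != rows[j][valid]).mean())
            if p < 0.75:
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            else:
                dist = p  # saturation: JC log undefined, fall back to p-distance
                fallback.append((taxa[i], taxa[j]))
            d[i, j] = d[j, i] = dist
    return d, fallback


def _bipartitions(tree, taxa: list[str]) -> set[frozenset]:
    all_taxa = frozenset(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(x.name for x in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = side if taxa[0] not in side else all_taxa - side
        out.add(key)
    return out


def nj_bootstrap(
    msa: MultipleAlignment,
    span: tuple[int, int] | None = None,
    focal: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BootstrapTree:
    """Neighbor-joining tree on Jukes-Cantor distances with bootstrap supports.

    ``span`` restricts the analysis: given with ``focal`` it is an ungapped
    focal-coordinate span, otherwise a 1-based alignment-column range.
    Supports are the percentage of column-resampled trees containing each
    bipartition of the full-data tree.  Deterministic given the seed.
    """
    if len(msa.taxa) < 4:
        raise ValueError("need at least 4 taxa for an informative tree")
    mat = msa.matrix()
    if span is None:
        cols = np.arange(msa.n_cols)
    elif focal is not None:
        cols = msa.ungapped_to_columns(focal, span[0], span[1])
    else:
        cols = np.arange(span[0] - 1, span[1])
    rows = mat[:, cols]
    if (rows == rows[0]).all():
        raise ValueError("span has no variable column")
    d, fallback = _jc_distance_matrix(rows, msa.taxa)
    tree = _skbio_nj(DistanceMatrix(d, msa.taxa))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    main_bips = _bipartitions(tree, msa.taxa)
    counts = {b: 0 for b in main_bips}
    rng = np.random.default_rng(seed)
    n_cols = rows.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, n_cols, n_cols)
        db, _ = _jc_distance_matrix(rows[:, idx], msa.taxa)
        bt = _skbio_nj(DistanceMatrix(db, msa.taxa))
        for b in _bipartitions(bt, msa.taxa):
            if b in counts:
                counts[b] += 1
    supports = {b: 100.0 * c / n_boot for b, c in counts.items()}
    return BootstrapTree(tree=tree, supports=supports, taxa=list(msa.taxa),
                         jc_fallback_pairs=fallback)


@dataclass
class OriginCall:
    focal: str
    region_label: str
    verdict: str  # native | foreign | unresolved
    sister_group: frozenset
    support: float
    foreign_source: str | None = None


def assign_origin(
    boot: BootstrapTree,
    focal: str,
    native: Iterable[str],
    foreign_sets: Mapping[str, Iterable[str]],
    bs_threshold: float = 70.0,
    outgroup: str | None = None,
    region_label: str = "",
) -> OriginCall:
    """Per-region origin verdict from the focal taxon's smallest supported clade.

    Among the (outgroup-rooted) clades containing the focal taxon with
    bootstrap support >= threshold, the smallest one with at least one
    other member decides: all-native membership is native, containment in
    one declared foreign lineage is foreign, anything else — including the
    absence of any supported clade — is unresolved.
    """
    if focal not in boot.taxa:
        raise ValueError(f"focal taxon {focal!r} not in tree")
    native = set(native)
    foreign = {k: set(v) for k, v in foreign_sets.items()}
    all_taxa = frozenset(boot.taxa)
    candidates = []
    for key, sup in boot.supports.items():
        if sup < bs_threshold:
            continue
        for side in (key, all_taxa - key):
            if focal not in side or len(side) < 2:
                continue
            if outgroup is not None and outgroup in side and len(side) < len(all_taxa):
                continue  # not a clade under outgroup rooting
            candidates.append((len(side), side, sup))
    if not candidates:
        return OriginCall(focal, region_label, "unresolved", frozenset(), 0.0)
    candidates.sort(key=lambda t: (t[0], sorted(t[1])))
    _, clade, support = candidates[0]
    sisters = frozenset(clade) - {focal}
    verdict, source = "unresolved", None
    if sisters <= native:
        verdict = "native"
    else:
        for label, taxa in foreign.items():
            if sisters <= taxa:
                verdict, source = "foreign", label
                break
    return OriginCall(focal, region_label, verdict, sisters, support, source)
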