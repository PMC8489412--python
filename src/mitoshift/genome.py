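"""Core sequence/annotation data model with circular-coordinate arithmetic.

Coordinates are 1-based inclusive throughout (GFF3 convention).  A feature
with ``start > end`` is only legal on a circular sequence and denotes a
span that wraps across the origin.  Conversion to 0-based half-open
happens only inside the I/O helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Malformed FASTA/GFF3 input or an invalid coordinate request."""


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    An involution: ``revcomp(revcomp(x)) == x``.
    """
    _validate_residues(s, context="revcomp input")
    return s.translate(_COMPLEMENT)[::-1]


def _validate_residues(s: str, context: str) -> None:
    bad = set(s) - VALID_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s, start=1) if c in bad)
        raise GenomeFormatError(
            f"{context}: invalid residue {s[pos - 1]!r} at position {pos}"
        )


@dataclass(frozen=True)
class CircularSequence:
    """A (possibly circular) DNA sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise GenomeFormatError(f"sequence {self.id!r} is empty")
        _validate_residues(self.residues, context=f"sequence {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureInterval:
    """A 1-based inclusive genomic interval; start > end encodes origin wrap."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise GenomeFormatError(
                f"interval {self.start}..{self.end}: coordinates are 1-based"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeFormatError(f"invalid strand {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def span_length(self, seq_len: int | None = None) -> int:
        """Number of residues covered, correcting for origin wrap."""
        if not self.wraps:
            return self.end - self.start + 1
        if seq_len is None:
            raise GenomeFormatError("wrapped interval needs the sequence length")
        return seq_len - self.start + 1 + self.end

    def overlaps(self, other: "FeatureInterval", seq_len: int | None = None) -> bool:
        """Whether the two intervals share at least one position (wrap-aware)."""
        if self.seq_id != other.seq_id:
            return False
        a = _arcs(self, seq_len)
        b = _arcs(other, seq_len)
        return any(s1 <= e2 and s2 <= e1 for s1, e1 in a for s2, e2 in b)


def _arcs(iv: FeatureInterval, seq_len: int | None) -> list[tuple[int, int]]:
    if not iv.wraps:
        return [(iv.start, iv.end)]
    if seq_len is None:
        raise GenomeFormatError("wrapped interval needs the sequence length")
    return [(iv.start, seq_len), (1, iv.end)]


@dataclass
class GeneModel:
    """A gene and its exons in transcript (5'→3' CDS) order.

    Transcript order is authoritative: for trans-spliced genes the exons'
    genomic order and strands may disagree with it.
    """

    gene: str
    product_kind: str = "protein"
    exons: list[FeatureInterval] = field(default_factory=list)
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise GenomeFormatError(f"gene {self.gene!r} has no exons")
        if self.product_kind not in {"protein", "rRNA", "tRNA"}:
            raise GenomeFormatError(
                f"gene {self.gene!r}: unknown product_kind {self.product_kind!r}"
            )


def extract(seq: CircularSequence, iv: FeatureInterval) -> str:
    """Residues of ``iv`` on ``seq``; minus-strand intervals are reverse-complemented.

    A wrapped interval (start > end) concatenates the suffix from ``start``
    with the prefix up to ``end`` and requires a circular sequence.
    """
    if iv.seq_id != seq.id:
        raise GenomeFormatError(
            f"interval on {iv.seq_id!r} does not belong to sequence {seq.id!r}"
        )
    if iv.start > seq.length or iv.end > seq.length:
        raise GenomeFormatError(
            f"interval {iv.start}..{iv.end} outside sequence of length {seq.length}"
        )
    if iv.wraps:
        if not seq.circular:
            raise GenomeFormatError(
                f"wrapped interval {iv.start}..{iv.end} on non-circular {seq.id!r}"
            )
        s = seq.residues[iv.start - 1 :] + seq.residues[: iv.end]
    else:
        s = seq.residues[iv.start - 1 : iv.end]
    return revcomp(s) if iv.strand == "-" else s


def read_fasta(path: str | Path, circular: bool = False) -> list[CircularSequence]:
    """Read a multi-record FASTA file.

    Residues are upper-cased and U is mapped to T so RNA-style FASTA is
    accepted; anything outside {A,C,G,T,N} is rejected with its position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"{path}: empty or not FASTA")
    out = []
    for rec in records:
        residues = str(rec.seq).upper().replace("U", "T")
        _validate_residues(residues, context=f"{path}:{rec.id}")
        out.append(CircularSequence(id=rec.id, residues=residues, circular=circular))
    return out


def write_fasta(seqs: Iterable[CircularSequence], path: str | Path) -> None:
    """Write sequences as FASTA, 60 columns per line."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 annotation -------------------------------------------------------
#
# Dialect: exon features carry attributes gene, part (1-based transcript
# order), product_kind and optionally pseudo=true.  The explicit part
# attribute is required because genome order is meaningless for
# trans-spliced genes.

_GFF_SOURCE = "mitoshift"


def write_annotation(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gm in models:
        for i, ex in enumerate(gm.exons, start=1):
            attrs = (
                f"ID={gm.gene}.exon{i};gene={gm.gene};part={i};"
                f"product_kind={gm.product_kind}"
            )
            if gm.pseudo:
                attrs += ";pseudo=true"
            lines.append(
                "\t".join(
                    [
                        ex.seq_id,
                        _GFF_SOURCE,
                        "exon",
                        str(ex.start),
                        str(ex.end),
                        ".",
                        ex.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(
    path: str | Path, seqs: Sequence[CircularSequence]
) -> list[GeneModel]:
    """Parse the GFF3 dialect above into GeneModels with exons in transcript order.

    Rejects exons referencing unknown sequences, duplicate part indices and
    gaps in the part numbering (each names the offending gene and index).
    """
    known = {s.id for s in seqs}
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, list[tuple[int, FeatureInterval]]] = {}
    meta: dict[str, tuple[str, bool]] = {}
    for f in db.features_of_type("exon"):
        if f.seqid not in known:
            raise GenomeFormatError(
                f"{path}: exon references unknown sequence {f.seqid!r}"
            )
        gene = f.attributes["gene"][0]
        part = int(f.attributes["part"][0])
        kind = f.attributes.get("product_kind", ["protein"])[0]
        pseudo = f.attributes.get("pseudo", ["false"])[0].lower() == "true"
        iv = FeatureInterval(
            seq_id=f.seqid,
            start=f.start,
            end=f.end,
            strand=f.strand if f.strand in {"+", "-"} else "+",
            kind="exon",
            attributes={"gene": gene, "part": str(part)},
        )
        by_gene.setdefault(gene, []).append((part, iv))
        meta[gene] = (kind, pseudo)
    models = []
    for gene in sorted(by_gene):
        parts = by_gene[gene]
        indices = [p for p, _ in parts]
        if len(set(indices)) != len(indices):
            dup = next(i for i in indices if indices.count(i) > 1)
            raise GenomeFormatError(
                f"{path}: gene {gene!r} has duplicate exon part index {dup}"
            )
        expected = set(range(1, len(parts) + 1))
        missing = expected - set(indices)
        if missing:
            raise GenomeFormatError(
                f"{path}: gene {gene!r} is missing exon part index {min(missing)}"
            )
        kind, pseudo = meta[gene]
        models.append(
            GeneModel(
                gene=gene,
                product_kind=kind,
                exons=[iv for _, iv in sorted(parts)],
                pseudo=pseudo,
            )
        )
    return models
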