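"""Report tables: intron calls, the cross-genome intron-mode matrix, and
TSV writers that echo the run configuration into every output header."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mitoshift.chimera import OriginCall
from mitoshift.genome import FeatureInterval
from mitoshift.homology import RepeatPair
from mitoshift.introns import IntronCall, SyntenyBlock


def write_tsv(df: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    """Write a TSV, prefixing '# key: value' lines echoing the run config."""
    with open(path, "w", newline="") as fh:
        if config:
            for k in sorted(config):
                fh.write(f"# {k}: {config[k]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def intron_calls_table(calls: Sequence[IntronCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            dict(
                intron=c.intron.name,
                gene=c.intron.gene,
                group=c.intron.group,
                mode=c.mode,
                raw_adjacency=c.raw_adjacency,
                override_applied=c.override_applied,
                genome_gap=c.genome_gap if c.genome_gap is not None else ".",
                upstream_exon=f"{c.upstream_exon.genome_iv.start}..{c.upstream_exon.genome_iv.end}({c.upstream_exon.genome_iv.strand})",
                downstream_exon=f"{c.downstream_exon.genome_iv.start}..{c.downstream_exon.genome_iv.end}({c.downstream_exon.genome_iv.strand})",
            )
        )
    return pd.DataFrame(
        rows, columns=["intron", "gene", "group", "mode", "raw_adjacency",
                       "override_applied", "genome_gap", "upstream_exon",
                       "downstream_exon"]
    )


def synteny_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        rows.append(
            dict(intron=b.intron_name, retained5=b.retained5_len,
                 retained3=b.retained3_len, lost_mid=b.lost_mid_len,
                 warning=b.warning)
        )
    return pd.DataFrame(rows, columns=["intron", "retained5", "retained3",
                                       "lost_mid", "warning"])


def origin_table(calls: Sequence[OriginCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            dict(focal=c.focal, region=c.region_label, verdict=c.verdict,
                 support=round(c.support, 1),
                 sister_group=",".join(sorted(c.sister_group)) or ".",
                 foreign_source=c.foreign_source or ".")
        )
    return pd.DataFrame(rows, columns=["focal", "region", "verdict", "support",
                                       "sister_group", "foreign_source"])


def intron_matrix(
    calls_per_genome: Mapping[str, Sequence[IntronCall]],
    ancestral: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Taxa x introns matrix with values cis/trans/absent.

    When an ancestral-state row is supplied it becomes the first row
    (labeled 'ancestral'); ``shift_events`` counts departures from it.
    Conflicting duplicate calls for one genome/intron cell are rejected.
    """
    if not calls_per_genome:
        raise ValueError("need at least one genome")
    cells: dict[str, dict[str, str]] = {}
    for genome, calls in calls_per_genome.items():
        row: dict[str, str] = {}
        for c in calls:
            if c.intron.name in row and row[c.intron.name] != c.mode:
                raise ValueError(
                    f"conflicting calls for {c.intron.name} in {genome!r}"
                )
            row[c.intron.name] = c.mode
        cells[genome] = row
    introns = sorted({n for row in cells.values() for n in row})
    if ancestral is not None:
        introns = sorted(set(introns) | set(ancestral))
    data = []
    index = []
    if ancestral is not None:
        index.append("ancestral")
        data.append([ancestral.get(n, "absent") for n in introns])
    for genome in sorted(cells):
        index.append(genome)
        data.append([cells[genome].get(n, "absent") for n in introns])
    return pd.DataFrame(data, index=index, columns=introns)


def shift_events(matrix: pd.DataFrame, ancestral_row: str = "ancestral") -> list[tuple]:
    """(genome, intron, from, to) for every departure from the ancestral row."""
    if ancestral_row not in matrix.index:
        raise ValueError(f"no row {ancestral_row!r} in matrix")
    anc = matrix.loc[ancestral_row]
    events = []
    for genome in matrix.index:
        if genome == ancestral_row:
            continue
        for intron in matrix.columns:
            a, b = anc[intron], matrix.loc[genome, intron]
            if "absent" not in (a, b) and a != b:
                events.append((genome, intron, a, b))
    return events


# --- repeat-pair TSV round-trip -------------------------------------------

_REPEAT_COLS = ["repeat_id", "seq_id", "copyA_start", "copyA_end",
                "copyB_start", "copyB_end", "orientation", "rep_len", "identity"]


def write_repeats_tsv(
    pairs: Iterable[RepeatPair], path: str | Path, config: Mapping | None = None
) -> None:
    rows = [
        dict(repeat_id=p.id, seq_id=p.copyA.seq_id,
             copyA_start=p.copyA.start, copyA_end=p.copyA.end,
             copyB_start=p.copyB.start, copyB_end=p.copyB.end,
             orientation=p.orientation, rep_len=p.rep_len,
             identity=round(p.identity, 2))
        for p in pairs
    ]
    write_tsv(pd.DataFrame(rows, columns=_REPEAT_COLS), path, config)


def read_repeats_tsv(path: str | Path) -> list[RepeatPair]:
    df = read_tsv(path)
    pairs = []
    for r in df.itertuples(index=False):
        pairs.append(
            RepeatPair(
                id=str(r.repeat_id),
                copyA=FeatureInterval(r.seq_id, int(r.copyA_start), int(r.copyA_end),
                                      "+", "repeat"),
                copyB=FeatureInterval(r.seq_id, int(r.copyB_start), int(r.copyB_end),
                                      "+", "repeat"),
                orientation=str(r.orientation),
                rep_len=int(r.rep_len),
                identity=float(r.identity),
            )
        )
    return pairs
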