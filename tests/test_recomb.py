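"""Alternative-conformation references and read-pair recombination support."""

import numpy as np
import pytest

from mitoshift.genome import CircularSequence, FeatureInterval, revcomp
from mitoshift.homology import RepeatPair
from mitoshift.recomb import (
    ReadPair,
    build_conformations,
    count_support,
    place_pair,
    read_paired_fastq,
    screen_all,
    support_table,
    write_paired_fastq,
)
from mitoshift.simulate import (
    ReadConfig,
    make_recombined_genome,
    random_dna,
    recombined_mixture,
    simulate_reads,
)


def _genome_with_pair(rng, orientation="direct", rep_len=100, sep=5000, total=20000):
    core = random_dna(rng, rep_len)
    copy_b = revcomp(core) if orientation == "inverted" else core
    bg = random_dna(rng, total)
    a_start = 4000
    b_start = a_start + rep_len + sep
    g = (bg[:a_start] + core + bg[a_start : a_start + sep] + copy_b
         + bg[a_start + sep :])[:total + 2 * rep_len]
    genome = CircularSequence("g", g, circular=True)
    pair = RepeatPair(
        id="r1",
        copyA=FeatureInterval("g", a_start + 1, a_start + rep_len, "+", "repeat"),
        copyB=FeatureInterval("g", b_start + 1, b_start + rep_len, "+", "repeat"),
        orientation=orientation, rep_len=rep_len, identity=100.0,
    )
    return genome, pair


class TestConformations:
    def test_direct_construction_identities(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        conf = build_conformations(genome, pair, flank=300)
        assert len(conf.alt1) == 700 and len(conf.alt2) == 700
        a, b = pair.copyA, pair.copyB
        assert conf.alt1[:300] == genome.residues[a.start - 301 : a.start - 1]
        assert conf.alt1[-300:] == genome.residues[b.end : b.end + 300]
        assert conf.alt2[:300] == genome.residues[b.start - 301 : b.start - 1]
        assert conf.alt2[-300:] == genome.residues[a.end : a.end + 300]
        assert conf.junctions["alt1"] == (301, 400)

    def test_inverted_construction_identities(self, rng):
        genome, pair = _genome_with_pair(rng, "inverted")
        conf = build_conformations(genome, pair, flank=300)
        b = pair.copyB
        assert conf.alt1[-300:] == revcomp(genome.residues[b.start - 301 : b.start - 1])
        assert conf.alt2[:300] == revcomp(genome.residues[b.end : b.end + 300])

    def test_recombined_genome_swaps_principals_and_alternatives(self, rng):
        """On the molecule(s) produced by recombination, the original
        alternative junctions are principal (and vice versa)."""
        genome, pair = _genome_with_pair(rng, "direct")
        conf = build_conformations(genome, pair, flank=100)
        products = make_recombined_genome(genome, pair)
        joined = {p.id: p.residues * 2 for p in products}  # circular contexts
        assert any(conf.alt1 in s for s in joined.values())
        assert any(conf.alt2 in s for s in joined.values())
        assert not any(conf.principalA in s for s in joined.values())
        assert not any(conf.principalB in s for s in joined.values())

    def test_inverted_recombination_is_involution(self, rng):
        genome, pair = _genome_with_pair(rng, "inverted")
        (rec,) = make_recombined_genome(genome, pair)
        rec = CircularSequence(genome.id, rec.residues, circular=True)
        (back,) = make_recombined_genome(rec, pair)
        assert back.residues == genome.residues

    def test_direct_recombination_preserves_total_length(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        products = make_recombined_genome(genome, pair)
        assert sum(p.length for p in products) == genome.length

    def test_pair_not_on_genome_rejected(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        other = CircularSequence("other", genome.residues, circular=True)
        with pytest.raises(ValueError):
            make_recombined_genome(other, pair)


def _oracle_place(rp, ref, max_mismatch):
    """Brute-force enumeration of every (offset1, offset2, orientation)."""
    def mm(read, off):
        return sum(a != b for a, b in zip(read, ref[off : off + len(read)]))

    cands = []
    for mate1_forward in (True, False):
        fwd = rp.mate1 if mate1_forward else rp.mate2
        rev = revcomp(rp.mate2 if mate1_forward else rp.mate1)
        for i in range(len(ref) - len(fwd) + 1):
            m1 = mm(fwd, i)
            if m1 > max_mismatch:
                continue
            for j in range(i, len(ref) - len(rev) + 1):
                m2 = mm(rev, j)
                if m2 <= max_mismatch:
                    cands.append((m1 + m2, i, j, mate1_forward))
    if not cands:
        return None
    best = min(c[0] for c in cands)
    winners = [c for c in cands if c[0] == best]
    return winners[0] if len(winners) == 1 else None


class TestPlacePair:
    def _pair_from(self, rng, ref, start, insert, read_len=60, errors=0):
        frag = ref[start : start + insert]
        m1, m2 = frag[:read_len], revcomp(frag[-read_len:])
        if errors:
            pos = rng.choice(read_len, size=errors, replace=False)
            m1 = "".join(
                c if i not in pos else {"A": "C", "C": "G", "G": "T", "T": "A"}[c]
                for i, c in enumerate(m1)
            )
        return ReadPair("p", m1, m2)

    def test_errorfree_pair_placed_at_true_offsets(self, rng):
        ref = random_dna(rng, 600)
        rp = self._pair_from(rng, ref, 100, 250)
        pl = place_pair(rp, ref)
        assert pl is not None and pl.fwd_start == 101
        assert pl.rev_end == 100 + 250 and pl.mismatches == 0

    def test_excess_mismatches_rejected(self, rng):
        ref = random_dna(rng, 600)
        rp = self._pair_from(rng, ref, 100, 250, errors=3)
        assert place_pair(rp, ref, max_mismatch=2) is None

    def test_agreement_with_bruteforce_oracle(self, rng):
        """200 random pairs, including unplaceable and error-bearing ones."""
        ref = random_dna(rng, 400)
        for k in range(200):
            if k % 3 == 0:
                rp = ReadPair("p", random_dna(rng, 40), random_dna(rng, 40))
            else:
                start = int(rng.integers(0, 250))
                insert = int(rng.integers(90, 150))
                rp = self._pair_from(rng, ref, start, insert, read_len=45,
                                     errors=int(rng.integers(0, 3)))
            got = place_pair(rp, ref, max_mismatch=2)
            want = _oracle_place(rp, ref, max_mismatch=2)
            if want is None:
                assert got is None
            else:
                mm, i, j, m1f = want
                assert got is not None
                assert (got.mismatches, got.fwd_start - 1, got.rev_start - 1,
                        got.mate1_forward) == (mm, i, j, m1f)


class TestCountSupport:
    def test_no_support_from_principal_genome(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        conf = build_conformations(genome, pair)
        reads, _ = simulate_reads([(genome, 1.0)],
                                  ReadConfig(n_pairs=600, error_rate=0.0), seed=5)
        assert count_support(reads, conf).n_total == 0

    def test_support_appears_with_recombined_fraction(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        conf = build_conformations(genome, pair)
        mix = recombined_mixture(genome, pair, 0.3)
        reads, _ = simulate_reads(mix, ReadConfig(n_pairs=1500), seed=6)
        sup = count_support(reads, conf)
        assert sup.n_total > 0
        assert len(sup.supporting_ids) == sup.n_total

    def test_duplicate_read_ids_rejected(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        conf = build_conformations(genome, pair)
        rp = ReadPair("dup", random_dna(rng, 50), random_dna(rng, 50))
        with pytest.raises(ValueError):
            count_support([rp, rp], conf)

    def test_copy_relabeling_permutes_counts(self, rng):
        genome, pair = _genome_with_pair(rng, "direct")
        swapped = RepeatPair(id=pair.id, copyA=pair.copyB, copyB=pair.copyA,
                             orientation=pair.orientation, rep_len=pair.rep_len,
                             identity=pair.identity)
        mix = recombined_mixture(genome, pair, 0.3)
        reads, _ = simulate_reads(mix, ReadConfig(n_pairs=1200), seed=8)
        s1 = count_support(reads, build_conformations(genome, pair))
        s2 = count_support(reads, build_conformations(genome, swapped))
        assert (s1.n_alt1, s1.n_alt2) == (s2.n_alt2, s2.n_alt1)
        assert s1.n_total == s2.n_total

    def test_screen_excludes_pairs_at_or_above_insert_cap(self, rng):
        genome, small = _genome_with_pair(rng, "direct", rep_len=100)
        big = RepeatPair(id="big", copyA=FeatureInterval("g", 1, 400, "+", "repeat"),
                         copyB=FeatureInterval("g", 1000, 1399, "+", "repeat"),
                         orientation="direct", rep_len=400, identity=100.0)
        reads, _ = simulate_reads([(genome, 1.0)], ReadConfig(n_pairs=50), seed=9)
        results = screen_all(genome, [small, big], reads, insert_cap=350)
        assert [p.id for p, _ in results] == ["r1"]
        table = support_table(results)
        assert list(table.repeat_id) == ["r1"]


class TestFastqRoundTrip:
    def test_paired_fastq_round_trip(self, tmp_path, rng):
        pairs = [ReadPair(f"p{i}", random_dna(rng, 80), random_dna(rng, 80))
                 for i in range(10)]
        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        write_paired_fastq(pairs, f1, f2)
        back = read_paired_fastq(f1, f2)
        assert [(p.id, p.mate1, p.mate2) for p in back] == [
            (p.id, p.mate1, p.mate2) for p in pairs
        ]
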