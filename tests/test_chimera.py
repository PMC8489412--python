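"""Gene-conversion screen, region splitting, NJ bootstrap, origin calls."""

import numpy as np
import pytest

from mitoshift.chimera import (
    BootstrapTree,
    MultipleAlignment,
    assign_origin,
    detect_fragments,
    filter_short,
    mask_sites,
    nj_bootstrap,
    pairwise_identity,
    read_alignment,
    split_even,
    split_regions,
    write_alignment,
)
from mitoshift.simulate import CladeConfig, evolve_clades, mutate, random_dna


def _msa(rows: dict) -> MultipleAlignment:
    return MultipleAlignment(taxa=list(rows), seqs=dict(rows))


class TestMasking:
    def test_empty_site_list_is_identity(self):
        m = _msa({"a": "ACGT", "b": "ACGA"})
        out = mask_sites(m, [])
        assert out.seqs == m.seqs and out.masked_cols == set()

    def test_single_site_removes_one_column(self):
        m = _msa({"a": "ACGTACGT", "b": "ACGTACGT"})
        out = mask_sites(m, [("a", 3)])
        assert out.n_cols == 7
        assert out.masked_cols == {3}
        assert out.seqs["a"] == "ACTACGT"

    def test_gapped_taxon_position_maps_through_gaps(self):
        m = _msa({"a": "A-CGT", "b": "AACGT"})
        out = mask_sites(m, [("a", 2)])  # a's 2nd ungapped base is column 3
        assert out.masked_cols == {3}
        assert out.seqs["b"] == "AAGT"

    def test_mask_round_trip_recovers_original_columns(self):
        m = _msa({"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGAACGAAC"})
        out = mask_sites(m, [("a", 2), ("b", 7)])
        assert out.col_map == [c for c in range(1, 11) if c not in out.masked_cols]
        # fragment coordinates expressed via col_map refer to original columns
        assert [out.col_map[i] for i in range(out.n_cols)] == sorted(
            set(range(1, 11)) - out.masked_cols
        )

    def test_site_beyond_sequence_rejected(self):
        m = _msa({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError):
            mask_sites(m, [("a", 9)])


class TestFilterShort:
    def test_printed_gene_lengths(self):
        msas = {
            "atp9": _msa({"a": "A" * 212, "b": "A" * 212}),
            "nad4L": _msa({"a": "A" * 284, "b": "A" * 284}),
            "rps14": _msa({"a": "A" * 296, "b": "A" * 296}),
            "atp1": _msa({"a": "A" * 1480, "b": "A" * 1480}),
        }
        kept, excluded = filter_short(msas, min_len=300)
        assert set(kept) == {"atp1"}
        assert excluded == [("atp9", 212), ("nad4L", 284), ("rps14", 296)]

    def test_zero_floor_excludes_nothing(self):
        msas = {"g": _msa({"a": "AC", "b": "AC"})}
        kept, excluded = filter_short(msas, min_len=0)
        assert set(kept) == {"g"} and excluded == []

    def test_exclusion_monotone_in_min_len(self):
        msas = {f"g{n}": _msa({"a": "A" * n, "b": "A" * n})
                for n in (100, 200, 300, 400)}
        counts = [len(filter_short(msas, min_len=m)[1]) for m in (350, 250, 150, 50)]
        assert counts == sorted(counts, reverse=True)


class TestDetectFragments:
    def test_identical_sequences_no_fragments(self):
        m = _msa({t: "ACGT" * 50 for t in "abc"})
        assert detect_fragments(m, n_perm=50, seed=0) == []

    def test_too_few_taxa_rejected(self):
        m = _msa({"a": "ACGT", "b": "ACGA"})
        with pytest.raises(ValueError):
            detect_fragments(m, n_perm=50, seed=0)

    def test_planted_conversion_detected(self):
        cfg = CladeConfig(seed=11)
        msa, truth = evolve_clades(cfg)
        s, e = truth["conversion"]
        frags = detect_fragments(msa, n_perm=1000, seed=11)
        hit = [
            f for f in frags
            if cfg.focal in f.pair
            and (set(f.pair) - {cfg.focal}) <= set(cfg.foreign)
            and min(f.end_col, e) - max(f.start_col, s) + 1 >= 0.8 * (e - s + 1)
        ]
        assert hit and hit[0].p_value < 0.05

    def test_coordinates_map_through_masking(self):
        cfg = CladeConfig(seed=12)
        msa, truth = evolve_clades(cfg)
        masked = mask_sites(msa, [(cfg.focal, p) for p in (5, 50, 500)])
        frags = detect_fragments(masked, n_perm=500, seed=12)
        for f in frags:
            assert 1 <= f.start_col <= f.end_col <= 1506  # original columns


class TestRegions:
    def test_atp1_regions_from_printed_coordinates(self):
        part = split_regions(1506, [1137, 1493], gene="atp1")
        assert part.regions == [("I", 1, 1137), ("II", 1138, 1493), ("III", 1494, 1506)]
        lengths = [e - s + 1 for _, s, e in part.regions]
        assert lengths == [1137, 356, 13]

    def test_no_breakpoints_single_region(self):
        part = split_regions(500, [])
        assert part.regions == [("I", 1, 500)]

    @pytest.mark.parametrize("gene_len,bps", [(100, [10, 20]), (57, [3]), (1000, [1, 999])])
    def test_regions_tile_exactly(self, gene_len, bps):
        part = split_regions(gene_len, bps)
        assert part.regions[0][1] == 1 and part.regions[-1][2] == gene_len
        for (_, _, e1), (_, s2, _) in zip(part.regions, part.regions[1:]):
            assert s2 == e1 + 1
        assert sum(e - s + 1 for _, s, e in part.regions) == gene_len

    def test_unsorted_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            split_regions(100, [50, 30])

    def test_split_even_with_comparand(self):
        assert split_even((1, 1137), 3, comparand_len=356) == [
            (1, 356), (357, 712), (713, 1137)
        ]

    def test_split_even_equal_thirds(self):
        assert split_even((1, 9), 3) == [(1, 3), (4, 6), (7, 9)]

    @pytest.mark.parametrize("region,k", [((1, 100), 3), ((50, 64), 4), ((7, 7), 1)])
    def test_split_even_tiles(self, region, k):
        spans = split_even(region, k)
        assert spans[0][0] == region[0] and spans[-1][1] == region[1]
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 == e1 + 1


class TestPairwiseIdentity:
    def test_identical_member_reaches_100(self):
        m = _msa({"f": "ACGTACGT", "a": "ACGTACGT", "b": "ACCTACCT"})
        lo, hi = pairwise_identity(m, (1, 8), "f", ["a", "b"])
        assert hi == 100.0 and lo == 75.0

    def test_empty_group_rejected(self):
        m = _msa({"f": "ACGT", "a": "ACGT"})
        with pytest.raises(ValueError):
            pairwise_identity(m, (1, 4), "f", [])

    def test_matches_bruteforce_column_count(self, rng):
        cfg = CladeConfig(seed=13)
        msa, _ = evolve_clades(cfg)
        for _ in range(25):
            s = int(rng.integers(1, 1400))
            e = int(rng.integers(s, min(s + 400, 1506)))
            lo, hi = pairwise_identity(msa, (s, e), cfg.focal, cfg.native)
            brute = []
            frow = msa.seqs[cfg.focal]
            for t in cfg.native:
                row = msa.seqs[t]
                matches = sum(frow[i] == row[i] for i in range(s - 1, e))
                brute.append(100 * matches / (e - s + 1))
            assert lo == pytest.approx(min(brute)) and hi == pytest.approx(max(brute))


def _additive_matrix_tree(rng):
    """Random 4-taxon tree ((A,B),(C,D)) with positive branch lengths; returns
    the additive distance matrix and the expected split."""
    a, b, c, d, inner = rng.uniform(0.05, 1.0, size=5)
    taxa = ["A", "B", "C", "D"]
    dm = np.zeros((4, 4))
    dm[0, 1] = dm[1, 0] = a + b
    dm[0, 2] = dm[2, 0] = a + inner + c
    dm[0, 3] = dm[3, 0] = a + inner + d
    dm[1, 2] = dm[2, 1] = b + inner + c
    dm[1, 3] = dm[3, 1] = b + inner + d
    dm[2, 3] = dm[3, 2] = c + d
    return taxa, dm


class TestNjBootstrap:
    def test_nj_recovers_additive_topologies_exactly(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for _ in range(15):
            taxa, dm = _additive_matrix_tree(rng)
            tree = skbio_nj(DistanceMatrix(dm, taxa))
            sides = {frozenset(t.name for t in n.tips())
                     for n in tree.non_tips(include_self=False)}
            sides = {s if len(s) == 2 else frozenset(taxa) - s for s in sides}
            assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides

    def test_simulated_quartet_recovered_with_support(self):
        rng = np.random.default_rng(3)
        root = random_dna(rng, 2000)
        anc1, anc2 = mutate(rng, root, 0.05), mutate(rng, root, 0.05)
        seqs = {"A": mutate(rng, anc1, 0.02), "B": mutate(rng, anc1, 0.02),
                "C": mutate(rng, anc2, 0.02), "D": mutate(rng, anc2, 0.02)}
        msa = _msa(seqs)
        bt = nj_bootstrap(msa, n_boot=200, seed=1)
        key = frozenset({"C", "D"})  # side not containing taxa[0] == "A"
        assert key in bt.supports and bt.supports[key] >= 95

    def test_identical_pair_still_builds_tree(self):
        m = _msa({"A": "ACGTACGTAA", "B": "ACGTACGTAA",
                  "C": "ACGTACTTAA", "D": "AGGTACTTAC"})
        bt = nj_bootstrap(m, n_boot=20, seed=0)
        assert sorted(t.name for t in bt.tree.tips()) == ["A", "B", "C", "D"]

    def test_constant_span_rejected(self):
        m = _msa({t: "AAAA" for t in "ABCD"})
        with pytest.raises(ValueError):
            nj_bootstrap(m, n_boot=10, seed=0)

    def test_newick_carries_supports(self):
        cfg = CladeConfig(seed=4)
        msa, _ = evolve_clades(cfg)
        bt = nj_bootstrap(msa, n_boot=50, seed=2)
        nwk = bt.to_newick()
        assert nwk.endswith(";\n") or nwk.endswith(";")
        assert any(ch.isdigit() for ch in nwk.split(")")[-2])


def _boot(taxa, supports):
    return BootstrapTree(tree=None, supports={frozenset(k): v for k, v in supports.items()},
                         taxa=taxa)


class TestAssignOrigin:
    taxa = ["out", "f", "n1", "n2", "d1", "d2"]

    def test_sister_to_native_with_support(self):
        bt = _boot(self.taxa, {("f", "n1", "n2"): 98.0})
        call = assign_origin(bt, "f", {"n1", "n2"}, {"don": {"d1", "d2"}},
                             outgroup="out")
        assert call.verdict == "native" and call.support == 98.0

    def test_nested_in_foreign(self):
        bt = _boot(self.taxa, {("f", "d1", "d2"): 85.0})
        call = assign_origin(bt, "f", {"n1", "n2"}, {"don": {"d1", "d2"}},
                             outgroup="out")
        assert call.verdict == "foreign" and call.foreign_source == "don"

    def test_below_threshold_unresolved(self):
        bt = _boot(self.taxa, {("f", "d1"): 55.0})
        call = assign_origin(bt, "f", {"n1", "n2"}, {"don": {"d1", "d2"}},
                             outgroup="out")
        assert call.verdict == "unresolved" and call.support == 0.0

    def test_weak_sister_inside_supported_foreign_clade(self):
        bt = _boot(self.taxa, {("f", "d1"): 55.0, ("f", "d1", "d2"): 92.0})
        call = assign_origin(bt, "f", {"n1", "n2"}, {"don": {"d1", "d2"}},
                             outgroup="out")
        assert call.verdict == "foreign" and call.support == 92.0

    def test_mixed_clade_unresolved(self):
        bt = _boot(self.taxa, {("f", "n1", "d1"): 95.0})
        call = assign_origin(bt, "f", {"n1", "n2"}, {"don": {"d1", "d2"}},
                             outgroup="out")
        assert call.verdict == "unresolved"

    def test_missing_focal_rejected(self):
        bt = _boot(self.taxa, {})
        with pytest.raises(ValueError):
            assign_origin(bt, "ghost", {"n1"}, {}, outgroup="out")


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        cfg = CladeConfig(seed=9)
        msa, _ = evolve_clades(cfg)
        p = tmp_path / "aln.fasta"
        write_alignment(msa, p)
        back = read_alignment(p)
        assert back.taxa == msa.taxa and back.seqs == msa.seqs
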