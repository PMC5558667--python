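import numpy as np
import pytest

from bhlhkit.duplication_evolution import (
    ClockParams,
    KaKsResult,
    assign_segmental,
    classify_selection,
    codon_align,
    divergence_time,
    evaluate_pair,
    find_tandem_pairs,
    global_identity,
    ng86_kaks,
    syn_site_fraction,
    translate,
)
from bhlhkit.io_formats import GeneAnnotation, SyntenyBlock
from bhlhkit.synthetic_data import gen_codon_pairs, gen_duplication_layout

from ng86_oracle import oracle_ng86


class TestCodonAlign:
    def test_identical_gapless(self):
        cds = "ATGGCTGCT"
        pairs = codon_align(cds, cds, ("MAA", "MAA"))
        assert pairs == [("ATG", "ATG"), ("GCT", "GCT"), ("GCT", "GCT")]

    def test_gap_drops_one_column(self):
        cds_a = "ATGGCTGCT"   # M A A
        cds_b = "ATGGCT"      # M A
        pairs = codon_align(cds_a, cds_b, ("MAA", "MA-"))
        assert len(pairs) == 2

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            codon_align("ATGTAAGCT", "ATGGCTGCT", ("MXA", "MAA"))

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 2"):
            codon_align("ATGGCTGCT", "ATGGCTGCT", ("MVA", "MAA"))

    def test_terminal_stop_tolerated(self):
        pairs = codon_align("ATGGCTTAA", "ATGGCTTGA", ("MA", "MA"))
        assert len(pairs) == 2


class TestNG86:
    def test_identical_sequences(self):
        result = ng86_kaks([("ATG", "ATG"), ("GCT", "GCT")])
        assert result.sd == result.nd == 0
        assert result.ka == result.ks == 0.0
        assert result.ratio is None

    def test_hand_computed_ten_codon_example(self):
        pairs = [("GCT", "GCT")] * 9 + [("TTT", "TTC")]
        result = ng86_kaks(pairs)
        assert result.s_sites == pytest.approx(28 / 3)
        assert result.sd == pytest.approx(1.0)
        assert result.ps == pytest.approx(3 / 28)
        assert result.ks == pytest.approx(0.1156, abs=2e-4)
        assert result.ka == 0.0

    def test_site_conservation_invariant(self, rng):
        from bhlhkit.synthetic_data import _random_cds

        for _ in range(20):
            n = int(rng.integers(2, 60))
            a, b = _random_cds(rng, n), _random_cds(rng, n)
            pairs = list(zip([a[i:i + 3] for i in range(0, 3 * n, 3)],
                             [b[i:i + 3] for i in range(0, 3 * n, 3)]))
            result = ng86_kaks(pairs)
            assert result.s_sites + result.n_sites == pytest.approx(3 * n, abs=1e-9)
            assert result.sd <= result.s_sites + 1e-12
            assert result.nd <= result.n_sites + 1e-12

    def test_symmetry(self, rng):
        from bhlhkit.synthetic_data import _random_cds

        a, b = _random_cds(rng, 40), _random_cds(rng, 40)
        pa = [(a[i:i + 3], b[i:i + 3]) for i in range(0, 120, 3)]
        pb = [(y, x) for x, y in pa]
        ra, rb = ng86_kaks(pa), ng86_kaks(pb)
        for attr in ("s_sites", "n_sites", "sd", "nd", "ks", "ka"):
            assert getattr(ra, attr) == pytest.approx(getattr(rb, attr), abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        from bhlhkit.synthetic_data import _random_cds

        for _ in range(30):
            n = 50
            pairs, _ = gen_codon_pairs(n, omega=0.5, expected_ks=0.2, n_pairs=1,
                                       seed=int(rng.integers(1 << 30)))
            a, b = pairs[0]
            mine = ng86_kaks([(a[i:i + 3], b[i:i + 3]) for i in range(0, 3 * n, 3)])
            ref = oracle_ng86(a, b)
            for attr in ("s_sites", "n_sites", "sd", "nd", "ks", "ka"):
                expected = ref[attr]
                got = getattr(mine, attr)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected, abs=1e-10), attr

    def test_saturated_flagged(self):
        result = KaKsResult(10, 20, 9, 1, 0.9, 0.05, None, 0.05, None)
        assert classify_selection(result) == "undefined"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ng86_kaks([])


class TestSynFraction:
    def test_fourfold_codon(self):
        assert syn_site_fraction("GCT") == pytest.approx(1.0)  # Ala: 3rd pos fourfold

    def test_methionine_zero(self):
        assert syn_site_fraction("ATG") == pytest.approx(0.0)

    def test_phe_one_third(self):
        assert syn_site_fraction("TTT") == pytest.approx(1 / 3)


class TestClock:
    def test_zero_ks(self):
        assert divergence_time(0.0) == 0.0

    def test_direct_formula(self):
        assert divergence_time(0.13, ClockParams(6.5e-9)) == pytest.approx(10.0)

    def test_linearity(self):
        t1 = divergence_time(0.2)
        t2 = divergence_time(0.4)
        assert t2 == pytest.approx(2 * t1)

    def test_saturated_none(self):
        assert divergence_time(None) is None

    def test_bad_lambda(self):
        with pytest.raises(ValueError):
            ClockParams(0.0)


def make_genes(spec):
    """spec: list of (gene_id, chrom, start)."""
    return [
        GeneAnnotation(g, c, s, s + 500, "+", exons=[(s, s + 500)])
        for g, c, s in spec
    ]


class TestTandem:
    def test_adjacent_pair_called(self):
        genes = make_genes([("f1", "c1", 100), ("f2", "c1", 1000), ("x1", "c1", 5000)])
        pairs = find_tandem_pairs(["f1", "f2"], genes)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("f1", "f2")]
        assert pairs[0].dup_type == "tandem"

    def test_intervening_gene_blocks(self):
        genes = make_genes([("f1", "c1", 100), ("x1", "c1", 1000), ("f2", "c1", 5000)])
        assert find_tandem_pairs(["f1", "f2"], genes) == []

    def test_chromosome_boundary(self):
        genes = make_genes([("f1", "c1", 100), ("f2", "c2", 100)])
        assert find_tandem_pairs(["f1", "f2"], genes) == []

    def test_identity_threshold(self):
        genes = make_genes([("f1", "c1", 100), ("f2", "c1", 1000)])
        proteins = {"f1": "M" + "A" * 60, "f2": "M" + "W" * 60}
        assert find_tandem_pairs(["f1", "f2"], genes, proteins, identity_min=0.4) == []
        proteins["f2"] = proteins["f1"]
        assert len(find_tandem_pairs(["f1", "f2"], genes, proteins, identity_min=0.4)) == 1

    def test_invariant_to_other_chromosomes(self):
        base = [("f1", "c1", 100), ("f2", "c1", 1000)]
        extra = [("z%d" % i, "c9", 100 * i + 10) for i in range(1, 20)]
        p1 = find_tandem_pairs(["f1", "f2"], make_genes(base))
        p2 = find_tandem_pairs(["f1", "f2"], make_genes(base + extra))
        assert [(p.gene_a, p.gene_b) for p in p1] == [(p.gene_a, p.gene_b) for p in p2]


class TestSegmental:
    BLOCK = SyntenyBlock("chr1", 100_000, 200_000, "chr3", 500_000, 600_000, "b1")

    def test_containment(self):
        genes = [
            GeneAnnotation("a", "chr1", 150_000, 151_000, "+"),
            GeneAnnotation("b", "chr3", 550_000, 551_000, "+"),
        ]
        pairs = assign_segmental(genes, [self.BLOCK])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]
        assert pairs[0].dup_type == "segmental"

    def test_outside_block_no_pair(self):
        genes = [
            GeneAnnotation("a", "chr1", 950_000, 951_000, "+"),
            GeneAnnotation("b", "chr3", 550_000, 551_000, "+"),
        ]
        assert assign_segmental(genes, [self.BLOCK]) == []

    def test_straddler_uses_start(self):
        inside = GeneAnnotation("a", "chr1", 199_999, 210_000, "+")   # start inside
        outside = GeneAnnotation("c", "chr1", 200_001, 210_000, "+")  # start outside
        partner = GeneAnnotation("b", "chr3", 550_000, 551_000, "+")
        assert len(assign_segmental([inside, partner], [self.BLOCK])) == 1
        assert assign_segmental([outside, partner], [self.BLOCK]) == []

    def test_tandem_not_reflagged(self):
        genes = [
            GeneAnnotation("a", "chr1", 150_000, 151_000, "+"),
            GeneAnnotation("b", "chr3", 550_000, 551_000, "+"),
        ]
        assert assign_segmental(genes, [self.BLOCK], exclude={("a", "b")}) == []


class TestEstimatorRecovery:
    def test_omega_zero_forces_ka_zero(self):
        pairs, truth = gen_codon_pairs(100, omega=0.0, expected_ks=0.2, n_pairs=5, seed=11)
        for (a, b), entry in zip(pairs, truth.entries):
            assert entry["nonsyn_events"] == 0
            result = ng86_kaks([(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)])
            assert result.ka == pytest.approx(0.0)

    def test_expected_ks_zero_identical(self):
        pairs, _ = gen_codon_pairs(50, omega=0.5, expected_ks=0.0, n_pairs=3, seed=2)
        for a, b in pairs:
            assert a == b

    @pytest.mark.parametrize("omega", [0.2, 0.5, 1.0])
    def test_mean_omega_recovered(self, omega):
        pairs, _ = gen_codon_pairs(500, omega=omega, expected_ks=0.3, n_pairs=50,
                                   seed=int(omega * 1000) + 17)
        ratios = []
        for a, b in pairs:
            result = ng86_kaks([(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)])
            assert result.ratio is not None
            ratios.append(result.ratio)
        assert abs(float(np.mean(ratios)) - omega) < 0.08
        if omega == 0.2:
            assert all(r < 1 for r in ratios)


class TestLayoutDetection:
    def test_planted_sets_recovered(self):
        bundle, truth = gen_duplication_layout(3, 2, 3, seed=21)
        tandem = find_tandem_pairs(bundle["family"], bundle["genes"], bundle["proteins"])
        got_tandem = sorted((p.gene_a, p.gene_b) for p in tandem)
        assert got_tandem == [tuple(p) for p in truth.entries[0]["tandem"]]
        family_genes = [g for g in bundle["genes"] if g.gene_id in set(bundle["family"])]
        seg = assign_segmental(family_genes, bundle["blocks"],
                               exclude=set(got_tandem))
        got_seg = sorted((p.gene_a, p.gene_b) for p in seg)
        assert got_seg == [tuple(p) for p in truth.entries[0]["segmental"]]

    def test_empty_blocks_no_segmental(self):
        bundle, _ = gen_duplication_layout(2, 1, 1, seed=4)
        family_genes = [g for g in bundle["genes"] if g.gene_id in set(bundle["family"])]
        assert assign_segmental(family_genes, []) == []


class TestEvaluatePair:
    def test_fills_fields(self):
        pairs, _ = gen_codon_pairs(60, omega=0.2, expected_ks=0.3, n_pairs=1, seed=6)
        a, b = pairs[0]
        from bhlhkit.duplication_evolution import DuplicationPair

        pair = evaluate_pair(DuplicationPair("ga", "gb", "tandem"), {"ga": a, "gb": b})
        assert pair.kaks is not None
        assert pair.selection in ("purifying", "neutral", "positive", "undefined")
        assert pair.t_mya is None or pair.t_mya >= 0

    def test_global_identity_bounds(self):
        assert global_identity("MKV", "MKV") == 1.0
        assert 0.0 <= global_identity("MKVVV", "MWY") < 1.0
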