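import itertools

import numpy as np
import pytest

from targetmr import (
    GeneRegion,
    LDMatrix,
    build_instrument_set,
    extract_region,
    greedy_clump,
    joint_strength,
    load_gene_regions,
    per_snp_r2,
)
from targetmr.errors import NoInstrumentsError

from conftest import make_record


class TestExtractRegion:
    def test_flank_boundary_inclusive(self, adrb1_region):
        rec = make_record(pos=adrb1_region.start - 10_000, pval=1e-9)
        assert extract_region([rec], adrb1_region) == [rec]
        outside = make_record(pos=adrb1_region.start - 10_001, pval=1e-9)
        assert extract_region([outside], adrb1_region) == []

    def test_threshold_is_strict(self, adrb1_region):
        rec = make_record(pos=adrb1_region.start, pval=5e-8)
        assert extract_region([rec], adrb1_region) == []

    def test_empty_region_is_valid(self, adrb1_region):
        recs = [make_record(pos=adrb1_region.start, pval=0.5)]
        assert extract_region(recs, adrb1_region) == []

    def test_sorted_by_position_and_idempotent(self, adrb1_region):
        recs = [
            make_record("rs2", pos=adrb1_region.end, pval=1e-9),
            make_record("rs1", pos=adrb1_region.start, pval=1e-9),
            make_record("rs3", chrom="11", pos=adrb1_region.start, pval=1e-9),
        ]
        once = extract_region(recs, adrb1_region)
        assert [r.variant_id for r in once] == ["rs1", "rs2"]
        assert extract_region(once, adrb1_region) == once


def _brute_force_clump(candidates, ld, r2_threshold):
    """Exhaustive oracle: emulate the greedy rule by scanning candidates in
    p-value rank order and keeping each one compatible with all keepers."""
    ranked = sorted(candidates, key=lambda r: (r.pval, r.pos, r.variant_id))
    best = []
    for r in ranked:
        if all(ld.r2_between(r.variant_id, k.variant_id) < r2_threshold for k in best):
            best.append(r)
    return sorted(best, key=lambda r: r.pos)


class TestGreedyClump:
    @pytest.fixture
    def three_snp_ld(self):
        r2 = np.array([[1.0, 0.5, 0.05], [0.5, 1.0, 0.05], [0.05, 0.05, 1.0]])
        return LDMatrix(("rs1", "rs2", "rs3"), r2)

    def test_hand_worked_example(self, three_snp_ld):
        cands = [
            make_record("rs1", pos=100, pval=1e-10),
            make_record("rs2", pos=200, pval=1e-9),
            make_record("rs3", pos=300, pval=1e-8),
        ]
        kept = greedy_clump(cands, three_snp_ld, 0.1)
        assert [r.variant_id for r in kept] == ["rs1", "rs3"]

    def test_independent_snps_all_retained(self):
        ld = LDMatrix(("rs1", "rs2"), np.eye(2))
        cands = [make_record("rs1", pos=1), make_record("rs2", pos=2)]
        assert len(greedy_clump(cands, ld, 0.1)) == 2

    def test_single_candidate_retained(self):
        ld = LDMatrix(("rs1",), np.ones((1, 1)))
        assert len(greedy_clump([make_record("rs1")], ld, 0.1)) == 1

    def test_missing_candidate_names_variant(self):
        ld = LDMatrix(("rs1",), np.ones((1, 1)))
        with pytest.raises(KeyError, match="rs9"):
            greedy_clump([make_record("rs9")], ld, 0.1)

    def test_matches_brute_force_on_random_instances(self):
        """Greedy result equals the exhaustive rank-scan oracle on 200
        random instances of up to 8 variants."""
        rng = np.random.default_rng(20240817)
        for _ in range(200):
            m = int(rng.integers(1, 9))
            corr = rng.uniform(-1, 1, size=(m, m))
            r2 = np.clip((corr + corr.T) / 2, 0, 1) ** 2
            np.fill_diagonal(r2, 1.0)
            ids = tuple(f"rs{i}" for i in range(m))
            ld = LDMatrix(ids, r2)
            cands = [
                make_record(ids[i], pos=int(rng.integers(1, 1000)),
                            pval=float(rng.uniform(1e-12, 1e-8)))
                for i in range(m)
            ]
            thr = float(rng.uniform(0.05, 0.5))
            assert greedy_clump(cands, ld, thr) == _brute_force_clump(cands, ld, thr)

    def test_result_pairwise_r2_below_threshold(self):
        rng = np.random.default_rng(7)
        m = 12
        a = rng.uniform(0, 1, size=(m, m))
        r2 = ((a + a.T) / 2) ** 2
        np.fill_diagonal(r2, 1.0)
        ids = tuple(f"rs{i}" for i in range(m))
        ld = LDMatrix(ids, r2)
        cands = [make_record(ids[i], pos=i + 1, pval=float(rng.uniform(0, 1e-8)))
                 for i in range(m)]
        kept = greedy_clump(cands, ld, 0.3)
        for a_, b_ in itertools.combinations(kept, 2):
            assert ld.r2_between(a_.variant_id, b_.variant_id) < 0.3


class TestStrength:
    def test_null_beta_gives_zero_r2(self):
        assert per_snp_r2(0.0, 0.1, 100) == 0.0

    def test_arithmetic_identity(self):
        # F = 4 at n = 6: R2 = 4/(6-2+4)
        assert per_snp_r2(0.2, 0.1, 6) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert per_snp_r2(0.1, 0.05, 1000) == pytest.approx(4 / 1002)

    def test_r2_f_round_trip(self):
        """Feeding R2 back through F = (n-2) R2/(1-R2) recovers (beta/se)^2."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            beta = float(rng.normal(0, 0.5)) or 0.1
            se = float(rng.uniform(0.001, 0.5))
            n = int(rng.integers(10, 10**6))
            r2 = per_snp_r2(beta, se, n)
            f_back = (n - 2) * r2 / (1 - r2)
            assert f_back == pytest.approx((beta / se) ** 2, rel=1e-9)

    def test_n_too_small_raises(self):
        with pytest.raises(ValueError):
            per_snp_r2(0.1, 0.05, 2)

    def test_joint_strength_formula_and_permutation_invariance(self):
        r2s = [1e-4, 2e-4, 5e-5]
        j1, f1 = joint_strength(r2s, 10_000)
        j2, f2 = joint_strength(r2s[::-1], 10_000)
        assert j1 == pytest.approx(j2, rel=1e-14)
        assert f1 == pytest.approx(f2, rel=1e-14)
        assert j1 == pytest.approx(sum(r2s))
        k = 3
        assert f1 == pytest.approx(((10_000 - k - 1) / k) * j1 / (1 - j1))

    def test_joint_strength_nulls_and_identity(self):
        assert joint_strength([0.0, 0.0], 100)[1] == 0.0
        # R2 = 0.5 at n = 103, k = 2: F = 50 * 1 = 50
        assert joint_strength([0.25, 0.25], 103)[1] == pytest.approx(50.0)

    def test_printed_inputs_evaluate_through_formula(self):
        """Joint F at the published ADRB1 inputs (n=757,601, k=2, joint
        R²=0.00028) is ~106.1 by the formula; asserting the formula, not the
        separately printed (unrounded-input) value."""
        joint, f = joint_strength([0.00014, 0.00014], 757_601)
        assert joint == pytest.approx(0.00028)
        assert f == pytest.approx(106.09, abs=0.05)

    def test_joint_r2_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            joint_strength([0.6, 0.5], 1000)


class TestBuildInstrumentSet:
    def _data(self):
        region = GeneRegion("ADRB1", "10", 115_803_625, 115_806_663)
        recs = [
            make_record("rs1", pos=115_803_700, beta=0.3, se=0.03, pval=1e-20, n=500_000),
            make_record("rs2", pos=115_804_000, beta=0.25, se=0.03, pval=1e-15, n=500_000),
            make_record("rs3", pos=115_805_000, beta=0.2, se=0.03, pval=1e-11, n=500_000),
        ]
        r2 = np.array([[1.0, 0.8, 0.02], [0.8, 1.0, 0.02], [0.02, 0.02, 1.0]])
        return region, recs, LDMatrix(("rs1", "rs2", "rs3"), r2)

    def test_composition_and_strength(self):
        region, recs, ld = self._data()
        inst = build_instrument_set(recs, ld, region=region)
        assert inst.variant_ids == ["rs1", "rs3"]
        assert inst.k == 2
        assert inst.joint_r2 == pytest.approx(sum(inst.per_snp_r2))
        assert not inst.weak
        assert inst.ld.variant_ids == ("rs1", "rs3")

    def test_weak_flag_below_f10(self):
        region = GeneRegion("G", "1", 1000, 2000)
        rec = make_record("rs1", chrom="1", pos=1500, beta=0.03, se=0.01, pval=4e-8, n=100)
        ld = LDMatrix(("rs1",), np.ones((1, 1)))
        inst = build_instrument_set([rec], ld, region=region)
        assert (rec.beta / rec.se) ** 2 == pytest.approx(9.0)
        assert inst.weak

    def test_no_instruments_error_names_target(self):
        region, recs, ld = self._data()
        weak = [r for r in recs if False]
        with pytest.raises(NoInstrumentsError, match="ADRB1"):
            build_instrument_set(weak, ld, region=region)

    def test_genome_wide_mode_ignores_region(self):
        _, recs, ld = self._data()
        inst = build_instrument_set(recs, ld, region=None, target="genome_wide")
        assert inst.k == 2


class TestLDMatrix:
    def test_read_write_round_trip(self, tmp_path):
        ld = LDMatrix(("rs1", "rs2"), np.array([[1.0, 0.25], [0.25, 1.0]]))
        p = tmp_path / "ld.tsv"
        ld.write(p)
        back = LDMatrix.read(p)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r2, ld.r2)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_block_diagonal(self):
        a = LDMatrix(("rs1",), np.ones((1, 1)))
        b = LDMatrix(("rs2", "rs3"), np.array([[1.0, 0.4], [0.4, 1.0]]))
        m = LDMatrix.block_diagonal([a, b])
        assert m.r2_between("rs1", "rs2") == 0.0
        assert m.r2_between("rs2", "rs3") == 0.4


def test_packaged_regions_table():
    regions = load_gene_regions()
    by_gene = {r.gene: r for rs in regions.values() for r in rs}
    assert by_gene["ADRB1"].start == 115_803_625
    assert by_gene["ADRB1"].end == 115_806_663
    assert by_gene["ADRB1"].flank == 10_000
    assert len(regions["calcium_channel_blocker"]) == 11
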