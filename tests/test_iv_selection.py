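"""Instrument quality control: filters, clumping, Steiger directionality."""

import numpy as np
import pytest
from mrkit.errors import DataError
from mrkit.iv_selection import (
    LdMatrix,
    filter_maf,
    filter_significance,
    ld_clump,
    select_instruments,
    steiger_test,
)
from mrkit.meta_power import variance_explained
from mrkit.sumstats_io import exposure_record
from mrkit.synthetic import block_ld_matrix

from conftest import make_instruments, make_record


class TestSignificanceFilter:
    def test_strict_threshold(self):
        records = [make_record("rs1", pvalue=4e-8), make_record("rs2", pvalue=5e-8),
                   make_record("rs3", pvalue=1e-10)]
        kept = filter_significance(records, 5e-8)
        assert [r.snp_id for r in kept] == ["rs1", "rs3"]

    def test_vacuous_threshold_keeps_all(self):
        records = [make_record("rs1", pvalue=0.99), make_record("rs2", pvalue=0.5)]
        assert filter_significance(records, 1.0) == records

    def test_empty_input(self):
        assert filter_significance([], 5e-8) == []


@pytest.mark.parametrize("eaf,kept", [(0.005, False), (0.995, False), (0.30, True),
                                      (0.01, False), (0.011, True)])
def test_maf_filter(eaf, kept):
    records = filter_maf([make_record(eaf=eaf)], 0.01)
    assert (len(records) == 1) is kept


def identity_ld(ids):
    return LdMatrix(snp_ids=tuple(ids), r2=np.eye(len(ids)))


class TestLdClump:
    def test_single_record_survives(self):
        r = make_record("rs1")
        assert ld_clump([r], identity_ld(["rs1"])) == [r]

    def test_correlated_pair_keeps_smaller_p(self):
        records = [make_record("rs1", pvalue=1e-9), make_record("rs2", pvalue=1e-10)]
        ld = LdMatrix(("rs1", "rs2"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        kept = ld_clump(records, ld, r2_limit=0.1)
        assert [r.snp_id for r in kept] == ["rs2"]

    def test_independent_triple_all_survive(self):
        records = [make_record(f"rs{i}", pvalue=10.0**-(9 + i)) for i in range(3)]
        ld = LdMatrix(tuple(f"rs{i}" for i in range(3)),
                      np.eye(3) + 0.05 - 0.05 * np.eye(3))
        kept = ld_clump(records, ld, r2_limit=0.1)
        assert len(kept) == 3
        # output ordered by ascending p-value
        assert [r.snp_id for r in kept] == ["rs2", "rs1", "rs0"]

    def test_missing_snp_is_hard_error(self):
        records = [make_record("rs1"), make_record("rs_absent")]
        with pytest.raises(DataError, match="rs_absent"):
            ld_clump(records, identity_ld(["rs1"]))

    def test_distant_snps_not_clumped(self):
        records = [make_record("rs1", pvalue=1e-10), make_record("rs2", pvalue=1e-9)]
        ld = LdMatrix(("rs1", "rs2"), np.array([[1.0, 0.9], [0.9, 1.0]]))
        positions = {"rs1": 1_000_000, "rs2": 1_000_000 + 10_001 * 1000}
        kept = ld_clump(records, ld, r2_limit=0.1, positions=positions, window_kb=10_000)
        assert len(kept) == 2

    def test_cross_chromosome_never_clumped(self):
        records = [make_record("rs1", pvalue=1e-10), make_record("rs2", pvalue=1e-9)]
        ld = LdMatrix(("rs1", "rs2"), np.array([[1.0, 0.9], [0.9, 1.0]]))
        positions = {"rs1": ("chr1", 100), "rs2": ("chr2", 200)}
        assert len(ld_clump(records, ld, 0.1, positions, 10_000)) == 2

    def test_tie_break_by_position_then_id(self):
        records = [make_record("rsB", pvalue=1e-9), make_record("rsA", pvalue=1e-9)]
        ld = LdMatrix(("rsA", "rsB"), np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = ld_clump(records, ld, 0.1, positions={"rsA": 200, "rsB": 100})
        assert [r.snp_id for r in kept] == ["rsB"]  # smaller bp wins the tie
        kept = ld_clump(records, ld, 0.1)  # no positions: lexicographic id
        assert [r.snp_id for r in kept] == ["rsA"]


def clump_oracle(records, ld, r2_limit):
    """Independent formulation: scan candidates in p order, keep a record iff
    it is compatible with everything already kept (all pairs within window)."""
    kept = []
    for r in sorted(records, key=lambda r: (r.pvalue, r.snp_id)):
        if all(ld.lookup(r.snp_id, k.snp_id) <= r2_limit for k in kept):
            kept.append(r)
    return kept


class TestClumpOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        ids = [f"rs{i}" for i in range(k)]
        a = rng.uniform(0, 1, size=(k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(tuple(ids), r2)
        records = [make_record(ids[i], pvalue=float(rng.uniform(1e-12, 1e-6)))
                   for i in range(k)]
        kept = ld_clump(records, ld, r2_limit=0.1)
        oracle = clump_oracle(records, ld, r2_limit=0.1)
        assert [r.snp_id for r in kept] == [r.snp_id for r in oracle]
        # pairwise independence invariant, exhaustively
        for i, a_rec in enumerate(kept):
            for b_rec in kept[i + 1:]:
                assert ld.lookup(a_rec.snp_id, b_rec.snp_id) <= 0.1


class TestSteiger:
    def test_zero_outcome_effect_supports_forward_direction(self):
        inst = make_instruments([0.2], [0.0], [0.01])[0]
        res = steiger_test(inst)
        assert res.r2_outcome == 0.0
        assert res.correct_direction

    def test_reverse_causal_snp_detected(self):
        # outcome z = 20 at n_outcome = 1000: r2_outcome = 400/1400 ~ 0.286
        inst = make_instruments([0.2], [0.2], [0.01], sx=[0.045], n_out=1000)[0]
        res = steiger_test(inst)
        assert res.r2_outcome == pytest.approx(400 / 1400)
        assert res.r2_exposure < res.r2_outcome
        assert not res.correct_direction

    def test_exposure_r2_matches_variance_explained(self):
        inst = make_instruments([0.2], [0.01], [0.01])[0]
        res = steiger_test(inst)
        assert res.r2_exposure == pytest.approx(variance_explained(exposure_record(inst)))


class TestSelectionPipeline:
    def make_inputs(self):
        exposure = [
            make_record("rs1", eaf=0.3, beta=0.4, se=0.04, pvalue=1e-24),
            make_record("rs2", eaf=0.2, beta=0.35, se=0.04, pvalue=1e-18),
            make_record("rs3", eaf=0.005, beta=0.5, se=0.05, pvalue=1e-22),  # rare
            make_record("rs4", eaf=0.4, beta=0.3, se=0.05, pvalue=1e-4),     # not GW significant
        ]
        outcome = [make_record(r.snp_id, eaf=r.eaf, beta=0.01, se=0.005, n=100_000)
                   for r in exposure]
        ld = block_ld_matrix([r.snp_id for r in exposure], [4], r2_within=0.05)
        return exposure, outcome, ld

    def test_pipeline_is_pure_subset_filter(self):
        exposure, outcome, ld = self.make_inputs()
        insts = select_instruments(exposure, outcome, ld=ld)
        ids = {i.snp_id for i in insts}
        assert ids == {"rs1", "rs2"}
        assert ids <= {r.snp_id for r in exposure}

    def test_pipeline_idempotent(self):
        exposure, outcome, ld = self.make_inputs()
        insts1 = select_instruments(exposure, outcome, ld=ld)
        surviving = [r for r in exposure if r.snp_id in {i.snp_id for i in insts1}]
        insts2 = select_instruments(surviving, outcome, ld=ld)
        assert insts1 == insts2

    def test_exclusion_list_respected(self):
        exposure, outcome, ld = self.make_inputs()
        insts = select_instruments(exposure, outcome, ld=ld, exclude_snps=["rs1"])
        assert {i.snp_id for i in insts} == {"rs2"}


class TestLdMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(DataError):
            LdMatrix(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))

    def test_bad_diagonal_rejected(self):
        with pytest.raises(DataError):
            LdMatrix(("a", "b"), np.array([[0.9, 0.5], [0.5, 1.0]]))

    def test_file_roundtrip(self, tmp_path):
        ld = block_ld_matrix(["rs1", "rs2", "rs3"], [2, 1], r2_within=0.7)
        path = tmp_path / "ld.tsv"
        ld.to_file(path)
        back = LdMatrix.from_file(path)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r2, ld.r2)
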