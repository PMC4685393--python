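"""LD-aware gene-level association test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netgwas import gene_scoring as gs
from netgwas import simulate as sim
from netgwas.errors import DataError


def snp_table(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "P"])


def gene_table(rows):
    return pd.DataFrame(rows, columns=["GENE", "CHR", "START", "END"])


class TestSnpToGeneMapping:
    GENES = gene_table([("G1", "1", 100_000, 101_000)])

    @pytest.mark.parametrize("pos,mapped", [
        (80_000, True),    # boundary: start - flank inclusive
        (79_999, False),   # one below
        (121_000, True),   # end + flank inclusive
        (121_001, False),
        (100_500, True),
    ])
    def test_flanked_window_boundaries(self, pos, mapped):
        snps = snp_table([("rs1", "1", pos, 0.5)])
        out = gs.map_snps_to_genes(snps, self.GENES, flank=20_000)
        assert ("G1" in out) == mapped

    def test_snp_can_map_to_multiple_genes(self):
        genes = gene_table([("A", "1", 50_000, 60_000),
                            ("B", "1", 55_000, 70_000),
                            ("C", "1", 62_000, 80_000)])
        snps = snp_table([("rs1", "1", 58_000, 0.5)])
        out = gs.map_snps_to_genes(snps, genes, flank=20_000)
        assert set(out) == {"A", "B", "C"}

    def test_brute_force_interval_agreement(self):
        rng = np.random.default_rng(5)
        genes = gene_table([(f"G{i}", "1", int(s), int(s) + 5_000)
                            for i, s in enumerate(rng.integers(1, 500_000, 30))])
        snps = snp_table([(f"rs{i}", "1", int(p), 0.5)
                          for i, p in enumerate(rng.integers(1, 500_000, 200))])
        out = gs.map_snps_to_genes(snps, genes, flank=2_000)
        for g in genes.itertuples(index=False):
            expect = {s.SNP for s in snps.itertuples(index=False)
                      if g.START - 2_000 <= s.POS <= g.END + 2_000}
            assert set(out.get(g.GENE, [])) == expect

    def test_non_autosomal_snps_dropped(self):
        snps = snp_table([("rs1", "X", 100_500, 0.5), ("rs2", "1", 100_500, 0.5)])
        out = gs.map_snps_to_genes(snps, self.GENES, flank=0)
        assert out == {"G1": ["rs2"]}

    def test_duplicate_snp_ids_rejected(self):
        snps = snp_table([("rs1", "1", 1, 0.5), ("rs1", "1", 2, 0.5)])
        with pytest.raises(DataError):
            gs.map_snps_to_genes(snps, self.GENES)


class TestGeneStatistic:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.05], 3.8415),
        ([1.0], 0.0),
        ([0.05, 0.05], 7.6829),
    ])
    def test_chi_square_quantile_sum(self, pvals, expected):
        assert gs.gene_statistic(pvals) == pytest.approx(expected, abs=1e-4)

    def test_empty_gene_raises(self):
        with pytest.raises(DataError):
            gs.gene_statistic([])

    def test_extreme_pvalue_is_clamped_finite(self):
        assert np.isfinite(gs.gene_statistic([1e-300]))


class TestLdCorrelation:
    def test_single_snp_identity(self):
        ld = gs.ld_correlation(np.array([[0., 1, 2, 1, 0]]), ["rs1"])
        assert np.allclose(ld.matrix, [[1.0]])

    def test_identical_vectors_repaired(self):
        x = np.array([0., 1, 2, 1, 0, 2, 1])
        ld = gs.ld_correlation(np.vstack([x, x]), ["a", "b"])
        assert ld.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)
        # repaired matrix admits a Cholesky factorisation
        np.linalg.cholesky(ld.matrix)

    def test_monomorphic_dropped(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(3, 50)).astype(float)
        d[1] = 1.0
        ld = gs.ld_correlation(d, ["a", "b", "c"])
        assert ld.snp_ids == ("a", "c")

    def test_all_missing_raises(self):
        d = np.full((1, 10), np.nan)
        with pytest.raises(DataError, match="rs9"):
            gs.ld_correlation(d, ["rs9"])

    def test_ar1_block_recovery(self):
        dos, _ = sim.simulate_snp_block(5, 0.8, 5_000, seed=1)
        ld = gs.ld_correlation(dos)
        adj = np.array([ld.matrix[i, i + 1] for i in range(4)])
        assert np.abs(adj - 0.8).mean() < 0.03


class TestGenePvalue:
    def test_zero_statistic_gives_p_one(self):
        ld = gs.LdMatrix(("a",), np.eye(1))
        p, _ = gs.gene_pvalue(0.0, ld, gs.SimulationSchedule((500,), ()), seed=1)
        assert p == 1.0

    def test_single_snp_reduces_to_snp_pvalue(self):
        snp_p = 0.013
        ld = gs.LdMatrix(("a",), np.eye(1))
        stat = gs.gene_statistic([snp_p])
        p, n = gs.gene_pvalue(stat, ld, gs.SimulationSchedule((50_000,), ()), seed=3)
        assert abs(p - snp_p) < 3 * np.sqrt(snp_p * (1 - snp_p) / n)

    def test_identity_ld_matches_chi2(self):
        ld = gs.LdMatrix(tuple("abcde"), np.eye(5))
        draws = gs.simulate_null_sums(ld, 10_000, np.random.default_rng(4))
        assert stats.kstest(draws, "chi2", args=(5,)).pvalue > 0.01

    def test_p_floor_and_monotonicity(self):
        ld = gs.LdMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        sched = gs.SimulationSchedule((2_000,), ())
        pvals = [gs.gene_pvalue(s, ld, sched, seed=9)[0] for s in (1.0, 5.0, 20.0, 80.0)]
        assert all(p >= 1 / 2_001 for p in pvals)
        assert pvals == sorted(pvals, reverse=True)

    def test_schedule_escalates_for_small_p(self):
        ld = gs.LdMatrix(("a",), np.eye(1))
        sched = gs.SimulationSchedule((500, 5_000), (0.1,))
        _, n_hi = gs.gene_pvalue(30.0, ld, sched, seed=2)   # p tiny -> escalate
        _, n_lo = gs.gene_pvalue(0.5, ld, sched, seed=2)    # p large -> stop early
        assert (n_hi, n_lo) == (5_000, 500)


class TestScoreAllGenes:
    @pytest.fixture
    def small_study(self):
        rng = np.random.default_rng(17)
        genes = gene_table([(f"G{i}", "1", 1 + i * 200_000, 100_000 + i * 200_000)
                            for i in range(10)])
        snp_rows, dosage_rows = [], {}
        for i in range(7):  # genes G0..G6 get 3 SNPs; G7..G9 none
            dos, pv = sim.simulate_snp_block(3, 0.5, 400, seed=100 + i)
            for j in range(3):
                sid = f"rs{i}_{j}"
                snp_rows.append((sid, "1", 10_000 + i * 200_000 + j * 50, pv[j]))
                dosage_rows[sid] = dos[j]
        snps = snp_table(snp_rows)
        dosages = pd.DataFrame(dosage_rows).T
        return snps, genes, dosages

    def test_genes_without_snps_omitted(self, small_study):
        snps, genes, dosages = small_study
        out = gs.score_all_genes(snps, genes, dosages, seed=1,
                                 schedule=gs.SimulationSchedule((500,), ()))
        assert len(out) == 7
        assert set(out["GENE"]) == {f"G{i}" for i in range(7)}

    def test_deterministic_given_seed(self, small_study):
        snps, genes, dosages = small_study
        sched = gs.SimulationSchedule((500,), ())
        a = gs.score_all_genes(snps, genes, dosages, seed=5, schedule=sched)
        b = gs.score_all_genes(snps, genes, dosages, seed=5, schedule=sched)
        pd.testing.assert_frame_equal(a, b)

    def test_table_round_trip(self, small_study, tmp_path):
        snps, genes, dosages = small_study
        out = gs.score_all_genes(snps, genes, dosages, seed=1,
                                 schedule=gs.SimulationSchedule((500,), ()))
        gs.write_gene_scores(out, tmp_path / "scores.tsv")
        back = gs.read_gene_scores(tmp_path / "scores.tsv")
        assert np.allclose(back["P"], out["P"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=8))
def test_statistic_additive_and_nonnegative(pvals):
    total = gs.gene_statistic(pvals)
    assert total >= 0
    parts = sum(gs.gene_statistic([p]) for p in pvals)
    assert total == pytest.approx(parts, rel=1e-9)
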