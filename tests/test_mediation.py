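"""Mediation screen, effect decomposition, pseudo markers, regression drop."""

import numpy as np
import pandas as pd
import pytest

import eqtl_atlas as ea
from eqtl_atlas.eqtl_pipeline import QTLRecord
from eqtl_atlas.expression_qc import log_transform, strain_means


class TestEstimateProportion:
    def test_full_mediation_noiseless(self):
        rng = np.random.default_rng(0)
        x = (rng.random(100) < 0.5).astype(float)
        m = 0.5 * x + 0.01 * rng.standard_normal(100)
        y = m.copy()
        total, direct, indirect, prop, ok = ea.estimate_proportion(x, m, y)
        assert prop == pytest.approx(1.0, abs=1e-10)
        assert abs(direct) < 1e-10
        assert ok

    def test_independent_mediator_no_mediation(self):
        rng = np.random.default_rng(1)
        x = (rng.random(400) < 0.5).astype(float)
        m = rng.standard_normal(400)
        y = 0.8 * x + rng.standard_normal(400)
        total, direct, indirect, prop, ok = ea.estimate_proportion(x, m, y)
        assert abs(prop) < 0.1

    def test_difference_equals_product_identity(self):
        """c - c' == a*b exactly for linear least squares on one sample."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(20, 80)
            x = rng.standard_normal(n)
            m = 0.5 * x + rng.standard_normal(n)
            y = 0.3 * x + 0.7 * m + rng.standard_normal(n)
            total, direct, indirect, _, _ = ea.estimate_proportion(x, m, y)
            # product method: a from M ~ X, b from Y ~ X + M
            ones = np.ones(n)
            a = np.linalg.lstsq(np.column_stack([ones, x]), m, rcond=None)[0][1]
            b = np.linalg.lstsq(np.column_stack([ones, x, m]), y, rcond=None)[0][2]
            assert indirect == pytest.approx(a * b, abs=1e-10)

    def test_zero_total_uninterpretable(self):
        rng = np.random.default_rng(3)
        x = np.tile([0.0, 1.0], 50)
        m = rng.standard_normal(100)
        y = np.tile([1.0, 1.0], 50) + 0 * x
        y = y + 1e-15 * rng.standard_normal(100)
        total, direct, indirect, prop, ok = ea.estimate_proportion(x, m, y)
        assert not ok


class TestMedTest:
    def test_extreme_case_minimal_padj(self):
        """Y = M = X exactly: the mediator is top-ranked at the minimal p."""
        x = np.tile([0.0, 1.0], 25)
        M = np.column_stack([x, np.random.default_rng(4).standard_normal(50)])
        res = ea.med_test(x, M, x.copy(), n_perm=200, seed=0)
        # perfect collinearity with X is flagged and excluded
        assert bool(res["collinear"][0])
        x2 = np.tile([0.0, 1.0], 25)
        rng = np.random.default_rng(5)
        m = 0.9 * x2 + 0.1 * rng.standard_normal(50)
        y = m.copy()
        res2 = ea.med_test(x2, np.column_stack([m, rng.standard_normal(50)]), y,
                           n_perm=200, seed=0)
        assert res2["estimate"][0] == res2["estimate"].max()
        assert res2["p_adj"][0] == pytest.approx(1 / 201)

    def test_padj_monotone_in_estimate(self):
        rng = np.random.default_rng(6)
        n, p = 120, 30
        x = (rng.random(n) < 0.5).astype(float)
        M = rng.standard_normal((n, p))
        M[:, 3] += 0.8 * x
        y = 0.7 * M[:, 3] + rng.standard_normal(n)
        res = ea.med_test(x, M, y, n_perm=300, seed=1)
        res = res.sort_values("estimate", ascending=False)
        padj = res["p_adj"].to_numpy()
        assert np.all(np.diff(padj) >= -1e-12)

    def test_planted_mediator_ranked_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            n, p = 150, 50
            x = (rng.random(n) < 0.5).astype(float)
            M = rng.standard_normal((n, p))
            M[:, 11] = 0.8 * x + 0.6 * rng.standard_normal(n)
            y = 0.5 * x + 1.0 * M[:, 11] + 0.8 * rng.standard_normal(n)
            res = ea.med_test(x, M, y, n_perm=100, seed=seed)
            if res["estimate"].idxmax() == 11:
                wins += 1
        assert wins >= 9

    def test_null_family_wise_error(self):
        """With no mediation, p_adj < 0.05 for any mediator in <= ~5% of runs."""
        false_pos = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(900 + seed)
            n, p = 80, 25
            x = (rng.random(n) < 0.5).astype(float)
            M = rng.standard_normal((n, p))
            y = 0.6 * x + rng.standard_normal(n)
            res = ea.med_test(x, M, y, n_perm=200, seed=seed)
            if (res["p_adj"] < 0.05).any():
                false_pos += 1
        assert false_pos / n_runs <= 0.1  # binomial slack around the 5% level

    def test_nan_entries_restrict_strains(self):
        rng = np.random.default_rng(7)
        n = 100
        x = (rng.random(n) < 0.5).astype(float)
        m = 0.9 * x + 0.3 * rng.standard_normal(n)
        m[:20] = np.nan
        y = m.copy()
        y[np.isnan(y)] = 0.0
        res = ea.med_test(x, m[:, None], y, n_perm=100, seed=0)
        assert np.isfinite(res["estimate"][0])


class TestCallSignificant:
    def test_own_percentile_not_significant(self):
        res = pd.DataFrame({"mediator": ["a"], "estimate": [0.5], "p_adj": [0.2]})
        out = ea.call_significant(res)
        assert not out["significant"][0]  # strict > against its own p99

    def test_small_padj_significant(self):
        res = pd.DataFrame(
            {"mediator": ["a", "b"], "estimate": [0.1, 0.2], "p_adj": [0.049, 0.5]}
        )
        out = ea.call_significant(res)
        assert bool(out["significant"][0])

    def test_rule_matches_direct_oracle(self):
        rng = np.random.default_rng(8)
        res = pd.DataFrame(
            {
                "mediator": [f"m{i}" for i in range(200)],
                "estimate": rng.random(200),
                "p_adj": rng.random(200),
            }
        )
        out = ea.call_significant(res, alpha=0.05, pct=99)
        cut = np.percentile(res["estimate"], 99)
        oracle = (res["p_adj"] < 0.05) | (res["estimate"] > cut)
        assert (out["significant"] == oracle).all()


class TestPseudoMarker:
    TABLE = pd.DataFrame(
        {
            "gene": ["g1", "g1", "g1", "g2"],
            "variant": ["v1", "v2", "v3", "v4"],
            "strain": ["A", "B", "B", "C"],
        }
    )

    def test_union_of_carriers(self):
        d = ea.make_pseudo_marker(self.TABLE, "g1", ["A", "B", "C", "D"])
        assert list(d) == [1.0, 1.0, 0.0, 0.0]

    def test_monomorphic_warned(self):
        with pytest.warns(RuntimeWarning):
            d = ea.make_pseudo_marker(self.TABLE, "g2", ["C"])
        assert list(d) == [1.0]

    def test_absent_gene_raises(self):
        with pytest.raises(ea.EmptyInputError):
            ea.make_pseudo_marker(self.TABLE, "nope", ["A"])


class TestAssembleTriples:
    def _qtl(self, left, right, marker="mX", chrom="II"):
        return QTLRecord("pheno", chrom, marker, (left + right) // 2, 8.0, left, right, 0.3)

    def _geno(self, n=40):
        rng = np.random.default_rng(9)
        markers = pd.DataFrame({"marker": ["mX"], "chrom": ["II"], "bp": [2_000_000]})
        strains = np.array([f"S{i}" for i in range(n)], dtype=object)
        return ea.GenotypeMatrix(strains, markers, (rng.random((n, 1)) < 0.5).astype(float))

    def test_boundary_overlap_included_and_variation_filter(self):
        G = self._geno()
        rng = np.random.default_rng(10)
        n_med = 30
        eqtl = pd.DataFrame(
            {
                "trait": [f"T{i}" for i in range(n_med)],
                "chrom": "II",
                "interval_left_bp": 1_000_000,
                "interval_right_bp": 2_000_000,  # touches QTL left edge
            }
        )
        expr = pd.DataFrame(
            rng.standard_normal((n_med, 40)),
            index=[f"T{i}" for i in range(n_med)],
            columns=list(G.strains),
        )
        expr.iloc[:5] = 3.14  # constant mediators fail the variation filter
        pheno = pd.Series(rng.standard_normal(40), index=G.strains)
        out = ea.assemble_triples(self._qtl(2_000_000, 3_000_000), eqtl, expr, G, pheno)
        assert len(out) == n_med - 5

    def test_no_overlap_empty(self):
        G = self._geno()
        eqtl = pd.DataFrame(
            {"trait": ["T0"], "chrom": ["II"], "interval_left_bp": [1], "interval_right_bp": [10]}
        )
        expr = pd.DataFrame(np.zeros((1, 40)), index=["T0"], columns=list(G.strains))
        pheno = pd.Series(np.zeros(40), index=G.strains)
        out = ea.assemble_triples(self._qtl(2_000_000, 3_000_000), eqtl, expr, G, pheno)
        assert out.empty

    def test_overlap_count_bookkeeping(self):
        """1193 overlapping eQTL, 36 failing variation -> 1157 analyses."""
        n = 60
        G = self._geno(n)
        rng = np.random.default_rng(11)
        n_med = 1193
        ids = [f"T{i}" for i in range(n_med)]
        eqtl = pd.DataFrame(
            {
                "trait": ids,
                "chrom": "II",
                "interval_left_bp": 1_500_000,
                "interval_right_bp": 2_500_000,
            }
        )
        expr = pd.DataFrame(
            rng.standard_normal((n_med, n)), index=ids, columns=list(G.strains)
        )
        expr.iloc[:36] = 0.0  # no variation
        pheno = pd.Series(rng.standard_normal(n), index=G.strains)
        out = ea.assemble_triples(self._qtl(2_000_000, 3_000_000), eqtl, expr, G, pheno)
        assert len(out) == 1157


class TestRegressionDrop:
    def test_complete_mediation_removes_signal(self):
        rng = np.random.default_rng(12)
        n = 120
        x = (rng.random(n) < 0.5).astype(float)
        m = 1.0 * x + 0.05 * rng.standard_normal(n)
        y = 2.0 * m + 0.1 * rng.standard_normal(n)  # (near-)complete mediation
        expr = pd.DataFrame(
            np.vstack([m, rng.standard_normal((4, n))]),
            index=["med"] + [f"null{i}" for i in range(4)],
            columns=[f"S{i}" for i in range(n)],
        )
        out = ea.regression_drop_scan(y, expr, x, np.eye(n)).set_index("transcript")
        base = out["baseline"].iloc[0]
        assert base > 5
        assert out.loc["med", "neglog10p"] < 1.5  # signal gone
        # independent transcripts stay near baseline
        others = out.drop("med")["neglog10p"]
        assert (np.abs(others - base) < max(2.0, 0.5 * base)).all()

    def test_planted_mediator_largest_drop(self, small_study):
        sim = small_study
        med = sim.truth.mediation_row
        traits = strain_means(log_transform(sim.tpm))
        x = sim.genotypes.dosage_of(med["exposure"])
        K = ea.kinship(ea.ld_prune(ea.filter_markers(sim.genotypes))).K
        sub = traits.loc[
            [med["mediator"]] + [t for t in traits.index[:30] if t != med["mediator"]]
        ]
        out = ea.regression_drop_scan(
            sim.phenotype.to_numpy(), sub, x, K
        ).set_index("transcript")
        drops = out["baseline"] - out["neglog10p"]
        assert drops.idxmax() == med["mediator"]


class TestMediateTrait:
    def test_recovers_planted_mediator(self, small_study, small_fit):
        sim = small_study
        med = sim.truth.mediation_row
        traits = small_fit.trait_matrix
        # organism QTL at the exposure marker with a generous interval
        m = sim.genotypes.markers.set_index("marker").loc[med["exposure"]]
        qtl = QTLRecord(
            "pheno", m["chrom"], med["exposure"], int(m["bp"]), 8.0,
            max(int(m["bp"]) - 300_000, 1), int(m["bp"]) + 300_000, 0.3,
        )
        eqtl = small_fit.eqtl
        out = ea.mediate_trait(
            qtl, eqtl, traits, sim.genotypes, sim.phenotype, n_perm=200, seed=0
        )
        assert med["mediator"] in set(out["mediator"])
        row = out.set_index("mediator").loc[med["mediator"]]
        assert row["p_adj"] < 0.05
        assert row["significant"]
        assert abs(row["proportion_mediated"] - med["proportion"]) < 0.25
        # linear identity: total = direct + indirect
        assert row["total_effect"] == pytest.approx(
            row["direct_effect"] + row["indirect_effect"], abs=1e-10
        )
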