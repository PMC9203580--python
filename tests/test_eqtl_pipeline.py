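"""QTL calling, intervals, classification, LD, permutation FDR, fine mapping."""

import numpy as np
import pandas as pd
import pytest

import eqtl_atlas as ea
from eqtl_atlas.eqtl_pipeline import QTLRecord, call_qtl, classify_eqtl, qtl_frame
from eqtl_atlas.expression_qc import log_transform, strain_means
from eqtl_atlas.mixedmodel import ScanResult


def fake_scan(neglog10p, trait="T"):
    m = len(neglog10p)
    return ScanResult(
        trait=trait,
        neglog10p=np.asarray(neglog10p, dtype=float),
        beta=np.zeros(m),
        se=np.ones(m),
        monomorphic=np.zeros(m, dtype=bool),
        n_used=100,
    )


def markers_frame(m, chrom="I", spacing=1000):
    return pd.DataFrame(
        {"marker": [f"m{j}" for j in range(m)], "chrom": chrom, "bp": (np.arange(m) + 1) * spacing}
    )


class TestCallQtl:
    def test_interval_index_arithmetic(self):
        """Significant markers 500-510 -> one QTL, interval markers 400-610."""
        m = 1000
        nl = np.zeros(m)
        nl[500:511] = 8.0
        rng = np.random.default_rng(0)
        dosage = (rng.random((50, m)) < 0.5).astype(float)
        y = rng.standard_normal(50)
        recs = call_qtl("T", fake_scan(nl), markers_frame(m), dosage, y, threshold=5.0)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.peak_marker == "m500"  # tie -> leftmost
        assert rec.interval_left_bp == 401 * 1000
        assert rec.interval_right_bp == 611 * 1000

    def test_interval_clamped_at_chromosome_ends(self):
        m = 150
        nl = np.zeros(m)
        nl[5] = 9.0
        rng = np.random.default_rng(1)
        dosage = (rng.random((50, m)) < 0.5).astype(float)
        recs = call_qtl("T", fake_scan(nl), markers_frame(m), dosage,
                        rng.standard_normal(50), threshold=5.0)
        assert recs[0].interval_left_bp == 1000  # clamped to first marker
        assert recs[0].interval_right_bp == 106 * 1000

    def test_gap_splits_qtl(self):
        m = 3000
        nl = np.zeros(m)
        nl[[10, 2500]] = 7.0
        rng = np.random.default_rng(2)
        dosage = (rng.random((40, m)) < 0.5).astype(float)
        recs = call_qtl("T", fake_scan(nl), markers_frame(m), dosage,
                        rng.standard_normal(40), threshold=5.0, gap_markers=1000)
        assert len(recs) == 2

    def test_no_significant_marker_empty(self):
        m = 100
        rng = np.random.default_rng(3)
        dosage = (rng.random((40, m)) < 0.5).astype(float)
        recs = call_qtl("T", fake_scan(np.zeros(m)), markers_frame(m), dosage,
                        rng.standard_normal(40), threshold=5.0)
        assert recs == []

    def test_lowering_threshold_keeps_peaks(self):
        rng = np.random.default_rng(4)
        m = 400
        nl = rng.uniform(0, 9, m)
        dosage = (rng.random((40, m)) < 0.5).astype(float)
        y = rng.standard_normal(40)
        hi = call_qtl("T", fake_scan(nl), markers_frame(m), dosage, y, threshold=7.0)
        lo = call_qtl("T", fake_scan(nl), markers_frame(m), dosage, y, threshold=5.0)
        hi_peaks = {r.peak_marker for r in hi}
        lo_sig = set()
        for r in lo:
            lo_sig.add(r.peak_marker)
        # every high-threshold peak is still significant at the lower threshold
        sig_markers_lo = {f"m{j}" for j in np.flatnonzero(nl >= 5.0)}
        assert hi_peaks <= sig_markers_lo


class TestMapTrait:
    def test_exact_marker_trait(self, pruned_panel):
        """y equal to one marker's dosage maps to that marker with VE=1."""
        G, K = pruned_panel
        y = G.dosage[:, 37].copy()
        recs = ea.map_trait(y, G, K, threshold=5.0, trait_id="t")
        assert len(recs) >= 1
        best = max(recs, key=lambda r: r.neglog10p)
        assert best.peak_marker == G.markers["marker"][37]
        assert best.variance_explained == pytest.approx(1.0, abs=1e-10)

    def test_planted_eqtl_detected_in_ld_block(self):
        """Planted local eQTL (h2=0.5) detected within the causal LD block."""
        hits = 0
        for seed in range(5):
            cfg = ea.SimConfig(
                n_strains=200, n_transcripts=2, markers_per_chrom=80,
                n_local_eqtl=1, n_distant_eqtl=0, hotspot_spec=(0, 0, 1.0),
                h2_local=0.5, seed=600 + seed,
            )
            sim = ea.simulate_study(cfg)
            traits = strain_means(log_transform(sim.tpm))
            G = ea.ld_prune(ea.filter_markers(sim.genotypes))
            K = ea.kinship(G)
            row = sim.truth.eqtl_table.iloc[0]
            causal = sim.genotypes.markers.set_index("marker").loc[row["marker"]]
            recs = ea.map_trait(
                traits.loc[row["transcript"]].to_numpy(), G, K, threshold=4.0
            )
            for r in recs:
                if r.chrom == causal["chrom"] and abs(r.peak_bp - causal["bp"]) <= 150_000:
                    hits += 1
                    break
        assert hits >= 4


class TestClassification:
    ANN = pd.DataFrame(
        {
            "transcript": ["T1", "T2", "T3"],
            "gene": ["G1", "G2", "G3"],
            "chrom": ["II", "II", "IV"],
            "tss": [1_200_000, 1_000_000, 1_000_000],
            "strand": ["+", "-", "+"],
        }
    )

    def rec(self, trait, chrom, bp):
        return QTLRecord(trait, chrom, "m", bp, 7.0, bp - 1, bp + 1, 0.1)

    def test_within_window_local(self):
        assert classify_eqtl(self.rec("T1", "II", 2_000_000), self.ANN) == "local"

    def test_one_bp_beyond_window_distant(self):
        assert classify_eqtl(self.rec("T2", "II", 2_000_001), self.ANN) == "distant"
        assert classify_eqtl(self.rec("T2", "II", 2_000_000), self.ANN) == "local"

    def test_other_chromosome_distant(self):
        assert classify_eqtl(self.rec("T3", "II", 1_000_000), self.ANN) == "distant"

    def test_missing_transcript_unclassified(self):
        with pytest.warns(RuntimeWarning):
            assert classify_eqtl(self.rec("TX", "II", 1), self.ANN) == "unclassified"

    def test_window_monotonicity(self):
        """Enlarging the window never converts local -> distant."""
        r = self.rec("T1", "II", 2_300_000)  # 1.1 Mb from the TSS
        small = classify_eqtl(r, self.ANN, window_bp=1_000_000)
        big = classify_eqtl(r, self.ANN, window_bp=2_000_000)
        assert small == "distant" and big == "local"


class TestQtlLD:
    def test_r2_against_corr_oracle(self, pruned_panel):
        G, _ = pruned_panel
        recs = [
            QTLRecord("T", "I", G.markers["marker"][0], 1, 7, 1, 2, 0.1),
            QTLRecord("T", "I", G.markers["marker"][0], 1, 7, 1, 2, 0.1),
            QTLRecord("T", "I", G.markers["marker"][50], 1, 6, 1, 2, 0.1),
        ]
        ld = ea.qtl_ld(recs, G)
        assert ld.iloc[0]["r2"] == pytest.approx(1.0, abs=1e-12)
        oracle = np.corrcoef(G.dosage[:, 0], G.dosage[:, 50])[0, 1] ** 2
        assert ld.iloc[1]["r2"] == pytest.approx(oracle, abs=1e-12)


class TestPermutationFdr:
    def test_cutoff_is_95th_percentile_and_above_raw(self, small_study):
        sim = small_study
        traits = strain_means(log_transform(sim.tpm))
        G = ea.ld_prune(ea.filter_markers(sim.genotypes))
        K = ea.kinship(G)
        spec = ea.make_thresholds(ea.meff_li_ji(G), G.n_markers)
        cut = ea.permutation_fdr(traits, G, K, spec, n_traits=20, n_perm=20, seed=3)
        assert cut >= spec.eigen_threshold

    def test_fallback_when_no_qtl(self, small_study):
        """An unreachable raw threshold yields no permuted QTL -> fallback."""
        sim = small_study
        traits = strain_means(log_transform(sim.tpm))
        G = ea.ld_prune(ea.filter_markers(sim.genotypes))
        K = ea.kinship(G)
        spec = ea.make_thresholds(ea.meff_li_ji(G), G.n_markers)
        spec.eigen_threshold = 250.0
        cut = ea.permutation_fdr(traits, G, K, spec, n_traits=5, n_perm=5, seed=3)
        assert cut == 250.0

    def test_too_few_traits_raises(self, small_study):
        traits = strain_means(log_transform(small_study.tpm)).iloc[:5]
        G = ea.ld_prune(ea.filter_markers(small_study.genotypes))
        K = ea.kinship(G)
        spec = ea.make_thresholds(10.0, G.n_markers)
        with pytest.raises(ea.EmptyInputError):
            ea.permutation_fdr(traits, G, K, spec, n_traits=50, n_perm=5)


class TestFinemap:
    def test_three_filter_composition(self, pruned_panel):
        """Survivors = top 5% AND non-divergent AND negative BLOSUM."""
        G, K = pruned_panel
        roi = G.subset(marker_idx=np.arange(100))
        rng = np.random.default_rng(5)
        y = 0.9 * roi.dosage[:, 42] + rng.standard_normal(G.n_strains)
        # rank markers once to build the oracle
        scan = ea.gls_scan(y, roi.dosage, K.K)
        order = np.argsort(-scan.neglog10p, kind="stable")
        top5 = set(roi.markers["marker"].to_numpy()[order[:5]])
        # divergent region containing two of the top markers
        top_bp = sorted(roi.markers["bp"].to_numpy()[order[:2]])
        common = pd.DataFrame(
            {"chrom": ["I", "I"], "start": [b - 1 for b in top_bp], "end": [b for b in top_bp]}
        )
        # negative BLOSUM for exactly one non-divergent top marker
        surviving = [m for m in top5
                     if roi.markers.set_index("marker").loc[m, "bp"] not in top_bp]
        ann = pd.DataFrame(
            {
                "marker": [surviving[0], surviving[1]],
                "consequence": ["missense", "missense"],
                "blosum": [-2, 3],
            }
        )
        out = ea.finemap(y, roi, K, common, ann, top_frac=0.05)
        assert list(out["marker"]) == [surviving[0]]

    def test_all_nonnegative_blosum_empty(self, pruned_panel):
        G, K = pruned_panel
        roi = G.subset(marker_idx=np.arange(50))
        rng = np.random.default_rng(6)
        y = rng.standard_normal(G.n_strains)
        ann = pd.DataFrame(
            {"marker": roi.markers["marker"], "consequence": "syn", "blosum": 1}
        )
        assert ea.finemap(y, roi, K, None, ann).empty

    def test_empty_annotation_warns(self, pruned_panel):
        G, K = pruned_panel
        roi = G.subset(marker_idx=np.arange(30))
        y = np.random.default_rng(7).standard_normal(G.n_strains)
        with pytest.warns(RuntimeWarning):
            out = ea.finemap(y, roi, K, None, pd.DataFrame())
        assert out.empty


class TestEndToEnd:
    def test_local_ve_exceeds_distant_ve(self, small_fit):
        eq = small_fit.eqtl
        ve = eq.groupby("classification")["variance_explained"].mean()
        assert ve["local"] > ve["distant"]

    def test_class_precision_against_truth(self, small_fit, small_study):
        truth = small_study.truth.eqtl_table.set_index("transcript")
        eq = small_fit.eqtl
        on_planted = eq[eq["trait"].isin(truth.index)]
        match = sum(
            truth.loc[t, "class"] == c
            for t, c in zip(on_planted["trait"], on_planted["classification"])
        )
        assert len(on_planted) > 20
        assert match / len(on_planted) >= 0.9
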