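"""End-to-end study orchestration: `EQTLStudy.fit() -> EQTLStudyResults`.

The study object holds the raw inputs (genotypes, replicate-level counts
and TPM, transcript annotation, divergent masks, genetic map) and `fit`
runs the full pipeline: sample QC, normalization, reliable-transcript
filtering, divergent masking, strain-mean trait construction, marker
filtering and LD pruning, kinship, effective-test thresholds, optional
permutation FDR calibration, per-transcript mixed-model mapping,
local/distant classification, and hotspot detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expression_qc as qc
from . import eqtl_pipeline as pipe
from . import hotspots as hs
from .genorel import consolidate_common_divergent, filter_markers, kinship, ld_prune
from .heritability import heritability_table
from .ioformats import (
    DivergentMaskSet,
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
)
from .mixedmodel import KinshipDecomposition, make_thresholds, meff_li_ji


@dataclass
class EQTLStudyResults:
    """Fitted pipeline outputs; see `summary()` for the headline numbers."""

    eqtl: pd.DataFrame
    thresholds: object
    threshold_used: float
    qc_report: qc.QCReport
    trait_matrix: pd.DataFrame  # transcripts x strains, mapping scale
    genotypes_pruned: GenotypeMatrix
    kinship: object
    hotspot_model: hs.HotspotModel | None = None
    common_divergent: pd.DataFrame | None = None
    log_expr: ExpressionMatrix | None = None
    records: list = field(default_factory=list)

    def heritability(self) -> pd.DataFrame:
        if self.log_expr is None:
            raise ValueError("replicate-level expression not retained")
        traits = self.trait_matrix.loc[list(self.log_expr.transcripts)]
        return heritability_table(traits, self.log_expr, self.kinship)

    def summary(self) -> str:
        n_local = int((self.eqtl["classification"] == "local").sum())
        n_distant = int((self.eqtl["classification"] == "distant").sum())
        lines = [
            "EQTLStudy results",
            f"  traits mapped          : {len(self.trait_matrix)}",
            f"  strains                : {self.trait_matrix.shape[1]}",
            f"  pruned markers         : {self.genotypes_pruned.n_markers}",
            f"  effective tests (Meff) : {self.thresholds.n_test:.1f}",
            f"  threshold (-log10 p)   : {self.threshold_used:.3f}",
            f"  eQTL detected          : {len(self.eqtl)}"
            f" ({n_local} local / {n_distant} distant)",
        ]
        if self.hotspot_model is not None:
            hm = self.hotspot_model
            lines.append(
                f"  hotspots               : {len(hm.hotspots)}"
                f" (lambda={hm.lambda_hat:.2f}, count threshold >{hm.q99})"
            )
        return "\n".join(lines)


class EQTLStudy:
    """Species-wide eQTL mapping study on an inbred strain panel."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        counts: ExpressionMatrix,
        tpm: ExpressionMatrix,
        annotation: pd.DataFrame,
        masks: DivergentMaskSet | None = None,
        genetic_map: GeneticMap | None = None,
    ):
        self.genotypes = genotypes
        self.counts = counts
        self.tpm = tpm
        self.annotation = annotation
        self.masks = masks or DivergentMaskSet()
        self.genetic_map = genetic_map

    @classmethod
    def from_simulation(cls, study) -> "EQTLStudy":
        return cls(
            study.genotypes,
            study.counts,
            study.tpm,
            study.annotation,
            study.masks,
            study.genetic_map,
        )

    def fit(
        self,
        threshold_mode: str = "eigen",
        run_sample_qc: bool = True,
        min_count: float = 5,
        min_strains: int = 10,
        min_strains_retained: int = 100,
        fdr_traits: int = 0,
        fdr_perms: int = 0,
        seed: int = 0,
        gap_markers: int = 1000,
        keep_expression: bool = True,
    ) -> EQTLStudyResults:
        """Run the full pipeline and return the results object.

        Set ``fdr_traits`` and ``fdr_perms`` > 0 to calibrate a permutation
        5% FDR cutoff; otherwise the raw EIGEN/Bonferroni threshold applies.
        """
        # ---- expression QC ----
        counts, tpm = self.counts, self.tpm
        report = qc.QCReport(kept_samples=list(counts.samples["sample"]))
        if run_sample_qc:
            kept, report = qc.select_samples(counts, self.annotation)
            counts = counts.keep_samples(kept)
            tpm = tpm.keep_samples(kept)
        count_factors = qc.norm_factors(counts, counts.transcripts)
        norm_counts = qc.apply_factors(counts, count_factors)
        reliable = qc.filter_reliable(norm_counts, min_count, min_strains)
        report.kept_transcripts = list(reliable)
        dropped_low = [t for t in counts.transcripts if t not in set(reliable)]
        keep_idx = [i for i, t in enumerate(tpm.transcripts) if t in set(reliable)]
        tpm = tpm.subset(transcript_idx=keep_idx)
        tpm_factors = qc.norm_factors(tpm, tpm.transcripts)
        norm_tpm = qc.apply_factors(tpm, tpm_factors)
        norm_tpm, dropped_div = qc.apply_divergent_mask(
            norm_tpm, self.masks, self.annotation, min_strains_retained
        )
        report.dropped_transcripts = pd.concat(
            [
                pd.DataFrame({"transcript": dropped_low, "reason": "low_expression"}),
                dropped_div,
            ],
            ignore_index=True,
        )
        log_expr = qc.log_transform(norm_tpm)
        traits = qc.strain_means(log_expr)

        # ---- genotypes ----
        G = filter_markers(self.genotypes.align_strains(list(traits.columns)))
        Gp = ld_prune(G)
        K = kinship(Gp)
        kd = KinshipDecomposition(K)
        n_test = meff_li_ji(Gp)
        thresholds = make_thresholds(n_test, Gp.n_markers)
        threshold = thresholds.threshold(threshold_mode)
        if fdr_traits > 0 and fdr_perms > 0:
            cutoff = pipe.permutation_fdr(
                traits,
                Gp,
                K,
                thresholds,
                mode=threshold_mode,
                n_traits=min(fdr_traits, len(traits)),
                n_perm=fdr_perms,
                seed=seed,
                gap_markers=gap_markers,
            )
            if threshold_mode == "eigen":
                thresholds.fdr5_eigen = cutoff
            else:
                thresholds.fdr5_bf = cutoff
            threshold = cutoff

        common_div = consolidate_common_divergent(
            self.masks, n_strains=self.genotypes.n_strains
        )

        # ---- per-trait mapping ----
        strain_order = list(Gp.strains)
        Gr = kd.rotate(Gp.dosage)
        records: list[pipe.QTLRecord] = []
        for tid, row in traits.iterrows():
            y = row.reindex(strain_order).to_numpy(dtype=float)
            if np.isfinite(y).sum() < 30 or np.nanvar(y) == 0:
                continue
            recs = pipe.map_trait(
                y,
                Gp,
                kd if np.isfinite(y).all() else K,
                threshold,
                trait_id=str(tid),
                gap_markers=gap_markers,
                rotated=Gr if np.isfinite(y).all() else None,
            )
            records.extend(recs)
        pipe.classify_all(records, self.annotation)
        pipe.flag_divergent(records, common_div)
        eqtl = pipe.qtl_frame(records)

        hotspot_model = None
        if self.genetic_map is not None and len(eqtl):
            bins = hs.bin_distant_eqtl(eqtl, self.genetic_map, common_div)
            hotspot_model = hs.detect_hotspots(bins)

        return EQTLStudyResults(
            eqtl=eqtl,
            thresholds=thresholds,
            threshold_used=threshold,
            qc_report=report,
            trait_matrix=traits,
            genotypes_pruned=Gp,
            kinship=K,
            hotspot_model=hotspot_model,
            common_divergent=common_div,
            log_expr=log_expr if keep_expression else None,
            records=records,
        )
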