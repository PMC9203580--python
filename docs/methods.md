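# Methods

`eqtl-atlas` implements a species-wide expression-QTL analysis for panels
of fully inbred (selfing) strains, together with a synthetic-study
generator that makes every stage testable against known ground truth. This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data do and do not establish
about behavior on real data.

## The mixed model

Each transcript's strain-mean expression `y` (n strains) is modeled as

    y = mu + g + e,    g ~ N(0, sigma_g^2 K),    e ~ N(0, sigma_e^2 I)

where `K` is the realized-relationship kinship matrix computed from
LD-pruned dosages: `K = M M' / sum_j p_j (1 - p_j)` with `M` the
column-centered dosage matrix. Variance components are estimated by REML
over the ratio `delta = sigma_e^2 / sigma_g^2` after one eigendecomposition
of `K`: the restricted likelihood is profiled analytically in the overall
scale, evaluated on a 100-point log-spaced grid over `delta in [1e-5, 1e5]`,
and refined by bounded scalar minimization between the best grid point's
neighbors (absolute tolerance 1e-10 on log delta). A boundary flag is set
when the grid optimum lies at either end (typically `sigma_g^2 ~ 0`);
components are still returned.

Association testing uses the P3D/EMMAX approximation: the null-model
variance components are fixed for all markers of a trait, the data are
whitened by `V^{-1/2}` with `V = sigma_g^2 K + sigma_e^2 I`, and each
marker is tested by an F statistic with (1, n-2) degrees of freedom in the
whitened basis. p-values are floored at 1e-300 so `-log10 p` stays finite;
monomorphic markers in the analyzed strain subset are reported at p = 1
with a flag. With `K = I` the scan reduces exactly to the OLS F-test
(verified to 1e-8 in the tests), and on null traits drawn from the fitted
covariance the empirical type-I error at alpha = 0.05 is calibrated (tested
over 2x10^4 marker tests).

## Multiple testing

The effective number of independent tests is estimated from the spectrum
of the marker correlation matrix (Li & Ji style): for eigenvalues
`lambda_i`, `Meff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]`.
The spectrum is computed on the smaller side (markers or strains) of the
standardized dosage matrix — both carry the same nonzero eigenvalues.
Eigenvalues are snapped at 1e-9 before the floor decomposition so exactly
duplicated markers collapse as the closed form dictates; note that the
estimator is *not* invariant to duplicating a whole correlated marker
panel in finite samples, because sample eigenvalues near 1 double across
the floor discontinuity. The EIGEN threshold is `-log10(0.05 / Meff)`; the
Bonferroni threshold uses the raw marker count.

The 5% permutation FDR cutoff takes a random subset of traits (200 at
full scale; 50 in the bundled tests), permutes each across strains (the
genotypes and kinship are never permuted), maps every permuted trait at
the raw EIGEN or Bonferroni threshold, pools the peak `-log10 p` of all
detected QTL, and returns the 95th percentile (linear/type-7
interpolation). If no permuted QTL is found the raw threshold is returned
with a warning. Self-consistency — roughly 5% of QTL detected on fresh
null traits exceed the cutoff — is enforced by test.

## QTL calling, classification, fine mapping

Markers above the applied threshold are grouped per chromosome into one
QTL when separated by at most 1000 marker indices (the grouping gap is
configurable; any value larger than typical LD-block spans behaves
identically on the synthetic data). The peak is the most significant
marker, leftmost on ties; the reported interval extends 100 marker indices
beyond the outermost significant markers, clamped to the chromosome; and
variance explained is the squared Pearson correlation between peak dosage
and the trait on the mapped scale.

An eQTL is *local* when its peak lies on the transcript's chromosome
within 1 Mb of the TSS (strand is ignored; the window is centered on the
TSS), otherwise *distant*. Fine mapping re-tests the unpruned markers of a
QTL interval with the same machinery and keeps candidates that (i) rank in
the top 5% by significance, (ii) fall outside common hyper-divergent
regions, and (iii) carry a negative BLOSUM substitution score in the
variant annotation.

## Expression QC

* **Sample selection.** Counts are summarized to gene level, normalized by
  median-of-ratios size factors, and log2(x+1) transformed — a light-weight
  variance-stabilizing stand-in with the same monotone, depth-free
  behavior as a full VST. Pairwise Euclidean distances between samples are
  compared per strain: every intra-strain replicate pair must be closer
  than the median of the strain's pooled inter-strain distances (strict
  inequality; ties fail). Strains where no pair passes are removed; in
  3-replicate strains with partial passes the minimum-distance pair is
  kept. The loop repeats until a fixed point (it is a contraction, and
  idempotent at the fixed point); 20 iterations is a hard cap.
* **Normalization.** Median-of-ratios factors over reference transcripts
  with all-positive values; normalized value = TPM / factor.
* **Reliable transcripts.** Kept iff at least `min_count = 5` normalized
  counts in *all* replicates of at least `min_strains = 10` strains.
* **Divergent masking.** A transcript is blanked for a strain when its TSS
  falls inside one of that strain's hyper-divergent intervals; transcripts
  retained in fewer than 100 strains are dropped (the floor is lowered
  automatically for panels smaller than 100 strains).
* **Mapping scale.** log2(normalized TPM + 0.5), transformed before
  replicate averaging, so the strain mean lives on the mapping scale.

## Heritability

Narrow-sense `h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)` comes from the
kinship REML fit of the strain-mean trait. Broad-sense `H^2` is the
strain-level variance fraction of replicate-level values under a one-way
random-intercept model, fit by REML with the variance ratio profiled out
and optimized on the log scale (tolerance 1e-12), which handles unbalanced
2-3 replicate designs and reproduces the balanced ANOVA closed form to
1e-6. Negative variance estimates are truncated at zero, so both
statistics are in [0, 1] by construction.

## Hotspots

Distant eQTL outside common hyper-divergent regions (genome split into
1 kb bins; a bin is "common" when >= 5% of strains mask it; adjacent bins
merged) are assigned to half-open 0.5 cM bins anchored at each
chromosome's minimum map position, with zero-count bins included.
`lambda` is the maximum-likelihood Poisson rate — the mean count over all
bins by default (`lambda_bins="nonempty"` is available) — and a bin is a
hotspot when its count strictly exceeds the 99th-percentile Poisson
quantile `q99` (smallest k with CDF(k; lambda) >= 0.99). Runs of adjacent
qualifying bins merge into single hotspots whose counts are the sums of
their member bins. Chromosomes absent from the genetic map (e.g.
mitochondrial) never enter the binning.

## Mediation

For an organism-level QTL, mediator candidates are transcripts whose eQTL
interval overlaps the QTL interval by at least 1 bp (closed intervals).
The screen statistic per mediator is `S = |a * b|` on standardized
variables: `a` the exposure-mediator correlation and `b` the standardized
coefficient of the mediator in the outcome regression adjusted for the
exposure. The permutation null permutes the mediator matrix rows jointly —
preserving the exposure-outcome pairing, which is the null of *no
mediation* rather than no association — and the adjusted p-value of each
mediator is the add-one-corrected fraction of permutations whose family
maximum reaches its observed S. This max-statistic construction controls
the family-wise error by design (verified at the 5% level over null
simulations). Mediators perfectly collinear with the exposure are flagged
and excluded.

For significant mediators (adjusted p < 0.05 or estimate strictly above
the per-analysis 99th percentile of estimates), effects are decomposed by
the difference method: total `c` from OLS `Y ~ X`, direct `c'` from
`Y ~ X + M`, indirect `c - c'`, proportion mediated `(c - c')/c`. For
linear least squares on one sample this equals the product `a*b`
identically (asserted to 1e-10). Proportions outside [0, 1] (with 1e-9
float slack at the boundaries) are uninterpretable and excluded from the
final reported set. The regression-drop scan residualizes the outcome on
each transcript in turn and re-tests the residual at a (pseudo) variant
marker; a residual variance below 1e-12 of the outcome variance is treated
as a fully explained outcome and skipped.

## The synthetic-study generator

The generator emulates the statistical structure of a wild isolate panel
at desk scale. Defaults (the study conditions): 200 strains in 3
population groups with Balding-Nichols divergence F = 0.15; 6 chromosomes
by 300 markers at 15 kb spacing (3 cM/Mb, so a chromosome spans ~13.5 cM);
10-marker LD blocks built by copying a block founder haplotype with
per-site flip probability 0.03, giving high within-block and decaying
cross-block r^2; ancestral block frequencies uniform on [0.1, 0.5] so
nearly all markers survive the 5% MAF filter; 500 transcripts with 60
planted local eQTL (target per-trait h^2 = 0.45), 60 distant eQTL
(h^2 = 0.25, so local effects are systematically larger, as observed in
real panels), and a 30-target master-regulator hotspot; 3 replicates per
strain with replicate noise SD 1.0 on the latent log2 scale (strain-level
variance fraction ~0.5); 5% average per-strain hyper-divergent coverage;
and one organism-level trait whose exposure-marker effect is 26% mediated
by a planted distant-eQTL transcript, with trait noise at half the
systematic SD (a clearly detectable QTL, matching the scenario the
mediation stage is designed for).

Implementation choices worth knowing:

* Strains are fully inbred: dosages are {0, 1}; heterozygous or missing
  VCF calls read as missing.
* TPM is `2^(latent + 5)` so the downstream `log2(TPM + 0.5)` transform
  recovers an approximately linear-Gaussian trait by construction; counts
  scale TPM by a per-sample library factor uniform on [30, 60].
* Planted effect sizes are scaled against the empirical dosage variance so
  the realized strain-level genetic variance fraction matches the target
  heritability on average (tested at +-0.05 over 100 traits).
* Hyper-divergent intervals recur at shared candidate 200 kb segments
  (covering about twice the per-strain target so that segment membership
  at ~50% yields common-divergent regions), because real divergent regions
  recur at common loci; the neighborhood of the hotspot master marker is
  excluded from the candidates, representing a well-genotyped regulatory
  locus. Fully i.i.d. random intervals would make "common divergent"
  regions cover half the genome at any realistic per-strain fraction.
* All randomness flows from one seed through deterministically spawned
  substreams; identical configurations give byte-identical outputs.

What the synthetic data do *not* emulate: coalescent demography and
selection, read-level RNA-seq noise, count overdispersion beyond the
log-normal replicate model, batch effects, dominance or epistasis, and
linkage between the divergent-mask process and local genotype quality.
Passing tests therefore establish the correctness and calibration of the
algorithms under the stated generative model, not the numerical results of
any particular real panel.

## Problem sizes in the test and acceptance runs

The bundled suites run the statistics at reduced scale chosen for quick
desk iteration: calibration panels of 150-200 strains and ~750 pruned
markers, 100-trait heritability batches, 50 traits x 50 permutations for
FDR calibration, 20-seed hotspot and mediation replications, and one
end-to-end study of 150 strains x 500 transcripts x ~2000 markers. The
same code paths scale to panel sizes like the motivating datasets simply
by changing the configuration.
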