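"""Synthetic genotypes, expression, masks, and mediated traits with ground truth.

The generator emulates the statistical structure of a species-wide panel of
wild, fully inbred (selfing) nematode strains at desk scale: ~200 strains
falling into three diverged population groups, biallelic markers organized
into LD blocks (block-copied founder haplotypes with per-site mutation
flips), 2-3 expression replicates per strain, planted local and distant
eQTL with local effects larger than distant ones, one master-regulator
hotspot marker affecting many target transcripts, per-strain hyper-divergent
masking, and one organism-level trait mediated by a transcript's expression.

Every random draw derives from a single seed through deterministically
spawned substreams, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .ioformats import DivergentMaskSet, ExpressionMatrix, GeneticMap, GenotypeMatrix

CHROM_NAMES = ["I", "II", "III", "IV", "V", "X"]
MARKER_SPACING_BP = 15_000
CM_PER_MB = 3.0  # coarse genome-wide average recombination rate
TPM_LOG2_BASE = 5.0  # latent 0 maps to TPM = 2^5 = 32


@dataclass
class SimConfig:
    """Configuration of one synthetic study; defaults are the study conditions.

    The defaults mirror the structure of the emulated panel at reduced
    scale: 200 strains in 3 groups, 6 chromosomes x 300 markers in 10-marker
    LD blocks with MAF in [0.1, 0.5], 500 transcripts carrying 60 local and
    60 distant planted eQTL plus a 30-target master-regulator hotspot,
    target per-trait heritabilities 0.45 (local) / 0.25 (distant), 3
    replicates per strain, and one mediated organismal trait with a true
    mediated proportion of 0.26.
    """

    n_strains: int = 200
    n_pops: int = 3
    pop_divergence: float = 0.15  # Fst-like Balding-Nichols parameter
    n_chrom: int = 6
    markers_per_chrom: int = 300
    ld_block_len: int = 10
    block_flip_rate: float = 0.03  # per-site mutation flip within a block
    maf_range: tuple = (0.1, 0.5)
    n_transcripts: int = 500
    n_local_eqtl: int = 60
    n_distant_eqtl: int = 60
    hotspot_spec: tuple = (150, 30, 1.0)  # (master marker index, n targets, rel. effect)
    h2_local: float = 0.45
    h2_distant: float = 0.25
    n_reps_per_strain: int = 3
    replicate_noise_sd: float = 1.0
    divergent_frac: float = 0.05
    mediation_spec: tuple = (None, None, 0.26, 1.0)  # (marker, transcript, prop, total)
    trait_noise_frac: float = 0.5  # mediated-trait noise sd / systematic sd
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_strains": self.n_strains,
            "n_pops": self.n_pops,
            "n_chrom": self.n_chrom,
            "markers_per_chrom": self.markers_per_chrom,
            "ld_block_len": self.ld_block_len,
            "n_transcripts": self.n_transcripts,
            "n_reps_per_strain": self.n_reps_per_strain,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise InvalidConfigError(f"{name} must be a positive integer")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < low < high <= 0.5")
        if not (0 <= self.pop_divergence < 1):
            raise InvalidConfigError("pop_divergence must be in [0, 1)")
        for name, v in (("h2_local", self.h2_local), ("h2_distant", self.h2_distant)):
            if not (0 <= v < 1):
                raise InvalidConfigError(f"{name} must be in [0, 1)")
        if self.replicate_noise_sd < 0:
            raise InvalidConfigError("replicate_noise_sd must be nonnegative")
        if not (0 <= self.divergent_frac <= 1):
            raise InvalidConfigError("divergent_frac must be in [0, 1]")
        if self.n_local_eqtl < 0 or self.n_distant_eqtl < 0:
            raise InvalidConfigError("eQTL counts must be nonnegative")
        _, n_targets, _ = self.hotspot_spec
        if n_targets > self.n_transcripts:
            raise InvalidConfigError("hotspot target count exceeds n_transcripts")
        if self.n_local_eqtl + self.n_distant_eqtl + n_targets > self.n_transcripts:
            raise InvalidConfigError("planted eQTL exceed available transcripts")
        prop = self.mediation_spec[2]
        if not (0 <= prop <= 1):
            raise InvalidConfigError("mediated proportion must be in [0, 1]")
        if not (0 <= self.block_flip_rate < 0.5):
            raise InvalidConfigError("block_flip_rate must be in [0, 0.5)")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    @property
    def chrom_length_bp(self) -> int:
        return (self.markers_per_chrom + 1) * MARKER_SPACING_BP

    def chrom_names(self) -> list:
        base = list(CHROM_NAMES)
        while len(base) < self.n_chrom:
            base.append(f"chr{len(base) + 1}")
        return base[: self.n_chrom]


@dataclass
class SimTruth:
    """Ground truth of the planted signals, for parameter-recovery tests."""

    eqtl_table: pd.DataFrame  # transcript, marker, class, effect, h2
    mediation_row: pd.Series | None = None  # exposure, mediator, proportion, total
    mask_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["strain", "transcript"])
    )


@dataclass
class SimExpressionResult:
    """Expression matrices plus the annotation and truth created with them."""

    tpm: ExpressionMatrix
    counts: ExpressionMatrix
    annotation: pd.DataFrame
    truth: SimTruth


@dataclass
class SimStudy:
    """Complete synthetic study bundle."""

    config: SimConfig
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    tpm: ExpressionMatrix
    counts: ExpressionMatrix
    annotation: pd.DataFrame
    masks: DivergentMaskSet
    phenotype: pd.Series | None
    truth: SimTruth


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sim_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate inbred dosages with LD blocks and population structure.

    Markers within an LD block are copies of a block founder column with
    independent per-site flips at ``block_flip_rate``, so adjacent-marker
    r^2 is high within blocks and decays across block boundaries.
    Population structure comes from group-specific allele frequencies drawn
    from a Balding-Nichols beta around each block's ancestral frequency.
    """
    rng = _substreams(cfg.seed, 4)[0]
    pops = np.arange(cfg.n_strains) % cfg.n_pops
    F = cfg.pop_divergence
    lo, hi = cfg.maf_range
    cols, rows = [], []
    for c, chrom in enumerate(cfg.chrom_names()):
        n_blocks = int(np.ceil(cfg.markers_per_chrom / cfg.ld_block_len))
        m_done = 0
        for b in range(n_blocks):
            block_m = min(cfg.ld_block_len, cfg.markers_per_chrom - m_done)
            p0 = rng.uniform(lo, hi)
            if F > 0:
                a = p0 * (1 - F) / F
                bb = (1 - p0) * (1 - F) / F
                p_pop = rng.beta(a, bb, size=cfg.n_pops)
            else:
                p_pop = np.full(cfg.n_pops, p0)
            founder = (rng.random(cfg.n_strains) < p_pop[pops]).astype(float)
            for k in range(block_m):
                flips = rng.random(cfg.n_strains) < cfg.block_flip_rate
                col = np.where(flips, 1.0 - founder, founder)
                j = m_done + k
                bp = (j + 1) * MARKER_SPACING_BP
                rows.append((f"{chrom}_{bp}", chrom, bp))
                cols.append(col)
            m_done += block_m
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "bp"])
    strains = np.array([f"S{i:03d}" for i in range(cfg.n_strains)], dtype=object)
    return GenotypeMatrix(strains, markers, np.column_stack(cols))


def sim_genetic_map(cfg: SimConfig) -> GeneticMap:
    """Regular physical spacing mapped linearly to cM (monotone per chromosome)."""
    rows = []
    for chrom in cfg.chrom_names():
        for bp in (0, cfg.chrom_length_bp):
            rows.append((chrom, max(bp, 1), bp * 1e-6 * CM_PER_MB))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "bp", "cM"]))


def _plant_effects(cfg: SimConfig, G: GenotypeMatrix, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose causal markers, transcript coordinates, and effect metadata."""
    chroms = cfg.chrom_names()
    chrom_arr = G.markers["chrom"].to_numpy()
    bp_arr = G.markers["bp"].to_numpy()
    master_idx, n_targets, _ = cfg.hotspot_spec
    master_idx = int(master_idx) % G.n_markers
    master_chrom = chrom_arr[master_idx]

    ann_rows, truth_rows = [], []
    t = 0

    def add_transcript(chrom, tss, strand="+"):
        tid = f"T{len(ann_rows):04d}"
        ann_rows.append((tid, f"G{len(ann_rows):04d}", chrom, int(tss), strand))
        return tid

    # local eQTL: TSS placed within 0.5 Mb of a random causal marker
    for _ in range(cfg.n_local_eqtl):
        j = int(rng.integers(G.n_markers))
        tss = int(np.clip(bp_arr[j] + rng.integers(-500_000, 500_001), 1, None))
        tid = add_transcript(chrom_arr[j], tss)
        truth_rows.append((tid, G.markers["marker"].iloc[j], "local", cfg.h2_local))
        t += 1
    # distant eQTL: causal marker on a different chromosome from the TSS
    for _ in range(cfg.n_distant_eqtl):
        j = int(rng.integers(G.n_markers))
        other = [c for c in chroms if c != chrom_arr[j]]
        chrom = other[int(rng.integers(len(other)))]
        tss = int(rng.integers(1, cfg.chrom_length_bp))
        tid = add_transcript(chrom, tss)
        truth_rows.append((tid, G.markers["marker"].iloc[j], "distant", cfg.h2_distant))
        t += 1
    # hotspot targets: all driven by the master marker, TSS elsewhere
    for _ in range(int(n_targets)):
        other = [c for c in chroms if c != master_chrom]
        chrom = other[int(rng.integers(len(other)))]
        tss = int(rng.integers(1, cfg.chrom_length_bp))
        tid = add_transcript(chrom, tss)
        truth_rows.append(
            (tid, G.markers["marker"].iloc[master_idx], "distant", cfg.h2_distant)
        )
        t += 1
    # remaining transcripts carry no planted effect
    while t < cfg.n_transcripts:
        chrom = chroms[int(rng.integers(len(chroms)))]
        add_transcript(chrom, int(rng.integers(1, cfg.chrom_length_bp)))
        t += 1
    annotation = pd.DataFrame(
        ann_rows, columns=["transcript", "gene", "chrom", "tss", "strand"]
    )
    truth = pd.DataFrame(truth_rows, columns=["transcript", "marker", "class", "h2"])
    return annotation, truth


def sim_expression(G: GenotypeMatrix, cfg: SimConfig) -> SimExpressionResult:
    """Simulate replicate-level TPM and counts with planted eQTL.

    Per transcript, the strain-level latent value is the planted genetic
    effect scaled to the target heritability plus strain-level environmental
    noise (unit total variance); replicates add independent noise at
    ``replicate_noise_sd``. TPM = 2^(latent + base) so the downstream
    log2(TPM + 0.5) transform recovers an approximately linear-Gaussian
    trait; counts scale TPM by a per-sample library factor.
    """
    rng = _substreams(cfg.seed, 4)[1]
    annotation, truth_tbl = _plant_effects(cfg, G, rng)
    n, r = cfg.n_strains, cfg.n_reps_per_strain
    n_samples = n * r
    strains = list(G.strains)
    sample_rows = [
        (f"{s}_r{k + 1}", s, k + 1) for s in strains for k in range(r)
    ]
    samples = pd.DataFrame(sample_rows, columns=["sample", "strain", "replicate"])
    strain_col = np.repeat(np.arange(n), r)

    causal = truth_tbl.set_index("transcript")
    latent = np.empty((cfg.n_transcripts, n))
    effects = []
    for i, tid in enumerate(annotation["transcript"]):
        if tid in causal.index:
            row = causal.loc[tid]
            x = G.dosage_of(row["marker"])
            h2 = float(row["h2"])
            vx = x.var()
            beta = np.sqrt(h2 / vx) if (vx > 0 and h2 > 0) else 0.0
            g = beta * x
            e = rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=n)
            latent[i] = g + e
            effects.append(beta)
        else:
            latent[i] = rng.normal(0.0, 1.0, size=n)
    truth_tbl = truth_tbl.assign(effect=effects)

    reps = latent[:, strain_col] + rng.normal(
        0.0, cfg.replicate_noise_sd, size=(cfg.n_transcripts, n_samples)
    )
    tpm_values = 2.0 ** (reps + TPM_LOG2_BASE)
    lib = rng.uniform(30.0, 60.0, size=n_samples)
    count_values = np.round(tpm_values * lib)

    tpm = ExpressionMatrix(annotation["transcript"].to_numpy(), samples, tpm_values)
    counts = ExpressionMatrix(annotation["transcript"].to_numpy(), samples, count_values)
    truth = SimTruth(eqtl_table=truth_tbl[["transcript", "marker", "class", "effect", "h2"]])
    return SimExpressionResult(tpm=tpm, counts=counts, annotation=annotation, truth=truth)


def sim_divergent_masks(cfg: SimConfig, G: GenotypeMatrix) -> DivergentMaskSet:
    """Per-strain divergent intervals recurring at shared genomic segments.

    Hyper-divergent regions in real panels recur at common loci: different
    strains are divergent over the same ancient haplotypes. The generator
    therefore first picks a set of candidate 200 kb segments (covering
    roughly 2x ``divergent_frac`` of the genome, excluding the neighborhood
    of the planted hotspot master marker, which represents a well-genotyped
    regulatory locus) and then includes each (strain, segment) pair
    independently so the average per-strain coverage equals
    ``divergent_frac``.
    """
    rng = _substreams(cfg.seed, 4)[2]
    if cfg.divergent_frac == 0:
        return DivergentMaskSet()
    seg_len = 200_000
    L = cfg.chrom_length_bp
    if cfg.divergent_frac >= 1.0:
        rows = [(s, c, 0, L) for s in G.strains for c in cfg.chrom_names()]
        return DivergentMaskSet(
            pd.DataFrame(rows, columns=["strain", "chrom", "start", "end"])
        )
    cand_cov = min(max(2.0 * cfg.divergent_frac, 0.2), 1.0)
    incl_p = cfg.divergent_frac / cand_cov
    master_idx = int(cfg.hotspot_spec[0]) % G.n_markers
    master_chrom = G.markers["chrom"].iloc[master_idx]
    master_bp = int(G.markers["bp"].iloc[master_idx])
    segments = []
    for chrom in cfg.chrom_names():
        n_seg = int(np.ceil(L / seg_len))
        for k in range(n_seg):
            start, end = k * seg_len, min((k + 1) * seg_len, L)
            if chrom == master_chrom and start - 100_000 <= master_bp <= end + 100_000:
                continue
            segments.append((chrom, start, end))
    n_pick = max(int(round(cand_cov * len(segments))), 1)
    pick = rng.choice(len(segments), size=min(n_pick, len(segments)), replace=False)
    candidates = [segments[i] for i in sorted(pick)]
    rows = []
    for s in G.strains:
        member = rng.random(len(candidates)) < incl_p
        rows.extend(
            (s, c, a, b) for (c, a, b), hit in zip(candidates, member) if hit
        )
    return DivergentMaskSet(
        pd.DataFrame(rows, columns=["strain", "chrom", "start", "end"])
    )


def sim_mediated_trait(
    G: GenotypeMatrix, expr: SimExpressionResult, cfg: SimConfig
) -> tuple[pd.Series, SimTruth]:
    """Simulate an organism-level trait mediated by one transcript's expression.

    Y = c' X + b M + e with X the exposure-marker dosage and M the
    strain-mean (log scale) expression of the mediator transcript.
    Coefficients are chosen so the indirect path carries the requested
    proportion of the total effect: c' = (1 - rho) c_tot and
    b = rho c_tot / a, where a is the realized slope of M on X.
    """
    rng = _substreams(cfg.seed, 4)[3]
    marker, transcript, rho, c_tot = cfg.mediation_spec
    truth_eqtl = expr.truth.eqtl_table
    if transcript is None:
        # default: the first planted distant-eQTL transcript and its marker
        distant = truth_eqtl[truth_eqtl["class"] == "distant"]
        if distant.empty:
            raise InvalidConfigError("no distant eQTL available for mediation_spec")
        transcript = distant["transcript"].iloc[0]
        marker = distant["marker"].iloc[0]
    if transcript not in set(expr.tpm.transcripts):
        raise InvalidConfigError(f"mediator transcript {transcript!r} not simulated")
    x = G.dosage_of(marker)
    ti = int(np.flatnonzero(expr.tpm.transcripts == transcript)[0])
    strain_ids = expr.tpm.samples["strain"].to_numpy()
    logv = np.log2(expr.tpm.values[ti] + 0.5)
    m = np.array(
        [logv[strain_ids == s].mean() for s in G.strains]
    )
    xc = x - x.mean()
    a = float((xc @ (m - m.mean())) / (xc @ xc))
    if abs(a) < 1e-9:
        raise InvalidConfigError("exposure marker has no effect on the mediator")
    b = rho * c_tot / a
    c_direct = (1.0 - rho) * c_tot
    systematic = c_direct * x + b * m
    noise_sd = cfg.trait_noise_frac * max(systematic.std(), 1e-12)
    y = systematic + rng.normal(0.0, noise_sd, size=len(x))
    pheno = pd.Series(y, index=pd.Index(G.strains, name="strain"), name="value")
    truth = SimTruth(
        eqtl_table=truth_eqtl,
        mediation_row=pd.Series(
            {
                "exposure": marker,
                "mediator": transcript,
                "proportion": rho,
                "total_effect": c_tot,
            }
        ),
        mask_table=expr.truth.mask_table,
    )
    return pheno, truth


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate the full synthetic study bundle (one call for CLI and tests)."""
    G = sim_genotypes(cfg)
    expr = sim_expression(G, cfg)
    masks = sim_divergent_masks(cfg, G)
    has_mediator = (
        cfg.mediation_spec[1] is not None
        or (expr.truth.eqtl_table["class"] == "distant").any()
    )
    if has_mediator:
        pheno, truth = sim_mediated_trait(G, expr, cfg)
    else:  # no mediator available: study has no organismal trait
        pheno, truth = None, expr.truth
    gmap = sim_genetic_map(cfg)
    return SimStudy(
        config=cfg,
        genotypes=G,
        genetic_map=gmap,
        tpm=expr.tpm,
        counts=expr.counts,
        annotation=expr.annotation,
        masks=masks,
        phenotype=pheno,
        truth=truth,
    )
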