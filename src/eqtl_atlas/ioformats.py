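"""Typed in-memory containers and readers/writers for the on-disk formats.

Coordinate dialects follow each standard exactly: VCF and transcript
annotation are 1-based inclusive, BED intervals are 0-based half-open.
Internally every position is stored in the dialect of the container that
carries it (``GenotypeMatrix.markers.bp`` and ``TranscriptAnnotation.tss``
are 1-based; ``DivergentMaskSet`` intervals are BED-style).

Genotypes of inbred, selfing strains are dosage-coded in {0, 1}: homozygous
reference is 0, homozygous alternate is 1, and heterozygous or missing calls
become NaN (an uncertain call in a selfing species is treated as missing,
not as half a dose).

All writers emit deterministic tab-separated UTF-8 output with ``\\n`` line
endings so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, MetadataError

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["transcript", "gene", "chrom", "tss", "strand"]


def _chrom_order(chroms) -> pd.Categorical:
    """Categorical with chromosomes in order of first appearance."""
    seen = pd.unique(np.asarray(chroms, dtype=object))
    return pd.Categorical(chroms, categories=list(seen), ordered=True)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Strains x biallelic markers, dosage-coded in {0, 1, NaN}.

    Parameters
    ----------
    strains : array of str
        Ordered, unique strain labels (rows of ``dosage``).
    markers : DataFrame
        One row per marker with columns ``marker``, ``chrom``, ``bp``
        (1-based) and optionally ``cM``. Sorted by (chrom, bp) on
        construction; chromosome order is order of first appearance.
    dosage : ndarray, shape (n_strains, n_markers)
        Float matrix with values in {0, 1} or NaN for missing calls.
    """

    strains: np.ndarray
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.strains = np.asarray(self.strains, dtype=object)
        if len(set(self.strains)) != len(self.strains):
            raise FormatError("strain labels must be unique")
        self.markers = self.markers.reset_index(drop=True).copy()
        for col in ("marker", "chrom", "bp"):
            if col not in self.markers.columns:
                raise FormatError(f"markers table lacks column {col!r}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.strains), len(self.markers)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        # enforce the sortedness invariant
        codes = _chrom_order(self.markers["chrom"]).codes
        order = np.lexsort((self.markers["bp"].to_numpy(), codes))
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0)
        return np.minimum(p, 1.0 - p)

    def subset(self, strain_idx=None, marker_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_strains) if strain_idx is None else np.asarray(strain_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            self.strains[s], self.markers.iloc[m], self.dosage[np.ix_(s, m)]
        )

    def align_strains(self, strain_ids) -> "GenotypeMatrix":
        """Reorder/subset rows to match ``strain_ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.strains)}
        try:
            idx = np.array([pos[s] for s in strain_ids])
        except KeyError as e:
            raise MetadataError(f"strain {e.args[0]!r} absent from genotypes") from None
        return self.subset(strain_idx=idx)

    def marker_index(self, marker_id) -> int:
        hit = np.flatnonzero(self.markers["marker"].to_numpy() == marker_id)
        if hit.size == 0:
            raise KeyError(marker_id)
        return int(hit[0])

    def dosage_of(self, marker_id) -> np.ndarray:
        return self.dosage[:, self.marker_index(marker_id)]


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and indels are skipped (a count is logged).
    Genotype coding: 0/0 -> 0, 1/1 -> 1, heterozygous or ./. -> NaN.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise FormatError(f"cannot read VCF {path}: {e}") from e
    strains = np.array(vcf.samples, dtype=object)
    rows, cols = [], []
    skipped = 0
    bases = {"A", "C", "G", "T"}
    for var in vcf:
        if (
            len(var.ALT) != 1
            or var.REF not in bases
            or var.ALT[0] not in bases
        ):
            skipped += 1
            continue
        gt = var.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        d = np.where(gt == 0, 0.0, np.where(gt == 3, 1.0, np.nan))
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((mid, var.CHROM, int(var.POS)))
        cols.append(d)
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNV records", skipped)
    if not rows:
        raise EmptyInputError(f"no biallelic SNV records in {path}")
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "bp"])
    return GenotypeMatrix(strains, markers, np.column_stack(cols))


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal genotype-only VCF (GT field, placeholder alleles)."""
    code = {0.0: "0/0", 1.0: "1/1"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.strains))
            + "\n"
        )
        for j, row in enumerate(G.markers.itertuples(index=False)):
            gts = "\t".join(code.get(d, "./.") for d in G.dosage[:, j])
            fh.write(f"{row.chrom}\t{row.bp}\t{row.marker}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x samples with (strain, replicate) sample metadata.

    ``values`` holds counts or TPM (nonnegative) or, when ``log_scale`` is
    true, log2-transformed abundances. ``mask`` marks (transcript, sample)
    entries that are missing (e.g. hyper-divergent masking); masked entries
    are ignored everywhere downstream.
    """

    transcripts: np.ndarray
    samples: pd.DataFrame  # columns: sample, strain, replicate
    values: np.ndarray
    mask: np.ndarray | None = None
    log_scale: bool = False

    def __post_init__(self):
        self.transcripts = np.asarray(self.transcripts, dtype=object)
        self.samples = self.samples.reset_index(drop=True).copy()
        for col in ("sample", "strain", "replicate"):
            if col not in self.samples.columns:
                raise MetadataError(f"sample metadata lacks column {col!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcripts), len(self.samples)):
            raise FormatError("expression values shape mismatch")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise FormatError("mask shape mismatch")
        if not self.log_scale:
            bad = (self.values < 0) & ~self.mask & np.isfinite(self.values)
            if bad.any():
                t, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"negative expression value for transcript "
                    f"{self.transcripts[t]!r}, sample {self.samples['sample'][s]!r}"
                )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def masked_values(self) -> np.ndarray:
        """Values with masked entries replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def subset(self, transcript_idx=None, sample_idx=None) -> "ExpressionMatrix":
        t = (
            np.arange(self.n_transcripts)
            if transcript_idx is None
            else np.asarray(transcript_idx)
        )
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return ExpressionMatrix(
            self.transcripts[t],
            self.samples.iloc[s],
            self.values[np.ix_(t, s)],
            self.mask[np.ix_(t, s)],
            self.log_scale,
        )

    def keep_samples(self, sample_ids) -> "ExpressionMatrix":
        keep = set(sample_ids)
        idx = [i for i, s in enumerate(self.samples["sample"]) if s in keep]
        return self.subset(sample_idx=idx)


def read_expression(path, meta_path) -> ExpressionMatrix:
    """Read a transcripts x samples TSV plus a sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str, "strain": str})
    for col in ("sample", "strain", "replicate"):
        if col not in meta.columns:
            raise MetadataError(f"metadata file lacks column {col!r}")
    meta = meta.set_index("sample", drop=False)
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise MetadataError(f"sample {missing[0]!r} absent from metadata")
    meta = meta.loc[list(df.columns)].reset_index(drop=True)
    return ExpressionMatrix(df.index.to_numpy(), meta, df.to_numpy(dtype=float))


def write_expression(expr: ExpressionMatrix, path, meta_path=None) -> None:
    df = pd.DataFrame(
        expr.masked_values(), index=expr.transcripts, columns=expr.samples["sample"]
    )
    df.index.name = "transcript"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
    if meta_path is not None:
        write_table(expr.samples[["sample", "strain", "replicate"]], meta_path)


# ---------------------------------------------------------------------------
# Annotation, genetic map, masks, small tables
# ---------------------------------------------------------------------------


def read_annotation(path) -> pd.DataFrame:
    """Transcript annotation TSV: transcript, gene, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation lacks column {col!r}")
    if df["transcript"].duplicated().any():
        raise FormatError("duplicate transcript ids in annotation")
    if (df["tss"] < 1).any():
        raise FormatError("annotation tss must be >= 1")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("annotation strand must be '+' or '-'")
    return df.reset_index(drop=True)


@dataclass
class GeneticMap:
    """Physical-to-genetic map: (chrom, bp, cM) with cM monotone per chromosome."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.reset_index(drop=True).copy()
        for col in ("chrom", "bp", "cM"):
            if col not in t.columns:
                raise FormatError(f"genetic map lacks column {col!r}")
        codes = _chrom_order(t["chrom"]).codes
        order = np.lexsort((t["bp"].to_numpy(), codes))
        t = t.iloc[order].reset_index(drop=True)
        for chrom, sub in t.groupby("chrom", sort=False, observed=True):
            cm = sub["cM"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"cM not monotone on chromosome {chrom}")
            if np.any(cm < 0):
                raise FormatError("cM must be nonnegative")
        self.table = t

    @property
    def chroms(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def interp(self, chrom, bp) -> np.ndarray:
        """Linear interpolation of cM at physical positions on one chromosome."""
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return np.interp(np.asarray(bp, dtype=float), sub["bp"], sub["cM"])

    def cm_range(self, chrom) -> tuple[float, float]:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return float(sub["cM"].min()), float(sub["cM"].max())


def read_genetic_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_genetic_map(gmap: GeneticMap, path) -> None:
    write_table(gmap.table[["chrom", "bp", "cM"]], path)


@dataclass
class DivergentMaskSet:
    """Per-strain hyper-divergent intervals, BED-style 0-based half-open.

    Intervals are normalized on construction: sorted and merged so that each
    strain's intervals are non-overlapping.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["strain", "chrom", "start", "end"])
    )

    def __post_init__(self):
        t = self.table.reset_index(drop=True).copy()
        for col in ("strain", "chrom", "start", "end"):
            if col not in t.columns:
                raise FormatError(f"mask table lacks column {col!r}")
        if len(t) and (t["end"] < t["start"]).any():
            raise FormatError("mask intervals must have end >= start")
        merged = []
        for (strain, chrom), sub in t.groupby(["strain", "chrom"], sort=True):
            iv = sub.sort_values("start")[["start", "end"]].to_numpy()
            cur_s, cur_e = None, None
            for s, e in iv:
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((strain, chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append((strain, chrom, cur_s, cur_e))
        self.table = pd.DataFrame(merged, columns=["strain", "chrom", "start", "end"])

    @property
    def strains(self) -> list:
        return sorted(set(self.table["strain"]))

    def is_empty(self) -> bool:
        return len(self.table) == 0

    def covers(self, strain, chrom, pos_1based) -> bool:
        """Whether 1-based position ``pos`` of ``strain`` falls in a masked interval."""
        sub = self.table[
            (self.table["strain"] == strain) & (self.table["chrom"] == chrom)
        ]
        p0 = pos_1based - 1  # convert to 0-based
        return bool(((sub["start"] <= p0) & (p0 < sub["end"])).any())


def read_bed_masks(path) -> DivergentMaskSet:
    """BED with the 4th (name) column holding the strain label."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED mask line needs 4 columns")
            rows.append((parts[3], parts[0], int(parts[1]), int(parts[2])))
    return DivergentMaskSet(pd.DataFrame(rows, columns=["strain", "chrom", "start", "end"]))


def write_bed_masks(masks: DivergentMaskSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        t = masks.table.sort_values(["strain", "chrom", "start"], kind="stable")
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.strain}\n")


def read_phenotype(path) -> pd.Series:
    """Organism-level phenotype TSV (strain, value) -> Series indexed by strain."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("phenotype file needs (strain, value) columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0], name="value")
    s.index.name = "strain"
    return s


def write_phenotype(pheno: pd.Series, path) -> None:
    df = pd.DataFrame({"strain": pheno.index, "value": pheno.to_numpy()})
    write_table(df, path)


def read_variant_annotation(path) -> pd.DataFrame:
    """Variant consequence annotation TSV: marker, consequence, blosum (optional)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("marker", "consequence"):
        if col not in df.columns:
            raise FormatError(f"variant annotation lacks column {col!r}")
    if "blosum" not in df.columns:
        df["blosum"] = np.nan
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV writer: given column order, UTF-8, '\\n' endings."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
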