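"""Cytohistological expression profiling and cell-lineage classification.

The pipeline consumes the HPA single-cell long format (one row per gene x
tissue x cluster x cell type, expression in nTPM — normalized transcripts per
million) and proceeds:

1.  lineage key formation: ``Tissue + " " + Cell.type`` (a cluster suffix
    ``" c-<cluster>"`` is appended in cluster-resolved mode);
2.  per-(gene, lineage) dispersion statistics over cluster replicates
    (sample standard deviation, n-1 denominator; coefficient of variation);
3.  median aggregation over clusters to one value per (gene, lineage);
4.  pivot to a dense lineage x gene matrix (absent combinations are 0 nTPM,
    i.e. no reads observed), dropping constant columns;
5.  per-gene Min-Max normalization to [0, 1];
6.  L1 (Manhattan) — optionally L2 — distances between lineage feature
    vectors, and nearest-lineage classification of query expression vectors;
7.  per-gene z-score profiles across lineages for differential expression.
"""

from __future__ import annotations

import difflib
import io
import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import linregress

logger = logging.getLogger(__name__)

REQUIRED_HEADERS = ("Gene", "Gene.name", "Tissue", "Cluster", "Cell.type",
                    "Read.count", "nTPM")

TIER_NONE = "none"
TIER_SIGNIFICANT = "significant"
TIER_VERY_SIGNIFICANT = "very_significant"
DEFAULT_Z_THRESHOLDS = (2.0, 3.0)


class GepFormatError(ValueError):
    """Input table missing a required header."""


class PipelineError(ValueError):
    """A pipeline stage received input violating its precondition."""


@dataclass
class ExpressionRecord:
    ensembl_id: str
    gene_symbol: str
    tissue: str
    cluster: str
    cell_type: str
    read_count: float
    ntpm: float


def lineage_key(tissue: str, cell_type: str, cluster: str | None = None) -> str:
    """Deterministic lineage key: tissue + " " + cell type (+ " c-<cluster>")."""
    key = f"{tissue.strip()} {cell_type.strip()}"
    if cluster is not None:
        tag = cluster.strip()
        if tag.startswith("c-"):  # HPA cluster labels already carry the prefix
            tag = tag[2:]
        key = f"{key} c-{tag}"
    return key


def load_expression_table(tsv_text: str) -> list[ExpressionRecord]:
    """Parse the 7-column HPA dialect (header order-insensitive).

    Rows with non-numeric or negative nTPM are rejected with a logged count.
    """
    frame = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    for header in REQUIRED_HEADERS:
        if header not in frame.columns:
            raise GepFormatError(f"expression table missing header {header!r}")
    ntpm = pd.to_numeric(frame["nTPM"], errors="coerce")
    reads = pd.to_numeric(frame["Read.count"], errors="coerce").fillna(0.0)
    bad = ntpm.isna() | (ntpm < 0)
    if bad.any():
        logger.warning("expression table: rejected %d row(s) with invalid nTPM",
                       int(bad.sum()))
    records: list[ExpressionRecord] = []
    for i in frame.index[~bad]:
        records.append(ExpressionRecord(
            ensembl_id=str(frame.at[i, "Gene"]),
            gene_symbol=str(frame.at[i, "Gene.name"]),
            tissue=str(frame.at[i, "Tissue"]),
            cluster=str(frame.at[i, "Cluster"]),
            cell_type=str(frame.at[i, "Cell.type"]),
            read_count=float(reads.at[i]),
            ntpm=float(ntpm.at[i]),
        ))
    return records


# ---------------------------------------------------------------------------
# Cluster statistics
# ---------------------------------------------------------------------------

@dataclass
class ClusterStats:
    gene_symbol: str
    lineage: str
    ntpm_list: list[float]
    mean: float
    median: float
    sd: float          # NaN for singleton groups (sample sd, n-1 denominator)
    cv_percent: float  # NaN when sd is NaN or mean == 0


def cluster_stats(records: list[ExpressionRecord]) -> list[ClusterStats]:
    """Dispersion over cluster replicates for each (gene, lineage) group."""
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        key = (rec.gene_symbol, lineage_key(rec.tissue, rec.cell_type))
        groups.setdefault(key, []).append(rec.ntpm)
    out: list[ClusterStats] = []
    for (gene, lineage), values in groups.items():
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
        if math.isnan(sd) or mean == 0:
            cv = math.nan
        else:
            cv = 100.0 * sd / mean
        out.append(ClusterStats(gene, lineage, list(values), mean,
                                float(np.median(arr)), sd, cv))
    return out


def summarize_dispersion(stats: list[ClusterStats]) -> dict[str, float]:
    """NA-excluded means of per-group sd and CV%; reports exclusion counts."""
    sds = [s.sd for s in stats if not math.isnan(s.sd)]
    cvs = [s.cv_percent for s in stats if not math.isnan(s.cv_percent)]
    excluded_sd = len(stats) - len(sds)
    excluded_cv = len(stats) - len(cvs)
    if excluded_sd or excluded_cv:
        logger.info("dispersion summary excluded %d NA sd and %d NA cv group(s)",
                    excluded_sd, excluded_cv)
    return {
        "mean_sd": float(np.mean(sds)) if sds else math.nan,
        "mean_cv_percent": float(np.mean(cvs)) if cvs else math.nan,
        "excluded_sd_groups": excluded_sd,
        "excluded_cv_groups": excluded_cv,
    }


# ---------------------------------------------------------------------------
# Aggregation and the expression matrix
# ---------------------------------------------------------------------------

def aggregate_median(records: list[ExpressionRecord],
                     cluster_mode: str = "merge") -> dict[str, dict[str, float]]:
    """Collapse to one nTPM per (lineage key, gene).

    ``merge``  — median over all cluster rows of a lineage;
    ``retain`` — one key per (lineage, cluster), median within the cluster.
    """
    if cluster_mode not in ("merge", "retain"):
        raise ValueError(f"cluster_mode must be 'merge' or 'retain', got {cluster_mode!r}")
    groups: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        cluster = rec.cluster if cluster_mode == "retain" else None
        key = lineage_key(rec.tissue, rec.cell_type, cluster)
        groups.setdefault(key, {}).setdefault(rec.gene_symbol, []).append(rec.ntpm)
    return {
        key: {gene: float(np.median(vals)) for gene, vals in genes.items()}
        for key, genes in groups.items()
    }


@dataclass
class ExpressionMatrix:
    """Dense lineage x gene nTPM matrix, optionally Min-Max normalized."""

    values: pd.DataFrame                       # index: lineage keys, columns: genes
    normalization: dict[str, tuple[float, float]] | None = None
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def row_keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_genes(self) -> list[str]:
        return list(self.values.columns)


def build_matrix(aggregated: dict[str, dict[str, float]]) -> ExpressionMatrix:
    """Pivot to a dense matrix; 0-fill gaps; drop constant (incl. all-zero) genes."""
    if len(aggregated) < 2:
        raise PipelineError("need at least 2 lineages to build a feature matrix")
    frame = pd.DataFrame.from_dict(aggregated, orient="index").fillna(0.0)
    frame = frame.sort_index().sort_index(axis=1)
    constant = [col for col in frame.columns if frame[col].nunique() == 1]
    if constant:
        logger.info("dropped %d constant gene column(s)", len(constant))
    frame = frame.drop(columns=constant)
    return ExpressionMatrix(values=frame, dropped_genes=sorted(constant))


def minmax_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene rescale to [0,1]; stores (min, max) for query normalization."""
    frame = matrix.values
    mins = frame.min(axis=0)
    maxs = frame.max(axis=0)
    constant = list(frame.columns[mins == maxs])
    if constant:
        raise PipelineError(
            f"constant column(s) reached normalization (cleaning skipped?): "
            f"{constant[:5]}"
        )
    normalized = (frame - mins) / (maxs - mins)
    params = {gene: (float(mins[gene]), float(maxs[gene])) for gene in frame.columns}
    return ExpressionMatrix(values=normalized, normalization=params,
                            dropped_genes=list(matrix.dropped_genes))


# ---------------------------------------------------------------------------
# Distances and classification
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    keys: list[str]
    d: pd.DataFrame  # symmetric, zero diagonal


def manhattan_matrix(matrix: ExpressionMatrix, metric: str = "L1") -> DistanceMatrix:
    """All-pairs lineage distances on the (normalized) feature vectors."""
    if metric not in ("L1", "L2"):
        raise ValueError(f"metric must be 'L1' or 'L2', got {metric!r}")
    data = matrix.values.to_numpy(dtype=float)
    dist = cdist(data, data, metric="cityblock" if metric == "L1" else "euclidean")
    keys = matrix.row_keys
    return DistanceMatrix(keys=keys, d=pd.DataFrame(dist, index=keys, columns=keys))


def normalize_query(query: dict[str, float], matrix: ExpressionMatrix) -> np.ndarray:
    """Project a raw gene->nTPM map onto the matrix's normalized feature space.

    Matrix genes absent from the query are 0 nTPM; query genes absent from
    the matrix are ignored with a warning; normalized values clamp to [0,1]
    because the stored (min, max) may not cover new data.
    """
    if matrix.normalization is None:
        raise PipelineError("matrix is not normalized; call minmax_normalize first")
    genes = matrix.col_genes
    known = set(genes)
    extra = [g for g in query if g not in known]
    if extra:
        logger.warning("query: ignoring %d gene(s) absent from the matrix", len(extra))
    if not any(g in known for g in query):
        raise PipelineError("query shares no genes with the expression matrix")
    vector = np.empty(len(genes), dtype=float)
    for i, gene in enumerate(genes):
        lo, hi = matrix.normalization[gene]
        raw = float(query.get(gene, 0.0))
        vector[i] = min(1.0, max(0.0, (raw - lo) / (hi - lo)))
    return vector


def classify_lineage(query: dict[str, float], matrix: ExpressionMatrix,
                     top_k: int = 10) -> list[tuple[str, float]]:
    """Nearest lineages to a query expression vector by L1 distance.

    Returns up to ``top_k`` (lineage key, distance) pairs ascending by
    distance, ties broken by key sort.
    """
    vector = normalize_query(query, matrix)
    data = matrix.values.to_numpy(dtype=float)
    dists = np.abs(data - vector).sum(axis=1)
    order = sorted(zip(matrix.row_keys, dists), key=lambda kv: (kv[1], kv[0]))
    return [(key, float(d)) for key, d in order[:top_k]]


# ---------------------------------------------------------------------------
# Differential expression profiles
# ---------------------------------------------------------------------------

@dataclass
class GeneZProfile:
    gene_symbol: str
    per_lineage: list[tuple[str, float, float, str]]  # (key, ntpm, z, tier)
    gene_mean: float
    gene_sd: float


def gene_zscores(matrix: ExpressionMatrix, gene: str,
                 thresholds: tuple[float, float] = DEFAULT_Z_THRESHOLDS
                 ) -> GeneZProfile:
    """Standardize one gene's expression across lineages and tier the z-values.

    z = (x - mean) / sd with the sample (n-1) standard deviation; a constant
    gene yields all-zero z and tier "none" throughout.
    """
    z_sig, z_very = thresholds
    if gene not in matrix.values.columns:
        near = difflib.get_close_matches(gene, list(matrix.values.columns), n=3)
        raise KeyError(f"gene {gene!r} not in matrix; near matches: {near}")
    if len(matrix.values.index) < 3:
        raise PipelineError("z-profiles need at least 3 lineages")
    column = matrix.values[gene].astype(float)
    mean = float(column.mean())
    sd = float(column.std(ddof=1))
    per_lineage: list[tuple[str, float, float, str]] = []
    for key, value in column.items():
        z = 0.0 if sd == 0 else (float(value) - mean) / sd
        if sd == 0 or abs(z) < z_sig:
            tier = TIER_NONE
        elif abs(z) < z_very:
            tier = TIER_SIGNIFICANT
        else:
            tier = TIER_VERY_SIGNIFICANT
        per_lineage.append((str(key), float(value), z, tier))
    return GeneZProfile(gene, per_lineage, mean, sd)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def regression_r2(x: list[float], y: list[float]) -> RegressionFit:
    """Ordinary least squares y ~ x; r_squared = 1 - SSres/SStot."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if float(np.std(x)) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = linregress(x, y)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue) ** 2)


def histogram_bins(values: list[float], n_bins: int) -> tuple[list[float], list[int]]:
    """Equal-width bins over [min, max], right-open except the last."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(values) == 0:
        raise ValueError("cannot histogram an empty value list")
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=n_bins)
    return [float(e) for e in edges], [int(c) for c in counts]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _safe_filename(key: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", key).strip("_") or "unnamed"


def export_profiles(matrix: ExpressionMatrix, stats: list[ClusterStats],
                    out_dir) -> dict:
    """Write per-lineage and per-gene TSVs plus the L1 distance matrix.

    Per-lineage files rank genes by nTPM descending; per-gene files rank
    lineages by z descending.  File count = #lineages + #genes + 1, recorded
    in a manifest written alongside.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    sd_lookup = {(s.gene_symbol, s.lineage): s for s in stats}

    for key in matrix.row_keys:
        row = matrix.values.loc[key].sort_values(ascending=False, kind="mergesort")
        name = f"lineage_{_safe_filename(key)}.tsv"
        with open(out / name, "w", encoding="utf-8") as fh:
            fh.write("gene\tntpm\tcluster_sd\n")
            for gene, value in row.items():
                s = sd_lookup.get((gene, key))
                sd_text = "" if s is None or math.isnan(s.sd) else f"{s.sd:.6g}"
                fh.write(f"{gene}\t{value:.6g}\t{sd_text}\n")
        files.append(name)

    for gene in matrix.col_genes:
        profile = gene_zscores(matrix, gene)
        ranked = sorted(profile.per_lineage, key=lambda r: (-r[2], r[0]))
        name = f"gene_{_safe_filename(gene)}.tsv"
        with open(out / name, "w", encoding="utf-8") as fh:
            fh.write("lineage\tntpm\tz\ttier\n")
            for key, ntpm, z, tier in ranked:
                fh.write(f"{key}\t{ntpm:.6g}\t{z:.6g}\t{tier}\n")
        files.append(name)

    distances = manhattan_matrix(minmax_normalize(matrix)
                                 if matrix.normalization is None else matrix)
    dist_name = "distance_matrix.tsv"
    distances.d.to_csv(out / dist_name, sep="\t", float_format="%.6g")
    files.append(dist_name)

    manifest = {
        "n_lineages": len(matrix.row_keys),
        "n_genes": len(matrix.col_genes),
        "n_files": len(files),
        "files": files,
        "dropped_genes": list(matrix.dropped_genes),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
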