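"""GeTMM expression normalization and exploratory summaries.

Cross-species read counts are made comparable in two steps: a within-sample
gene-length correction (reads per kilobase, RPK) followed by between-sample
trimmed-mean-of-M-values (TMM) scaling computed on the RPK table — the GeTMM
procedure.  The TMM factor for a sample against a reference sample r is

    f_s = 2 ** ( sum_g w_g M_g / sum_g w_g )   over doubly-trimmed genes g,

with M_g = log2((x_g/N_s) / (r_g/N_r)), A_g = 0.5*log2((x_g/N_s)*(r_g/N_r)),
precision weights w_g = (N_s - x_g)/(N_s x_g) + (N_r - r_g)/(N_r r_g), the top
and bottom 30% of genes by M and 5% by A removed, and the reference chosen as
the sample whose upper-quartile/library-size ratio is closest to the mean such
ratio.  Factors are rescaled to geometric mean 1.  The normalized value is

    GeTMM[g, s] = RPK[g, s] * 1e6 / (sum_g RPK[g, s] * f_s).

Also provided: the species-wise low-expression filter, log2(x+1) transform,
variance filtering, PCA (SVD on gene-centred data) and Spearman-correlation
complete-linkage clustering of samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .exceptions import AnalysisError
from .io import OrthologCountMatrix

_log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """GeTMM expression values (per-million scale) with their TMM factors."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    reference_sample_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise AnalysisError("normalized matrix contains non-finite values")
        gm = float(np.exp(np.mean(np.log(self.tmm_factors.to_numpy()))))
        if abs(gm - 1.0) > 1e-8:
            raise AnalysisError(f"TMM factors have geometric mean {gm}, expected 1")


@dataclass
class ExpressionSummary:
    """PCA + Spearman clustering summaries of a log-expression table."""

    pca_scores: pd.DataFrame | None = None
    pca_loadings: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    spearman: pd.DataFrame | None = None
    linkage: np.ndarray | None = None
    newick: str | None = None


def filter_low_expression(matrix: OrthologCountMatrix, mode: str = "all_species") -> OrthologCountMatrix:
    """Drop genes not expressed (count > 0) consistently within species groups.

    ``mode='all_species'`` keeps a gene only when every sample of every species
    has a positive count; ``mode='any_species'`` keeps genes fully expressed in
    at least one species.
    """
    species = matrix.samples["species"]
    per_species_ok = pd.DataFrame(
        {
            sp: (matrix.counts[species.index[species == sp]] > 0).all(axis=1)
            for sp in species.unique()
        }
    )
    if mode == "all_species":
        keep = per_species_ok.all(axis=1)
    elif mode == "any_species":
        keep = per_species_ok.any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    removed = int((~keep).sum())
    _log.info("low-expression filter (%s): removed %d of %d genes", mode, removed, len(keep))
    if not keep.any():
        raise AnalysisError("low-expression filter removed all genes; review inputs")
    return matrix.subset(genes=list(matrix.counts.index[keep]))


def rpk(matrix: OrthologCountMatrix) -> pd.DataFrame:
    """Reads per kilobase: count / (gene length in kb)."""
    if (matrix.gene_lengths <= 0).any():
        raise AnalysisError("gene lengths must be positive")
    return matrix.counts.div(matrix.gene_lengths / 1000.0, axis=0)


def _tmm_one_sample(x: np.ndarray, r: np.ndarray, trim_m: float, trim_a: float) -> float:
    n_x, n_r = x.sum(), r.sum()
    both = (x > 0) & (r > 0)
    xs, rs = x[both], r[both]
    m = np.log2((xs / n_x) / (rs / n_r))
    a = 0.5 * np.log2((xs / n_x) * (rs / n_r))
    w = (n_x - xs) / (n_x * xs) + (n_r - rs) / (n_r * rs)
    n = len(m)
    if n == 0:
        return 1.0
    # double trim: drop the lowest/highest floor(n*trim) genes by M and by A
    rank_m = scipy.stats.rankdata(m, method="ordinal")
    rank_a = scipy.stats.rankdata(a, method="ordinal")
    lo_m, lo_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
    keep = (
        (rank_m > lo_m)
        & (rank_m <= n - lo_m)
        & (rank_a > lo_a)
        & (rank_a <= n - lo_a)
    )
    if keep.sum() < 10:
        _log.warning(
            "TMM: only %d genes survive trimming; falling back to untrimmed weighted mean",
            int(keep.sum()),
        )
        keep = np.ones(n, dtype=bool)
    wk = 1.0 / w[keep]
    return float(2.0 ** (np.sum(wk * m[keep]) / np.sum(wk)))


def tmm_factors(
    rpk_table: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[pd.Series, str]:
    """TMM scaling factors per sample (geometric mean 1) and the reference id."""
    if rpk_table.shape[1] < 2:
        raise AnalysisError("TMM needs at least two samples")
    x = rpk_table.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise AnalysisError("TMM: a sample has zero total expression")
    uq_ratio = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq_ratio - uq_ratio.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [_tmm_one_sample(x[:, j], ref, trim_m, trim_a) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=rpk_table.columns, name="tmm_factor"), str(
        rpk_table.columns[ref_idx]
    )


def getmm(
    matrix: OrthologCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizedMatrix:
    """GeTMM normalization: RPK scaled to per-million with TMM factors."""
    rpk_table = rpk(matrix)
    lib = rpk_table.sum(axis=0)
    if (lib <= 0).any():
        raise AnalysisError("GeTMM: a sample has zero RPK library")
    factors, ref = tmm_factors(rpk_table, trim_m=trim_m, trim_a=trim_a)
    values = rpk_table * 1e6 / (lib * factors)
    return NormalizedMatrix(values=values, tmm_factors=factors, reference_sample_id=ref)


def log_transform(values: pd.DataFrame | NormalizedMatrix) -> pd.DataFrame:
    """log2(x + 1) on a non-negative expression table."""
    if isinstance(values, NormalizedMatrix):
        values = values.values
    if (values.to_numpy() < 0).any():
        raise AnalysisError("log transform requires non-negative values")
    return np.log2(values + 1.0)


def variance_filter(log_table: pd.DataFrame, quantile: float = 0.5) -> pd.DataFrame:
    """Drop the ``quantile`` fraction of genes with lowest cross-sample variance.

    Ties exactly at the cutoff variance are retained.
    """
    if not (0.0 <= quantile < 1.0):
        raise AnalysisError(f"variance filter quantile must be in [0, 1), got {quantile}")
    if log_table.shape[1] < 2:
        raise AnalysisError("variance filter needs at least two samples")
    if quantile == 0.0:
        return log_table
    variances = log_table.var(axis=1, ddof=1, skipna=True)
    k = int(np.floor(len(variances) * quantile))
    if k == 0:
        return log_table
    cutoff = np.sort(variances.to_numpy())[k - 1]
    keep = variances > cutoff
    _log.info("variance filter (q=%.2f): removed %d of %d genes", quantile, int((~keep).sum()), len(keep))
    return log_table.loc[keep]


def pca(log_table: pd.DataFrame) -> ExpressionSummary:
    """PCA of samples from a genes x samples log table via SVD.

    Rows (genes) are centred; explained-variance fractions come from squared
    singular values; each component's sign is fixed so its largest-magnitude
    gene loading is positive.
    """
    if log_table.shape[0] < 2 or log_table.shape[1] < 2:
        raise AnalysisError("PCA needs at least 2 genes and 2 samples")
    x = log_table.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    if np.allclose(xc, 0):
        raise AnalysisError("PCA input is constant")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] *= -1
            vt[j, :] *= -1
    frac = s**2 / np.sum(s**2)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame((vt.T * s), index=log_table.columns, columns=comps)
    loadings = pd.DataFrame(u, index=log_table.index, columns=comps)
    return ExpressionSummary(pca_scores=scores, pca_loadings=loadings, explained_variance=frac)


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def rec(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        row = z[i - n]
        left, hl = rec(int(row[0]))
        right, hr = rec(int(row[1]))
        h = float(row[2])
        return f"({left}:{h - hl:.6g},{right}:{h - hr:.6g})", h

    tree, _ = rec(2 * n - 2)
    return tree + ";"


def spearman_cluster(log_table: pd.DataFrame, method: str = "complete") -> ExpressionSummary:
    """Spearman correlation between samples and hierarchical clustering.

    Distance is 1 - rho (midrank ties); agglomeration uses complete linkage by
    default.  Returns the correlation table, the linkage matrix and a Newick
    rendering of the dendrogram.
    """
    if log_table.shape[1] < 3:
        raise AnalysisError("clustering needs at least three samples")
    corr = log_table.corr(method="spearman")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = sch.linkage(ssd.squareform(dist, checks=False), method=method)
    newick = _linkage_to_newick(z, [str(c) for c in log_table.columns])
    return ExpressionSummary(spearman=corr, linkage=z, newick=newick)
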