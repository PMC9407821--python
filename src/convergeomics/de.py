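"""Differential expression by the negative-binomial conditional exact test.

Each focal (panda) species is contrasted against each outgroup species within a
tissue.  Counts are first equalized to a common effective library size (the
geometric mean of library size x TMM factor, rounded pseudo-counts), summed
within groups, and the per-gene p-value is the conditional exact test: under
the null of equal means, with a common dispersion phi, the group sums are
S_A ~ NB(n_A m, phi/n_A) and S_B ~ NB(n_B m, phi/n_B), and

    p = sum over k of P(S_A = k | S_A + S_B = t)  for outcomes k no more
        probable than the observed one.

Because both group sums share the NB success probability 1/(1 + phi m), the
conditional law is free of the unknown mean m and depends only on
r_A = n_A/phi and r_B = n_B/phi (a negative hypergeometric); phi = 0 gives the
binomial (Poisson) limit.  The common dispersion is a method-of-moments
estimate pooled within groups.  Fold changes are reported on the GeTMM scale
with a prior count; p-values are BH-adjusted within each contrast, and a DEG
requires padj < 0.05 and |log2FC| > 1.  A gene is convergent when it is a DEG
in the same direction in every outgroup contrast of both focal species.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError
from .io import OrthologCountMatrix
from .normalize import NormalizedMatrix

_log = logging.getLogger(__name__)

DEG_ALPHA = 0.05
DEG_LFC = 1.0
_TIE_TOL = 1e-10  # relative tolerance for "no more probable" pmf comparisons


def estimate_common_dispersion(
    counts: pd.DataFrame,
    effective_libs: pd.Series,
    groups: pd.Series,
    min_mean: float = 5.0,
) -> float:
    """Common NB dispersion (variance = mu + phi mu^2) by method of moments.

    Counts are scaled to the geometric-mean effective library, residual
    variance is pooled within groups, and the common phi is the median of the
    per-gene max(0, (s^2 - mean)/mean^2) over genes with mean > ``min_mean``.
    """
    libs = effective_libs.loc[counts.columns].to_numpy(dtype=float)
    geo = float(np.exp(np.mean(np.log(libs))))
    y = counts.to_numpy(dtype=float) * (geo / libs)
    labels = groups.loc[counts.columns].to_numpy()
    n, g = y.shape[1], len(np.unique(labels))
    if n - g < 1:
        raise AnalysisError("dispersion estimation needs >=2 replicates in some group")
    resid_ss = np.zeros(y.shape[0])
    for lab in np.unique(labels):
        sub = y[:, labels == lab]
        if sub.shape[1] >= 2:
            resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = resid_ss / (n - g)
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = np.maximum(0.0, (s2 - mu) / mu**2)
    ok = mu > min_mean
    if not ok.any():
        _log.warning("no gene with mean > %g; defaulting to phi = 0.1", min_mean)
        return 0.1
    return float(np.median(phi_g[ok]))


def _conditional_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    k = np.arange(t + 1)
    if phi <= 1e-12:
        # Poisson limit -> Binomial(t, n_a/(n_a+n_b))
        p = n_a / (n_a + n_b)
        logw = (
            gammaln(t + 1)
            - gammaln(k + 1)
            - gammaln(t - k + 1)
            + k * np.log(p)
            + (t - k) * np.log1p(-p)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(t - k + r_b)
            - gammaln(t - k + 1)
        )
    return logw - logsumexp(logw)


def nb_exact_test(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional p-value for equal group means (see module docstring).

    ``s_a``/``s_b`` are equalized within-group count sums over ``n_a``/``n_b``
    replicates; ``phi`` is the common dispersion.  Returns p in (0, 1].
    """
    t = int(s_a) + int(s_b)
    if t == 0:
        return 1.0
    logp = _conditional_logpmf(t, n_a, n_b, phi)
    obs = logp[int(s_a)]
    included = logp <= obs + _TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logp[included]))))


def log2fc(norm_focal: np.ndarray, norm_other: np.ndarray, prior: float = 1.0) -> float:
    """log2 fold change on the normalized scale; positive = higher in focal."""
    return float(
        np.log2((np.mean(norm_focal) + prior) / (np.mean(norm_other) + prior))
    )


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene statistics of one focal-vs-outgroup contrast in one tissue."""

    focal: str
    outgroup: str
    tissue: str | None
    table: pd.DataFrame  # index gene_id; log2fc, p, padj, is_deg, direction
    phi: float


def call_contrast(
    norm: NormalizedMatrix,
    matrix: OrthologCountMatrix,
    focal: str,
    outgroup: str,
    tissue: str | None = None,
    phi: float | None = None,
    alpha: float = DEG_ALPHA,
    lfc: float = DEG_LFC,
    prior: float = 1.0,
) -> DEResult:
    """Call DEGs for one focal species against one outgroup species."""
    samples_a = matrix.samples_for(species=focal, tissue=tissue)
    samples_b = matrix.samples_for(species=outgroup, tissue=tissue)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise AnalysisError(
            f"contrast {focal} vs {outgroup}: need >=2 replicates per group "
            f"(got {len(samples_a)} and {len(samples_b)})"
        )
    genes = norm.values.index
    counts = matrix.counts.loc[genes, samples_a + samples_b]
    eff_libs = matrix.counts[samples_a + samples_b].sum(axis=0) * norm.tmm_factors.loc[
        samples_a + samples_b
    ]
    groups = pd.Series(
        [focal] * len(samples_a) + [outgroup] * len(samples_b),
        index=samples_a + samples_b,
    )
    if phi is None:
        phi = estimate_common_dispersion(counts, eff_libs, groups)
    libs = eff_libs.to_numpy(dtype=float)
    geo = float(np.exp(np.mean(np.log(libs))))
    pseudo = np.rint(counts.to_numpy(dtype=float) * (geo / libs)).astype(np.int64)
    n_a = len(samples_a)
    s_a = pseudo[:, :n_a].sum(axis=1)
    s_b = pseudo[:, n_a:].sum(axis=1)
    pvals = np.array(
        [nb_exact_test(a, b, n_a, len(samples_b), phi) for a, b in zip(s_a, s_b)]
    )
    padj = bh_adjust(pvals)
    vals = norm.values
    lfc_vals = np.log2(
        (vals[samples_a].mean(axis=1) + prior) / (vals[samples_b].mean(axis=1) + prior)
    ).to_numpy()
    is_deg = (padj < alpha) & (np.abs(lfc_vals) > lfc)
    direction = np.where(~is_deg, "none", np.where(lfc_vals > 0, "up", "down"))
    table = pd.DataFrame(
        {
            "log2fc": lfc_vals,
            "p": pvals,
            "padj": padj,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=genes,
    )
    return DEResult(focal=focal, outgroup=outgroup, tissue=tissue, table=table, phi=phi)


@dataclass
class ConvergentDEGSet:
    """Directional convergent DEGs plus the per-focal intersected sets."""

    tissue: str | None
    up_genes: list[str]
    down_genes: list[str]
    per_focal: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def status_of(self, gene_id: str) -> str:
        if gene_id in self.up_genes:
            return "up"
        if gene_id in self.down_genes:
            return "down"
        return "none"


def convergent_degs(results: list[DEResult], tissue: str | None = None) -> ConvergentDEGSet:
    """Intersect per-contrast DEG calls into convergent up/down sets.

    For each focal species a gene is directionally called only when it is a
    DEG in the same direction against every outgroup; the convergent sets are
    the intersections of the focal species' directional sets.
    """
    focals = sorted({r.focal for r in results})
    universes = [set(r.table.index) for r in results]
    universe = universes[0]
    if any(u != universe for u in universes[1:]):
        raise AnalysisError("contrasts have different gene universes")
    per_focal: dict[str, dict[str, list[str]]] = {}
    for focal in focals:
        sub = [r for r in results if r.focal == focal]
        up: set[str] | None = None
        down: set[str] | None = None
        for r in sub:
            r_up = set(r.table.index[r.table["direction"] == "up"])
            r_down = set(r.table.index[r.table["direction"] == "down"])
            up = r_up if up is None else up & r_up
            down = r_down if down is None else down & r_down
        per_focal[focal] = {"up": sorted(up or ()), "down": sorted(down or ())}
    conv_up = set.intersection(*(set(per_focal[f]["up"]) for f in focals))
    conv_down = set.intersection(*(set(per_focal[f]["down"]) for f in focals))
    return ConvergentDEGSet(
        tissue=tissue,
        up_genes=sorted(conv_up),
        down_genes=sorted(conv_down),
        per_focal=per_focal,
    )
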