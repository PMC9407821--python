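"""Convergent promoter differential methylation.

The promoter methylation level of a gene in a sample pools reads over the CpG
sites of its 1 kb promoter: sum(mC)/sum(mC+uC).  A genes x samples promoter
matrix (variance-filtered like the expression matrix) defines the tested
universe.  For each focal species vs the outgroup, a one-tailed Wilcoxon
rank-sum test is run per gene; the default observation unit is the per-(CpG
site, sample) level at coverage >= 5 — with 3-4 biological replicates a
per-sample rank-sum cannot reach significance after genome-wide correction
(the minimum one-sided p at 4 vs 3 is 1/35), so site-level observations are
the unit that makes promoter-scale inference possible; a per-sample mode is
available.  p-values are BH-adjusted across genes within each direction
family; hypo means lower in the focal species than in the outgroup.  A
promoter is convergent when both focal species are called in the same
direction against the outgroup.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import AnalysisError
from .io import CytosineReport, Gene, GenomeAnnotation
from .normalize import variance_filter

_log = logging.getLogger(__name__)

DMP_ALPHA = 0.05
EXACT_MAX_N = 12  # exact enumeration when tie-free and n_a + n_b <= this


@dataclass
class PromoterMethylationMatrix:
    """Promoter methylation levels by gene x sample, with supporting counts."""

    levels: pd.DataFrame  # float in [0,1], NaN where no covered promoter site
    n_sites: pd.DataFrame
    coverage: pd.DataFrame
    samples: pd.DataFrame  # sample sheet rows for the matrix columns


class _SiteIndex:
    """Sorted per-chromosome CG-site arrays for fast promoter lookup."""

    def __init__(self, report: CytosineReport):
        df = report.data
        if df["context"].isna().any():
            raise AnalysisError("promoter analysis requires context-annotated reports")
        df = df[df["context"] == "CG"]
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False, observed=True):
            order = np.argsort(sub["pos"].to_numpy(), kind="stable")
            pos = sub["pos"].to_numpy()[order]
            mc = sub["mc"].to_numpy()[order]
            cov = mc + sub["uc"].to_numpy()[order]
            self.by_chrom[str(chrom)] = (pos, mc, cov)

    def promoter(self, gene: Gene, min_cov: int = 1) -> tuple[np.ndarray, np.ndarray]:
        if gene.chrom not in self.by_chrom:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos, mc, cov = self.by_chrom[gene.chrom]
        s, e = gene.promoter
        i, j = np.searchsorted(pos, [s, e])
        keep = cov[i:j] >= min_cov
        return mc[i:j][keep], cov[i:j][keep]


def _resolve_gene(
    ortholog: str,
    species: str,
    annotation: GenomeAnnotation | Mapping[str, GenomeAnnotation],
    ortholog_map: pd.DataFrame | None,
) -> Gene | None:
    ann = annotation[species] if isinstance(annotation, Mapping) else annotation
    gene_id = ortholog
    if ortholog_map is not None:
        if ortholog not in ortholog_map.index or species not in ortholog_map.columns:
            return None
        gene_id = ortholog_map.loc[ortholog, species]
    return ann[gene_id] if gene_id in ann else None


def promoter_matrix(
    reports: Mapping[str, CytosineReport],
    annotation: GenomeAnnotation | Mapping[str, GenomeAnnotation],
    samples: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
    var_quantile: float = 0.5,
    min_cov: int = 1,
) -> PromoterMethylationMatrix:
    """Build the ortholog x sample promoter methylation matrix.

    ``annotation`` is one shared annotation or a mapping species -> annotation,
    with ``ortholog_map`` (index ortholog id, one column per species) linking
    gene ids when they differ; orthologs without an annotation entry in some
    species are dropped (logged).  Cells with no covered promoter CpG are
    missing.  The variance filter (default: drop the lowest-variance half)
    is applied to the level matrix.
    """
    sample_ids = [s for s in samples.index if s in reports]
    if len(sample_ids) < len(samples):
        missing = sorted(set(samples.index) - set(reports))
        raise AnalysisError(f"no cytosine report for samples: {missing}")
    if isinstance(annotation, Mapping):
        some_ann = next(iter(annotation.values()))
    else:
        some_ann = annotation
    orthologs = (
        list(ortholog_map.index) if ortholog_map is not None else [g.gene_id for g in some_ann]
    )
    indexes = {sid: _SiteIndex(reports[sid]) for sid in sample_ids}
    levels = np.full((len(orthologs), len(sample_ids)), np.nan)
    n_sites = np.zeros_like(levels, dtype=np.int64)
    covs = np.zeros_like(n_sites)
    dropped = 0
    for gi, ortho in enumerate(orthologs):
        genes = {}
        ok = True
        for sp in samples["species"].unique():
            gene = _resolve_gene(ortho, sp, annotation, ortholog_map)
            if gene is None:
                ok = False
                break
            genes[sp] = gene
        if not ok:
            dropped += 1
            levels[gi, :] = np.nan
            continue
        for si, sid in enumerate(sample_ids):
            gene = genes[str(samples.loc[sid, "species"])]
            mc, cov = indexes[sid].promoter(gene, min_cov=min_cov)
            if cov.sum() > 0:
                levels[gi, si] = mc.sum() / cov.sum()
                n_sites[gi, si] = len(cov)
                covs[gi, si] = cov.sum()
    if dropped:
        _log.info("promoter matrix: dropped %d orthologs without annotation in all species", dropped)
    level_df = pd.DataFrame(levels, index=orthologs, columns=sample_ids)
    level_df = level_df.dropna(how="all")
    filtered = variance_filter(level_df, quantile=var_quantile)
    keep = filtered.index
    return PromoterMethylationMatrix(
        levels=filtered,
        n_sites=pd.DataFrame(n_sites, index=orthologs, columns=sample_ids).loc[keep],
        coverage=pd.DataFrame(covs, index=orthologs, columns=sample_ids).loc[keep],
        samples=samples.loc[sample_ids],
    )


def wilcoxon_one_tailed(obs_a: np.ndarray, obs_b: np.ndarray, direction: str) -> float:
    """One-tailed Wilcoxon rank-sum p-value.

    ``direction='less'`` tests whether A tends below B, ``'greater'`` the
    reverse.  Exact null enumeration when the pooled sample is tie-free and of
    size <= 12, otherwise the normal approximation with tie-corrected variance
    and continuity correction.  Identical inputs give p = 1.
    """
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    a = np.asarray(obs_a, dtype=float)
    b = np.asarray(obs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("Wilcoxon needs >=2 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= EXACT_MAX_N) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative=direction, method=method)
    return float(min(1.0, res.pvalue))


@dataclass
class DMPResult:
    """Per-gene promoter differential methylation calls for one comparison."""

    focal: str
    outgroup: str
    tissue: str | None
    table: pd.DataFrame  # index gene; level_focal, level_outgroup, p_less, ...


def call_dmp(
    matrix: PromoterMethylationMatrix,
    reports: Mapping[str, CytosineReport],
    annotation: GenomeAnnotation | Mapping[str, GenomeAnnotation],
    focal: str,
    outgroup: str,
    tissue: str | None = None,
    ortholog_map: pd.DataFrame | None = None,
    min_cov: int = 5,
    alpha: float = DMP_ALPHA,
    unit: str = "site",
) -> DMPResult:
    """Directional promoter methylation calls for one focal species vs outgroup.

    ``unit='site'`` uses per-(CpG site, sample) promoter levels at coverage >=
    ``min_cov`` as Wilcoxon observations; ``unit='sample'`` uses the per-sample
    pooled promoter levels from the matrix.  hypo = focal below outgroup.
    """
    samples = matrix.samples
    sel = samples["species"].isin([focal, outgroup])
    if tissue is not None and "tissue" in samples:
        sel &= samples["tissue"] == tissue
    sub = samples[sel]
    focal_ids = list(sub.index[sub["species"] == focal])
    out_ids = list(sub.index[sub["species"] == outgroup])
    if not focal_ids or not out_ids:
        raise AnalysisError(f"comparison {focal} vs {outgroup}: species missing from matrix")
    indexes = (
        {sid: _SiteIndex(reports[sid]) for sid in focal_ids + out_ids}
        if unit == "site"
        else {}
    )
    rows = []
    for gene_id in matrix.levels.index:
        if unit == "site":
            obs = {}
            for label, ids in (("focal", focal_ids), ("outgroup", out_ids)):
                chunks = []
                for sid in ids:
                    sp = str(samples.loc[sid, "species"])
                    gene = _resolve_gene(gene_id, sp, annotation, ortholog_map)
                    if gene is None:
                        continue
                    mc, cov = indexes[sid].promoter(gene, min_cov=min_cov)
                    if len(cov):
                        chunks.append(mc / cov)
                obs[label] = np.concatenate(chunks) if chunks else np.empty(0)
            obs_a, obs_b = obs["focal"], obs["outgroup"]
        elif unit == "sample":
            obs_a = matrix.levels.loc[gene_id, focal_ids].dropna().to_numpy()
            obs_b = matrix.levels.loc[gene_id, out_ids].dropna().to_numpy()
        else:
            raise ValueError(f"unknown observation unit {unit!r}")
        if len(obs_a) < 2 or len(obs_b) < 2:
            _log.debug("gene %s skipped: <2 qualifying observations in a group", gene_id)
            continue
        p_less = wilcoxon_one_tailed(obs_a, obs_b, "less")
        p_greater = wilcoxon_one_tailed(obs_a, obs_b, "greater")
        rows.append(
            {
                "gene_id": gene_id,
                "n_obs_focal": len(obs_a),
                "n_obs_outgroup": len(obs_b),
                "level_focal": float(np.mean(obs_a)),
                "level_outgroup": float(np.mean(obs_b)),
                "p_less": p_less,
                "p_greater": p_greater,
            }
        )
    if not rows:
        raise AnalysisError(f"comparison {focal} vs {outgroup}: no testable genes")
    table = pd.DataFrame(rows).set_index("gene_id")
    from .de import bh_adjust  # BH within each direction family across genes

    table["padj_less"] = bh_adjust(table["p_less"].to_numpy())
    table["padj_greater"] = bh_adjust(table["p_greater"].to_numpy())
    hypo = table["padj_less"] < alpha
    hyper = table["padj_greater"] < alpha
    both = hypo & hyper
    if both.any():
        _log.warning("%d genes significant in both directions; left unlabeled", int(both.sum()))
    table["direction"] = np.select(
        [hypo & ~both, hyper & ~both], ["hypo", "hyper"], default="none"
    )
    return DMPResult(focal=focal, outgroup=outgroup, tissue=tissue, table=table)


@dataclass
class ConvergentPromoterSet:
    """Convergent hypo/hyper promoters plus the per-focal differential sets."""

    tissue: str | None
    hypo_genes: list[str]
    hyper_genes: list[str]
    per_focal: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def status_of(self, gene_id: str) -> str:
        if gene_id in self.hypo_genes:
            return "hypo"
        if gene_id in self.hyper_genes:
            return "hyper"
        return "none"


def convergent_promoters(
    calls: list[DMPResult], tissue: str | None = None
) -> ConvergentPromoterSet:
    """Intersect per-focal promoter calls into convergent hypo/hyper sets."""
    per_focal: dict[str, dict[str, list[str]]] = {}
    for res in calls:
        d = res.table["direction"]
        per_focal[res.focal] = {
            "hypo": sorted(d.index[d == "hypo"]),
            "hyper": sorted(d.index[d == "hyper"]),
        }
    focals = sorted(per_focal)
    hypo = set.intersection(*(set(per_focal[f]["hypo"]) for f in focals))
    hyper = set.intersection(*(set(per_focal[f]["hyper"]) for f in focals))
    return ConvergentPromoterSet(
        tissue=tissue,
        hypo_genes=sorted(hypo),
        hyper_genes=sorted(hyper),
        per_focal=per_focal,
    )
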