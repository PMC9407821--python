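"""Bisulfite methylation quantification.

All region-level quantities pool reads, not site levels: the methylation level
of a site is mC/(mC+uC) and the level of any collection of sites is
sum(mC)/sum(mC+uC) over its member sites.  Provided quantities: trinucleotide
context classification (CG/CHG/CHH), per-site levels, 10 kb genomic bin
levels, coverage strata summaries, pooled gene-element levels (promoter, gene,
exon, intron) and the 60-bin metagene profile (20 bins across 2 kb upstream,
20 across the length-normalized gene body, 20 across 2 kb downstream, 5'->3').
"""
from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from ._seq import classify_context  # re-exported; see _seq for the definition
from .exceptions import AnalysisError
from .io import CytosineReport, GenomeAnnotation

_log = logging.getLogger(__name__)

__all__ = [
    "classify_context",
    "site_level",
    "bin_levels",
    "coverage_summary",
    "element_levels",
    "metagene_profile",
]


def site_level(mc: int, uc: int) -> float:
    """Methylation level of one cytosine: mC / (mC + uC)."""
    cov = mc + uc
    if cov < 1:
        raise AnalysisError("site level undefined at zero coverage")
    return mc / cov


def _context_subset(report: CytosineReport, context: str | None) -> pd.DataFrame:
    df = report.data
    if context is None:
        return df
    if df["context"].isna().any():
        raise AnalysisError(
            "report lacks context annotation; read it with a genome or use the context dialect"
        )
    return df[df["context"] == context]


def bin_levels(
    report: CytosineReport, bin_size: int = 10_000, context: str | None = "CG"
) -> pd.DataFrame:
    """Pooled methylation level per fixed genomic bin.

    Bins are [k*bin_size, (k+1)*bin_size) per chromosome; the level pools reads
    over the member sites of the requested context.  Bins without covered
    sites are omitted.
    """
    df = _context_subset(report, context)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "bin_start", "bin_end", "level", "n_sites", "coverage"])
    grouped = df.assign(bin_start=(df["pos"] // bin_size) * bin_size).groupby(
        ["chrom", "bin_start"], sort=True, observed=True
    )
    out = grouped.agg(mc=("mc", "sum"), uc=("uc", "sum"), n_sites=("pos", "size")).reset_index()
    out["bin_end"] = out["bin_start"] + bin_size
    out["coverage"] = out["mc"] + out["uc"]
    out["level"] = out["mc"] / out["coverage"]
    return out[["chrom", "bin_start", "bin_end", "level", "n_sites", "coverage"]]


def coverage_summary(report: CytosineReport) -> dict[str, dict[str, float]]:
    """Per-context site counts at coverage >=1 and >=5, and the fraction of
    >=5-covered sites with methylation level above 0.5."""
    df = report.data
    if df["context"].isna().any():
        raise AnalysisError("coverage summary requires context annotation")
    cov = df["mc"] + df["uc"]
    level = df["mc"] / cov
    out: dict[str, dict[str, float]] = {}
    for ctx in ("CG", "CHG", "CHH"):
        mask = df["context"] == ctx
        ge5 = mask & (cov >= 5)
        n5 = int(ge5.sum())
        out[ctx] = {
            "n_cov1": int(mask.sum()),
            "n_cov5": n5,
            "frac_gt50_cov5": float((level[ge5] > 0.5).mean()) if n5 else float("nan"),
        }
    return out


def _sites_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False, observed=True):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos = sub["pos"].to_numpy()[order]
        mc = sub["mc"].to_numpy()[order]
        cov = (sub["mc"] + sub["uc"]).to_numpy()[order]
        out[str(chrom)] = (pos, mc, cov)
    return out


def element_levels(
    report: CytosineReport, annotation: GenomeAnnotation, context: str = "CG"
) -> dict[str, float]:
    """Pooled methylation level per gene-element class (promoter/gene/exon/intron).

    Sites on either strand inside any (union-merged) interval of a class
    contribute once; levels pool reads across all genes.
    """
    df = _context_subset(report, context)
    sites = _sites_by_chrom(df)
    out: dict[str, float] = {}
    for element in ("promoter", "gene", "exon", "intron"):
        total_mc = 0
        total_cov = 0
        for chrom, intervals in annotation.element_intervals(element).items():
            if chrom not in sites:
                continue
            pos, mc, cov = sites[chrom]
            for s, e in intervals:
                i, j = np.searchsorted(pos, [s, e])
                total_mc += int(mc[i:j].sum())
                total_cov += int(cov[i:j].sum())
        out[element] = total_mc / total_cov if total_cov else float("nan")
    return out


def metagene_profile(
    report: CytosineReport,
    annotation: GenomeAnnotation,
    n_bins: int = 20,
    flank: int = 2000,
    context: str = "CG",
) -> np.ndarray:
    """Mean methylation profile across genes: flank | body | flank, 3*n_bins bins.

    Each gene contributes a pooled level per bin (upstream flank in fixed
    flank/n_bins bp bins, gene body in n_bins equal fractions of its length,
    downstream flank likewise); the profile is the unweighted mean over genes
    of the per-gene bin levels, with minus-strand genes reversed so index 0 is
    always the 5'-most upstream bin.  Genes shorter than n_bins bp are
    excluded (logged).  Bins a gene does not cover are ignored in its mean.
    """
    df = _context_subset(report, context)
    sites = _sites_by_chrom(df)
    total = 3 * n_bins
    prof_sum = np.zeros(total)
    prof_n = np.zeros(total, dtype=np.int64)
    n_used = n_skipped = 0
    for gene in annotation:
        if gene.length < n_bins:
            n_skipped += 1
            continue
        if gene.chrom not in sites:
            continue
        pos, mc, cov = sites[gene.chrom]
        win_lo, win_hi = gene.start - flank, gene.end + flank
        i, j = np.searchsorted(pos, [max(0, win_lo), win_hi])
        if i == j:
            continue
        p, m, c = pos[i:j], mc[i:j], cov[i:j]
        rel_bin = np.empty(len(p), dtype=np.int64)
        before = p < gene.start
        after = p >= gene.end
        body = ~before & ~after
        rel_bin[before] = (p[before] - win_lo) * n_bins // flank
        rel_bin[body] = n_bins + (p[body] - gene.start) * n_bins // gene.length
        rel_bin[after] = 2 * n_bins + (p[after] - gene.end) * n_bins // flank
        rel_bin = np.clip(rel_bin, 0, total - 1)
        if gene.strand == "-":
            rel_bin = total - 1 - rel_bin
        mc_bins = np.bincount(rel_bin, weights=m, minlength=total)
        cov_bins = np.bincount(rel_bin, weights=c, minlength=total)
        covered = cov_bins > 0
        prof_sum[covered] += mc_bins[covered] / cov_bins[covered]
        prof_n[covered] += 1
        n_used += 1
    if n_skipped:
        _log.info("metagene: skipped %d genes shorter than %d bp", n_skipped, n_bins)
    if n_used == 0:
        raise AnalysisError("metagene profile: no qualifying genes")
    with np.errstate(invalid="ignore"):
        return prof_sum / prof_n
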