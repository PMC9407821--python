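"""End-to-end driver: simulate -> normalize -> DE -> methylation -> DMP -> integrate.

``run_pipeline`` executes the whole convergent transcriptomics + methylomics
analysis on synthetic data for one or more tissues (independent runs with
derived child seeds), writes every intermediate table under an output
directory, and scores the calls against the planted truth.  ``evaluate_calls``
computes sensitivity and observed false discovery rate of directional call
sets against a ground-truth status column.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, de, dmp, integrate as integration, io, methylation, normalize, simulate

_log = logging.getLogger(__name__)


def load_config(path: str | Path) -> simulate.SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping (plus ``tissues``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("tissues", None)
    for key in ("focal_species", "outgroup_species", "meth_species"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    for key in ("library_size_range", "gene_length_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = simulate.SimulationConfig(**raw)
    cfg.validate()
    return cfg


def read_tissues(path: str | Path) -> list[str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tissues = raw.get("tissues") or [raw.get("tissue", "stomach")]
    return [str(t) for t in tissues]


def evaluate_calls(
    called: Mapping[str, list[str]], truth: pd.Series, labels: Mapping[str, str]
) -> dict[str, float]:
    """Sensitivity and observed FDR of directional calls against planted truth.

    ``called`` maps call direction -> gene list, ``labels`` maps call
    direction -> the truth status it should recover (e.g. up -> up).
    """
    n_true = n_called = n_correct = 0
    for direction, genes in called.items():
        want = labels[direction]
        truth_set = set(truth.index[truth == want])
        n_true += len(truth_set)
        n_called += len(genes)
        n_correct += len(set(genes) & truth_set)
    return {
        "sensitivity": n_correct / n_true if n_true else float("nan"),
        "fdr": (n_called - n_correct) / n_called if n_called else 0.0,
        "n_called": float(n_called),
        "n_true": float(n_true),
    }


@dataclass
class TissueResult:
    """All artifacts of one tissue's end-to-end run."""

    tissue: str
    config: simulate.SimulationConfig
    matrix: io.OrthologCountMatrix
    truth: simulate.GroundTruth
    norm: normalize.NormalizedMatrix
    contrasts: list[de.DEResult]
    degs: de.ConvergentDEGSet
    promoter_matrix: dmp.PromoterMethylationMatrix
    dmp_calls: list[dmp.DMPResult]
    promoters: dmp.ConvergentPromoterSet
    integration: pd.DataFrame
    element_levels: dict[str, dict[str, float]]
    metrics: dict[str, float] = field(default_factory=dict)


def run_tissue(config: simulate.SimulationConfig, outdir: Path | None = None) -> TissueResult:
    """Run the full pipeline for a single tissue configuration."""
    tissue = config.tissue
    _log.info("[%s] simulating expression (%d genes)", tissue, config.n_genes)
    matrix, truth = simulate.simulate_expression(config)

    filtered = normalize.filter_low_expression(matrix)
    norm = normalize.getmm(filtered)
    log_table = normalize.log_transform(norm)
    var_table = normalize.variance_filter(log_table, quantile=0.5)
    summary = normalize.pca(var_table)
    clustering = normalize.spearman_cluster(var_table)

    _log.info("[%s] calling differential expression", tissue)
    contrasts = [
        de.call_contrast(norm, filtered, focal, outgroup, tissue=tissue)
        for focal in config.focal_species
        for outgroup in config.outgroup_species
    ]
    degs = de.convergent_degs(contrasts, tissue=tissue)

    _log.info("[%s] simulating genome + methylome", tissue)
    genome, annotation = simulate.simulate_genome_and_annotation(config)
    reports, meth_truth = simulate.simulate_methylome(config, genome, annotation)
    meth_samples = pd.DataFrame(
        {
            "species": [sid.rsplit("_bs", 1)[0].rsplit(f"_{tissue}", 1)[0] for sid in reports],
            "tissue": tissue,
            "group": [
                "focal" if config.is_focal(sid.rsplit(f"_{tissue}_bs", 1)[0]) else "outgroup"
                for sid in reports
            ],
        },
        index=pd.Index(list(reports), name="sample_id"),
    )

    elements = {
        sid: methylation.element_levels(rep, annotation) for sid, rep in reports.items()
    }

    _log.info("[%s] promoter differential methylation", tissue)
    pmatrix = dmp.promoter_matrix(reports, annotation, meth_samples)
    outgroup_meth = [sp for sp in config.methylation_panel if not config.is_focal(sp)][0]
    dmp_calls = [
        dmp.call_dmp(pmatrix, reports, annotation, focal, outgroup_meth, tissue=tissue)
        for focal in config.focal_species
    ]
    promoters = dmp.convergent_promoters(dmp_calls, tissue=tissue)

    records = integration.integrate(degs, promoters, tissue=tissue)

    metrics = _score(config, truth, meth_truth, degs, promoters, records)
    result = TissueResult(
        tissue=tissue,
        config=config,
        matrix=matrix,
        truth=truth,
        norm=norm,
        contrasts=contrasts,
        degs=degs,
        promoter_matrix=pmatrix,
        dmp_calls=dmp_calls,
        promoters=promoters,
        integration=records,
        element_levels=elements,
        metrics=metrics,
    )
    if outdir is not None:
        _write_tissue(result, summary, clustering, genome, annotation, reports, meth_truth, Path(outdir))
    return result


def _score(
    config: simulate.SimulationConfig,
    truth: simulate.GroundTruth,
    meth_truth: simulate.GroundTruth,
    degs: de.ConvergentDEGSet,
    promoters: dmp.ConvergentPromoterSet,
    records: pd.DataFrame,
) -> dict[str, float]:
    metrics: dict[str, float] = {}
    expr_eval = evaluate_calls(
        {"up": degs.up_genes, "down": degs.down_genes},
        truth.table["expr_status"],
        {"up": "up", "down": "down"},
    )
    metrics.update({f"deg_{k}": v for k, v in expr_eval.items()})
    meth_eval = evaluate_calls(
        {"hypo": promoters.hypo_genes, "hyper": promoters.hyper_genes},
        meth_truth.table["meth_status"],
        {"hypo": "hypo", "hyper": "hyper"},
    )
    metrics.update({f"promoter_{k}": v for k, v in meth_eval.items()})
    t = truth.table
    planted_inverse = set(t.index[(t["expr_status"] == "up") & (t["meth_status"] == "hypo")])
    planted_inverse |= set(t.index[(t["expr_status"] == "down") & (t["meth_status"] == "hyper")])
    recovered = (
        set(records.loc[records["inverse_consistent"], "gene_id"]) if len(records) else set()
    )
    metrics["inverse_n_true"] = float(len(planted_inverse))
    metrics["inverse_n_called"] = float(len(recovered))
    metrics["inverse_sensitivity"] = (
        len(recovered & planted_inverse) / len(planted_inverse) if planted_inverse else float("nan")
    )
    return metrics


def _write_tissue(
    result: TissueResult,
    summary: normalize.ExpressionSummary,
    clustering: normalize.ExpressionSummary,
    genome: dict[str, str],
    annotation: io.GenomeAnnotation,
    reports: Mapping[str, io.CytosineReport],
    meth_truth: simulate.GroundTruth,
    outdir: Path,
) -> None:
    d = outdir / result.tissue
    d.mkdir(parents=True, exist_ok=True)
    io.write_counts(result.matrix, d / "counts.tsv", d / "samples.tsv")
    simulate.write_truth(result.truth, d / "truth_expression.tsv")
    simulate.write_truth(meth_truth, d / "truth_methylation.tsv")
    result.norm.values.to_csv(d / "getmm.tsv", sep="\t")
    result.norm.tmm_factors.to_csv(d / "tmm_factors.tsv", sep="\t")
    summary.pca_scores.to_csv(d / "pca_scores.tsv", sep="\t")
    clustering.spearman.to_csv(d / "spearman.tsv", sep="\t")
    (d / "dendrogram.nwk").write_text(clustering.newick + "\n")
    for r in result.contrasts:
        r.table.to_csv(d / f"de_{r.focal}_vs_{r.outgroup}.tsv", sep="\t")
    pd.Series(result.degs.up_genes, name="gene_id").to_csv(d / "convergent_up.tsv", index=False, sep="\t")
    pd.Series(result.degs.down_genes, name="gene_id").to_csv(d / "convergent_down.tsv", index=False, sep="\t")
    io.write_fasta(genome, d / "genome.fa")
    io.write_annotation_gff3(annotation, d / "annotation.gff3")
    io.write_annotation_bed12(annotation, d / "annotation.bed")
    meth_dir = d / "cytosine_reports"
    meth_dir.mkdir(exist_ok=True)
    for sid, rep in reports.items():
        io.write_cytosine_report(rep, meth_dir / f"{sid}.cov.tsv", dialect="context")
    pd.DataFrame(result.element_levels).to_csv(d / "element_levels.tsv", sep="\t")
    result.promoter_matrix.levels.to_csv(d / "promoter_methylation.tsv", sep="\t")
    for r in result.dmp_calls:
        r.table.to_csv(d / f"dmp_{r.focal}_vs_{r.outgroup}.tsv", sep="\t")
    pd.Series(result.promoters.hypo_genes, name="gene_id").to_csv(d / "convergent_hypo.tsv", index=False, sep="\t")
    pd.Series(result.promoters.hyper_genes, name="gene_id").to_csv(d / "convergent_hyper.tsv", index=False, sep="\t")
    result.integration.to_csv(d / "integration.tsv", sep="\t", index=False)
    with open(d / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2)


def run_pipeline(
    config_path: str | Path, outdir: str | Path | None = None, seed: int | None = None
) -> dict[str, TissueResult]:
    """Run every tissue in a YAML config; returns tissue -> result.

    Tissues are independent runs with child seeds derived from the config
    seed.  A run manifest (version, parameters, per-tissue metrics) is written
    when ``outdir`` is given.
    """
    base = load_config(config_path)
    if seed is not None:
        base = dataclasses.replace(base, seed=int(seed))
    tissues = read_tissues(config_path)
    children = np.random.SeedSequence(base.seed).spawn(len(tissues))
    results: dict[str, TissueResult] = {}
    for tissue, child in zip(tissues, children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = dataclasses.replace(base, tissue=tissue, seed=child_seed)
        results[tissue] = run_tissue(cfg, outdir=Path(outdir) if outdir else None)
    if outdir is not None:
        manifest: dict[str, Any] = {
            "version": __version__,
            "seed": base.seed,
            "tissues": tissues,
            "parameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(base).items()
            },
            "metrics": {t: r.metrics for t, r in results.items()},
        }
        with open(Path(outdir) / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
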