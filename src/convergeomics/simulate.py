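"""Synthetic multi-species expression and methylome generator with planted truth.

The generator emulates the study design the pipeline targets: two focal
herbivore species ("pandas") and a panel of non-herbivore outgroups, 3-4
biological replicates per species, per-ortholog read counts with library-size
and gene-length variation, and whole-genome bisulfite cytosine reports with
CpG-island-like promoter troughs.  Convergent effects are planted with known
identity so every downstream stage can be scored against ground truth:

* expression — counts are negative binomial with mean
  ``baseline_g * length_g * libsize_s`` scaled by ``2**(+-effect_log2fc)`` in
  both focal species for planted up/down genes (variance ``mu + phi mu^2``,
  one common dispersion phi);
* methylation — per (CpG site, sample) the true level is Beta-distributed
  around a region mean (gene-body baseline genome-wide, a linear trough
  tapering to ``baseline_promoter_meth`` at the TSS inside promoters), with
  planted promoters shifted by ``meth_delta`` between focal and outgroup
  species; coverage is Poisson truncated at 1 and methylated counts are
  binomial.  Non-CpG (CHG/CHH) cytosines sit near zero methylation.

Methylation statuses are planted preferentially on expression-planted genes
(hypo on convergent-up genes first, hyper on convergent-down first) so that
inverse methylation-expression pairs exist by construction.  All outputs are
fully determined by ``SimulationConfig.seed``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import cytosine_sites
from .exceptions import ConfigurationError
from .io import CytosineReport, Gene, GenomeAnnotation, OrthologCountMatrix

_log = logging.getLogger(__name__)

# independent sub-streams derived from the config seed
_STREAM_EXPRESSION = 1
_STREAM_GENOME = 2
_STREAM_METHYLOME = 3

_NONCG_METH = 0.01  # CHG/CHH background methylation mean


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic tissue run.

    Defaults mirror the target study's scale where stated (two focal panda
    species vs a non-herbivore panel, 3-4 replicates, |log2FC| = 2 planted
    expression shifts, 0.3 promoter methylation shifts at ~10x CpG depth).
    """

    n_genes: int = 2000
    focal_species: tuple[str, ...] = ("giant_panda", "red_panda")
    outgroup_species: tuple[str, ...] = ("ferret", "dog", "mouse")
    replicates_per_species: int | Mapping[str, int] | None = None
    n_convergent_up: int = 100
    n_convergent_down: int = 100
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    gene_length_range: tuple[int, int] = (500, 3000)
    n_hypo_promoters: int = 100
    n_hyper_promoters: int = 100
    meth_delta: float = 0.3
    baseline_promoter_meth: float = 0.1
    baseline_body_meth: float = 0.8
    beta_precision: float = 50.0
    read_depth_mean: float = 10.0
    meth_species: tuple[str, ...] | None = None
    cpg_per_promoter: int = 20
    body_cpg_per_kb: float = 10.0
    flank_cpg_per_kb: float = 2.0
    cg_only_reports: bool = False
    genes_per_chrom: int = 100
    tissue: str = "stomach"
    seed: int = 0

    # -- derived views ------------------------------------------------------

    @property
    def species_panel(self) -> tuple[str, ...]:
        return self.focal_species + self.outgroup_species

    @property
    def methylation_panel(self) -> tuple[str, ...]:
        if self.meth_species is not None:
            return self.meth_species
        return self.focal_species + self.outgroup_species[:1]

    def replicates(self, species: str) -> int:
        r = self.replicates_per_species
        if r is None:
            return 4 if species in self.focal_species else 3
        if isinstance(r, Mapping):
            return int(r[species])
        return int(r)

    def is_focal(self, species: str) -> bool:
        return species in self.focal_species

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if len(self.focal_species) != 2:
            raise ConfigurationError("exactly two focal species are required")
        if len(self.outgroup_species) < 1:
            raise ConfigurationError("at least one outgroup species is required")
        if self.n_convergent_up + self.n_convergent_down > self.n_genes:
            raise ConfigurationError("planted expression genes exceed n_genes")
        if self.n_hypo_promoters + self.n_hyper_promoters > self.n_genes:
            raise ConfigurationError("planted promoters exceed n_genes")
        for sp in self.species_panel:
            if self.replicates(sp) < 1:
                raise ConfigurationError(f"replicates for {sp} must be positive")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be non-negative")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if not (0 < self.meth_delta < 1):
            raise ConfigurationError("meth_delta must lie in (0, 1)")
        for name in ("baseline_promoter_meth", "baseline_body_meth"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.beta_precision <= 0 or self.read_depth_mean <= 0:
            raise ConfigurationError("beta_precision and read_depth_mean must be positive")
        for name in ("library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be a positive (lo, hi) pair")
        if not set(self.methylation_panel) <= set(self.species_panel):
            raise ConfigurationError("meth_species must be a subset of the species panel")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruth:
    """Per-gene planted truth: expression and promoter methylation statuses."""

    table: pd.DataFrame  # index gene_id; expr_status, meth_status, ...

    def genes_with(self, expr_status: str | None = None, meth_status: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if expr_status is not None:
            mask &= self.table["expr_status"] == expr_status
        if meth_status is not None:
            mask &= self.table["meth_status"] == meth_status
        return list(self.table.index[mask])


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"gene{i:05d}" for i in range(config.n_genes)]


def planted_statuses(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic planted status assignment shared by both simulators.

    Expression: the first ``n_convergent_up`` genes are up, the next
    ``n_convergent_down`` down.  Methylation: hypo promoters take the
    convergent-up genes first (then nulls), hyper promoters the
    convergent-down genes first (then remaining nulls), so inverse-consistent
    pairs exist whenever both kinds of effects are planted.
    """
    config.validate()
    ids = gene_ids(config)
    expr = np.array(["null"] * config.n_genes, dtype=object)
    expr[: config.n_convergent_up] = "up"
    expr[config.n_convergent_up : config.n_convergent_up + config.n_convergent_down] = "down"
    meth = np.array(["null"] * config.n_genes, dtype=object)
    order_hypo = [i for i in range(config.n_genes) if expr[i] == "up"]
    order_hypo += [i for i in range(config.n_genes) if expr[i] == "null"]
    order_hypo += [i for i in range(config.n_genes) if expr[i] == "down"]
    for i in order_hypo[: config.n_hypo_promoters]:
        meth[i] = "hypo"
    order_hyper = [i for i in range(config.n_genes) if expr[i] == "down" and meth[i] == "null"]
    order_hyper += [i for i in range(config.n_genes) if expr[i] == "null" and meth[i] == "null"]
    order_hyper += [i for i in range(config.n_genes) if meth[i] == "null"]
    for i in order_hyper[: config.n_hyper_promoters]:
        meth[i] = "hyper"
    return pd.DataFrame({"expr_status": expr, "meth_status": meth}, index=pd.Index(ids, name="gene_id"))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> tuple[OrthologCountMatrix, GroundTruth]:
    """Simulate the ortholog count matrix with planted convergent DEGs."""
    config.validate()
    rng = config._rng(_STREAM_EXPRESSION)
    ids = gene_ids(config)
    statuses = planted_statuses(config)

    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    weight = baseline * lengths
    rel = weight / weight.sum()

    sample_rows = []
    for sp in config.species_panel:
        for i in range(config.replicates(sp)):
            sample_rows.append(
                {
                    "sample_id": f"{sp}_{config.tissue}_{i + 1}",
                    "species": sp,
                    "tissue": config.tissue,
                    "group": "focal" if config.is_focal(sp) else "outgroup",
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    lib_sizes = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, len(samples)
    )

    shift = np.ones(config.n_genes)
    up = (statuses["expr_status"] == "up").to_numpy()
    down = (statuses["expr_status"] == "down").to_numpy()
    shift[up] = 2.0**config.effect_log2fc
    shift[down] = 2.0**-config.effect_log2fc

    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples.index):
        sp = str(samples.loc[sid, "species"])
        mu = rel * lib_sizes[j] * (shift if config.is_focal(sp) else 1.0)
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    matrix = OrthologCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"), columns=samples.index),
        gene_lengths=pd.Series(lengths, index=pd.Index(ids, name="gene_id"), name="length_bp"),
        samples=samples,
    )
    truth = statuses.copy()
    mean_lib = float(lib_sizes.mean())
    for sp in config.species_panel:
        sp_shift = shift if config.is_focal(sp) else np.ones(config.n_genes)
        truth[f"expr_mu_{sp}"] = rel * mean_lib * sp_shift
    return matrix, GroundTruth(table=truth)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

_FLANK = 2000  # bp of simulated flank on each side of every gene
_GAP = 200  # bp between consecutive gene slots


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random nucleotides with the CpG dinucleotide suppressed."""
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)
    for _ in range(2):  # a replacement cannot create a new CG, two passes for safety
        cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        arr[cg + 1] = b"A"
    return arr


def _plant_cpgs(arr: np.ndarray, start: int, end: int, n: int) -> None:
    """Place ``n`` CG dinucleotides evenly spaced inside [start, end)."""
    if n <= 0 or end - start < 2:
        return
    pos = np.linspace(start, end - 2, num=n).astype(np.int64)
    pos = np.unique(pos)
    arr[pos] = b"C"
    arr[pos + 1] = b"G"


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Simulate chromosomes and single-transcript gene models.

    Each gene sits in its own slot with >= 2 kb of flank on both sides.  The
    background sequence is CpG-depleted; CG dinucleotides are planted at
    CpG-island-like density in promoters (``cpg_per_promoter`` per 1 kb
    promoter), at moderate density in gene bodies and sparsely in flanks.
    Strands are random and every transcript has >= 2 exons.
    """
    config.validate()
    rng = config._rng(_STREAM_GENOME)
    ids = gene_ids(config)
    body_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    genome: dict[str, str] = {}
    genes: list[Gene] = []
    gi = 0
    chrom_idx = 0
    while gi < config.n_genes:
        chunk = range(gi, min(gi + config.genes_per_chrom, config.n_genes))
        chrom = f"chr{chrom_idx + 1}"
        slots = [(_GAP + _FLANK, int(body_lengths[i]), _FLANK) for i in chunk]
        chrom_len = sum(l + b + r for l, b, r in slots) + _GAP
        arr = _random_sequence(rng, chrom_len)
        cursor = 0
        for i, (left, body, right) in zip(chunk, slots):
            start = cursor + left
            end = start + body
            cursor = end + right
            strand = str(strands[i])
            gene = _make_gene(ids[i], chrom, strand, start, end, rng)
            ps, pe = gene.promoter
            _plant_cpgs(arr, ps, pe, config.cpg_per_promoter)
            _plant_cpgs(arr, start, end, int(round(body / 1000.0 * config.body_cpg_per_kb)))
            if strand == "+":
                _plant_cpgs(arr, start - _FLANK, ps, int(round((_FLANK - (pe - ps)) / 1000.0 * config.flank_cpg_per_kb)))
                _plant_cpgs(arr, end, end + _FLANK, int(round(_FLANK / 1000.0 * config.flank_cpg_per_kb)))
            else:
                _plant_cpgs(arr, pe, end + _FLANK, int(round((_FLANK - (pe - ps)) / 1000.0 * config.flank_cpg_per_kb)))
                _plant_cpgs(arr, start - _FLANK, start, int(round(_FLANK / 1000.0 * config.flank_cpg_per_kb)))
            genes.append(gene)
        genome[chrom] = arr.tobytes().decode("ascii")
        gi = chunk.stop
        chrom_idx += 1
    ann = GenomeAnnotation(genes=genes, chrom_sizes={c: len(s) for c, s in genome.items()})
    return genome, ann


def _make_gene(
    gene_id: str, chrom: str, strand: str, start: int, end: int, rng: np.random.Generator
) -> Gene:
    body = end - start
    n_exons = int(rng.integers(2, 4))
    n_cuts = 2 * n_exons - 2
    cuts = np.sort(rng.choice(np.arange(1, body), size=n_cuts, replace=False))
    bounds = np.concatenate([[0], cuts, [body]])
    exons = tuple(
        (start + int(bounds[k]), start + int(bounds[k + 1])) for k in range(0, len(bounds) - 1, 2)
    )
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end, exons=exons)


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (every simulated site is observed)."""
    k = rng.poisson(lam, size)
    zero = np.flatnonzero(k == 0)
    while len(zero):
        k[zero] = rng.poisson(lam, len(zero))
        zero = zero[k[zero] == 0]
    return k


def simulate_methylome(
    config: SimulationConfig,
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
) -> tuple[dict[str, CytosineReport], GroundTruth]:
    """Simulate per-sample cytosine reports with planted convergent promoters.

    Returns one :class:`CytosineReport` per sample of the methylation species
    panel (both focal species plus the first outgroup by default) and the
    per-gene truth with expected promoter levels for the focal and outgroup
    groups.  For "hypo" genes the outgroup promoter mean is raised by
    ``meth_delta`` (focal = outgroup - delta); for "hyper" genes the focal
    mean is raised.  Region means are clipped to [0.01, 0.99] (logged when
    clipping occurs).
    """
    config.validate()
    for gene in annotation:
        if gene.start - _FLANK < 0 or (
            annotation.chrom_sizes is not None
            and gene.end + _FLANK > annotation.chrom_sizes[gene.chrom]
        ):
            raise ConfigurationError(f"gene {gene.gene_id} lacks a {_FLANK} bp flank")
    rng = config._rng(_STREAM_METHYLOME)
    statuses = planted_statuses(config)

    chrom_sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, seq in genome.items():
        chrom_sites[chrom] = cytosine_sites(seq, cg_only=config.cg_only_reports)

    # region mean (no planted shift) and planted-shift group per site
    base_mu: dict[str, np.ndarray] = {}
    shift_group: dict[str, np.ndarray] = {}  # 0 none, 1 hypo (outgroup +d), 2 hyper (focal +d)
    for chrom, (pos, strand, ctx) in chrom_sites.items():
        mu = np.where(ctx == "CG", config.baseline_body_meth, _NONCG_METH)
        base_mu[chrom] = mu
        shift_group[chrom] = np.zeros(len(pos), dtype=np.int8)

    prom_mu: dict[str, float] = {}  # mean promoter mu per gene (unshifted)
    gene_status = statuses["meth_status"]
    for gene in annotation:
        pos, strand, ctx = chrom_sites[gene.chrom]
        ps, pe = gene.promoter
        i, j = np.searchsorted(pos, [ps, pe])
        sel = np.arange(i, j)[ctx[i:j] == "CG"]
        if len(sel) == 0:
            prom_mu[gene.gene_id] = float("nan")
            continue
        p = pos[sel]
        u = (p - ps + 1) / (pe - ps) if gene.strand == "+" else (pe - p) / (pe - ps)
        mu = config.baseline_body_meth + (
            config.baseline_promoter_meth - config.baseline_body_meth
        ) * u
        base_mu[gene.chrom][sel] = mu
        status = gene_status.get(gene.gene_id, "null")
        if status == "hypo":
            shift_group[gene.chrom][sel] = 1
        elif status == "hyper":
            shift_group[gene.chrom][sel] = 2
        prom_mu[gene.gene_id] = float(mu.mean())

    reports: dict[str, CytosineReport] = {}
    n_clipped = 0
    for sp in config.methylation_panel:
        focal = config.is_focal(sp)
        for rep in range(config.replicates(sp)):
            sid = f"{sp}_{config.tissue}_bs{rep + 1}"
            frames = []
            for chrom in genome:
                pos, strand, ctx = chrom_sites[chrom]
                mu = base_mu[chrom].copy()
                grp = shift_group[chrom]
                if focal:
                    mu[grp == 2] += config.meth_delta
                else:
                    mu[grp == 1] += config.meth_delta
                clipped = (mu < 0.01) | (mu > 0.99)
                n_clipped += int(clipped.sum())
                mu = np.clip(mu, 0.01, 0.99)
                c = config.beta_precision
                level = rng.beta(mu * c, (1.0 - mu) * c)
                cov = _truncated_poisson(rng, config.read_depth_mean, len(pos))
                mc = rng.binomial(cov, level)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": strand,
                            "context": ctx,
                            "mc": mc,
                            "uc": cov - mc,
                        }
                    )
                )
            reports[sid] = CytosineReport(
                data=pd.concat(frames, ignore_index=True), sample_id=sid
            )
    if n_clipped:
        _log.warning(
            "methylome: %d site means clipped to [0.01, 0.99] (meth_delta at the taper edge)",
            n_clipped,
        )

    truth = statuses.copy()
    mu_series = pd.Series(prom_mu).reindex(truth.index)
    delta = config.meth_delta
    meth = truth["meth_status"]
    truth["prom_mu_focal"] = np.where(meth == "hyper", np.clip(mu_series + delta, 0.01, 0.99), mu_series)
    truth["prom_mu_outgroup"] = np.where(meth == "hypo", np.clip(mu_series + delta, 0.01, 0.99), mu_series)
    return reports, GroundTruth(table=truth)


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")


def read_truth(path) -> GroundTruth:
    return GroundTruth(table=pd.read_csv(path, sep="\t", index_col="gene_id"))
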