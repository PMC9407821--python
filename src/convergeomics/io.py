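"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention is used everywhere in memory: 0-based half-open
intervals (``0 <= start < end``, length ``end - start``).  Conversion to and
from 1-based closed coordinates happens only at the GFF3 and Bismark-coverage
file boundaries.  Readers validate strictly and raise :class:`FormatError`
rather than silently coercing.

Formats covered: FASTA genomes, GFF3 / BED12 gene annotation, TSV ortholog
count matrix + sample sheet, Bismark-coverage cytosine reports (6-column
coverage dialect and a 7-column context-annotated dialect), and GMT gene sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import classify_context
from .exceptions import FormatError

_log = logging.getLogger(__name__)

PROMOTER_BP = 1000  # promoter = this many bp immediately upstream of the TSS


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """One gene with a single transcript model, 0-based half-open intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: exon [{s}, {e}) outside gene span")
            if s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or are unsorted")
            if s >= e:
                raise FormatError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcript start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcript end site (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def promoter(self) -> tuple[int, int]:
        """The ``PROMOTER_BP`` bp immediately upstream of the TSS, strand-aware.

        Truncated at the chromosome start for plus-strand genes near position 0.
        """
        if self.strand == "+":
            return (max(0, self.tss - PROMOTER_BP), self.tss)
        return (self.tss + 1, self.tss + 1 + PROMOTER_BP)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """A set of single-transcript gene models on one assembly."""

    genes: list[Gene]
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(f"duplicate gene_id {g.gene_id!r} in annotation")
            seen.add(g.gene_id)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def element_intervals(self, element: str) -> dict[str, list[tuple[int, int]]]:
        """Merged (union) intervals per chromosome for one element class.

        ``element`` is one of ``promoter``, ``gene``, ``exon``, ``intron``.
        Overlapping intervals from different genes are merged, so a cytosine
        inside two promoters contributes once to the pooled promoter level.
        """
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            if element == "promoter":
                ivals: Sequence[tuple[int, int]] = [g.promoter]
            elif element == "gene":
                ivals = [(g.start, g.end)]
            elif element == "exon":
                ivals = g.exons
            elif element == "intron":
                ivals = g.introns
            else:
                raise ValueError(f"unknown element class {element!r}")
            per_chrom.setdefault(g.chrom, []).extend(ivals)
        return {c: _merge_intervals(v) for c, v in per_chrom.items()}


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read gene models from GFF3 (gene/mRNA/exon hierarchy) or BED12."""
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA")) or list(
            db.children(g, featuretype="transcript")
        )
        if not mrnas:
            raise FormatError(f"gene {g.id}: no mRNA/transcript child in {path}")
        if len(mrnas) > 1:
            _log.info("gene %s has %d transcripts; using the first", g.id, len(mrnas))
        m = mrnas[0]
        exons = sorted((e.start - 1, e.end) for e in db.children(m, featuretype="exon"))
        if not exons:
            raise FormatError(f"gene {g.id}: transcript {m.id} has no exons in {path}")
        genes.append(
            Gene(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,  # GFF3 is 1-based closed
                end=g.end,
                exons=tuple(exons),
            )
        )
    return GenomeAnnotation(genes=genes)


def _read_bed12(path: Path) -> GenomeAnnotation:
    genes: list[Gene] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 requires 12 columns, got {len(f)}")
            start, end = int(f[1]), int(f[2])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{ln}: blockCount inconsistent with block lists")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(
                Gene(gene_id=f[3], chrom=f[0], strand=f[5], start=start, end=end, exons=exons)
            )
    return GenomeAnnotation(genes=genes)


def write_annotation_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann:
            base = (g.chrom, "convergeomics", "%s", str(g.start + 1), str(g.end), ".", g.strand, ".")
            fh.write("\t".join(base).replace("%s", "gene") + f"\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(base).replace("%s", "mRNA") + f"\tID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tconvergeomics\texon\t{s + 1}\t{e}\t.\t{g.strand}\t."
                    f"\tID={mid}.exon{i};Parent={mid}\n"
                )


def write_annotation_bed12(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ann:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Ortholog count matrix + sample sheet
# ---------------------------------------------------------------------------

@dataclass
class OrthologCountMatrix:
    """Integer read counts by ortholog x sample, with gene lengths and labels.

    ``counts`` is genes x samples (integer), ``gene_lengths`` is indexed by
    gene_id (bp), ``samples`` is indexed by sample_id with columns ``species``,
    ``tissue`` and ``group`` (``focal`` / ``outgroup``).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise FormatError("count matrix contains missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative counts")
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise FormatError("gene_lengths missing for some genes")
        if (self.gene_lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
        if list(self.counts.columns) != list(self.samples.index):
            raise FormatError("count matrix columns do not match sample sheet order")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene_id {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def species_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "species"])

    def samples_for(self, species: str | None = None, tissue: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if tissue is not None and "tissue" in self.samples:
            mask &= self.samples["tissue"] == tissue
        return list(self.samples.index[mask])

    def subset(self, genes: Sequence[str] | None = None, samples: Sequence[str] | None = None) -> "OrthologCountMatrix":
        counts = self.counts
        lengths = self.gene_lengths
        sheet = self.samples
        if genes is not None:
            counts = counts.loc[list(genes)]
            lengths = lengths.loc[list(genes)]
        if samples is not None:
            counts = counts[list(samples)]
            sheet = sheet.loc[list(samples)]
        return OrthologCountMatrix(counts=counts.copy(), gene_lengths=lengths.copy(), samples=sheet.copy())


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns or "species" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet needs 'sample_id' and 'species' columns")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    for col in ("tissue", "group"):
        if col not in sheet.columns:
            sheet[col] = "NA"
    return sheet.set_index("sample_id")


def read_counts(path: str | Path, sample_sheet_path: str | Path) -> OrthologCountMatrix:
    """Read a TSV count matrix (gene_id, length_bp, one column per sample)."""
    sheet = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "length_bp":
        raise FormatError(f"{path}: first two columns must be gene_id, length_bp")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        line = int(df.index[df["gene_id"] == dup][1]) + 2
        raise FormatError(f"{path}:{line}: duplicate gene_id {dup!r}")
    tsv_samples = list(df.columns[2:])
    missing = [s for s in sheet.index if s not in tsv_samples]
    if missing:
        raise FormatError(f"{path}: samples in sheet absent from counts: {missing}")
    unknown = [s for s in tsv_samples if s not in sheet.index]
    if unknown:
        raise FormatError(f"{path}: unknown samples not in sheet: {unknown}")
    counts = df.set_index("gene_id")[list(sheet.index)]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))
            g, s = bad[0]
            raise FormatError(
                f"{path}: non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        counts = counts.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        bad = np.argwhere(counts.to_numpy() < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {counts.index[bad[0]]!r}, sample {counts.columns[bad[1]]!r}"
        )
    lengths = df.set_index("gene_id")["length_bp"].astype(np.int64)
    return OrthologCountMatrix(counts=counts, gene_lengths=lengths, samples=sheet)


def write_counts(matrix: OrthologCountMatrix, path: str | Path, sample_sheet_path: str | Path | None = None) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length_bp", matrix.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if sample_sheet_path is not None:
        matrix.samples.reset_index().to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cytosine reports (Bismark-coverage dialects)
# ---------------------------------------------------------------------------

@dataclass
class CytosineReport:
    """Per-cytosine bisulfite counts for one sample.

    ``data`` columns: chrom, pos (0-based), strand, context (CG/CHG/CHH or
    missing), mc (methylated reads), uc (unmethylated reads).  Retained records
    have mc + uc >= 1.
    """

    data: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "context", "mc", "uc"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"cytosine report missing columns: {sorted(missing)}")
        cov = self.data["mc"] + self.data["uc"]
        if (cov < 1).any():
            raise FormatError("cytosine report has records with zero coverage")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coverage(self) -> pd.Series:
        return self.data["mc"] + self.data["uc"]


def read_cytosine_report(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> CytosineReport:
    """Read a Bismark-coverage-style cytosine report.

    Two dialects: the 6-column coverage dialect (chrom, start 1-based, end,
    methylation_percent, count_methylated, count_unmethylated) and a 7-column
    context dialect (chrom, pos 1-based, strand, context, count_methylated,
    count_unmethylated, methylation_percent).  With a genome and the 6-column
    dialect, strand and context are inferred from the reference sequence.
    Zero-coverage records are dropped (logged); a methylation percentage
    inconsistent with the counts by more than 0.5 points triggers a warning.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] == 6:
        raw.columns = ["chrom", "start", "end", "pct", "mc", "uc"]
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "pos": raw["start"].astype(np.int64) - 1,
                "strand": ".",
                "context": pd.NA,
                "mc": raw["mc"].astype(np.int64),
                "uc": raw["uc"].astype(np.int64),
            }
        )
        pct = raw["pct"].astype(float)
    elif raw.shape[1] == 7:
        raw.columns = ["chrom", "pos", "strand", "context", "mc", "uc", "pct"]
        bad_ctx = ~raw["context"].isin(["CG", "CHG", "CHH"])
        if bad_ctx.any():
            raise FormatError(
                f"{path}:{int(raw.index[bad_ctx][0]) + 1}: invalid context "
                f"{raw.loc[bad_ctx, 'context'].iloc[0]!r}"
            )
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "pos": raw["pos"].astype(np.int64) - 1,
                "strand": raw["strand"].astype(str),
                "context": raw["context"].astype(str),
                "mc": raw["mc"].astype(np.int64),
                "uc": raw["uc"].astype(np.int64),
            }
        )
        pct = raw["pct"].astype(float)
    else:
        raise FormatError(f"{path}: expected 6 or 7 columns, got {raw.shape[1]}")

    cov = df["mc"] + df["uc"]
    if (df[["mc", "uc"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative methylation counts")
    n_zero = int((cov == 0).sum())
    if n_zero:
        _log.info("%s: dropped %d zero-coverage records", path, n_zero)
        keep = cov > 0
        df, pct, cov = df[keep].reset_index(drop=True), pct[keep].reset_index(drop=True), cov[keep].reset_index(drop=True)
    observed_pct = 100.0 * df["mc"] / cov
    inconsistent = (observed_pct - pct).abs() > 0.5
    if inconsistent.any():
        _log.warning(
            "%s: %d records with methylation_percent inconsistent with counts by >0.5",
            path,
            int(inconsistent.sum()),
        )
    if genome is not None and (df["context"].isna().any() or (df["strand"] == ".").any()):
        strands, contexts = [], []
        for chrom, pos in zip(df["chrom"], df["pos"]):
            base = genome[chrom][pos].upper()
            if base == "C":
                strand = "+"
            elif base == "G":
                strand = "-"
            else:
                raise FormatError(f"{path}: reference base at {chrom}:{pos} is {base}, not C/G")
            strands.append(strand)
            contexts.append(classify_context(genome, chrom, pos, strand))
        df["strand"] = strands
        df["context"] = contexts
    return CytosineReport(data=df, sample_id=sample_id or path.stem)


def write_cytosine_report(report: CytosineReport, path: str | Path, dialect: str = "context") -> None:
    """Write a cytosine report in the 6-column coverage or 7-column context dialect."""
    df = report.data
    cov = df["mc"] + df["uc"]
    pct = (100.0 * df["mc"] / cov).round(6)
    if dialect == "coverage":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"] + 1,
                "end": df["pos"] + 1,
                "pct": pct,
                "mc": df["mc"],
                "uc": df["uc"],
            }
        )
    elif dialect == "context":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"] + 1,
                "strand": df["strand"],
                "context": df["context"],
                "mc": df["mc"],
                "uc": df["uc"],
                "pct": pct,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into a mapping set-name -> unique member gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f for f in fields[2:]):
                _log.warning("%s:%d: gene set %r has no members; skipped", path, ln, fields[0])
                continue
            name = fields[0]
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            if name in sets:
                _log.warning("%s:%d: duplicate set name %r; keeping first", path, ln, name)
                continue
            sets[name] = members
    if not sets:
        _log.warning("%s: no gene sets read", path)
    return sets
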