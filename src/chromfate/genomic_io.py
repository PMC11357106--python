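"""Readers/writers for the genomics formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GFF3 input
(1-based inclusive) is converted at the boundary. Round-trips
(write followed by read) are identities for every format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "GeneModel",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_models",
    "write_gene_models",
    "read_counts",
    "write_counts",
]


class FormatError(ValueError):
    """Malformed record in an input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding interval with summit offset and MACS2-style scores."""

    interval: GenomicInterval
    summit_offset: int
    fold_enrichment: float = 0.0
    neg_log10_q: float = 0.0
    name: str = "."

    def __post_init__(self):
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        for v in (self.fold_enrichment, self.neg_log10_q):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"non-finite or negative peak score {v}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (bp)."""
        return self.interval.start + self.summit_offset


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage with a fixed bin size.

    ``data[chrom][i]`` is the mean signal over bases
    ``[i*bin_size, min((i+1)*bin_size, chrom_length))``.
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            n = self.n_bins(chrom)
            if chrom not in self.data:
                self.data[chrom] = np.zeros(n)
            elif len(self.data[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins for length {length}, "
                    f"got {len(self.data[chrom])}"
                )

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    def values_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp signal over [start, end); out-of-range positions are 0."""
        out = np.zeros(end - start)
        length = self.chrom_lengths[chrom]
        lo, hi = max(start, 0), min(end, length)
        if lo < hi:
            idx = np.arange(lo, hi) // self.bin_size
            out[lo - start : hi - start] = self.data[chrom][idx]
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Summed signal over a region in bin units (per-bp sum / bin_size)."""
        return float(self.values_bp(chrom, start, end).sum() / self.bin_size)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS/TES."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class ExpressionMatrix:
    """Cells x genes raw counts with per-cell cluster labels.

    Counts are stored sparse (CSR). Every cell must have a positive total;
    cluster labels must come from the declared ``clusters`` order.
    """

    def __init__(self, counts, gene_ids, cell_ids, cluster_labels, clusters=None):
        counts = scipy.sparse.csr_matrix(counts)
        if counts.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        if (counts.data < 0).any():
            raise ValueError("negative counts")
        totals = np.asarray(counts.sum(axis=1)).ravel()
        if (totals == 0).any():
            bad = [cell_ids[i] for i in np.where(totals == 0)[0]]
            raise ValueError(f"cells with zero total counts: {bad}")
        self.counts = counts
        self.gene_ids = list(gene_ids)
        self.cell_ids = list(cell_ids)
        self.cluster_labels = np.asarray(cluster_labels, dtype=object)
        if clusters is None:
            clusters = list(pd.unique(self.cluster_labels))
        unknown = set(self.cluster_labels) - set(clusters)
        if unknown:
            raise ValueError(f"cluster labels outside declared set: {sorted(unknown)}")
        self.clusters = list(clusters)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(
                {"cluster": self.cluster_labels}, index=self.cell_ids
            ),
            var=pd.DataFrame(index=self.gene_ids),
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path) -> list[Peak]:
    """Parse an ENCODE narrowPeak (BED6+4) file.

    A summit column of -1 (absent summit) maps to the interval midpoint, so
    downstream summit-centric operations stay total.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                fe, neg_log10_q = float(fields[6]), float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if summit == -1:
                summit = (end - start) // 2
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end, fields[5] if fields[5] in "+-" else "."),
                    summit_offset=summit,
                    fold_enrichment=fe,
                    neg_log10_q=neg_log10_q,
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        "0",
                        p.interval.strand,
                        repr(float(p.fold_enrichment)),
                        "-1",
                        repr(float(p.neg_log10_q)),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, bin_size: int, chrom_lengths: dict[str, int]) -> SignalTrack:
    """Bin a bedGraph into a :class:`SignalTrack`.

    Each bin's value is the length-weighted mean of the records overlapping
    it (uncovered bp contribute 0), so signal mass is conserved on fully
    covered chromosomes.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        float_precision="round_trip",
    )
    track = SignalTrack(bin_size=bin_size, chrom_lengths=dict(chrom_lengths))
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        length = chrom_lengths[chrom]
        if (sub["end"] > length).any():
            raise FormatError(
                f"{path}: record exceeds declared length {length} of {chrom}"
            )
        mass = np.zeros(track.n_bins(chrom))
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                mass[b0] += value * (end - start)
                continue
            mass[b0] += value * ((b0 + 1) * bin_size - start)
            mass[b1] += value * (end - b1 * bin_size)
            mass[b0 + 1 : b1] += value * bin_size
        # partial final bin: divide by its true width so constant coverage
        # stays constant
        widths = np.full(len(mass), bin_size, dtype=float)
        widths[-1] = length - (len(mass) - 1) * bin_size
        track.data[chrom] = mass / widths
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write one record per run of equal-valued bins (zeros included)."""
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            values = track.data[chrom]
            length = track.chrom_lengths[chrom]
            edges = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(values)]])
            for b0, b1 in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{b0 * track.bin_size}"
                    f"\t{min(b1 * track.bin_size, length)}\t{float(values[b0])!r}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 (gene records only)

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gene_models(path) -> list[GeneModel]:
    """Read gene features from a GFF3 subset (1-based inclusive -> half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "start": np.int64, "end": np.int64},
    )
    genes = []
    for row in df.itertuples(index=False):
        if row.type != "gene":
            continue
        if row.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene at {row.seqid}:{row.start}-{row.end} lacks a strand"
            )
        gene_id = "."
        for part in str(row.attributes).split(";"):
            if part.startswith("ID="):
                gene_id = part[3:]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(row.seqid, row.start - 1, row.end, row.strand),
            )
        )
    return genes


def write_gene_models(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom, "chromfate", "gene",
                        str(g.interval.start + 1), str(g.interval.end),
                        ".", g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Triplet count matrix (MatrixMarket) + TSV sidecars


def read_counts(matrix_path, genes_path, cells_path) -> ExpressionMatrix:
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None, names=["gene_id"])
    cells = pd.read_csv(cells_path, sep="\t", header=None, names=["cell_id", "cluster"])
    if counts.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix is {counts.shape} but sidecars declare "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    return ExpressionMatrix(
        counts,
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        cluster_labels=cells["cluster"].to_numpy(),
    )


def write_counts(matrix: ExpressionMatrix, matrix_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(
        str(matrix_path), scipy.sparse.coo_matrix(matrix.counts), field="integer"
    )
    pd.DataFrame({"gene_id": matrix.gene_ids}).to_csv(
        genes_path, sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"cell_id": matrix.cell_ids, "cluster": matrix.cluster_labels}
    ).to_csv(cells_path, sep="\t", header=False, index=False)
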