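"""Genomic file formats and the coordinate/track conventions used package-wide.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  GFF/GTF
input (1-based, inclusive) is converted on read.  Coverage is held in
:class:`SignalTrack` objects — fixed-width bins of read counts per bin plus a
library size — which every quantification step consumes.  bedGraph values are
interpreted as per-base read density, so a record of value ``v`` spanning
``L`` bases contributes ``v * L`` reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}
_FASTA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed record in an input file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    On the + strand the TSS is ``body.start``; on the - strand it is
    ``body.end - 1`` (the last base of the half-open body).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body {self.body.start}-{self.body.end}"
            )


@dataclass
class SignalTrack:
    """Binned non-negative read coverage plus the library size used for scaling.

    ``values[chrom][i]`` is the number of reads falling in bin
    ``[i*bin_size, (i+1)*bin_size)``.  Within a bin, reads are treated as
    uniformly distributed, so sub-bin windows are quantified by fractional
    overlap — this makes windowed sums exactly equal to a per-base
    rasterization of the source bedGraph.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    library_size: float

    _warned_chroms: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not np.isfinite(self.library_size) or self.library_size <= 0:
            raise ValueError("library_size must be positive and finite")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"track values for {chrom} must be finite and >= 0")
            self.values[chrom] = arr

    def _chrom_values(self, chrom: str) -> np.ndarray | None:
        arr = self.values.get(chrom)
        if arr is None and chrom not in self._warned_chroms:
            logger.warning("chromosome %s absent from track; treating as zero", chrom)
            self._warned_chroms.add(chrom)
        return arr

    def region_reads(self, chrom: str, start: int, end: int) -> float:
        """Reads in ``[start, end)``, with fractional overlap at partial bins.

        Coordinates beyond the stored array (or a missing chromosome)
        contribute zero.
        """
        if end <= start:
            return 0.0
        arr = self._chrom_values(chrom)
        if arr is None:
            return 0.0
        start = max(start, 0)
        bs = self.bin_size
        lo = start // bs
        hi = min(-(-end // bs), len(arr))  # ceil division, clipped
        if lo >= hi:
            return 0.0
        idx = np.arange(lo, hi)
        left = np.maximum(start, idx * bs)
        right = np.minimum(end, (idx + 1) * bs)
        frac = (right - left) / bs
        return float(np.dot(arr[lo:hi], frac))

    def region_rpm(self, chrom: str, start: int, end: int) -> float:
        """Reads per million mapped reads in ``[start, end)``."""
        return self.region_reads(chrom, start, end) * 1e6 / self.library_size


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3–BED6 file, preserving input order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6, sorted by chromosome then start."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ordered:
            fields = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name if iv.name is not None else ".",
                format(iv.score, "g") if iv.score is not None else "0",
                iv.strand,
            ]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, bin_size: int = 10) -> SignalTrack:
    """Rasterize a bedGraph of per-base read densities into a binned track.

    Records must be sorted and non-overlapping within each chromosome.  An
    interval of density ``v`` over ``L`` bases deposits ``v * L`` reads,
    length-weighted into the bins it touches; the track's ``library_size`` is
    the total deposited reads.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            recs = per_chrom.setdefault(chrom, [])
            if recs and start < recs[-1][1]:
                raise ParseError(
                    f"{path}:{lineno}: records overlap or are unsorted on {chrom}"
                )
            recs.append((start, end, value))

    values: dict[str, np.ndarray] = {}
    library_size = 0.0
    for chrom, recs in per_chrom.items():
        extent = recs[-1][1]
        arr = np.zeros(-(-extent // bin_size), dtype=float)
        for start, end, value in recs:
            if value == 0.0:
                continue
            library_size += value * (end - start)
            lo = start // bin_size
            hi = -(-end // bin_size)
            idx = np.arange(lo, hi)
            left = np.maximum(start, idx * bin_size)
            right = np.minimum(end, (idx + 1) * bin_size)
            arr[lo:hi] += value * (right - left)
        values[chrom] = arr
    if library_size <= 0:
        raise ParseError(f"{path}: track carries no signal (library size 0)")
    return SignalTrack(bin_size=bin_size, values=values, library_size=library_size)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph (per-base density = reads/bin_size)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            # run-length encode equal-density stretches
            if len(arr) == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s] / bs
                if v == 0.0:
                    continue
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{v:.10g}\n")


def _gene_from_span(
    gene_id: str, chrom: str, strand: str, start: int, end: int
) -> GeneModel:
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, chrom, strand, tss, GenomicInterval(chrom, start, end))


def read_tss_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3/GTF (``gene`` features) or a 4-column TSV.

    The TSV dialect has a header ``gene_id  chrom  strand  tss`` and carries
    the TSS directly; GFF/GTF coordinates are converted from 1-based
    inclusive to 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        genes: list[GeneModel] = []
        seen: set[str] = set()
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [feat.id]))[0]
            if gene_id in seen:
                raise ParseError(f"duplicate gene_id {gene_id!r} in {path}")
            seen.add(gene_id)
            if feat.strand not in {"+", "-"}:
                raise ParseError(f"gene {gene_id}: unknown strand {feat.strand!r}")
            genes.append(
                _gene_from_span(gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end)
            )
        return genes

    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 TSV columns")
            gene_id, chrom, strand, tss_s = fields[:4]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            tss = int(tss_s)
            # a TSS table carries no gene body; synthesize a 1 bp body at the TSS
            if strand == "+":
                genes.append(GeneModel(gene_id, chrom, strand, tss,
                                       GenomicInterval(chrom, tss, tss + 1)))
            else:
                genes.append(GeneModel(gene_id, chrom, strand, tss,
                                       GenomicInterval(chrom, tss, tss + 1)))
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an upper-cased ``{chrom: sequence}`` mapping."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: sequence {record.id} contains non-IUPAC-DNA "
                f"characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
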