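"""Domain types, coordinate conventions, interval algebra and file I/O.

All coordinates are 0-based half-open internally (BED convention):
an interval covers bases ``start .. end-1`` and its width is ``end - start``.
SNP positions in locus tables are 1-based on disk (VCF convention) and are
converted on read/write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    score : float, optional
        Free-form numeric payload (signal, -log10 q, ...).
    name : str, optional
        Feature label (4th BED column).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def expand(self, pad: int) -> "GenomicInterval":
        """Widen by ``pad`` bp on each side (clipped at 0)."""
        return GenomicInterval(
            self.chrom, max(0, self.start - pad), self.end + pad,
            self.strand, self.score, self.name,
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals; 0 if they overlap or abut,
        ``None`` on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class GenomeTable(dict):
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, lengths: dict[str, int]):
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        super().__init__(lengths)

    @property
    def total_length(self) -> int:
        return sum(self.values())

    def check(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom}")
        if interval.end > self[interval.chrom]:
            raise ValueError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self[interval.chrom]}"
            )


@dataclass(frozen=True)
class Gene:
    """A gene body with its transcription start site.

    The TSS is the 5' end of the gene body: ``interval.start`` on the +
    strand and ``interval.end - 1`` on the - strand.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class ReadSet:
    """Read evidence for one replicate of one condition, reduced to
    per-chromosome sorted midpoint positions."""

    condition: str
    replicate: str
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in self.positions.items()
        }

    @property
    def library_size(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with paired sample metadata.

    ``samples`` has one row per column of ``values`` with columns
    ``sample``, ``condition``, ``donor``; the paired design requires each
    donor to appear exactly once per condition.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["sample"]):
            raise ValueError("expression columns do not match sample table")
        counts = self.samples.groupby(["donor", "condition"]).size()
        if (counts != 1).any():
            raise ValueError("paired design requires one sample per donor per condition")

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    @property
    def donors(self) -> list:
        return list(pd.unique(self.samples["donor"]))

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Sub-matrix for one condition with columns ordered by donor."""
        meta = self.samples[self.samples["condition"] == condition]
        meta = meta.set_index("donor").loc[self.donors]
        return self.values[meta["sample"].tolist()]


class Coverage:
    """Piecewise-constant per-chromosome coverage (bedGraph semantics).

    Stored as parallel arrays of segment starts, ends and values; bases not
    covered by any segment have value 0.
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.segments = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping coverage segments on {chrom}")
            self.segments[chrom] = (starts, ends, values)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.segments:
            return 0.0
        starts, ends, values = self.segments[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def mean_over(self, interval: GenomicInterval) -> float:
        """Mean coverage over the interval (uncovered bases count as 0)."""
        if interval.chrom not in self.segments:
            return 0.0
        starts, ends, values = self.segments[interval.chrom]
        lo = np.clip(starts, interval.start, interval.end)
        hi = np.clip(ends, interval.start, interval.end)
        total = float(np.sum((hi - lo) * values))
        return total / interval.width


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``max_gap`` bp.

    ``max_gap=0`` merges overlapping and book-ended intervals only.  Output
    is sorted by (chrom, start); strand/score/name are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    merged: list[GenomicInterval] = []
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= max_gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def filter_by_width(
    intervals: Iterable[GenomicInterval],
    min_bp: int = 0,
    max_bp: float = math.inf,
) -> list[GenomicInterval]:
    """Keep intervals with ``min_bp <= width <= max_bp`` (bounds inclusive)."""
    if min_bp > max_bp:
        raise ValueError("min_bp must not exceed max_bp")
    return [iv for iv in intervals if min_bp <= iv.width <= max_bp]


NO_MATCH = ("", None)


def nearest_tss(
    interval: GenomicInterval, genes: Sequence[Gene]
) -> tuple[str, int | None]:
    """Nearest gene by |interval midpoint - TSS| on the same chromosome.

    Returns ``(gene_id, signed_distance)`` with distance = midpoint - TSS;
    ties by lexicographically smaller gene_id.  Returns the no-match
    sentinel ``("", None)`` if no gene shares the chromosome.
    """
    if not genes:
        raise ValueError("gene set is empty")
    mid = interval.midpoint
    best: tuple[int, str, int] | None = None
    for gene in genes:
        if gene.chrom != interval.chrom:
            continue
        dist = mid - gene.tss
        key = (abs(dist), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(dist), gene.gene_id, dist)
    if best is None:
        return NO_MATCH
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving input order."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, score, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else ".",
                    iv.strand,
                ]
            handle.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> Coverage:
    """Read a 4-column bedGraph into piecewise-constant coverage."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    return Coverage({
        chrom: (
            np.array([s for s, _, _ in rows]),
            np.array([e for _, e, _ in rows]),
            np.array([v for _, _, v in rows]),
        )
        for chrom, rows in per_chrom.items()
    })


def write_bedgraph(path: str | Path, coverage: Coverage) -> None:
    with open(path, "w") as handle:
        for chrom in coverage.segments:
            starts, ends, values = coverage.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                handle.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_gene_table(path: str | Path) -> list[Gene]:
    """TSV with columns gene_id, chrom, start, end, strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if missing := required - set(df.columns):
        raise FormatError(f"gene table missing columns: {sorted(missing)}")
    return [
        Gene(
            str(row.gene_id),
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            row.strand,
        )
        for row in df.itertuples()
    ]


def write_gene_table(path: str | Path, genes: Iterable[Gene]) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "start": g.interval.start,
            "end": g.interval.end, "strand": g.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GwasLocus:
    """A GWAS locus: index SNP plus high-LD proxies, positions 0-based.

    ``size`` (index + proxies) is the matching unit for the size-binned
    background in the permutation enrichment test.
    """

    trait: str
    locus_id: str
    index_snp: str
    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(self.positions)))
        if len(pos) != len(self.positions) or pos != tuple(self.positions):
            object.__setattr__(self, "positions", pos)
        if not self.positions:
            raise ValueError("locus needs >= 1 SNP position")

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.positions[0], self.positions[-1] + 1)


def read_locus_table(path: str | Path) -> list[GwasLocus]:
    """TSV: trait, locus_id, index_snp, chrom, positions (comma-separated,
    1-based on disk, converted to 0-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"trait", "locus_id", "index_snp", "chrom", "positions"}
    if missing := required - set(df.columns):
        raise FormatError(f"locus table missing columns: {sorted(missing)}")
    loci = []
    for row in df.itertuples():
        try:
            positions = tuple(int(p) - 1 for p in row.positions.split(","))
        except ValueError as exc:
            raise FormatError(f"malformed positions for locus {row.locus_id}") from exc
        if any(p < 0 for p in positions):
            raise FormatError(f"locus {row.locus_id}: positions must be 1-based >= 1")
        loci.append(GwasLocus(row.trait, row.locus_id, row.index_snp, row.chrom,
                              tuple(sorted(set(positions)))))
    return loci


def write_locus_table(path: str | Path, loci: Iterable[GwasLocus]) -> None:
    rows = [
        {
            "trait": l.trait, "locus_id": l.locus_id, "index_snp": l.index_snp,
            "chrom": l.chrom,
            "positions": ",".join(str(p + 1) for p in l.positions),
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with a 2-row header (condition, donor) over sample columns."""
    raw = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    samples = pd.DataFrame({
        "sample": [f"{c}:{d}" for c, d in raw.columns],
        "condition": [c for c, _ in raw.columns],
        "donor": [d for _, d in raw.columns],
    })
    values = raw.copy()
    values.columns = samples["sample"].tolist()
    return ExpressionMatrix(values, samples)


def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    out = expr.values.copy()
    out.columns = pd.MultiIndex.from_arrays(
        [expr.samples["condition"], expr.samples["donor"].astype(str)],
        names=["condition", "donor"],
    )
    out.to_csv(path, sep="\t")


def reads_from_bed(path: str | Path, condition: str, replicate: str) -> ReadSet:
    """Load read midpoints from a BED of read intervals (midpoint of each)."""
    positions: dict[str, list[int]] = {}
    for iv in read_bed(path):
        positions.setdefault(iv.chrom, []).append(iv.midpoint)
    return ReadSet(condition, replicate,
                   {c: np.array(p, dtype=np.int64) for c, p in positions.items()})


def coverage_from_reads(
    readsets: Sequence[ReadSet], genome: GenomeTable, bin_bp: int = 10,
    per_million: bool = True,
) -> Coverage:
    """Binned midpoint density pooled over read sets, as step coverage.

    Value = reads per bin, optionally scaled to reads-per-million so tracks
    from different library sizes are comparable.
    """
    total = sum(rs.library_size for rs in readsets)
    scale = 1e6 / total if (per_million and total) else 1.0
    segments = {}
    for chrom, length in genome.items():
        n_bins = -(-length // bin_bp)
        counts = np.zeros(n_bins)
        for rs in readsets:
            if chrom in rs.positions:
                idx = rs.positions[chrom] // bin_bp
                np.add.at(counts, idx, 1)
        starts = np.arange(n_bins, dtype=np.int64) * bin_bp
        ends = np.minimum(starts + bin_bp, length)
        keep = counts > 0
        segments[chrom] = (starts[keep], ends[keep], counts[keep] * scale)
    return Coverage(segments)
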