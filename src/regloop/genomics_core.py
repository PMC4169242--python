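"""Genomic coordinate model, interval algebra, and BED/GFF3 readers.

Every coordinate in this package is 0-based and half-open, ``[start, end)``.
BED files already use that convention and are read and written natively;
GFF3 is 1-based closed and is converted at the boundary (``start - 1, end``).
Strand is carried on gene models but ignored by all overlap arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "GenomeLayout",
    "GenomicInterval",
    "GeneModel",
    "PeakSet",
    "ChromCoverage",
    "merge_interval_arrays",
    "merge_intervals",
    "intersect_intervals",
    "complement_intervals",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "basepair_overlap",
    "directional_peak_overlap_counts",
]


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, defining the coordinate space.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs.  Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ValidationError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end {self.end} must exceed start {self.start} ({self.chrom})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span, strand and optional exon structure."""

    gene_id: str
    span: GenomicInterval
    strand: str = "+"
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValidationError(f"exon of {self.gene_id} on a different chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(f"exon outside the span of gene {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(f"exons of {self.gene_id} overlap or are unsorted")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.span.chrom


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, with overlapping/touching-at->0bp runs merged.

    Abutting intervals ([0,5) and [5,9)) are *not* merged — only intervals
    sharing at least one basepair are.  Names and scores are dropped on merge.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=_sort_key):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.name, iv.score))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval collections (union taken of each first)."""
    a_merged = merge_intervals(a)
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in a_merged:
        for other in by_chrom.get(iv.chrom, ()):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if e > s:
                out.append(GenomicInterval(iv.chrom, s, e))
    out.sort(key=_sort_key)
    return out


def complement_intervals(
    intervals: Iterable[GenomicInterval], genome: GenomeLayout
) -> list[GenomicInterval]:
    """Uncovered regions of the genome (complement of the union)."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in genome.names}
    for iv in merged:
        if iv.end > genome.length_of(iv.chrom):
            raise ValidationError(f"interval beyond {iv.chrom}")
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom, L in genome.chromosomes:
        pos = 0
        for iv in by_chrom[chrom]:
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < L:
            out.append(GenomicInterval(chrom, pos, L))
    return out


def merge_interval_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping intervals given as parallel arrays (one chromosome).

    Vectorised union used in resampling hot loops.  Returns sorted, disjoint
    ``(starts, ends)``.
    """
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    emax = np.maximum.accumulate(e)
    # a new merged run starts where this start is >= the running max end so far
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] >= emax[:-1]
    idx = np.flatnonzero(new_run)
    out_s = s[idx]
    out_e = emax[np.append(idx[1:] - 1, len(s) - 1)]
    return out_s, out_e


class ChromCoverage:
    """Prefix-sum coverage of a disjoint sorted interval set on one chromosome.

    Supports O(log n) queries for the number of covered basepairs below a
    coordinate, hence O(m log n) basepair-overlap against m query intervals.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])

    def covered_below(self, x: np.ndarray) -> np.ndarray:
        """Covered basepairs in [0, x) for each x (vectorised)."""
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(self.starts, x, side="right")
        base = self.cum[i]
        over = np.where(i > 0, np.clip(self.ends[np.maximum(i - 1, 0)] - x, 0, None), 0)
        return base - over

    def overlap_bp(self, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        """Basepairs of each query interval covered by the set."""
        return self.covered_below(qends) - self.covered_below(qstarts)


class PeakSet:
    """A sorted, internally disjoint set of genomic intervals with scores.

    The unit of peak calling and overlap statistics.  ``probe_counts``, when
    present, is aligned 1:1 with ``intervals`` and records how many array
    probes supported each peak.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        source_label: str = "",
        probe_counts: Sequence[int] | None = None,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.source_label = source_label
        self.probe_counts: list[int] | None = list(probe_counts) if probe_counts is not None else None
        if self.probe_counts is not None and len(self.probe_counts) != len(self.intervals):
            raise ValidationError("probe_counts not aligned with intervals")
        prev: GenomicInterval | None = None
        seen_after: dict[str, GenomicInterval] = {}
        for iv in self.intervals:
            if prev is not None and (prev.chrom, prev.start, prev.end) > (iv.chrom, iv.start, iv.end):
                raise ValidationError("intervals not sorted by (chrom, start)")
            last = seen_after.get(iv.chrom)
            if last is not None and iv.start < last.end:
                raise ValidationError(
                    f"overlapping intervals within the set on {iv.chrom}: "
                    f"[{last.start},{last.end}) and [{iv.start},{iv.end})"
                )
            seen_after[iv.chrom] = iv
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [
            (i.chrom, i.start, i.end) for i in self.intervals
        ] == [(i.chrom, i.start, i.end) for i in other.intervals]

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def chroms(self) -> list[str]:
        out: list[str] = []
        for iv in self.intervals:
            if not out or out[-1] != iv.chrom:
                out.append(iv.chrom)
        return out

    def arrays_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` int64 arrays, sorted."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chroms():
            ivs = [iv for iv in self.intervals if iv.chrom == chrom]
            out[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return out

    def validate_against(self, genome: GenomeLayout) -> None:
        for iv in self.intervals:
            if iv.end > genome.length_of(iv.chrom):
                raise ValidationError(
                    f"interval [{iv.start},{iv.end}) exceeds {iv.chrom} "
                    f"length {genome.length_of(iv.chrom)}"
                )


# ---------------------------------------------------------------------------
# File formats


def read_bed(path: str | Path, source_label: str | None = None) -> PeakSet:
    """Read a 3-6 column BED file into a :class:`PeakSet`.

    Overlapping input intervals are merged (with a logged warning) because a
    PeakSet is disjoint by construction.  Malformed lines raise
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    raw: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start or start < 0:
                raise ValidationError(f"{path}:{lineno}: invalid interval [{start},{end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
            raw.append(GenomicInterval(chrom, start, end, name=name, score=score))
    raw.sort(key=_sort_key)
    merged: list[GenomicInterval] = []
    warned = False
    for iv in raw:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if not warned:
                logger.warning("%s: overlapping intervals merged on read", path)
                warned = True
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), last.name, last.score
            )
        else:
            merged.append(iv)
    return PeakSet(merged, source_label=source_label if source_label is not None else path.stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED (0-based half-open, natively)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name if iv.name is not None else f"peak_{i + 1}"
            if iv.score is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:.6g}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene (and child exon) features from GFF3 into gene models.

    GFF3 coordinates are 1-based closed and are converted to the internal
    0-based half-open convention.  A gene feature without an ID attribute is
    a validation error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if "ID" not in g.attributes:
            raise ValidationError(f"gene feature at {g.seqid}:{g.start} lacks an ID attribute")
        span = GenomicInterval(g.seqid, g.start - 1, g.end)
        exons = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        )
        strand = g.strand if g.strand in ("+", "-") else "+"
        genes.append(GeneModel(g.attributes["ID"][0], span, strand, exons))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (converting to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tregloop\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for k, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tregloop\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.e{k};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Overlap arithmetic


def basepair_overlap(a: PeakSet, b: PeakSet) -> int:
    """Total basepairs in the intersection of two disjoint peak sets.

    Symmetric in its arguments; ``basepair_overlap(a, a)`` equals the total
    length of ``a``.
    """
    a_arrays = a.arrays_by_chrom()
    total = 0
    for chrom, (bs, be) in b.arrays_by_chrom().items():
        if chrom not in a_arrays:
            continue
        cov = ChromCoverage(*a_arrays[chrom])
        total += int(cov.overlap_bp(bs, be).sum())
    return total


def directional_peak_overlap_counts(a: PeakSet, b: PeakSet) -> tuple[int, int, float]:
    """Counts of peaks in each set touching (>=1 bp) the other, plus the mean.

    Because peak lengths differ between factors, one peak in one set can
    overlap several in the other; the two directional counts therefore differ
    and their average is reported alongside.
    """

    def _count(x: PeakSet, y: PeakSet) -> int:
        y_arrays = y.arrays_by_chrom()
        n = 0
        for chrom, (xs, xe) in x.arrays_by_chrom().items():
            if chrom not in y_arrays:
                continue
            cov = ChromCoverage(*y_arrays[chrom])
            n += int((cov.overlap_bp(xs, xe) > 0).sum())
        return n

    count_a = _count(a, b)
    count_b = _count(b, a)
    return count_a, count_b, (count_a + count_b) / 2.0
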