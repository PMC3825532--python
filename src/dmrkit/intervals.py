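"""Genomic interval primitives.

All coordinates in the package are 0-based, half-open (BED convention).
Conversion to/from 1-based dialects happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree


class GenomicInterval(NamedTuple):
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Overlap of at least 1 bp (book-ended intervals do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure.

    ``start < end`` always; the transcription start site is ``start`` on the
    plus strand and ``end - 1`` (the last covered base) on the minus strand.
    Exons are non-overlapping, ordered by coordinate, and cover >= 1 exon.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.name}: needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.name}: exon ({s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or are unordered")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def tss_interval(self) -> GenomicInterval:
        """TSS as a 1 bp interval for overlap purposes."""
        return GenomicInterval(self.chrom, self.tss, self.tss + 1)

    def promoter(self, upstream: int = 3000, chrom_length: int | None = None) -> GenomicInterval:
        """Strand-aware promoter: ``upstream`` bp immediately 5' of the TSS."""
        if self.strand == "+":
            start, end = max(0, self.start - upstream), self.start
        else:
            start, end = self.end, self.end + upstream
            if chrom_length is not None:
                end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end)

    def introns(self) -> list[GenomicInterval]:
        """Gene body minus exons."""
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append(GenomicInterval(self.chrom, prev, s))
            prev = e
        if self.end > prev:
            out.append(GenomicInterval(self.chrom, prev, self.end))
        return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Fuse overlapping or book-ended intervals per chromosome.

    Output is sorted (chrom, start) and disjoint with gaps >= 1 bp, matching
    ``bedtools merge`` defaults. Idempotent and order-independent.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        if iv.start > iv.end:
            raise ValueError(f"invalid interval: start {iv.start} > end {iv.end}")
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def build_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if iv.length <= 0:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def any_overlap(iv: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
    """True if ``iv`` shares >= 1 bp with any interval in ``trees``."""
    tree = trees.get(iv.chrom)
    if tree is None or iv.length <= 0:
        return False
    return bool(tree.overlap(iv.start, iv.end))


def complement(intervals: Iterable[GenomicInterval],
               chrom_lengths: dict[str, int]) -> list[GenomicInterval]:
    """Complement of the union of ``intervals`` over the given chromosomes."""
    merged = merge_intervals(
        GenomicInterval(iv.chrom, max(0, iv.start), min(iv.end, chrom_lengths[iv.chrom]))
        for iv in intervals if iv.chrom in chrom_lengths
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom, length in sorted(chrom_lengths.items()):
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            out.append(GenomicInterval(chrom, pos, length))
    return out
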