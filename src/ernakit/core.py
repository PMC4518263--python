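"""Coordinate conventions, interval arithmetic and sequence utilities.

Every coordinate in the package is 0-based half-open (BED-native):
``start`` is the first covered base, ``end`` one past the last.  Inputs in
1-based dialects must be converted at the reader boundary.  Sequences are
stored in the DNA alphabet; ``U`` is normalised to ``T`` on entry.
"""

from __future__ import annotations

import math
import re

import numpy as np
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Enhancer",
    "overlaps",
    "interval_gap",
    "distance_to_nearest_gene_boundary",
    "subtract_intervals",
    "merge_intervals",
    "intergenic_segments",
    "reverse_complement",
    "GeneIndex",
]

#: strand sentinel for unstranded features
UNSTRANDED = "."

_VALID_STRANDS = frozenset({"+", "-", UNSTRANDED})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    @property
    def region_id(self) -> str:
        """Coordinate-derived identifier used to key expression tables."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene (RefSeq-style transcript span) with optional coding end.

    ``coding_end`` is the strand-aware end of the coding region in genomic
    coordinates; ``None`` marks a noncoding gene.  The 3'UTR runs from the
    coding end to the transcript end on the transcript's strand.
    """

    gene_id: str
    interval: GenomicInterval
    coding_end: int | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene models must be stranded")
        if self.coding_end is not None and not (
            self.interval.start <= self.coding_end <= self.interval.end
        ):
            raise ValueError(
                f"coding_end {self.coding_end} outside transcript "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (genomic coordinate)."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Enhancer:
    """An enhancer locus in one tissue with its target gene set."""

    enhancer_id: str
    interval: GenomicInterval
    tissue: str
    target_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_gene_ids", frozenset(self.target_gene_ids))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals on the same chromosome; 0 if they
    overlap or abut; ``inf`` on different chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def _boundary_distance(iv: GenomicInterval, coord: int) -> int:
    if coord >= iv.end:
        return coord - iv.end
    if coord <= iv.start:
        return iv.start - coord
    return 0


def distance_to_nearest_gene_boundary(
    iv: GenomicInterval, genes: Iterable[GeneModel]
) -> float:
    """Minimum gap between ``iv`` and any transcript boundary (start or end)
    of a gene on the same chromosome.

    Returns 0 when ``iv`` overlaps a gene and ``inf`` when the chromosome
    carries no gene.  Boundaries are transcript spans, not CDS.
    """
    best = math.inf
    for gene in genes:
        if gene.chrom != iv.chrom:
            continue
        if overlaps(iv, gene.interval):
            return 0
        d = min(
            _boundary_distance(iv, gene.interval.start),
            _boundary_distance(iv, gene.interval.end),
        )
        best = min(best, d)
    return best


def merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand dropped)."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    region: GenomicInterval, cutters: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Ordered disjoint sub-intervals of ``region`` not covered by any cutter.

    Conserves bases: ``|region| == sum(|result|) + |region ∩ union(cutters)|``.
    """
    covered = [
        c for c in merge_intervals(cutters)
        if c.chrom == region.chrom and c.start < region.end and c.end > region.start
    ]
    out: list[GenomicInterval] = []
    cursor = region.start
    for c in covered:
        if c.start > cursor:
            out.append(GenomicInterval(region.chrom, cursor, c.start, region.strand))
        cursor = max(cursor, c.end)
    if cursor < region.end:
        out.append(GenomicInterval(region.chrom, cursor, region.end, region.strand))
    return out


def intergenic_segments(
    chrom_sizes: dict[str, int],
    genes: Iterable[GeneModel],
    margin: int = 0,
) -> list[GenomicInterval]:
    """Chromosome space not covered by any gene span padded by ``margin`` bp.

    With ``margin=3000`` this is the space in which intergenic enhancers and
    length-matched random controls are allowed to live.
    """
    padded: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        if size is None:
            continue
        lo = max(0, g.interval.start - margin)
        hi = min(size, g.interval.end + margin)
        if hi > lo:
            padded[g.chrom].append(GenomicInterval(g.chrom, lo, hi))
    out: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        whole = GenomicInterval(chrom, 0, size)
        out.extend(subtract_intervals(whole, padded[chrom]))
    return out


class GeneIndex:
    """Sorted-array index over gene transcript spans for fast queries.

    Supports overlap tests and minimum boundary-gap queries per chromosome
    without scanning the full gene list.
    """

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.genes = list(genes)
        self._starts: dict[str, "np.ndarray"] = {}
        self._ends: dict[str, "np.ndarray"] = {}
        self._bounds: dict[str, "np.ndarray"] = {}
        self._maxend: dict[str, "np.ndarray"] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            gs.sort(key=lambda g: (g.interval.start, g.interval.end))
            starts = np.array([g.interval.start for g in gs])
            ends = np.array([g.interval.end for g in gs])
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            # running max of ends handles nested/overlapping gene spans
            self._maxend[chrom] = np.maximum.accumulate(ends)
            self._bounds[chrom] = np.sort(np.concatenate([starts, ends]))

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and bool(self._maxend[iv.chrom][i - 1] > iv.start)

    def min_boundary_gap(self, iv: GenomicInterval) -> float:
        """Gap to the nearest transcript boundary; 0 when overlapping a
        gene; inf on a gene-free chromosome."""
        bounds = self._bounds.get(iv.chrom)
        if bounds is None:
            return math.inf
        if self.overlaps_any(iv):
            return 0
        i = int(np.searchsorted(bounds, iv.start))
        best = math.inf
        if i < bounds.size:
            best = min(best, _boundary_distance(iv, int(bounds[i])))
        if i > 0:
            best = min(best, _boundary_distance(iv, int(bounds[i - 1])))
        # a boundary inside [start, end) gives gap 0 via the overlap branch
        j = int(np.searchsorted(bounds, iv.end - 1, side="right"))
        if j > i:
            return 0
        return best


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"^[ACGTUNacgtun]*$")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``; validate the alphabet."""
    if not _VALID_SEQ.match(seq):
        for i, ch in enumerate(seq):
            if ch.upper() not in "ACGTUN":
                raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA).

    ``U`` is treated as ``T``; ``N`` is self-complementary.  Applying the
    function twice returns the (normalised) input.
    """
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]
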