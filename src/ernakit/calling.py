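"""Enhancer transcription-state calling from RNA-seq contigs.

An intergenic enhancer is *transcribing* (state ``eRNA``) in a tissue when
some strand-aware RNA contig starts — at its 5' end — within a window
extending ``window`` bp on both sides of the enhancer locus.  Contigs that
overlap any annotated gene, and enhancers closer than ``margin`` bp to any
gene transcript boundary, are excluded first so that gene-derived
transcription is never mistaken for enhancer transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Enhancer, GeneIndex, GeneModel, GenomicInterval

__all__ = [
    "RnaContig",
    "ErnaCall",
    "five_prime_start",
    "filter_intergenic_enhancers",
    "filter_gene_overlapping_contigs",
    "call_state",
    "call_states",
    "state_proportions",
]

ERNA = "eRNA"
NO_ERNA = "no-eRNA"


@dataclass(frozen=True)
class RnaContig:
    """A strand-aware RNA-seq contig with its BPKM expression level."""

    interval: GenomicInterval
    bpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.bpkm < 0:
            raise ValueError("bpkm must be >= 0")


@dataclass(frozen=True)
class ErnaCall:
    """State of one enhancer in one tissue.

    ``contig`` is the attached eRNA (highest BPKM among qualifying contigs)
    and is present iff ``state == "eRNA"``; ``qualifying`` retains every
    contig whose 5' start fell in the window.
    """

    enhancer_id: str
    tissue: str
    state: str
    contig: RnaContig | None = None
    qualifying: tuple[RnaContig, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in (ERNA, NO_ERNA):
            raise ValueError(f"invalid state {self.state!r}")
        if (self.state == ERNA) != (self.contig is not None):
            raise ValueError("state 'eRNA' requires an attached contig and vice versa")


def five_prime_start(contig: RnaContig) -> int:
    """Genomic coordinate of the contig's transcript start (5' end).

    ``start`` on the plus strand; the last covered base ``end - 1`` on the
    minus strand.  Unstranded contigs have no defined 5' end.
    """
    strand = contig.interval.strand
    if strand == "+":
        return contig.interval.start
    if strand == "-":
        return contig.interval.end - 1
    raise ValueError("5' end undefined for unstranded contig")


def filter_intergenic_enhancers(
    enhancers: Iterable[Enhancer],
    genes: Sequence[GeneModel] | GeneIndex,
    margin: int = 3000,
) -> list[Enhancer]:
    """Keep enhancers >= ``margin`` bp from every gene transcript boundary
    and overlapping no gene."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [e for e in enhancers if index.min_boundary_gap(e.interval) >= margin]


def filter_gene_overlapping_contigs(
    contigs: Iterable[RnaContig], genes: Sequence[GeneModel] | GeneIndex
) -> list[RnaContig]:
    """Drop contigs overlapping any gene transcript span."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [c for c in contigs if not index.overlaps_any(c.interval)]


def _window(enhancer: Enhancer, window: int) -> tuple[int, int]:
    # half-open [start - w, end + w)
    return enhancer.interval.start - window, enhancer.interval.end + window


def call_state(
    enhancer: Enhancer,
    contigs: Sequence[RnaContig],
    window: int = 3000,
) -> ErnaCall:
    """Call one enhancer's transcription state.

    State is ``eRNA`` iff some contig's 5' start lies in the half-open
    window ``[start - window, end + window)`` on the enhancer's chromosome.
    Among qualifying contigs the one with the highest BPKM is attached
    (ties broken by leftmost 5' start, then plus strand first).
    """
    lo, hi = _window(enhancer, window)
    chrom = enhancer.interval.chrom
    qual = [
        c
        for c in contigs
        if c.interval.chrom == chrom and lo <= five_prime_start(c) < hi
    ]
    if not qual:
        return ErnaCall(enhancer.enhancer_id, enhancer.tissue, NO_ERNA)
    qual.sort(key=lambda c: (-c.bpkm, five_prime_start(c), c.interval.strand != "+"))
    return ErnaCall(
        enhancer.enhancer_id,
        enhancer.tissue,
        ERNA,
        contig=qual[0],
        qualifying=tuple(qual),
    )


def call_states(
    enhancers: Sequence[Enhancer],
    contigs: Sequence[RnaContig],
    genes: Sequence[GeneModel] | GeneIndex,
    window: int = 3000,
    margin: int = 3000,
    prefiltered: bool = False,
) -> list[ErnaCall]:
    """Filter and call every enhancer of one tissue.

    Applies the intergenic-enhancer and gene-overlap filters (unless
    ``prefiltered``), then calls states against the surviving contigs.
    """
    if not prefiltered:
        index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
        enhancers = filter_intergenic_enhancers(enhancers, index, margin=margin)
        contigs = filter_gene_overlapping_contigs(contigs, index)
    # index contig 5' starts per chromosome for fast window queries
    by_chrom: dict[str, tuple[np.ndarray, list[RnaContig]]] = {}
    for chrom in {c.interval.chrom for c in contigs}:
        sub = [c for c in contigs if c.interval.chrom == chrom]
        starts = np.array([five_prime_start(c) for c in sub])
        order = np.argsort(starts, kind="stable")
        by_chrom[chrom] = (starts[order], [sub[i] for i in order])
    calls = []
    for enh in enhancers:
        entry = by_chrom.get(enh.interval.chrom)
        if entry is None:
            calls.append(ErnaCall(enh.enhancer_id, enh.tissue, NO_ERNA))
            continue
        starts, sub = entry
        lo, hi = _window(enh, window)
        i, j = np.searchsorted(starts, [lo, hi])
        calls.append(call_state(enh, sub[i:j], window=window))
    return calls


def state_proportions(calls: Iterable[ErnaCall]) -> pd.DataFrame:
    """Per-tissue counts of transcribing / non-transcribing enhancers.

    Returns a frame indexed by tissue with columns ``n_eRNA``,
    ``n_no_eRNA`` and ``fraction_eRNA``; tissues with no calls are absent.
    """
    rows: dict[str, list[int]] = {}
    for call in calls:
        n = rows.setdefault(call.tissue, [0, 0])
        n[0 if call.state == ERNA else 1] += 1
    df = pd.DataFrame(
        [
            {
                "tissue": t,
                "n_eRNA": a,
                "n_no_eRNA": b,
                "fraction_eRNA": a / (a + b),
            }
            for t, (a, b) in sorted(rows.items())
        ]
    )
    return df.set_index("tissue") if len(df) else df
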