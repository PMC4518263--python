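"""eRNA–target-gene expression correlation with matched backgrounds.

Expression is measured as BPKM (bases per kilobase of region per million
mapped bases).  For every transcribing enhancer the eRNA's BPKM is paired
with the BPKM of a target-gene region matched in length to the eRNA, with
1-kb flanking bins outside the calling window, and with two negative
backgrounds (upstream of random non-target genes; random intergenic
intervals).  Pearson correlation per region class gives the profile in
which genuine eRNA–target coupling must exceed every background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ERNA, ErnaCall, RnaContig
from .core import Enhancer, GeneIndex, GeneModel, GenomicInterval, intergenic_segments

__all__ = [
    "BpkmTable",
    "CorrelationResult",
    "bpkm",
    "matched_gene_region",
    "flanking_regions",
    "pearson",
    "background_regions",
    "correlation_profile",
    "REGION_CLASSES",
]

FLANK_LABELS = ("flank_0_1k", "flank_1_2k", "flank_2_3k")
REGION_CLASSES = ("target_gene",) + FLANK_LABELS + ("gene_upstream", "random_intergenic")


def bpkm(covered_bases: float, region_length: int, total_mapped_bases: float) -> float:
    """Bases per kilobase of region per million mapped bases.

    ``covered / (length/1e3) / (library/1e6)``.
    """
    if region_length <= 0:
        raise ValueError("region_length must be > 0")
    if total_mapped_bases <= 0:
        raise ValueError("total_mapped_bases must be > 0")
    if covered_bases < 0:
        raise ValueError("covered_bases must be >= 0")
    return covered_bases / (region_length / 1e3) / (total_mapped_bases / 1e6)


class BpkmTable:
    """Per-region, per-tissue BPKM values.

    Rows are keyed by ``(region_id, tissue)`` where ``region_id`` is either
    a coordinate id ``chrom:start-end`` or a gene id.  ``total_mapped_bases``
    records each tissue's library size in bases.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        total_mapped_bases: Mapping[str, float] | None = None,
    ) -> None:
        required = {"region_id", "tissue", "bpkm"}
        if not required.issubset(frame.columns):
            raise ValueError(f"BPKM frame needs columns {sorted(required)}")
        if (frame["bpkm"] < 0).any():
            raise ValueError("BPKM values must be >= 0")
        self.frame = frame.reset_index(drop=True)
        self.total_mapped_bases = dict(total_mapped_bases or {})
        for t, v in self.total_mapped_bases.items():
            if v <= 0:
                raise ValueError(f"total_mapped_bases must be > 0 (tissue {t})")
        self._index: dict[tuple[str, str], float] = {
            (r, t): b
            for r, t, b in zip(frame["region_id"], frame["tissue"], frame["bpkm"])
        }

    def get(self, region_id: str, tissue: str) -> float | None:
        return self._index.get((region_id, tissue))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of eRNA expression against one region class."""

    tissue: str
    label: str
    n: int
    r: float
    p: float

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.r) or np.isnan(self.p))


def matched_gene_region(gene: GeneModel, erna_length: int) -> GenomicInterval:
    """Target-gene region starting at the strand-aware TSS and spanning the
    paired eRNA's length (truncated at the transcript end)."""
    if erna_length <= 0:
        raise ValueError("erna_length must be > 0")
    iv = gene.interval
    length = min(erna_length, iv.length)
    if gene.strand == "+":
        return GenomicInterval(iv.chrom, iv.start, iv.start + length, "+")
    return GenomicInterval(iv.chrom, iv.end - length, iv.end, "-")


def flanking_regions(
    enhancer: Enhancer,
    erna: RnaContig,
    genes: Sequence[GeneModel] | GeneIndex = (),
    window: int = 3000,
    bin_size: int = 1000,
) -> list[tuple[str, str, GenomicInterval]]:
    """Up to six 1-kb flanking bins as ``(label, side, interval)``.

    On each side three bins start at the boundary of the calling window —
    or at the eRNA's far end when the eRNA extends past that boundary — and
    step away from the enhancer.  Bins overlapping any gene are discarded.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    chrom = enhancer.interval.chrom
    down_boundary = max(enhancer.interval.end + window, erna.interval.end)
    up_boundary = min(enhancer.interval.start - window, erna.interval.start)
    out: list[tuple[str, str, GenomicInterval]] = []
    for k, label in enumerate(FLANK_LABELS):
        down = GenomicInterval(
            chrom, down_boundary + k * bin_size, down_boundary + (k + 1) * bin_size
        )
        up_end = up_boundary - k * bin_size
        candidates = [("down", down)]
        if up_end - bin_size >= 0:
            candidates.append(("up", GenomicInterval(chrom, up_end - bin_size, up_end)))
        for side, iv in candidates:
            if not index.overlaps_any(iv):
                out.append((label, side, iv))
    return out


def pearson(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """Sample Pearson r with a p-value from the t-transform (df = n - 2).

    The default alternative tests for positive correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _sample_from_segments(
    segments: Sequence[GenomicInterval], length: int, rng: np.random.Generator
) -> GenomicInterval | None:
    """Uniform placement of a ``length``-bp interval inside the segments."""
    fits = [s for s in segments if s.length >= length]
    if not fits:
        return None
    weights = np.array([s.length - length + 1 for s in fits], dtype=float)
    seg = fits[rng.choice(len(fits), p=weights / weights.sum())]
    start = int(seg.start + rng.integers(0, seg.length - length + 1))
    return GenomicInterval(seg.chrom, start, start + length)


def background_regions(
    calls: Sequence[tuple[ErnaCall, Enhancer, GeneModel]],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    rng_seed: int,
    margin: int = 3000,
) -> pd.DataFrame:
    """Deterministically sampled background regions for each eRNA–gene pair.

    Two classes per pair: ``gene_upstream`` — an interval of the eRNA's
    length immediately 5' of a random non-target gene's TSS — and
    ``random_intergenic`` — a length-matched interval sampled uniformly
    from intergenic space (same ``margin`` as enhancer filtering).  Pairs
    are processed in sorted (tissue, enhancer, gene) order so a fixed seed
    reproduces the same regions.
    """
    rng = np.random.default_rng(rng_seed)
    segments = intergenic_segments(dict(chrom_sizes), genes, margin=margin)
    ordered = sorted(calls, key=lambda t: (t[0].tissue, t[0].enhancer_id, t[2].gene_id))
    rows = []
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    for call, enhancer, gene in ordered:
        if call.state != ERNA or call.contig is None:
            continue
        length = call.contig.interval.length
        g = None
        if len(gene_list) > len(enhancer.target_gene_ids):
            while True:
                g = gene_list[int(rng.integers(0, len(gene_list)))]
                if g.gene_id not in enhancer.target_gene_ids:
                    break
        if g is not None:
            if g.strand == "+":
                start, end = g.tss - length, g.tss
            else:
                start, end = g.tss, g.tss + length
            if start >= 0 and end <= chrom_sizes.get(g.chrom, np.inf):
                rows.append(
                    (call.tissue, call.enhancer_id, gene.gene_id, "gene_upstream",
                     g.chrom, start, end)
                )
        iv = _sample_from_segments(segments, length, rng)
        if iv is not None:
            rows.append(
                (call.tissue, call.enhancer_id, gene.gene_id, "random_intergenic",
                 iv.chrom, iv.start, iv.end)
            )
    return pd.DataFrame(
        rows,
        columns=["tissue", "enhancer_id", "gene_id", "label", "chrom", "start", "end"],
    )


def _pairs_to_result(tissue: str, label: str, pairs: list[tuple[float, float]]) -> CorrelationResult:
    if len(pairs) < 3:
        return CorrelationResult(tissue, label, len(pairs), float("nan"), float("nan"))
    x, y = zip(*pairs)
    try:
        r, p = pearson(x, y)
    except ValueError:
        return CorrelationResult(tissue, label, len(pairs), float("nan"), float("nan"))
    return CorrelationResult(tissue, label, len(pairs), r, p)


def correlation_profile(
    calls: Sequence[ErnaCall],
    enhancers: Mapping[tuple[str, str], Enhancer],
    genes: Sequence[GeneModel],
    table: BpkmTable,
    chrom_sizes: Mapping[str, int],
    rng_seed: int = 0,
    window: int = 3000,
    classes: Sequence[str] = REGION_CLASSES,
) -> list[CorrelationResult]:
    """One Pearson correlation per region class per tissue.

    For every transcribing enhancer and each of its target genes, the eRNA
    BPKM is paired with the BPKM of the class's region; pairs whose region
    has no expression entry are dropped listwise within the class.
    ``enhancers`` maps ``(tissue, enhancer_id)`` to the enhancer record.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    triples: list[tuple[ErnaCall, Enhancer, GeneModel]] = []
    for call in calls:
        if call.state != ERNA:
            continue
        enh = enhancers[(call.tissue, call.enhancer_id)]
        for gid in sorted(enh.target_gene_ids):
            gene = gene_by_id.get(gid)
            if gene is not None:
                triples.append((call, enh, gene))

    bg = None
    if "gene_upstream" in classes or "random_intergenic" in classes:
        bg = background_regions(triples, genes, chrom_sizes, rng_seed=rng_seed)
        bg_idx = {
            (t, e, g, lab): GenomicInterval(c, s, en)
            for t, e, g, lab, c, s, en in bg.itertuples(index=False)
        }

    gene_index = GeneIndex(genes)
    pairs: dict[tuple[str, str], list[tuple[float, float]]] = {}
    flank_wanted = [c for c in classes if c in FLANK_LABELS]
    seen_flank: set[tuple[str, str]] = set()
    for call, enh, gene in triples:
        tissue = call.tissue
        erna_val = table.get(call.contig.interval.region_id, tissue)
        if erna_val is None:
            continue
        if flank_wanted and (tissue, call.enhancer_id) not in seen_flank:
            # flank bins belong to the enhancer, not the (enhancer, gene) pair
            seen_flank.add((tissue, call.enhancer_id))
            for lab, _side, iv in flanking_regions(
                enh, call.contig, gene_index, window=window
            ):
                if lab not in flank_wanted:
                    continue
                val = table.get(iv.region_id, tissue)
                if val is not None:
                    pairs.setdefault((tissue, lab), []).append((erna_val, val))
        for label in classes:
            if label == "target_gene":
                region = matched_gene_region(gene, call.contig.interval.length)
                val = table.get(region.region_id, tissue)
            elif label in FLANK_LABELS:
                continue
            else:
                iv = bg_idx.get((tissue, call.enhancer_id, gene.gene_id, label))
                val = table.get(iv.region_id, tissue) if iv is not None else None
            if val is not None:
                pairs.setdefault((tissue, label), []).append((erna_val, val))

    tissues = sorted({c.tissue for c in calls})
    return [
        _pairs_to_result(tissue, label, pairs.get((tissue, label), []))
        for tissue in tissues
        for label in classes
    ]
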