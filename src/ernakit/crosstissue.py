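"""Cross-tissue comparison of target-gene expression by enhancer state.

Enhancers from different tissues that sit at the same genomic position
(midpoints linked at <= 1 kb) and target the same gene are grouped; groups
containing both a transcribing and a non-transcribing member isolate the
presence of the eRNA as the only varying factor.  Target-gene expression is
standardised to per-tissue z-scores and compared with a paired t-test
(within groups) and a one-sided Wilcoxon rank-sum test (pooled per tissue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ERNA, NO_ERNA, ErnaCall
from .core import Enhancer, GenomicInterval

__all__ = [
    "EnhancerGroup",
    "TestResult",
    "build_groups",
    "validate_group",
    "zscore_by_tissue",
    "group_paired_means",
    "paired_t_test",
    "rank_sum_test",
    "least_rectangles_line",
    "compare_state_expression",
]


@dataclass(frozen=True)
class EnhancerGroup:
    """Same-positioned enhancers across tissues sharing a target gene.

    ``members`` are ``(tissue, enhancer_id, state)`` triples; ``anchor`` is
    the span from the leftmost to the rightmost member midpoint.
    """

    gene_id: str
    members: tuple[tuple[str, str, str], ...]
    anchor: GenomicInterval

    @property
    def states(self) -> set[str]:
        return {state for _, _, state in self.members}

    @property
    def enhancer_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((t, e) for t, e, _ in self.members)


def validate_group(
    group: EnhancerGroup,
    enhancers: Mapping[tuple[str, str], Enhancer],
    window: int = 1000,
) -> bool:
    """Construction-independent check of the grouping contract.

    Members must all target ``gene_id``, carry both states, and be
    single-linkage connected at <= ``window`` bp between midpoints.
    """
    if not ({ERNA, NO_ERNA} <= group.states):
        return False
    mids = []
    for tissue, enh_id, _state in group.members:
        enh = enhancers[(tissue, enh_id)]
        if group.gene_id not in enh.target_gene_ids:
            return False
        mids.append(enh.interval.midpoint)
    mids.sort()
    return all(b - a <= window for a, b in zip(mids, mids[1:]))


def _candidate_groups(
    enhancers: Sequence[Enhancer],
    states: Mapping[tuple[str, str], str],
    window: int,
) -> list[EnhancerGroup]:
    """Single-linkage clusters of midpoints per target gene, keeping only
    clusters that contain both states."""
    per_gene: dict[str, list[Enhancer]] = {}
    for enh in enhancers:
        for gid in enh.target_gene_ids:
            per_gene.setdefault(gid, []).append(enh)
    groups = []
    for gid in sorted(per_gene):
        members = sorted(
            per_gene[gid], key=lambda e: (e.interval.chrom, e.interval.midpoint, e.tissue, e.enhancer_id)
        )
        cluster: list[Enhancer] = []
        chunks: list[list[Enhancer]] = []
        for enh in members:
            if cluster and (
                enh.interval.chrom != cluster[-1].interval.chrom
                or enh.interval.midpoint - cluster[-1].interval.midpoint > window
            ):
                chunks.append(cluster)
                cluster = []
            cluster.append(enh)
        if cluster:
            chunks.append(cluster)
        for chunk in chunks:
            triples = tuple(
                (e.tissue, e.enhancer_id, states[(e.tissue, e.enhancer_id)])
                for e in chunk
            )
            st = {s for _, _, s in triples}
            if not ({ERNA, NO_ERNA} <= st):
                continue
            mids = [e.interval.midpoint for e in chunk]
            anchor = GenomicInterval(
                chunk[0].interval.chrom,
                int(min(mids)),
                int(max(mids)) + 1,
            )
            groups.append(EnhancerGroup(gid, triples, anchor))
    return groups


def build_groups(
    enhancers: Sequence[Enhancer],
    calls: Sequence[ErnaCall],
    window: int = 1000,
    rng_seed: int = 0,
) -> list[EnhancerGroup]:
    """Group same-positioned enhancers across tissues.

    Candidate groups are single-linkage clusters (midpoint distance <=
    ``window``) of all tissues' enhancers targeting one gene, restricted to
    clusters with at least one transcribing and one non-transcribing
    member.  Where surviving groups share an enhancer (a multi-target
    enhancer appears in several genes' groups), the largest is kept, ties
    broken by a seeded uniform choice; fully disjoint groups all survive.
    """
    states = {(c.tissue, c.enhancer_id): c.state for c in calls}
    candidates = _candidate_groups(enhancers, states, window)
    rng = np.random.default_rng(rng_seed)
    tiebreak = rng.permutation(len(candidates))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-len(candidates[i].members), tiebreak[i]),
    )
    kept: list[EnhancerGroup] = []
    used: set[tuple[str, str]] = set()
    for i in order:
        g = candidates[i]
        if used & g.enhancer_keys:
            continue
        kept.append(g)
        used |= g.enhancer_keys
    kept.sort(key=lambda g: (g.anchor.chrom, g.anchor.start, g.gene_id))
    return kept


def zscore_by_tissue(gene_bpkm: pd.DataFrame) -> pd.DataFrame:
    """Standardise BPKM to z-scores within each tissue.

    Input columns: ``gene_id``, ``tissue``, ``bpkm``.  Uses the sample
    (n-1) standard deviation; a tissue with fewer than two distinct values
    has no defined z-score and raises.
    """
    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("z-score undefined: constant or singleton tissue vector")
        return (x - x.mean()) / sd

    out = gene_bpkm.copy()
    out["z"] = gene_bpkm.groupby("tissue")["bpkm"].transform(_z)
    return out


def group_paired_means(
    group: EnhancerGroup, z: Mapping[tuple[str, str], float]
) -> tuple[float, float]:
    """Mean target-gene z-score over member tissues, split by state.

    ``z`` maps ``(gene_id, tissue)`` to the tissue-standardised expression
    of the gene.  Returns ``(mean_z_eRNA, mean_z_no_eRNA)``.
    """
    by_state: dict[str, list[float]] = {ERNA: [], NO_ERNA: []}
    for tissue, _enh, state in group.members:
        by_state[state].append(z[(group.gene_id, tissue)])
    return (
        float(np.mean(by_state[ERNA])),
        float(np.mean(by_state[NO_ERNA])),
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    alternative: str
    n: int


def paired_t_test(
    pairs: Sequence[tuple[float, float]], alternative: str = "greater"
) -> TestResult:
    """Paired t-test on ``(mean_z_eRNA, mean_z_no_eRNA)`` pairs.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = eRNA - no_eRNA`` and
    df = n - 1; the default alternative is ``d > 0``.
    """
    d = np.array([a - b for a, b in pairs], dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(d) == 0:
        raise ValueError("degenerate paired differences (zero variance)")
    res = stats.ttest_1samp(d, 0.0, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, d.size)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> TestResult:
    """One-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration for small tie-free samples (both n <= 20); otherwise
    the normal approximation with tie correction and continuity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, x.size + y.size)


def least_rectangles_line(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Least-rectangles (geometric-mean) regression line.

    ``slope = sign(r) * sd(y)/sd(x)``; the line passes through the means.
    Symmetric in the roles of x and y, unlike ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("least-rectangles line undefined for constant input")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    return float(slope), float(y.mean() - slope * x.mean())


def compare_state_expression(
    calls: Sequence[ErnaCall],
    enhancers: Mapping[tuple[str, str], Enhancer],
    z: pd.DataFrame,
    dedupe: bool = True,
    value_column: str = "bpkm",
) -> dict[str, TestResult]:
    """Per-tissue rank-sum comparison of target-gene expression by state.

    For each tissue, genes targeted by transcribing enhancers are compared
    against genes targeted by non-transcribing enhancers (alternative:
    transcribing higher).  With ``dedupe`` each (gene, state) contributes
    once per tissue.
    """
    values = {
        (g, t): v for g, t, v in zip(z["gene_id"], z["tissue"], z[value_column])
    }
    per_tissue: dict[str, dict[str, list[float]]] = {}
    seen: set[tuple[str, str, str]] = set()
    for call in calls:
        enh = enhancers[(call.tissue, call.enhancer_id)]
        for gid in sorted(enh.target_gene_ids):
            if (gid, call.tissue) not in values:
                continue
            key = (call.tissue, gid, call.state)
            if dedupe and key in seen:
                continue
            seen.add(key)
            bucket = per_tissue.setdefault(call.tissue, {ERNA: [], NO_ERNA: []})
            bucket[call.state].append(values[(gid, call.tissue)])
    out = {}
    for tissue, bucket in sorted(per_tissue.items()):
        if bucket[ERNA] and bucket[NO_ERNA]:
            out[tissue] = rank_sum_test(bucket[ERNA], bucket[NO_ERNA])
    return out
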