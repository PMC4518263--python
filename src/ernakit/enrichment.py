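"""ncRNA-family annotation enrichment of eRNAs over random controls.

The covariance-model scan itself (Infernal/Rfam) is consumed as a tabular
hit list; this module contributes the control construction and the
statistics: length-matched random intergenic control sampling, a one-sided
pooled two-proportion z-test per family, and the class-level comparison of
miRNA families against all other ncRNA families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import RnaContig
from .core import GeneModel, GenomicInterval, intergenic_segments
from .crosstissue import TestResult, least_rectangles_line

__all__ = [
    "ProportionTestResult",
    "sample_matched_controls",
    "two_proportion_test",
    "family_enrichment",
    "mirna_vs_other",
]

HIT_COLUMNS = ["query_id", "family_id", "family_class", "score"]


@dataclass(frozen=True)
class ProportionTestResult:
    """One-sided two-proportion test of family hit rates, eRNAs vs controls."""

    family_id: str
    family_class: str
    k1: int
    n1: int
    k2: int
    n2: int
    z: float
    p: float
    significant: bool
    degenerate: bool = False


def sample_matched_controls(
    ernas: Sequence[RnaContig],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    rng_seed: int = 0,
    margin: int = 3000,
    max_retries: int = 100,
) -> list[GenomicInterval]:
    """Length-matched random intergenic control intervals.

    Emits exactly one control per eRNA; each control's length is drawn with
    replacement from the eRNA length multiset and the interval is placed
    uniformly in intergenic space (genes padded by ``margin`` bp, matching
    the enhancer filter).  Deterministic under ``rng_seed``.
    """
    if not ernas:
        return []
    rng = np.random.default_rng(rng_seed)
    segments = intergenic_segments(dict(chrom_sizes), genes, margin=margin)
    seg_lengths = np.array([s.length for s in segments], dtype=float)
    lengths = np.array([e.interval.length for e in ernas])
    out: list[GenomicInterval] = []
    for _ in range(len(ernas)):
        placed = None
        for _attempt in range(max_retries):
            length = int(lengths[rng.integers(0, len(lengths))])
            fits = seg_lengths >= length
            if not fits.any():
                continue
            weights = np.where(fits, seg_lengths - length + 1, 0.0)
            seg = segments[int(rng.choice(len(segments), p=weights / weights.sum()))]
            start = int(seg.start + rng.integers(0, seg.length - length + 1))
            placed = GenomicInterval(seg.chrom, start, start + length)
            break
        if placed is None:
            raise RuntimeError(
                "could not place a length-matched control in intergenic space"
            )
        out.append(placed)
    return out


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "greater"
) -> tuple[float, float, bool]:
    """Pooled two-proportion z-test; returns ``(z, p, degenerate)``.

    ``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with the pooled ``p``.
    When the pooled proportion is 0 or 1 the statistic is undefined; the
    equality convention ``p = 0.5`` is returned with the degenerate flag.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 0.5, True
    z = (k1 / n1 - k2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p), False


def _hit_counts(hits: pd.DataFrame) -> pd.DataFrame:
    """Distinct queries hit per family (one indicator per query)."""
    dedup = hits.drop_duplicates(["query_id", "family_id"])
    counts = (
        dedup.groupby(["family_id", "family_class"])["query_id"]
        .nunique()
        .reset_index(name="k")
    )
    return counts


def family_enrichment(
    hits_real: pd.DataFrame,
    hits_control: pd.DataFrame,
    n_real: int,
    n_control: int,
    alpha: float = 0.001,
) -> list[ProportionTestResult]:
    """Per-family one-sided enrichment of eRNA hits over control hits.

    Each query counts at most once per family; totals are the full numbers
    of eRNAs and of controls.  Families with ``p < alpha`` are flagged
    significant.
    """
    real = _hit_counts(hits_real).set_index("family_id")
    ctrl = _hit_counts(hits_control).set_index("family_id")
    families = sorted(set(real.index) | set(ctrl.index))
    results = []
    for fam in families:
        k1 = int(real["k"].get(fam, 0))
        k2 = int(ctrl["k"].get(fam, 0))
        fclass = str(
            real["family_class"].get(fam, ctrl["family_class"].get(fam, "other"))
        )
        z, p, degenerate = two_proportion_test(k1, n_real, k2, n_control)
        results.append(
            ProportionTestResult(
                fam, fclass, k1, n_real, k2, n_control, z, p,
                significant=bool(p < alpha), degenerate=degenerate,
            )
        )
    return results


def mirna_vs_other(
    results: Sequence[ProportionTestResult],
) -> tuple[TestResult | None, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Class-level comparison: miRNA-family excess versus other families.

    Aggregates significant families' hit counts by class and tests whether
    the miRNA class's real-vs-control hit composition exceeds the other
    class's with a one-sided two-proportion z-test.  Also emits per-family
    scatter coordinates — each family's share of all significant real
    (resp. control) hits — and a least-rectangles trend line per class.
    """
    sig = [r for r in results if r.significant]
    total_real = sum(r.k1 for r in sig)
    total_ctrl = sum(r.k2 for r in sig)
    points = pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "family_class": r.family_class,
                "real_ratio": r.k1 / total_real if total_real else np.nan,
                "control_ratio": r.k2 / total_ctrl if total_ctrl else np.nan,
            }
            for r in sig
        ],
        columns=["family_id", "family_class", "real_ratio", "control_ratio"],
    )
    lines: dict[str, tuple[float, float]] = {}
    for cls in ("miRNA", "other"):
        sub = points[points["family_class"] == cls].dropna()
        if len(sub) >= 2:
            try:
                lines[cls] = least_rectangles_line(
                    sub["control_ratio"], sub["real_ratio"]
                )
            except ValueError:
                pass
    k_mi = sum(r.k1 for r in sig if r.family_class == "miRNA")
    c_mi = sum(r.k2 for r in sig if r.family_class == "miRNA")
    k_ot = sum(r.k1 for r in sig if r.family_class != "miRNA")
    c_ot = sum(r.k2 for r in sig if r.family_class != "miRNA")
    if (k_mi + c_mi) == 0 or (k_ot + c_ot) == 0:
        return None, points, lines
    z, p, _ = two_proportion_test(k_mi, k_mi + c_mi, k_ot, k_ot + c_ot)
    test = TestResult(z, p, "greater", len(sig))
    return test, points, lines
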