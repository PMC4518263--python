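"""Grouping, standardisation and the paired/unpaired state comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ernakit.calling import ERNA, NO_ERNA, ErnaCall, RnaContig
from ernakit.core import Enhancer, GenomicInterval
from ernakit.crosstissue import (
    EnhancerGroup,
    build_groups,
    compare_state_expression,
    group_paired_means,
    least_rectangles_line,
    paired_t_test,
    rank_sum_test,
    validate_group,
    zscore_by_tissue,
)


def enh(eid, tissue, mid, genes=("g",), length=200, chrom="chr1"):
    start = int(mid - length / 2)
    return Enhancer(eid, GenomicInterval(chrom, start, start + length), tissue, set(genes))


def call(e, state):
    contig = (
        RnaContig(GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end, "+"), 1.0)
        if state == ERNA
        else None
    )
    return ErnaCall(e.enhancer_id, e.tissue, state, contig, ())


class TestBuildGroups:
    def test_two_tissues_within_window_both_states(self):
        a = enh("e1", "A", 1250)
        b = enh("e2", "B", 1450)
        groups = build_groups([a, b], [call(a, ERNA), call(b, NO_ERNA)])
        assert len(groups) == 1
        assert len(groups[0].members) == 2
        assert groups[0].gene_id == "g"

    def test_distant_enhancers_not_grouped(self):
        a = enh("e1", "A", 1000)
        b = enh("e2", "B", 3000)
        assert build_groups([a, b], [call(a, ERNA), call(b, NO_ERNA)]) == []

    def test_single_state_cluster_discarded(self):
        a = enh("e1", "A", 1000)
        b = enh("e2", "B", 1100)
        assert build_groups([a, b], [call(a, ERNA), call(b, ERNA)]) == []

    def test_multi_target_enhancer_kept_in_one_group_only(self):
        # both genes' clusters contain the same two enhancers; only one group
        # may survive, chosen by the seeded tie-break
        a = enh("e1", "A", 1000, genes=("g1", "g2"))
        b = enh("e2", "B", 1100, genes=("g1", "g2"))
        groups = build_groups([a, b], [call(a, ERNA), call(b, NO_ERNA)], rng_seed=3)
        assert len(groups) == 1
        assert groups[0].gene_id in {"g1", "g2"}

    def test_deterministic_under_seed(self):
        enhancers, calls = [], []
        rng = np.random.default_rng(0)
        for i in range(20):
            tissue = f"t{i % 4}"
            e = enh(f"e{i}", tissue, 1000 + int(rng.integers(0, 5000)),
                    genes=(f"g{i % 3}",))
            enhancers.append(e)
            calls.append(call(e, ERNA if i % 2 else NO_ERNA))
        g1 = build_groups(enhancers, calls, rng_seed=11)
        g2 = build_groups(enhancers, calls, rng_seed=11)
        assert g1 == g2


def enumerate_valid_outcomes(enhancers, calls, window=1000):
    """Oracle: every outcome of repeatedly keeping a maximum-size candidate
    group compatible (enhancer-disjoint) with those already kept."""
    from ernakit.crosstissue import _candidate_groups

    states = {(c.tissue, c.enhancer_id): c.state for c in calls}
    candidates = _candidate_groups(enhancers, states, window)
    outcomes = set()

    def rec(kept, used):
        compatible = [g for g in candidates if not (used & g.enhancer_keys)]
        remaining = [g for g in compatible if g not in kept]
        if not remaining:
            outcomes.add(frozenset(kept))
            return
        max_size = max(len(g.members) for g in remaining)
        for g in remaining:
            if len(g.members) == max_size:
                rec(kept | {g}, used | g.enhancer_keys)

    rec(frozenset(), frozenset())
    return outcomes


class TestGroupingOracle:
    def test_output_in_exhaustive_choice_set(self, rng):
        for world in range(25):
            enhancers, calls = [], []
            for i in range(int(rng.integers(4, 10))):
                genes = tuple(
                    rng.choice(["g0", "g1", "g2"], size=int(rng.integers(1, 3)),
                               replace=False)
                )
                e = enh(
                    f"e{i}", f"t{int(rng.integers(0, 4))}",
                    1000 + int(rng.integers(0, 40)) * 250, genes=genes,
                )
                enhancers.append(e)
                calls.append(call(e, ERNA if rng.random() < 0.5 else NO_ERNA))
            got = frozenset(build_groups(enhancers, calls, rng_seed=world))
            valid = enumerate_valid_outcomes(enhancers, calls)
            assert got in valid
            index = {(e.tissue, e.enhancer_id): e for e in enhancers}
            for group in got:
                assert validate_group(group, index)


class TestZScore:
    def test_basic_standardisation(self):
        df = pd.DataFrame(
            {"gene_id": list("abc"), "tissue": ["T"] * 3, "bpkm": [1.0, 2.0, 3.0]}
        )
        z = zscore_by_tissue(df)
        assert list(z["z"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_affine_invariance(self, rng):
        x = rng.normal(10, 3, size=40)
        df1 = pd.DataFrame({"gene_id": range(40), "tissue": "T", "bpkm": x})
        df2 = pd.DataFrame({"gene_id": range(40), "tissue": "T", "bpkm": 5 * x + 7})
        assert zscore_by_tissue(df1)["z"].to_numpy() == pytest.approx(
            zscore_by_tissue(df2)["z"].to_numpy()
        )

    def test_constant_tissue_rejected(self):
        df = pd.DataFrame({"gene_id": list("ab"), "tissue": "T", "bpkm": [2.0, 2.0]})
        with pytest.raises(ValueError):
            zscore_by_tissue(df)


class TestGroupPairedMeans:
    def test_means_by_state(self):
        group = EnhancerGroup(
            "g",
            (("A", "e1", ERNA), ("B", "e2", NO_ERNA), ("C", "e3", ERNA)),
            GenomicInterval("chr1", 1000, 1100),
        )
        z = {("g", "A"): 1.0, ("g", "B"): -0.2, ("g", "C"): 0.0}
        assert group_paired_means(group, z) == (0.5, -0.2)


class TestPairedT:
    def test_hand_computed_example(self):
        # d = [1,2,3,4]: mean 2.5, sd 1.2910, t = 2.5/(1.2910/2) = 3.8730
        pairs = [(1.0, 0.0), (2.0, 0.0), (3.0, 0.0), (4.0, 0.0)]
        res = paired_t_test(pairs)
        assert res.statistic == pytest.approx(3.8730, abs=1e-4)
        assert res.n == 4

    def test_null_centre(self, rng):
        d = rng.normal(0, 1, size=2000)
        res = paired_t_test([(v, 0.0) for v in d])
        assert 0.05 < res.p < 0.95

    def test_degenerate_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([(1.0, 0.0), (1.0, 0.0)])


class TestRankSum:
    def test_exact_enumeration_small_sample(self):
        res = rank_sum_test([4, 5, 6], [1, 2, 3])
        assert res.p == pytest.approx(1 / 20)

    def test_exact_p_matches_full_enumeration(self, rng):
        x = [1.3, 2.7, 9.1, 4.2]
        y = [0.5, 3.3, 2.0]
        res = rank_sum_test(x, y)
        # enumerate all C(7,3) label assignments of the pooled sample
        pooled = sorted(x + y)
        u_obs = sum(1 for xi in x for yi in y if xi > yi)
        count = total = 0
        for comb in itertools.combinations(range(7), len(x)):
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(7) if i not in comb]
            u = sum(1 for xi in xs for yi in ys if xi > yi)
            total += 1
            count += u >= u_obs
        assert res.p == pytest.approx(count / total)

    def test_identical_samples_p_near_half(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        res = rank_sum_test(np.concatenate([x, y]), np.concatenate([y, x]))
        assert 0.3 < res.p < 0.7


class TestLeastRectangles:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept = least_rectangles_line(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)

    def test_standardised_slope_is_one(self, rng):
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200) * 0.9
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        slope, _ = least_rectangles_line(xs, ys)
        assert slope == pytest.approx(1.0)

    def test_magnitude_at_least_ols_slope(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            slope, _ = least_rectangles_line(x, y)
            ols = float(np.polyfit(x, y, 1)[0])
            assert abs(slope) >= abs(ols) - 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            least_rectangles_line([1.0, 1.0], [0.0, 1.0])


class TestCompareStateExpression:
    def test_detects_planted_shift(self, rng):
        genes = [f"g{i}" for i in range(200)]
        enh_index, calls, rows = {}, [], []
        for i, g in enumerate(genes):
            e = enh(f"e{i}", "T", 1000 + 5000 * i, genes=(g,))
            enh_index[("T", e.enhancer_id)] = e
            state = ERNA if i < 100 else NO_ERNA
            calls.append(call(e, state))
            shift = 1.0 if state == ERNA else 0.0
            rows.append({"gene_id": g, "tissue": "T",
                         "bpkm": float(rng.normal(10 + shift, 1))})
        res = compare_state_expression(calls, enh_index, pd.DataFrame(rows))
        assert res["T"].p < 1e-6
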