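"""The enrichment metric panel against independent oracles.

Every metric is checked against a route independent of the implementation:
brute-force pairwise counting and sklearn's trapezoidal ROC for the AUC,
direct summation of the exponential-weight formula for RIE, exhaustive
best/worst placement for BEDROC, and hand arithmetic for the rank-based
percentages.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenrich import (
    ActivityTable,
    MetricParams,
    ParameterError,
    RankedScreen,
    UndefinedMetricError,
    bedroc,
    enrichment_factor,
    evaluate_screen,
    hit_rate,
    rie,
    roc_auc,
    roc_points,
    screening_percentage,
    total_gain,
)
from tests.conftest import make_ranking, random_tied_ranking


def pairwise_auc(labels, scores):
    """Brute-force Mann-Whitney oracle: loop over all (active, inactive)
    pairs, ties credited one half."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    wins = 0.0
    pairs = 0
    for sa in scores[labels]:
        for si in scores[~labels]:
            pairs += 1
            if sa > si:
                wins += 1.0
            elif sa == si:
                wins += 0.5
    return wins / pairs


def rie_by_direct_summation(active_ranks, N, alpha):
    """Independent RIE oracle: the formula summed term by term."""
    num = sum(math.exp(-alpha * r / N) for r in active_ranks)
    n = len(active_ranks)
    denom = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    return num / denom


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc(make_ranking([1, 1, 0, 0])) == 1.0

    def test_inverted_ranking(self):
        assert roc_auc(make_ranking([0, 0, 1, 1])) == 0.0

    def test_alternating(self):
        # 4 pairs: active@1 beats both inactives, active@3 beats one
        assert roc_auc(make_ranking([1, 0, 1, 0])) == 0.75

    def test_tie_block_gets_half_credit(self):
        lr = make_ranking([1, 0], scores=[3.0, 3.0])
        assert roc_auc(lr) == 0.5

    @pytest.mark.parametrize("labels", [[1, 1], [0, 0]])
    def test_single_class_undefined(self, labels):
        with pytest.raises(UndefinedMetricError):
            roc_auc(make_ranking(labels))

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            lr = random_tied_ranking(rng, max_n=30)
            assert roc_auc(lr) == pytest.approx(
                pairwise_auc(lr.labels, lr.scores), abs=1e-12
            )

    def test_roc_polygon_trapezoid_equals_auc(self):
        from sklearn.metrics import auc as sk_trapezoid

        rng = np.random.default_rng(3)
        for _ in range(50):
            lr = random_tied_ranking(rng, max_n=40)
            pts = roc_points(lr)
            assert sk_trapezoid(pts[:, 0], pts[:, 1]) == pytest.approx(
                roc_auc(lr), abs=1e-12
            )


class TestRie:
    def test_single_active_on_top(self):
        lr = make_ranking([1] + [0] * 9)
        expected = rie_by_direct_summation([1], 10, 20.0)
        assert rie(lr) == pytest.approx(expected, rel=1e-12)
        assert round(rie(lr), 2) == 8.65

    def test_single_active_last_is_machine_zero(self):
        lr = make_ranking([0] * 9 + [1])
        expected = rie_by_direct_summation([10], 10, 20.0)
        assert rie(lr) == pytest.approx(expected, rel=1e-12)
        assert rie(lr) < 1e-6

    @pytest.mark.parametrize("N", [5, 10, 50])
    @pytest.mark.parametrize("alpha", [5.0, 20.0, 100.0])
    def test_normalization_identity(self, N, alpha):
        """The denominator is the exhaustive single-active mean: averaging
        RIE over all N placements gives exactly 1."""
        params = MetricParams(alpha=alpha)
        values = []
        for pos in range(N):
            labels = np.zeros(N, dtype=bool)
            labels[pos] = True
            values.append(rie(make_ranking(labels), params))
        assert np.mean(values) == pytest.approx(1.0, abs=1e-12)

    def test_no_actives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            rie(make_ranking([0, 0, 0]))


class TestBedroc:
    @pytest.mark.parametrize("n,N,alpha", [(1, 10, 20.0), (3, 25, 5.0), (5, 40, 20.0)])
    def test_endpoints(self, n, N, alpha):
        params = MetricParams(alpha=alpha)
        perfect = make_ranking([1] * n + [0] * (N - n))
        inverted = make_ranking([0] * (N - n) + [1] * n)
        assert bedroc(perfect, params) == pytest.approx(1.0, abs=1e-9)
        assert bedroc(inverted, params) == pytest.approx(0.0, abs=1e-9)

    def test_equals_exhaustive_minmax_oracle(self):
        """BEDROC at rank 5 of 10 equals (RIE - RIE_min)/(RIE_max - RIE_min)
        with the extremes computed by brute-force placement."""
        N, alpha = 10, 20.0
        labels = np.zeros(N, dtype=bool)
        labels[4] = True  # rank 5
        lr = make_ranking(labels)
        r = rie_by_direct_summation([5], N, alpha)
        r_max = rie_by_direct_summation([1], N, alpha)
        r_min = rie_by_direct_summation([N], N, alpha)
        assert bedroc(lr) == pytest.approx((r - r_min) / (r_max - r_min), rel=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            lr = random_tied_ranking(rng)
            assert 0.0 <= bedroc(lr) <= 1.0

    def test_conditioning_warning_when_alpha_ra_large(self):
        lr = make_ranking([1, 1, 1, 0])  # alpha * n/N = 15
        with pytest.warns(RuntimeWarning, match="poorly conditioned"):
            bedroc(lr)


class TestTotalGain:
    def test_separated_tied_blocks_reach_one_exactly(self):
        # one tie block per class: the predictiveness curve is exactly the
        # two-level step whose mean absolute deviation is 2*pi*(1-pi)
        labels = [1] * 10 + [0] * 90
        scores = [2.0] * 10 + [1.0] * 90
        lr = make_ranking(labels, scores=scores)
        assert total_gain(lr, MetricParams(tg_window=5)) == pytest.approx(1.0, abs=1e-12)

    def test_separated_distinct_scores_approach_one(self):
        labels = [1] * 100 + [0] * 1900
        lr = make_ranking(labels)
        assert total_gain(lr, MetricParams(tg_window=2)) > 0.97

    def test_full_tie_is_zero(self):
        lr = make_ranking([1, 0, 1, 0, 0, 0], scores=[1.0] * 6)
        assert total_gain(lr, MetricParams(tg_window=2)) == pytest.approx(0.0, abs=1e-12)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(19)
        values = []
        for _ in range(50):
            labels = rng.random(2000) < 0.5
            values.append(total_gain(make_ranking(labels)))
        assert np.median(values) < 0.1

    def test_window_larger_than_list_rejected(self):
        with pytest.raises(ParameterError):
            total_gain(make_ranking([1, 0, 1, 0]), MetricParams(tg_window=10))


class TestScreeningPercentage:
    def test_top_of_hundred(self):
        labels = [1] + [0] * 99
        lr = make_ranking(labels, parent_ids=[f"p{i}" for i in range(100)])
        assert screening_percentage(lr, "p0") == 1.0

    def test_last_place(self):
        lr = make_ranking([0, 0, 0, 1])
        assert screening_percentage(lr, "p3") == 100.0

    def test_tie_counted_pessimistically(self):
        # scores [5,4,4,3]: the score-4 target cannot be reached before the
        # whole tie block is screened -> rank 3 of 4 -> 75%
        lr = make_ranking([0, 0, 1, 0], scores=[5.0, 4.0, 4.0, 3.0])
        assert screening_percentage(lr, "p2") == 75.0

    def test_unknown_parent(self):
        with pytest.raises(LookupError):
            screening_percentage(make_ranking([1, 0]), "nope")


class TestEnrichmentFactor:
    def test_printed_arithmetic_examples(self):
        # 50% recovery reached at 1.76% screened -> 28-fold; at 9.80% -> ~5-fold
        assert 0.5 / 0.0176 == pytest.approx(28.4, abs=0.01)
        N = 2500
        labels = np.zeros(N, dtype=bool)
        labels[[9, 43, 499, 2199]] = True  # ranks 10, 44, 500, 2200
        ef = enrichment_factor(make_ranking(labels), 0.5)
        assert ef == pytest.approx(0.5 / (44 / N), rel=1e-12)
        assert round(ef) == 28

    def test_uniform_placement_gives_unit_enrichment(self):
        # actives exactly at the uniform quantiles of the list
        N, m = 1000, 4
        labels = np.zeros(N, dtype=bool)
        labels[[249, 499, 749, 999]] = True
        lr = make_ranking(labels)
        for f in (0.25, 0.5, 0.75, 1.0):
            assert enrichment_factor(lr, f) == pytest.approx(1.0, rel=1e-12)

    def test_recovery_fraction_validated(self):
        lr = make_ranking([1, 0])
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ParameterError):
                enrichment_factor(lr, bad)

    def test_explicit_subset(self):
        labels = [1, 1, 0, 1, 0, 0]
        lr = make_ranking(labels)
        # only the last active counts: 100% recovery at rank 4 of 6
        assert enrichment_factor(lr, 1.0, active_subset=["p3"]) == pytest.approx(6 / 4)


class TestHitRate:
    def test_printed_values(self):
        assert hit_rate(4, 1364) == 0.29
        assert hit_rate(19, 1364) == 1.39

    def test_zero_hits(self):
        assert hit_rate(0, 500) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            hit_rate(1, 0)
        with pytest.raises(ParameterError):
            hit_rate(5, 4)


class TestMonotonicity:
    @given(st.data())
    @settings(max_examples=150, derandomize=True)
    def test_adjacent_active_up_swap_never_decreases(self, data):
        """Promoting an active past the inactive directly above it can only
        improve AUC, RIE and BEDROC."""
        N = data.draw(st.integers(4, 25))
        n = data.draw(st.integers(1, N - 1))
        labels = np.zeros(N, dtype=bool)
        labels[data.draw(st.permutations(range(N)))[:n]] = True
        swaps = [i for i in range(N - 1) if not labels[i] and labels[i + 1]]
        if not swaps:
            return
        i = swaps[len(swaps) // 2]
        before = make_ranking(labels)
        swapped = labels.copy()
        swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
        after = make_ranking(swapped)
        params = MetricParams(alpha=20.0)
        assert roc_auc(after) >= roc_auc(before)
        assert rie(after, params) >= rie(before, params)
        assert bedroc(after, params) >= bedroc(before, params) - 1e-12


class TestEvaluateScreen:
    def _separation_screen(self):
        import pandas as pd

        # all active states tied at a better score than all inactive states
        rows = []
        for i in range(5):
            rows.append((f"a{i}", f"A{i}", -10.0))
        for i in range(45):
            rows.append((f"i{i}", f"I{i}", -1.0))
        screen = RankedScreen.from_frame(
            pd.DataFrame(rows, columns=["state_id", "parent_id", "score"]),
            direction="lower_better",
            name="sep",
        )
        residuals = {f"A{i}": {"CK1": 10.0} for i in range(5)}
        residuals.update({f"I{i}": {"CK1": 90.0} for i in range(45)})
        activity = ActivityTable.from_mapping(residuals, primary_kinase="CK1")
        return screen, activity

    def test_separation_limit_report(self):
        screen, activity = self._separation_screen()
        rep = evaluate_screen(screen, activity, MetricParams(tg_window=4))
        assert rep.auc == 1.0 and rep.bedroc == 1.0
        assert rep.tg == pytest.approx(1.0, abs=1e-12)

    def test_report_consistent_with_individual_metrics(self, two_class_screen):
        from screenrich import collapse_no_duplicates, label_ranking

        activity = ActivityTable.from_mapping(
            {"A": {"CK1": 10.0}, "B": {"CK1": 90.0}}, primary_kinase="CK1"
        )
        params = MetricParams(alpha=20.0, tg_window=2)
        rep = evaluate_screen(
            two_class_screen, activity, params, treatment="no_duplicates"
        )
        lr = collapse_no_duplicates(label_ranking(two_class_screen, activity))
        assert rep.auc == roc_auc(lr)
        assert rep.rie == rie(lr, params)
        assert rep.bedroc == bedroc(lr, params)
        assert rep.tg == total_gain(lr, params)

    def test_deterministic_repeat(self, two_class_screen):
        activity = ActivityTable.from_mapping(
            {"A": {"CK1": 10.0}, "B": {"CK1": 90.0}}, primary_kinase="CK1"
        )
        params = MetricParams(tg_window=2)
        r1 = evaluate_screen(two_class_screen, activity, params)
        r2 = evaluate_screen(two_class_screen, activity, params)
        assert r1.to_dict() == r2.to_dict()

    def test_no_actives_refused(self):
        import pandas as pd

        screen = RankedScreen.from_frame(
            pd.DataFrame(
                [("a", "A", -1.0), ("b", "B", -2.0)],
                columns=["state_id", "parent_id", "score"],
            ),
            direction="lower_better",
        )
        activity = ActivityTable.from_mapping(
            {"A": {"CK1": 80.0}, "B": {"CK1": 90.0}}, primary_kinase="CK1"
        )
        with pytest.raises(UndefinedMetricError):
            evaluate_screen(screen, activity, MetricParams(tg_window=2))
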