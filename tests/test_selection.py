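"""Anchoring, information ranking, fallback, and the CAM rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from delibank.irt import ItemParams, ThetaEstimate, item_information
from delibank.selection import (
    CamResult,
    apply_fallback,
    cam_algorithm,
    rank_by_information,
    run_selection,
    select_top_k,
    sensitivity_analysis,
    theta_anchor,
)

from .oracles import item_info_closed_form


def scores_from(eaps):
    eaps = np.asarray(eaps, float)
    return ThetaEstimate(
        person_ids=[f"p{i}" for i in range(len(eaps))],
        eap=eaps, sd=np.full(len(eaps), 0.5),
        n_observed=np.full(len(eaps), 10),
    )


def params_from(pairs, ids=None):
    a, b = zip(*pairs)
    ids = ids or [f"v{i}" for i in range(len(pairs))]
    return ItemParams(indicator_ids=list(ids), a=list(a), b=list(b))


class TestThetaAnchor:
    def test_odd_length_median(self):
        s = scores_from([1.0, 2.0, 3.0, -5.0])
        assert theta_anchor(s, [1, 1, 1, 0], 50) == 2.0

    def test_all_positive_uses_whole_cohort(self):
        s = scores_from([0.0, 1.0, 2.0, 3.0])
        assert theta_anchor(s, [1, 1, 1, 1], 50) == np.percentile(s.eap, 50)

    def test_no_positives_is_an_error(self):
        s = scores_from([0.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            theta_anchor(s, [0, 0], 50)

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(3)
        s = scores_from(rng.normal(0, 1, 500))
        lab = rng.random(500) < 0.3
        t25 = theta_anchor(s, lab, 25)
        t50 = theta_anchor(s, lab, 50)
        t75 = theta_anchor(s, lab, 75)
        assert t25 <= t50 <= t75

    def test_positive_anchor_exceeds_cohort_median(self):
        # positives thresholded on the trait sit higher than the cohort
        from scipy.special import ndtri

        rng = np.random.default_rng(4)
        theta = rng.normal(0, 1, 20000)
        cut = ndtri(1 - 0.133)
        lab = theta > cut
        s = scores_from(theta)  # perfect measurement limit
        assert theta_anchor(s, lab, 50) > np.median(theta)


class TestRankByInformation:
    def test_higher_discrimination_wins_at_shared_location(self):
        p = params_from([(2.0, 0.0), (1.0, 0.0)], ids=["hi", "lo"])
        ranking, info = rank_by_information(p, 0.0)
        assert ranking == ["hi", "lo"]
        assert info["hi"] > info["lo"]

    def test_translation_invariance(self):
        pairs = [(1.5, 0.2), (0.9, 1.0), (2.2, -0.3)]
        p1 = params_from(pairs)
        shift = 0.8
        p2 = params_from([(a, b + shift) for a, b in pairs])
        r1, _ = rank_by_information(p1, 0.4)
        r2, _ = rank_by_information(p2, 0.4 + shift)
        assert r1 == r2

    def test_published_inattention_second_factor_ranking(self):
        # five attention-test indicators (backwards spans) with printed
        # (a, b), ranked at the reported anchor theta* = 0.27; expected
        # order computed with an independent closed-form oracle
        pairs = [
            ("days_backwards", 1.65, 1.29),
            ("months_backwards", 1.17, 0.20),
            ("digit_back_3", 1.12, 0.85),
            ("digit_back_4", 1.20, -0.34),
            ("digit_fwd_4", 1.11, 2.09),
        ]
        p = ItemParams(
            indicator_ids=[n for n, _, _ in pairs],
            a=[a for _, a, _ in pairs], b=[b for _, _, b in pairs],
        )
        theta_star = 0.27
        oracle = sorted(
            pairs, key=lambda t: -item_info_closed_form(theta_star, t[1], t[2], 1.7)
        )
        ranking, info = rank_by_information(p, theta_star)
        assert ranking == [n for n, _, _ in oracle]
        # a well-located modest item beats a high-severity one
        assert ranking.index("months_backwards") < ranking.index("digit_fwd_4")

    def test_severity_screening_contrast(self):
        # high-discrimination item peaked two units above the anchor loses
        # to a modest item peaked at the anchor, per the closed form
        theta_star = 0.5
        p = params_from([(2.0, theta_star + 2.0), (1.2, theta_star)],
                        ids=["severe", "screen"])
        ranking, info = rank_by_information(p, theta_star)
        i_severe = item_info_closed_form(theta_star, 2.0, theta_star + 2.0, 1.7)
        i_screen = item_info_closed_form(theta_star, 1.2, theta_star, 1.7)
        assert i_screen > i_severe
        assert ranking == ["screen", "severe"]


class TestSelectTopK:
    def test_short_list_returned_whole(self):
        assert select_top_k(["a", "b", "c"], 5) == ["a", "b", "c"]

    def test_prefix_of_ranking(self):
        ranking = [f"v{i}" for i in range(15)]
        sel = select_top_k(ranking, 5)
        assert sel == ranking[:5]

    def test_deterministic(self):
        ranking = ["c", "a", "b"]
        assert select_top_k(ranking, 2) == select_top_k(ranking, 2)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_top_k(["a"], 0)


class TestSensitivity:
    def test_common_difficulty_identical_rankings(self):
        # with a shared difficulty the information ordering in a is stable
        # as long as every anchor stays within the region |theta - b| <
        # 2.4 / (D a_max) where a^2 P(1-P) is still increasing in a; the
        # feature-positive upper tail of a screening cohort is such a
        # region when b sits at its center
        rng = np.random.default_rng(5)
        eaps = rng.normal(0, 1, 4000)
        s = scores_from(eaps)
        lab = eaps > np.percentile(eaps, 87)  # screening-like positives
        b = float(np.percentile(eaps[lab], 50))
        p = params_from([(a, b) for a in (0.8, 1.2, 1.6, 2.0, 2.4)])
        out = sensitivity_analysis(s, lab, p)
        r = [out["percentiles"][pct]["ranking"] for pct in (25, 50, 75)]
        assert r[0] == r[1] == r[2]
        assert out["essentially_same"]

    def test_rerank_oracle_agreement(self):
        rng = np.random.default_rng(6)
        s = scores_from(rng.normal(0, 1, 600))
        lab = rng.random(600) < 0.25
        pairs = [(1.65, 1.29), (1.17, 0.20), (1.12, 0.85), (1.20, -0.34),
                 (1.11, 2.09), (2.0, 0.5), (0.9, 1.7)]
        p = params_from(pairs)
        out = sensitivity_analysis(s, lab, p, k=5)
        for pct in (25, 50, 75):
            t = theta_anchor(s, lab, pct)
            oracle_rank = sorted(
                range(len(pairs)),
                key=lambda j: -item_info_closed_form(t, pairs[j][0], pairs[j][1], 1.7),
            )
            expected = [p.indicator_ids[j] for j in oracle_rank]
            assert out["percentiles"][pct]["ranking"] == expected

    def test_anchor_monotonicity_reported(self):
        rng = np.random.default_rng(7)
        s = scores_from(rng.normal(0, 1, 500))
        lab = rng.random(500) < 0.3
        p = params_from([(1.0, 0.0), (1.5, 1.0), (0.8, 2.0), (1.2, 0.5)])
        out = sensitivity_analysis(s, lab, p)
        ts = [out["percentiles"][pct]["theta_star"] for pct in (25, 50, 75)]
        assert ts == sorted(ts)


class TestFallback:
    @staticmethod
    def setup_scores():
        rng = np.random.default_rng(8)
        s = scores_from(rng.normal(0, 1, 800))
        lab = rng.random(800) < 0.3
        return s, lab

    def test_informative_set_untouched(self):
        s, lab = self.setup_scores()
        t50 = theta_anchor(s, lab, 50)
        p = params_from([(1.5, t50), (1.2, t50 + 0.2), (1.0, t50 - 0.2), (2.0, t50)])
        res = run_selection(s, lab, p)
        out = apply_fallback(res, p, s, lab, floor=0.25)
        assert not out.fallback_triggered
        assert out.percentile_used == 50
        assert out.selected == res.selected

    def test_uninformative_set_falls_back_to_75th(self):
        s, lab = self.setup_scores()
        t50 = theta_anchor(s, lab, 50)
        # every difficulty far above the anchor with weak slopes
        p = params_from([(0.5, t50 + 3.0), (0.4, t50 + 3.5), (0.5, t50 + 4.0),
                         (0.45, t50 + 3.2)])
        res = run_selection(s, lab, p)
        assert max(res.info_at_star.values()) < 0.25
        out = apply_fallback(res, p, s, lab, floor=0.25)
        assert out.fallback_triggered
        assert out.percentile_used == 75
        assert out.theta_star >= res.theta_star  # quantile monotonicity

    def test_fallback_requires_median_start(self):
        s, lab = self.setup_scores()
        p = params_from([(1.0, 0.0)] * 2)
        res = run_selection(s, lab, p, percentile=75)
        with pytest.raises(ValueError):
            apply_fallback(res, p, s, lab)


class TestCamAlgorithm:
    @pytest.mark.parametrize("f, expected", [
        ((1, 1, 1, 0), True),
        ((1, 0, 1, 1), False),  # inattention is required
        ((1, 1, 0, 0), False),  # needs disorganized thinking or altered LOC
        ((1, 1, 0, 1), True),
        ((0, 1, 1, 1), False),
    ])
    def test_truth_table(self, f, expected):
        assert cam_algorithm(*f) is expected

    @given(st.tuples(*[st.booleans()] * 4))
    def test_matches_boolean_formula(self, f):
        f1, f2, f3, f4 = f
        assert cam_algorithm(f1, f2, f3, f4) == (f1 and f2 and (f3 or f4))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        F = rng.random((100, 4)) < 0.5
        vec = cam_algorithm(F[:, 0], F[:, 1], F[:, 2], F[:, 3])
        scal = [cam_algorithm(*row) for row in F]
        assert vec.tolist() == scal

    def test_cam_result_from_labels(self, default_cohort):
        res = CamResult.from_labels(default_cohort.feature_labels)
        lab = default_cohort.feature_labels.to_numpy().astype(bool)
        expected = lab[:, 0] & lab[:, 1] & (lab[:, 2] | lab[:, 3])
        assert np.array_equal(res.delirium, expected)
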