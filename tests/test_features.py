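"""Integral/centroid features, t-test selection, test-retest comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdnirs.features import (
    FEATURE_INDEX,
    centroid_feature,
    integral_feature,
    select_features,
)
from tdnirs.features import test_retest_compare as compare_sessions
from tdnirs.pipeline import cohort_feature_table
from tdnirs.protocol import TaskProtocol
from tdnirs.synthetic import CohortSpec, VariabilitySpec, generate_cohort, null_effects
from tdnirs.synthetic import GroupEffectSpec


class TestCanonicalIndex:
    def test_table_footnote_assignments(self):
        assert FEATURE_INDEX["F3"] == ("RHbO1", "suppressive", "integral")
        assert FEATURE_INDEX["F6"] == ("RHbO1", "channel_avg", "centroid")
        assert FEATURE_INDEX["F7"] == ("RHbO2", "activated", "integral")
        assert FEATURE_INDEX["F8"] == ("RHbO2", "activated", "centroid")
        assert FEATURE_INDEX["F12"] == ("RHbO2", "channel_avg", "centroid")


class TestIntegral:
    def test_reference_curve_integrates_to_zero(self, protocol):
        assert integral_feature(np.ones(protocol.n_frames), protocol, 1.0) == 0.0

    def test_boxcar_closed_form(self, protocol):
        """Boxcar of height h over the whole task window -> exactly h*T."""
        t = protocol.frame_times_s
        curve = np.ones_like(t)
        curve[protocol.task_mask()] = 1.0 + 0.07
        got = integral_feature(curve, protocol, 1.0)
        assert got == pytest.approx(0.07 * protocol.task_s, abs=1e-12)

    def test_suppressive_curve_integral_negative(self, protocol):
        from tdnirs.synthetic import SUPPRESSIVE, ResponseClassParams, hrf_curve

        curve = hrf_curve(SUPPRESSIVE, ResponseClassParams(0.04, 5.0, 20.0), protocol)
        assert integral_feature(curve, protocol, 1.0) < 0

    def test_matches_riemann_oracle(self, protocol):
        rng = np.random.default_rng(2)
        curve = 1.0 + rng.normal(0, 0.05, protocol.n_frames)
        got = integral_feature(curve, protocol, 1.0)
        # independently coded trapezoid as a Riemann limit over segments
        t = protocol.frame_times_s
        mask = protocol.task_mask()
        idx = np.flatnonzero(mask)
        want = 0.0
        for a, b in zip(idx[:-1], idx[1:]):
            want += 0.5 * ((curve[a] - 1.0) + (curve[b] - 1.0)) * (t[b] - t[a])
        assert got == pytest.approx(want, rel=1e-9)

    def test_too_few_frames_gives_missing(self, protocol):
        curve = np.full(protocol.n_frames, np.nan)
        curve[0] = 1.0
        assert np.isnan(integral_feature(curve, protocol, 1.0))


class TestCentroid:
    def test_all_weight_on_first_task_frame(self, protocol):
        curve = np.ones(protocol.n_frames)
        onset_idx = int(protocol.task_onset_s * protocol.fs_hz)
        curve[onset_idx] = 1.3
        assert centroid_feature(curve, protocol, 1.0) == 0.0

    def test_zero_weight_missing(self, protocol):
        assert np.isnan(centroid_feature(np.ones(protocol.n_frames), protocol, 1.0))

    def test_matches_bruteforce_weighted_mean(self, protocol):
        rng = np.random.default_rng(3)
        curve = 1.0 + rng.normal(0, 0.05, protocol.n_frames)
        got = centroid_feature(curve, protocol, 1.0)
        t = protocol.frame_times_s
        num = den = 0.0
        for j in range(protocol.n_frames):
            if protocol.task_onset_s <= t[j] <= protocol.task_end_s:
                w = abs(curve[j] - 1.0)
                num += (t[j] - protocol.task_onset_s) * w
                den += w
        assert got == pytest.approx(num / den, rel=1e-12)

    def test_lies_within_task_window(self, direct_cohort):
        feats, _ = cohort_feature_table(direct_cohort)
        for col, (fam, resp, var) in FEATURE_INDEX.items():
            if var == "centroid":
                vals = feats[col].dropna()
                assert ((vals >= 0) & (vals <= 60.0)).all()


class TestFrameRateInvariance:
    def test_refining_grid_changes_features_under_one_percent(self):
        from tdnirs.synthetic import ACTIVATED, ResponseClassParams, hrf_curve

        params = ResponseClassParams(0.05, 6.0, 20.0)
        p1 = TaskProtocol(fs_hz=1.0)
        p2 = TaskProtocol(fs_hz=2.0)
        c1 = hrf_curve(ACTIVATED, params, p1)
        c2 = hrf_curve(ACTIVATED, params, p2)
        i1, i2 = integral_feature(c1, p1, 1.0), integral_feature(c2, p2, 1.0)
        t1, t2 = centroid_feature(c1, p1, 1.0), centroid_feature(c2, p2, 1.0)
        assert abs(i2 - i1) / abs(i1) < 0.01
        assert abs(t2 - t1) / t1 < 0.01


class TestSelection:
    def test_identical_groups_not_selected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 20)
        df = pd.DataFrame(
            {"group": ["HC"] * 20 + ["MDD"] * 20, "value": np.concatenate([x, x])}
        )
        rep = select_features(df, features=["value"])
        assert rep.loc["value", "t"] == 0.0
        assert rep.loc["value", "p"] == 1.0
        assert not rep.loc["value", "selected"]

    def test_matches_independent_welch_formula(self):
        """Cross-check the selection decision against a hand-coded Welch test."""
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 27)
        b = rng.normal(2, 1, 27)
        df = pd.DataFrame({"group": ["HC"] * 27 + ["MDD"] * 27, "f": np.concatenate([a, b])})
        rep = select_features(df, features=["f"])
        va, vb = a.var(ddof=1) / 27, b.var(ddof=1) / 27
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / 26 + vb**2 / 26)
        p_hand = 2 * stats.t.sf(abs(t_hand), dof)
        assert rep.loc["f", "t"] == pytest.approx(t_hand, rel=1e-12)
        assert rep.loc["f", "p"] == pytest.approx(p_hand, rel=1e-10)
        assert bool(rep.loc["f", "selected"])

    def test_degenerate_zero_variance_flagged(self):
        df = pd.DataFrame({"group": ["HC"] * 3 + ["MDD"] * 3, "f": [1, 1, 1, 2, 2, 2]})
        rep = select_features(df, features=["f"])
        assert rep.loc["f", "p"] == 0.0
        assert bool(rep.loc["f", "degenerate"])

    def test_bh_correction_is_more_conservative(self, direct_cohort):
        feats, _ = cohort_feature_table(direct_cohort)
        cols = [f"F{i}" for i in range(1, 13)]
        raw = select_features(feats, features=cols)
        bh = select_features(feats, features=cols, correction="bh")
        assert bh["selected"].sum() <= raw["selected"].sum()


class TestTestRetest:
    def _feature_table(self, seed, session_shift=0.0, n=12):
        effects = null_effects()
        effects = GroupEffectSpec(
            hc=effects.hc,
            mdd=effects.mdd,
            variability=VariabilitySpec(session_shift=session_shift),
        )
        spec = CohortSpec(
            seed=seed,
            n_per_group=n,
            sessions_per_subject=2,
            effects=effects,
            corruption_probability=0.0,
        )
        feats, _ = cohort_feature_table(generate_cohort(spec))
        return feats

    def test_identical_sessions_report_p_one(self):
        feats = self._feature_table(seed=50)
        s1 = feats[feats.session == 1].copy()
        s2 = s1.copy()
        s2["session"] = 2
        rep = compare_sessions(pd.concat([s1, s2]), features=["F7", "F8"])
        assert (rep["p"] == 1.0).all()

    def test_null_session_effect_rarely_significant(self):
        hits = 0
        n_rep = 40
        for r in range(n_rep):
            rep = compare_sessions(self._feature_table(seed=600 + r), features=["F7"])
            hits += int(rep.loc["F7", "p"] <= 0.05)
        # nominal 5% rate: generous binomial band for 40 replicates
        assert hits <= 8

    def test_programmed_session_shift_detected_with_power(self):
        """A 30% session-2 amplitude shift is detected in most replicates.

        Power is established by this Monte-Carlo loop itself: the paired
        test must reject for the shifted feature in >= 80% of cohorts.
        """
        hits = 0
        n_rep = 25
        for r in range(n_rep):
            rep = compare_sessions(
                self._feature_table(seed=700 + r, session_shift=0.30), features=["F7"]
            )
            hits += int(rep.loc["F7", "p"] <= 0.05)
        assert hits / n_rep >= 0.8
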