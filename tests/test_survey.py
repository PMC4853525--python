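"""Weighted reach estimation: point estimates, SEs, identities, I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mediareach.survey import (
    ADOLESCENTS,
    ADULTS,
    DEFAULT_AGE_BANDS,
    Respondent,
    Stratum,
    SurveyDataError,
    mean_proportion_viewed,
    per_video_proportion,
    read_survey,
    respondent_fraction_seen,
    write_survey,
)

from conftest import make_respondent

VIDS = [f"v{i}" for i in range(4)]


def resp(rid, frac_seen_of=VIDS, seen_n=0, age=15, gender="female", weight=1.0):
    seen = {v: (i < seen_n) for i, v in enumerate(frac_seen_of)}
    return make_respondent(rid, age, gender, weight, seen)


class TestFractionSeen:
    def test_extremes_and_exact_fraction(self):
        vids32 = [f"v{i}" for i in range(32)]
        none = make_respondent("a", 15, "male", 1.0, {v: False for v in vids32})
        all_ = make_respondent("b", 15, "male", 1.0, {v: True for v in vids32})
        eight = make_respondent("c", 15, "male", 1.0, {v: i < 8 for i, v in enumerate(vids32)})
        assert respondent_fraction_seen(none, vids32) == 0.0
        assert respondent_fraction_seen(all_, vids32) == 1.0
        assert respondent_fraction_seen(eight, vids32) == 0.25

    def test_missing_video_named(self):
        r = resp("a")
        with pytest.raises(SurveyDataError, match="v99"):
            respondent_fraction_seen(r, VIDS + ["v99"])


class TestWeightedMean:
    def test_hand_weighted_mean(self):
        # weights 1,2,1 and fractions 0.5, 0.25, 1.0 -> (0.5+0.5+1.0)/4 = 0.5
        rs = [
            resp("a", seen_n=2, weight=1.0),   # 2/4 = 0.5
            resp("b", seen_n=1, weight=2.0),   # 1/4 = 0.25
            resp("c", seen_n=4, weight=1.0),   # 4/4 = 1.0
        ]
        e = mean_proportion_viewed(rs, VIDS, ADOLESCENTS)
        assert e.p_bar == pytest.approx(0.5)

    def test_degenerate_variance(self):
        rs = [resp(f"r{i}", seen_n=1, weight=w) for i, w in enumerate([0.5, 2.0, 3.1])]
        e = mean_proportion_viewed(rs, VIDS, ADOLESCENTS)
        assert e.p_bar == pytest.approx(0.25)
        assert e.se == 0.0
        assert (e.ci_low, e.ci_high) == (e.p_bar, e.p_bar)

    def test_equal_weights_match_brute_force_loop(self):
        rng = np.random.default_rng(0)
        n = 400
        rs = [
            resp(f"r{i}", seen_n=int(rng.integers(0, 5)), weight=1.0)
            for i in range(n)
        ]
        e = mean_proportion_viewed(rs, VIDS, ADOLESCENTS)
        fr = [respondent_fraction_seen(r, VIDS) for r in rs]
        mean = sum(fr) / n
        sd = math.sqrt(sum((f - mean) ** 2 for f in fr) / (n - 1))
        assert e.p_bar == pytest.approx(mean)
        assert e.se == pytest.approx(sd / math.sqrt(n))
        assert e.n_effective == pytest.approx(n)

    def test_ci_ordering_and_clipping(self):
        rs = [resp(f"r{i}", seen_n=(i % 5), weight=1 + 0.1 * i) for i in range(20)]
        e = mean_proportion_viewed(rs, VIDS, ADOLESCENTS)
        assert 0.0 <= e.ci_low <= e.p_bar <= e.ci_high <= 1.0
        assert e.n_effective <= e.n_respondents

    def test_empty_and_single_respondent_errors(self):
        rs = [resp("a", age=15)]
        with pytest.raises(SurveyDataError, match="no respondents"):
            mean_proportion_viewed(rs, VIDS, ADULTS)
        with pytest.raises(SurveyDataError, match="single respondent"):
            mean_proportion_viewed(rs, VIDS, ADOLESCENTS)

    def test_merged_strata_estimate_is_between(self):
        teens = [resp(f"t{i}", seen_n=3, age=14, weight=1.0) for i in range(5)]
        adults = [resp(f"a{i}", seen_n=1, age=40, weight=2.0) for i in range(5)]
        lo_hi = sorted(
            [
                mean_proportion_viewed(teens, VIDS, ADOLESCENTS).p_bar,
                mean_proportion_viewed(adults, VIDS, ADULTS).p_bar,
            ]
        )
        merged = mean_proportion_viewed(teens + adults, VIDS, Stratum(11, None)).p_bar
        assert lo_hi[0] <= merged <= lo_hi[1]


class TestPerVideo:
    def test_all_seen(self):
        rs = [resp(f"r{i}", seen_n=4) for i in range(3)]
        e = per_video_proportion(rs, "v0", ADOLESCENTS)
        assert (e.p_bar, e.se) == (1.0, 0.0)

    def test_hand_weighted_indicator(self):
        # weights 1,1,2 with indicators 1,0,0 -> 0.25
        rs = [
            resp("a", seen_n=1, weight=1.0),
            resp("b", seen_n=0, weight=1.0),
            resp("c", seen_n=0, weight=2.0),
        ]
        assert per_video_proportion(rs, "v0", ADOLESCENTS).p_bar == pytest.approx(0.25)

    def test_fubini_identity(self):
        """Weighted mean of per-respondent fractions equals the average over
        videos of per-video weighted proportions, exactly."""
        rng = np.random.default_rng(3)
        rs = [
            make_respondent(
                f"r{i}", 15, "male", float(rng.uniform(0.2, 3.0)),
                {v: bool(rng.random() < 0.4) for v in VIDS},
            )
            for i in range(30)
        ]
        overall = mean_proportion_viewed(rs, VIDS, ADOLESCENTS).p_bar
        per_video_mean = np.mean(
            [per_video_proportion(rs, v, ADOLESCENTS).p_bar for v in VIDS]
        )
        assert overall == pytest.approx(per_video_mean, abs=1e-12)


class TestStratum:
    def test_default_bands_partition_ages(self):
        for age in range(11, 100):
            hits = [b for b in DEFAULT_AGE_BANDS if b.contains(age, "female")]
            assert len(hits) == 1

    def test_parse_round_trip(self):
        for s in (*DEFAULT_AGE_BANDS, Stratum(19, None, "female")):
            assert Stratum.parse(s.label) == s

    @given(st.integers(11, 80), st.integers(11, 80), st.integers(11, 80))
    @settings(max_examples=50, deadline=None)
    def test_overlap_symmetry(self, a, b, c):
        lo1, hi1 = sorted((a, b))
        s1 = Stratum(lo1, hi1 + 1)
        s2 = Stratum(c, None)
        assert s1.overlaps(s2) == s2.overlaps(s1)


class TestIO:
    def _respondents(self, n=5):
        rng = np.random.default_rng(1)
        return [
            make_respondent(
                f"r{i}", int(rng.integers(11, 60)), "female" if rng.random() < 0.5 else "male",
                float(rng.uniform(0.3, 2.5)),
                {v: bool(rng.random() < 0.3) for v in VIDS},
            )
            for i in range(n)
        ]

    def test_round_trip_preserves_indicators(self, tmp_path):
        rs = self._respondents()
        path = tmp_path / "survey.csv"
        write_survey(rs, path)
        back = read_survey(path)
        assert len(back) == len(rs)
        for a, b in zip(rs, back):
            assert a.seen == b.seen
            assert a.weight == pytest.approx(b.weight)

    def test_duplicate_id_rejected(self, tmp_path):
        rs = self._respondents(3)
        path = tmp_path / "survey.csv"
        write_survey(rs, path)
        df = pd.read_csv(path)
        pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(SurveyDataError, match="duplicate respondent_id"):
            read_survey(path)

    def test_nonpositive_weight_names_row(self, tmp_path):
        rs = self._respondents(3)
        path = tmp_path / "survey.csv"
        write_survey(rs, path)
        df = pd.read_csv(path)
        df.loc[1, "weight"] = -0.5
        df.to_csv(path, index=False)
        with pytest.raises(SurveyDataError, match="nonpositive weight"):
            read_survey(path)

    def test_missing_answers_policy(self, tmp_path):
        rs = self._respondents(4)
        path = tmp_path / "survey.csv"
        write_survey(rs, path)
        df = pd.read_csv(path)
        df.loc[0, "v0"] = np.nan
        df.to_csv(path, index=False)
        kept = read_survey(path, missing="not_seen")
        assert len(kept) == 4 and kept[0].seen["v0"] is False
        dropped = read_survey(path, missing="drop")
        assert len(dropped) == 3
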