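"""The impressions estimator: G = p_bar x N x I, its CIs and identities.

Published-cell comparisons carry a tolerance of one unit in the last
printed decimal place; internal identities are held to machine precision.
"""

import numpy as np
import pytest

from mediareach.content_coding import ContentClass
from mediareach.impressions import (
    aggregate_impressions,
    compute_impressions,
    gross_impressions,
    per_capita,
    video_level_impressions,
)
from mediareach.reference_data import (
    ALCOHOL_INTERVALS,
    PUBLISHED_GROSS,
    PUBLISHED_VIDEO_GROSS,
    TOBACCO_INTERVALS,
)
from mediareach.survey import ADOLESCENTS, ADULTS, ReachEstimate, Stratum


def reach(p, lo=None, hi=None, stratum=ADULTS, se=0.01):
    lo = p if lo is None else lo
    hi = p if hi is None else hi
    return ReachEstimate(stratum, p, se, lo, hi, 100, 95.0)


class TestGrossImpressions:
    def test_zero_reach_gives_zero(self):
        r = gross_impressions(reach(0.0), 49.20, 233)
        assert (r.gross, r.per_capita) == (0.0, 0.0)

    def test_direct_multiplication_of_printed_rounded_inputs(self):
        # 0.06 x 49.20 x 233 = 687.816: differs from the published 695.09
        # because the printed reach 0.06 is itself rounded to 2 dp.
        r = gross_impressions(reach(0.06), 49.20, 233)
        assert r.gross == pytest.approx(0.06 * 49.20 * 233) == pytest.approx(687.816)

    def test_saturation_bound(self):
        r = gross_impressions(reach(1.0), 5.91, 821)
        assert r.gross == pytest.approx(5.91 * 821) == pytest.approx(4852.11)

    def test_zero_intervals_is_valid_zero_result(self):
        r = gross_impressions(reach(0.2), 5.91, 0)
        assert r.gross == 0.0 and r.per_capita == 0.0

    def test_negative_intervals_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gross_impressions(reach(0.2), 5.91, -1)

    def test_per_capita_round_trips_to_p_times_i(self):
        r = gross_impressions(reach(0.2174), 5.91, 233)
        assert per_capita(r.gross, r.population_m) == pytest.approx(0.2174 * 233, rel=1e-15)

    def test_ci_endpoints_scale_linearly(self):
        r = gross_impressions(reach(0.2, 0.15, 0.25), 10.0, 100)
        assert r.gross_ci_low == pytest.approx(0.15 * 1000)
        assert r.gross_ci_high == pytest.approx(0.25 * 1000)
        assert r.pc_ci_low == pytest.approx(15.0)


class TestPerCapita:
    @pytest.mark.parametrize(
        "gross,n,expected",
        [
            (695.09, 49.20, 14.13),   # adults, alcohol
            (202.90, 55.11, 3.68),    # total, tobacco
            (0.0, 49.20, 0.0),
        ],
    )
    def test_published_cells(self, gross, n, expected):
        assert round(per_capita(gross, n), 2) == expected

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            per_capita(100.0, 0.0)


class TestAggregation:
    def _band_results(self, cls="alcohol"):
        out = []
        intervals = ALCOHOL_INTERVALS if cls == "alcohol" else TOBACCO_INTERVALS
        for label in ("11-12", "13-15", "16-18", "19-24", "25-34", "35-44", "45-54", "55+"):
            g, lo, hi = PUBLISHED_GROSS[(label, cls)]
            s = Stratum.parse(label)
            # reconstruct the implied reach from the published gross cell
            from mediareach.reference_data import uk_mid_year_population
            from mediareach.population import population_for

            n = population_for(uk_mid_year_population(), s)
            scale = n * intervals
            out.append(
                gross_impressions(
                    ReachEstimate(s, g / scale, 0.0, lo / scale, hi / scale, 100, 95.0),
                    n,
                    intervals,
                    ContentClass.of(cls),
                )
            )
        return out

    def test_published_age_band_gross_values_sum_to_total(self):
        agg = aggregate_impressions(self._band_results("alcohol"))
        # published Total row 1005.86; band cells carry 2-dp rounding
        assert agg.gross == pytest.approx(1005.86, abs=0.02)
        assert agg.population_m == pytest.approx(55.10, abs=0.02)

    def test_single_stratum_aggregate_is_identity(self):
        r = self._band_results()[0]
        assert aggregate_impressions([r]) is r

    def test_aggregate_per_capita_is_between_constituents(self):
        rs = self._band_results()
        agg = aggregate_impressions(rs)
        pcs = [r.per_capita for r in rs]
        assert min(pcs) <= agg.per_capita <= max(pcs)
        # and equals the population-weighted combination, brute force
        brute = sum(r.gross for r in rs) / sum(r.population_m for r in rs)
        assert agg.per_capita == pytest.approx(brute, rel=1e-15)

    def test_gross_conservation_exact(self):
        rs = self._band_results("tobacco")
        agg = aggregate_impressions(rs)
        assert agg.gross == sum(r.gross for r in rs)
        assert agg.gross_ci_low == sum(r.gross_ci_low for r in rs)

    def test_rss_cis_are_narrower(self):
        rs = self._band_results()
        wide = aggregate_impressions(rs)
        narrow = aggregate_impressions(rs, ci_method="rss")
        assert (narrow.gross_ci_high - narrow.gross_ci_low) < (
            wide.gross_ci_high - wide.gross_ci_low
        )

    def test_mixed_classes_rejected(self):
        a = self._band_results("alcohol")[0]
        t = self._band_results("tobacco")[1]
        with pytest.raises(ValueError, match="content class"):
            aggregate_impressions([a, t])

    def test_overlapping_strata_rejected(self):
        rs = self._band_results()
        with pytest.raises(ValueError, match="overlap"):
            aggregate_impressions([rs[0], rs[0]])


class TestSubstanceRatioIdentity:
    def test_exact_on_any_reach(self):
        r = reach(0.1234, 0.1, 0.15, stratum=ADOLESCENTS)
        alc = gross_impressions(r, 5.91, ALCOHOL_INTERVALS)
        tob = gross_impressions(r, 5.91, TOBACCO_INTERVALS)
        assert tob.gross / alc.gross == pytest.approx(
            TOBACCO_INTERVALS / ALCOHOL_INTERVALS, rel=1e-14
        )

    def test_published_table_conforms_to_4_significant_figures(self):
        for label in ("11-18", "19+"):
            ratio = PUBLISHED_GROSS[(label, "tobacco")][0] / PUBLISHED_GROSS[(label, "alcohol")][0]
            assert ratio == pytest.approx(47 / 233, rel=5e-4)


class TestLinearity:
    def test_scaling_population_and_intervals(self):
        r = reach(0.11, 0.08, 0.14)
        base = gross_impressions(r, 10.0, 50)
        double_n = gross_impressions(r, 20.0, 50)
        double_i = gross_impressions(r, 10.0, 100)
        assert double_n.gross == pytest.approx(2 * base.gross)
        assert double_n.per_capita == pytest.approx(base.per_capita)
        assert double_i.gross == pytest.approx(2 * base.gross)
        assert double_i.per_capita == pytest.approx(2 * base.per_capita)


class TestVideoLevel:
    def test_timber_adolescent_per_capita(self):
        g, lo, hi = PUBLISHED_VIDEO_GROSS["timber"]["adolescent"]
        assert round(per_capita(g, 5.91), 2) == 7.52

    def test_trumpets_adult_per_capita_from_total_minus_adolescent(self):
        total = PUBLISHED_VIDEO_GROSS["trumpets"]["total"][0]
        adol = PUBLISHED_VIDEO_GROSS["trumpets"]["adolescent"][0]
        adult_gross = total - adol
        assert adult_gross == pytest.approx(24.53)
        assert round(per_capita(adult_gross, 49.20), 2) == 0.50

    def test_timber_adult_per_capita(self):
        total = PUBLISHED_VIDEO_GROSS["timber"]["total"][0]
        adol = PUBLISHED_VIDEO_GROSS["timber"]["adolescent"][0]
        assert round(per_capita(total - adol, 49.20), 2) == 2.40

    def test_zero_interval_video_gives_all_zero(self):
        r = video_level_impressions(reach(0.3, 0.2, 0.4), 5.91, 0)
        assert (r.gross, r.gross_ci_high, r.per_capita, r.pc_ci_high) == (0, 0, 0, 0)


class TestEndToEnd:
    def test_pipeline_matches_manual_composition(self, default_scenario):
        scn = default_scenario
        cls = ContentClass.alcohol()
        res = compute_impressions(scn.videos, scn.respondents, scn.population, ADOLESCENTS, cls)
        from mediareach.content_coding import total_content_intervals
        from mediareach.population import population_for
        from mediareach.survey import mean_proportion_viewed

        vids = [v.video_id for v in scn.videos]
        p = mean_proportion_viewed(scn.respondents, vids, ADOLESCENTS).p_bar
        n = population_for(scn.population, ADOLESCENTS)
        i = total_content_intervals(scn.videos, cls)
        assert res.gross == pytest.approx(p * n * i, rel=1e-14)
        assert res.inputs == {"p_bar": p, "N_millions": n, "intervals": i}
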