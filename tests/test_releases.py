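import numpy as np
import pandas as pd
import pytest

import dendropatterns as dp


def series(widths, first_year=1900, tree_id="T1"):
    return dp.RingSeries(tree_id=tree_id, first_year=first_year, widths=np.asarray(widths, float))


def gc_oracle(widths, window=10):
    """Brute-force two-window percent growth change (independent loops)."""
    out = {}
    for t in range(window - 1, len(widths) - window):
        m1 = sum(widths[t - window + 1 : t + 1]) / window
        m2 = sum(widths[t + 1 : t + window + 1]) / window
        out[t] = (m2 - m1) / m1 * 100.0 if m1 > 0 else float("nan")
    return out


class TestPercentGrowthChange:
    def test_constant_series_zero_everywhere(self):
        g = dp.percent_growth_change(series(np.ones(40)))
        np.testing.assert_allclose(g.gc, 0.0)
        assert set(g.classes) == {"none"}

    def test_step_series_hits_fifty_at_step(self):
        g = dp.percent_growth_change(series(np.r_[np.ones(10), np.full(10, 1.5)]))
        # the last year of the first window is the step year
        assert g.years[0] == 1909
        assert g.gc[0] == pytest.approx(50.0)
        assert g.classes[0] == "major_release"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.uniform(0.0, 3.0, int(rng.integers(20, 80)))
            g = dp.percent_growth_change(series(w))
            oracle = gc_oracle(list(w))
            assert len(g.gc) == len(oracle)
            for year, got in zip(g.years, g.gc):
                exp = oracle[year - 1900]
                if np.isnan(exp):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(exp, abs=1e-9)

    def test_zero_first_window_flagged_not_raised(self):
        g = dp.percent_growth_change(series(np.r_[np.zeros(10), np.ones(10)]))
        assert np.isnan(g.gc[0])
        assert g.classes[0] == "undefined"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            dp.percent_growth_change(series(np.ones(19)))

    def test_multiplicative_step_1p6_is_major_release(self):
        g = dp.percent_growth_change(series(np.r_[np.ones(12), np.full(12, 1.6)]))
        step = np.where(g.years == 1911)[0][0]
        assert g.gc[step] == pytest.approx(60.0)
        assert g.classes[step] == "major_release"


class TestClassify:
    @pytest.mark.parametrize(
        "gc,expected",
        [
            (50.0, "major_release"),
            (120.0, "major_release"),
            (49.999, "minor_release"),
            (25.0, "minor_release"),
            (24.999, "none"),
            (10.0, "none"),
            (-24.999, "none"),
            (-25.0, "minor_suppression"),
            (-49.999, "minor_suppression"),
            (-50.0, "major_suppression"),
            (-80.0, "major_suppression"),
            (float("nan"), "undefined"),
        ],
    )
    def test_boundary_mapping(self, gc, expected):
        assert dp.classify_growth_change(gc) == expected

    def test_exactly_one_class_per_value(self):
        rng = np.random.default_rng(1)
        for gc in rng.uniform(-150, 150, 200):
            assert dp.classify_growth_change(gc) in {
                "major_release",
                "minor_release",
                "none",
                "minor_suppression",
                "major_suppression",
            }


class TestSiteChronology:
    def test_single_tree_full_percent(self):
        g = dp.percent_growth_change(series(np.r_[np.ones(10), np.full(10, 2.0)]))
        chron = dp.site_change_chronology([g], site_id="S")
        row = chron.table.set_index("year").loc[1909]
        assert row["pct_major_release"] == 100.0
        assert row["n_trees"] == 1

    def test_two_trees_half_percent(self):
        a = dp.percent_growth_change(series(np.r_[np.ones(10), np.full(10, 2.0)], tree_id="A"))
        b = dp.percent_growth_change(series(np.ones(20), tree_id="B"))
        chron = dp.site_change_chronology([a, b])
        row = chron.table.set_index("year").loc[1909]
        assert row["pct_major_release"] == 50.0

    def test_class_percentages_sum_bounded(self, low_noise_dataset):
        _, all_series, _ = low_noise_dataset
        gc = [dp.percent_growth_change(s) for s in all_series[:60]]
        chron = dp.site_change_chronology(gc)
        four = chron.table[
            [
                "pct_major_release",
                "pct_minor_release",
                "pct_minor_suppression",
                "pct_major_suppression",
            ]
        ].sum(axis=1)
        assert (four <= 100.0 + 1e-9).all()

    def test_release_peaks_align_with_outbreaks(self, low_noise_dataset):
        """Site-level release maxima fall at the scheduled outbreak episodes."""
        _, all_series, _ = low_noise_dataset
        gc = [dp.percent_growth_change(s) for s in all_series]
        chron = dp.site_change_chronology(gc)
        t = chron.table
        for start, end in dp.DEFAULT_OUTBREAK_PERIODS:
            near = t[(t.year >= start - 5) & (t.year <= end + 5)]
            assert near["pct_all_releases"].max() >= 10.0
        quiet = t[(t.year >= 1835) & (t.year <= 1855)]  # before the first episode
        assert quiet["pct_all_releases"].max() < 10.0


class TestLoess:
    def test_constant_reproduced(self):
        x = np.arange(30.0)
        out = dp.loess_smooth(x, np.full(30, 5.0))
        np.testing.assert_allclose(out, 5.0, atol=1e-10)

    def test_line_reproduced(self):
        x = np.arange(40.0)
        y = 2.0 * x - 7.0
        np.testing.assert_allclose(dp.loess_smooth(x, y, degree=1), y, atol=1e-8)
        np.testing.assert_allclose(dp.loess_smooth(x, y, degree=2), y, atol=1e-8)

    def test_matches_direct_wls_oracle(self):
        rng = np.random.default_rng(3)
        x = np.arange(60.0)
        y = np.sin(x / 6) + rng.normal(0, 0.2, 60)
        span, degree = 0.4, 2
        got = dp.loess_smooth(x, y, span=span, degree=degree)
        q = int(np.ceil(span * len(x)))
        for i in range(5, 55):  # interior points
            d = np.abs(x - x[i])
            idx = np.sort(np.argsort(d)[:q])
            w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
            coef = np.polynomial.polynomial.polyfit(
                x[idx] - x[i], y[idx], degree, w=np.sqrt(w)
            )
            assert got[i] == pytest.approx(coef[0], abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            dp.loess_smooth(np.arange(3.0), np.arange(3.0), degree=2)


class TestDetectPeaks:
    def _chron(self, y):
        years = np.arange(1900, 1900 + y.size)
        table = pd.DataFrame(
            {
                "year": years,
                "n_trees": 10,
                "pct_major_release": y / 2,
                "pct_minor_release": y / 2,
                "pct_minor_suppression": 0.0,
                "pct_major_suppression": 0.0,
                "pct_all_releases": y,
                "pct_all_suppressions": 0.0,
            }
        )
        return dp.SiteChronology(site_id="S", table=table)

    def test_flat_curve_no_peaks(self):
        assert dp.detect_release_peaks(self._chron(np.full(100, 3.0)), min_height=5) == []

    def test_two_bumps_forty_years_apart(self):
        x = np.arange(100.0)
        y = 40 * np.exp(-0.5 * ((x - 25) / 5) ** 2) + 35 * np.exp(
            -0.5 * ((x - 65) / 5) ** 2
        )
        peaks = dp.detect_release_peaks(self._chron(y), min_height=10, min_separation=15)
        assert len(peaks) == 2
        assert abs(peaks[0].year - 1925) <= 2
        assert abs(peaks[1].year - 1965) <= 2
        assert peaks[0].start_year <= peaks[0].year <= peaks[0].end_year


class TestPatternSectionFrequencies:
    def _inputs(self):
        w = np.r_[np.full(50, 0.5), np.full(20, 2.0)]  # release at ring 50
        s = series(w, first_year=1900, tree_id="A")
        prof = dp.segment_series(s)
        g = dp.percent_growth_change(s)
        other = np.random.default_rng(1).uniform(0.2, 2.0, 70)
        m = dp.standardize_segment_matrix(
            [prof, dp.segment_series(series(other, tree_id="B"))]
        )
        part = dp.best_kmeans(m, 2, n_restarts=10, seed=0)
        return [g], [prof], part

    def test_single_release_counts_once_per_section(self):
        gcs, profs, part = self._inputs()
        tab = dp.pattern_section_frequencies(gcs, profs, part)
        pat = part.pattern_of()["A"]
        mine = tab[tab.pattern == pat]
        hits = mine[mine["pct_major_release"] > 0]
        assert (hits["pct_major_release"] == 100.0).all()
        # release step at 1949/1950 sits in the middle sections
        assert hits["section"].between(12, 16).all()

    def test_no_events_all_zero(self):
        g = dp.percent_growth_change(series(np.ones(40), tree_id="A"))
        prof = dp.segment_series(series(np.ones(40), tree_id="A"))
        prof_b = dp.segment_series(series(np.linspace(0.5, 1.5, 40), tree_id="B"))
        m = dp.standardize_segment_matrix([prof, prof_b])
        part = dp.best_kmeans(m, 2, n_restarts=10, seed=0)
        tab = dp.pattern_section_frequencies([g], [prof], part)
        assert (tab.filter(like="pct_").to_numpy() == 0).all()

    def test_missing_tree_rejected(self):
        gcs, profs, part = self._inputs()
        stray = dp.percent_growth_change(series(np.ones(30), tree_id="ZZ"))
        with pytest.raises(ValueError, match="ZZ"):
            dp.pattern_section_frequencies(gcs + [stray], profs, part)

    def test_ascending_trees_release_late_suppress_early(self, low_noise_dataset, low_noise_matrix):
        _, all_series, truth = low_noise_dataset
        profiles, m = low_noise_matrix
        part = dp.name_patterns(dp.best_kmeans(m, 9, n_restarts=200, seed=3), m)
        gcs = [dp.percent_growth_change(s) for s in all_series]
        tab = dp.pattern_section_frequencies(gcs, profiles, part)
        asc = tab[tab.pattern.str.endswith("ascending")]
        early = asc[asc.section <= 10]
        late = asc[asc.section > 10]
        assert late["pct_major_release"].sum() > early["pct_major_release"].sum()
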