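"""The response-fitting pipeline: aggregation, screening, binning, NLS."""

import numpy as np
import pandas as pd
import pytest

from ringdemog.fitting import (
    BinnedMeans,
    FittingConfig,
    FittingError,
    bin_and_average,
    best_month_window,
    default_window_candidates,
    fit_best,
    fit_density_response,
    fit_range,
    make_pairs,
    remove_outliers,
    remove_outliers_per_site,
    site_annual_aggregate,
)
from ringdemog.response import DensityResponse, SiteConfig, evaluate_lwd
from ringdemog.synth import DEFAULT_RESPONSE, derive_seed, gen_climate, gen_lwd_dataset, gen_site_gradient


def _tree_table(rows):
    return pd.DataFrame(rows, columns=["site_id", "tree_id", "year", "lwd_kgC_m3"])


class TestSiteAnnualAggregate:
    def test_single_tree_passthrough(self):
        df = _tree_table([("s", "t1", 2000, 250.0), ("s", "t1", 2001, 260.0)])
        out = site_annual_aggregate(df)
        assert out["lwd"].tolist() == [250.0, 260.0]

    def test_mean_over_trees(self):
        df = _tree_table([("s", "t1", 2000, 100.0), ("s", "t2", 2000, 200.0)])
        assert site_annual_aggregate(df)["lwd"].tolist() == [150.0]

    def test_missing_tree_year_ignored(self):
        df = _tree_table(
            [("s", "t1", 2000, 100.0), ("s", "t2", 2000, 200.0), ("s", "t1", 2001, 300.0)]
        )
        out = site_annual_aggregate(df).set_index("year")["lwd"]
        assert out.loc[2001] == 300.0

    def test_empty_rejected(self):
        with pytest.raises(FittingError):
            site_annual_aggregate(_tree_table([]))


class TestRemoveOutliers:
    def test_constant_series_unchanged(self):
        x = np.full(10, 7.0)
        assert np.array_equal(remove_outliers(x), x)

    def test_single_spike_small_sample_is_boundary(self):
        # one deviant among nine equal values: |z| is exactly 3 with the
        # population sd, whatever the spike size, so the strict rule keeps it
        for spike in (60.0, 61.0, 1e6):
            x = np.array([10.0] * 9 + [spike])
            z = abs(spike - x.mean()) / x.std()
            assert z == pytest.approx(3.0)
            assert len(remove_outliers(x)) == 10

    def test_spike_in_larger_sample_removed(self):
        x = np.array([10.0] * 19 + [60.0])
        z = abs(60.0 - x.mean()) / x.std()
        assert z > 3.0  # brute-force oracle for the cut decision
        out = remove_outliers(x)
        assert len(out) == 19 and 60.0 not in out

    def test_all_within_threshold_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        x = x[np.abs(x - x.mean()) / x.std() <= 3.0]  # oracle pre-filter
        assert np.array_equal(remove_outliers(x.copy()), x)

    def test_idempotent_away_from_boundary(self):
        x = np.array([10.0] * 19 + [60.0])
        once = remove_outliers(x)
        assert np.array_equal(remove_outliers(once), once)

    def test_too_short_rejected(self):
        with pytest.raises(FittingError):
            remove_outliers([1.0])

    def test_per_site_screening_is_independent(self):
        df = pd.DataFrame(
            {
                "site_id": ["a"] * 20 + ["b"] * 3,
                "year": list(range(20)) + [0, 1, 2],
                "lwd": [10.0] * 19 + [60.0] + [100.0, 101.0, 102.0],
            }
        )
        out = remove_outliers_per_site(df)
        assert len(out[out.site_id == "a"]) == 19
        assert len(out[out.site_id == "b"]) == 3


class TestBinning:
    def test_single_pair_single_bin(self):
        b = bin_and_average(pd.DataFrame({"t_window": [10.2], "lwd": [250.0]}))
        assert len(b) == 1 and b.mean_lwd[0] == 250.0 and b.bin_centers[0] == pytest.approx(10.25)

    def test_same_half_open_bin(self):
        b = bin_and_average(pd.DataFrame({"t_window": [10.1, 10.4], "lwd": [100.0, 200.0]}))
        assert len(b) == 1 and b.mean_lwd[0] == 150.0

    def test_half_open_boundary_splits(self):
        b = bin_and_average(pd.DataFrame({"t_window": [10.49, 10.50], "lwd": [1.0, 2.0]}))
        assert len(b) == 2
        assert b.bin_centers.tolist() == pytest.approx([10.25, 10.75])


class TestBestMonthWindow:
    def test_recovers_generating_window(self):
        site = SiteConfig("s", 11.5)
        clim = gen_climate(site, 200, seed=8)
        jas = clim.jas_series()
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "site_id": "s",
                "year": jas.index,
                "lwd": 20.0 * jas.to_numpy() + rng.normal(0, 3.0, len(jas)),
            }
        )
        window, r2 = best_month_window(df, clim)
        assert window == (7, 8, 9)
        assert r2 > 0.5

    def test_independent_density_gives_near_zero_r2(self):
        site = SiteConfig("s", 11.5)
        clim = gen_climate(site, 500, seed=8)
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"site_id": "s", "year": clim.years, "lwd": rng.normal(250, 10, clim.n_years)}
        )
        _, r2 = best_month_window(df, clim)
        assert r2 < 0.05

    def test_single_candidate_returned(self):
        site = SiteConfig("s", 11.5)
        clim = gen_climate(site, 50, seed=8)
        df = pd.DataFrame({"site_id": "s", "year": clim.years, "lwd": np.linspace(200, 300, 50)})
        cfg = FittingConfig(window_candidates=((5, 6),))
        window, _ = best_month_window(df, clim, cfg)
        assert window == (5, 6)

    def test_no_overlap_rejected(self):
        site = SiteConfig("s", 11.5)
        clim = gen_climate(site, 50, seed=8, start_year=0)
        df = pd.DataFrame({"site_id": "s", "year": [999], "lwd": [250.0]})
        with pytest.raises(FittingError):
            best_month_window(df, clim)

    def test_window_candidates_default_span(self):
        wins = default_window_candidates()
        assert (7, 8, 9) in wins
        assert all(4 <= w[0] and w[-1] <= 10 and len(w) <= 4 for w in wins)


def _binned_from_curve(resp, t, noise=None):
    y = evaluate_lwd(t, resp)
    if noise is not None:
        y = y + noise
    return BinnedMeans(t, y, np.ones_like(t, dtype=int), 0.5)


class TestFitBest:
    TRUE = DensityResponse(a=100.0, b=300.0, c=0.8, d=12.0)

    def test_noiseless_self_consistency(self):
        t = np.arange(4.25, 20.25, 0.5)
        res = fit_best(_binned_from_curve(self.TRUE, t))
        r = res.response
        for name in ("a", "b", "c", "d"):
            assert getattr(r, name) == pytest.approx(getattr(self.TRUE, name), rel=1e-4)
        assert res.n_converged > 0

    def test_matches_independent_nls_oracle(self):
        # same fixture fitted with R's minpack.lm::nlsLM (start a=240,b=340,c=1,d=11):
        #   a=237.381208107909 b=350.903019006822 c=0.775915960715 d=11.386738119694
        #   sse=687.39668399
        t = np.arange(5.25, 18.25, 0.5)
        rng = np.random.default_rng(12345)
        y = 240.0 + 110.0 / (1.0 + np.exp(-0.8 * (t - 11.5))) + rng.normal(0, 5.0, t.size)
        res = fit_best(BinnedMeans(t, y, np.ones_like(t, int), 0.5))
        r = res.response
        assert r.a == pytest.approx(237.381208107909, rel=1e-4)
        assert r.b == pytest.approx(350.903019006822, rel=1e-4)
        assert r.c == pytest.approx(0.775915960715, rel=1e-3)
        assert r.d == pytest.approx(11.386738119694, rel=1e-4)
        assert res.sse == pytest.approx(687.39668399, rel=1e-6)

    def test_flat_data_rejected_as_degenerate(self):
        t = np.arange(4.25, 20.25, 0.5)
        with pytest.raises(FittingError):
            fit_best(BinnedMeans(t, np.full_like(t, 200.0), np.ones_like(t, int), 0.5))

    def test_too_few_bins_rejected(self):
        t = np.array([10.25, 10.75, 11.25, 11.75])
        with pytest.raises(FittingError):
            fit_best(_binned_from_curve(self.TRUE, t))


class TestFitRange:
    TRUE = DensityResponse(a=100.0, b=300.0, c=0.8, d=12.0)

    def _pairs_and_bins(self, lo, hi):
        t = np.arange(4.25, 20.25, 0.5)
        binned = _binned_from_curve(self.TRUE, t)
        pairs = pd.DataFrame({"t_window": t, "lwd": np.clip(evaluate_lwd(t, self.TRUE), lo, hi)})
        return pairs, binned

    def test_midpoint_copied_exactly(self):
        pairs, binned = self._pairs_and_bins(-np.inf, np.inf)
        best = fit_best(binned).response
        rng_resp = fit_range(pairs, best, binned)
        assert rng_resp.d == best.d
        assert rng_resp.label == "range"

    def test_wider_observations_stretch_asymptotes(self):
        t = np.arange(4.25, 20.25, 0.5)
        binned = _binned_from_curve(self.TRUE, t)
        best = fit_best(binned).response
        pairs = pd.DataFrame({"t_window": [5.0, 15.0], "lwd": [60.0, 340.0]})
        out = fit_range(pairs, best, binned)
        assert out.a < best.a and out.b > best.b
        # asymptote span covers the rounded observed span
        assert out.a <= 60.0 and out.b >= 340.0

    def test_degenerate_range_rejected(self):
        t = np.arange(4.25, 20.25, 0.5)
        binned = _binned_from_curve(self.TRUE, t)
        best = fit_best(binned).response
        pairs = pd.DataFrame({"t_window": [10.0, 11.0], "lwd": [200.0, 200.2]})
        with pytest.raises(FittingError):
            fit_range(pairs, best, binned)


class TestPipeline:
    def test_end_to_end_recovers_generating_response(self):
        grad = gen_site_gradient()
        frames, clims = [], {}
        for i, site in enumerate(grad):
            clim = gen_climate(site, 99, seed=derive_seed(3, i), start_year=1901)
            clims[site.site_id] = clim
            frames.append(gen_lwd_dataset(DEFAULT_RESPONSE, clim, n_trees=10, noise_sd=10.0, seed=derive_seed(3, i, 1)))
        report = fit_density_response(pd.concat(frames, ignore_index=True), clims, window=(7, 8, 9))
        best = report["best"]
        assert abs(best.d - DEFAULT_RESPONSE.d) < 0.5
        assert abs(best.b - DEFAULT_RESPONSE.b) / DEFAULT_RESPONSE.b < 0.05
        # range variant spans at least the best-fit asymptotes' data range
        assert report["range"].a <= report["best"].a + 1e-9 or report["range"].b >= report["best"].b - 1e-9

    def test_lapse_adjustment_shifts_pairs(self):
        site = SiteConfig("s", 11.5, elevation_site=1100.0, elevation_ref=1000.0)
        clim = gen_climate(site, 30, seed=4)
        density = pd.DataFrame({"site_id": "s", "year": clim.years, "lwd": np.linspace(250, 300, 30)})
        plain = make_pairs(density, clim, (7, 8, 9))
        adjusted = make_pairs(density, clim, (7, 8, 9), {"s": site})
        assert np.allclose(adjusted["t_window"], plain["t_window"] - 0.649)
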