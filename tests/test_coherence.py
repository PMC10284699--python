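import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watercarbon.containers import AnnualSeries, CoherenceSeries, DegenerateInputError
from watercarbon.coherence import (
    coherence_fraction,
    period_coherence,
    subset_coupling,
    yearly_coherence,
)

from conftest import make_yearly_field


def pairwise_yearly_oracle(x, weights=None):
    """Explicit double loop over cell pairs for one year's map."""
    x = np.asarray(x, dtype=float)
    if weights is not None:
        x = x * weights
    num = den = 0.0
    for i in range(x.size):
        for j in range(x.size):
            if i == j:
                continue
            num += x[i] * x[j]
            den += abs(x[i] * x[j])
    return 100.0 * num / den


def pairwise_period_oracle(data):
    """Explicit double loop over cell-pair covariances, (years, cells)."""
    n, m = data.shape
    c = np.cov(data.T, ddof=1)
    num = den = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            num += c[i, j]
            den += abs(c[i, j])
    return 100.0 * num / den


class TestYearlyCoherence:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ([1.0, 1.0], 100.0),
            ([1.0, -1.0], -100.0),
            # pairwise products 2*(2*1) + 2*(2*-1) + 2*(1*-1) = -2 over 10
            ([2.0, 1.0, -1.0], -20.0),
        ],
    )
    def test_closed_form_examples(self, cells, expected):
        field = make_yearly_field(
            np.array(cells)[None, None, :], lat=np.array([0.0]),
            lon=np.arange(len(cells), dtype=float),
        )
        cs = yearly_coherence(field)
        assert cs.coherence[0] == pytest.approx(expected, abs=1e-12)

    def test_single_nonzero_cell_year_invalid(self):
        field = make_yearly_field(
            np.array([[[1.0, 0.0, 0.0]]]), lat=np.array([0.0]),
            lon=np.arange(3.0),
        )
        cs = yearly_coherence(field)
        assert not cs.valid[0]

    def test_matches_pairwise_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.standard_normal((1, 3, 4))
            cs = yearly_coherence(make_yearly_field(vals))
            oracle = pairwise_yearly_oracle(vals.ravel())
            assert cs.coherence[0] == pytest.approx(oracle, abs=1e-10)

    def test_area_weighting_matches_weighted_oracle(self):
        rng = np.random.default_rng(1)
        lat = np.array([-60.0, 0.0, 60.0])
        vals = rng.standard_normal((1, 3, 4))
        cs = yearly_coherence(make_yearly_field(vals, lat=lat), area_weighted=True)
        w = np.repeat(np.cos(np.deg2rad(lat)), 4)
        assert cs.coherence[0] == pytest.approx(
            pairwise_yearly_oracle(vals.ravel(), w), abs=1e-10
        )

    @given(st.floats(0.1, 100.0), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_and_sign_flip_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((4, 3, 3))
        base = yearly_coherence(make_yearly_field(vals)).coherence
        scaled = yearly_coherence(make_yearly_field(scale * vals)).coherence
        flipped = yearly_coherence(make_yearly_field(-vals)).coherence
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        np.testing.assert_allclose(flipped, base, atol=1e-9)
        assert np.all(np.abs(base) <= 100.0 + 1e-9)

    def test_tercile_bins_partition_valid_years(self):
        rng = np.random.default_rng(2)
        cs = yearly_coherence(make_yearly_field(rng.standard_normal((30, 4, 4))))
        counts = {b: int((cs.bins == b).sum()) for b in ("LOW", "MEDIUM", "HIGH")}
        assert sum(counts.values()) == int(cs.valid.sum())
        assert max(counts.values()) - min(counts.values()) <= 1


class TestPeriodCoherence:
    def test_identical_series_everywhere_is_100(self):
        rng = np.random.default_rng(3)
        shared = rng.standard_normal(20)
        vals = np.tile(shared[:, None, None], (1, 10, 10))
        assert period_coherence(make_yearly_field(vals)) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_two_cell_antiphase_is_minus_100(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(8)
        vals = np.stack([s, -s], axis=1)[:, None, :]
        field = make_yearly_field(vals, lat=np.array([0.0]), lon=np.array([0.0, 1.0]))
        assert period_coherence(field) == pytest.approx(-100.0, abs=1e-9)

    def test_blockwise_equals_pairwise_loop(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((6, 1, 5))
        field = make_yearly_field(vals, lat=np.array([0.0]), lon=np.arange(5.0))
        mine = period_coherence(field, block_size=2)
        oracle = pairwise_period_oracle(vals.reshape(6, 5))
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_rank_one_field_matches_yearly_value_of_pattern(self):
        # field = a_t * x: covariances are var(a) * x_i x_j, so the period
        # coherence equals the single-map pairwise statistic of x
        rng = np.random.default_rng(6)
        x = rng.standard_normal(12)
        a = rng.standard_normal(9)
        vals = np.einsum("t,c->tc", a, x).reshape(9, 3, 4)
        field = make_yearly_field(vals)
        assert period_coherence(field) == pytest.approx(
            pairwise_yearly_oracle(x), abs=1e-9
        )

    def test_window_restriction(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((10, 2, 3))
        field = make_yearly_field(vals, years=np.arange(2000, 2010))
        full = period_coherence(field)
        sub = period_coherence(field, window=(2000, 2005))
        oracle = pairwise_period_oracle(vals[:6].reshape(6, 6))
        assert sub == pytest.approx(oracle, abs=1e-10)
        assert sub != pytest.approx(full)

    def test_degenerate_inputs_raise(self):
        flat = make_yearly_field(np.ones((5, 2, 2)))
        with pytest.raises(DegenerateInputError):
            period_coherence(flat)  # zero covariance everywhere
        short = make_yearly_field(np.random.default_rng(0).standard_normal((2, 2, 2)))
        with pytest.raises(DegenerateInputError):
            period_coherence(short)


class TestFractionsAndSubsets:
    def _cs(self, bins, years=None):
        bins = np.asarray(bins, dtype=str)
        years = np.arange(2000, 2000 + bins.size) if years is None else years
        return CoherenceSeries(
            years, np.linspace(-50, 90, bins.size), bins,
            np.ones(bins.size, bool),
        )

    def test_all_high_gives_one(self):
        cs = self._cs(["HIGH"] * 6)
        assert coherence_fraction(cs, (2000, 2005)) == 1.0

    def test_whole_record_fraction_is_a_third(self):
        rng = np.random.default_rng(8)
        cs = yearly_coherence(make_yearly_field(rng.standard_normal((30, 4, 4))))
        frac = coherence_fraction(cs, (int(cs.years.min()), int(cs.years.max())))
        assert frac == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            coherence_fraction(self._cs(["LOW"] * 4), (1900, 1910))

    def test_coupling_only_in_high_coherence_years(self):
        # inject a strong water-CGR relation in HIGH years only
        rng = np.random.default_rng(9)
        n = 60
        years = np.arange(1960, 1960 + n)
        bins = np.array((["LOW", "MEDIUM", "HIGH"] * (n // 3)))
        ws = rng.standard_normal(n)
        cgr = np.where(bins == "HIGH", -3.0 * ws, 0.0) + 0.3 * rng.standard_normal(n)
        cs = CoherenceSeries(years, np.zeros(n), bins, np.ones(n, bool))
        df = subset_coupling(
            cs,
            AnnualSeries(years, cgr),
            AnnualSeries(years, ws),
            AnnualSeries(years, rng.standard_normal(n)),
        )
        r_by_bin = dict(zip(df["bin"], df["r_ws_cgr"]))
        assert r_by_bin["HIGH"] < -0.9
        assert abs(r_by_bin["LOW"]) < 0.5
        assert bool(df.set_index("bin").loc["HIGH", "significant_05"])

    def test_small_bin_reported_undefined(self):
        years = np.arange(2000, 2010)
        bins = np.array(["HIGH"] * 8 + ["LOW"] * 2)
        cs = CoherenceSeries(years, np.zeros(10), bins, np.ones(10, bool))
        rng = np.random.default_rng(10)
        s = lambda: AnnualSeries(years, rng.standard_normal(10))
        df = subset_coupling(cs, s(), s(), s()).set_index("bin")
        assert np.isnan(df.loc["LOW", "r_ws_cgr"])
        assert np.isfinite(df.loc["HIGH", "r_ws_cgr"])
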