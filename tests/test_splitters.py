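"""Splitter unit and property tests: plotting positions, Tukey hinges,
fences, the Q-Q regression cutoff, and the shared strict-above convention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import popsplit as ps


def normal_scores(n):
    return norm.ppf((np.arange(1, n + 1) - 0.5) / n)


class TestQQPoints:
    def test_large_n_plotting_positions(self):
        qq = ps.qq_points(np.arange(2000.0))
        # rank 1000 of 2000 -> position (1000 - 0.5)/2000
        assert norm.cdf(qq.theor_quantiles[999]) == pytest.approx(0.49975)

    def test_median_rank_maps_near_zero(self):
        qq = ps.qq_points(np.arange(2001.0))
        assert qq.theor_quantiles[1000] == pytest.approx(0.0, abs=1e-12)

    def test_small_n_blom_positions(self):
        qq = ps.qq_points([5, 3, 4])
        positions = norm.cdf(qq.theor_quantiles)
        np.testing.assert_allclose(positions, [0.625 / 3.25, 0.5, 2.625 / 3.25])
        np.testing.assert_array_equal(qq.sorted_values, [3, 4, 5])

    @pytest.mark.parametrize("bad", [[1.0], [1.0, np.inf]])
    def test_rejects_degenerate_input(self, bad):
        with pytest.raises(ValueError):
            ps.qq_points(bad)


class TestTukeyHinges:
    @pytest.mark.parametrize(
        "data, expected",
        [
            ([1, 2, 3, 4, 5], (1, 2, 3, 4, 5)),
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], (1, 3, 5.5, 8, 100)),
            ([7, 7, 7, 7], (7, 7, 7, 7, 7)),
        ],
    )
    def test_hand_computed_summaries(self, data, expected):
        fns = ps.tukey_hinges(data)
        got = (fns.min, fns.hinge_lower, fns.median, fns.hinge_upper, fns.max)
        assert got == pytest.approx(expected)

    def test_matches_reference_fivenum(self, rng):
        # cross-check against R's fivenum() hinge formula on random data
        for n in (5, 6, 21, 100):
            x = np.sort(rng.normal(size=n))
            n4 = np.floor((n + 3) / 2) / 2
            d = np.array([1, n4, (n + 1) / 2, n + 1 - n4, n])
            ref = 0.5 * (x[np.floor(d).astype(int) - 1] + x[np.ceil(d).astype(int) - 1])
            fns = ps.tukey_hinges(x)
            np.testing.assert_allclose(
                [fns.min, fns.hinge_lower, fns.median, fns.hinge_upper, fns.max], ref
            )


class TestBoxplotSplit:
    def test_hand_computed_fence(self):
        r = ps.split_boxplot([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], k=1.5)
        assert r.cutoff == pytest.approx(8 + 1.5 * 5)
        assert r.small_pct == pytest.approx(10.0)
        assert r.n_small == 1

    def test_constant_data_yields_empty_small_population(self):
        r = ps.split_boxplot([7.0] * 50, k=1.5)
        assert r.iqr == 0
        assert r.cutoff == pytest.approx(7.0)
        assert r.small_pct == 0.0  # ties go to the large subpopulation

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="too few cells"):
            ps.split_boxplot([1, 2, 3], k=1.5)

    def test_fence_ordering(self, table2_values):
        mild = ps.split_boxplot(table2_values, k=1.5)
        extreme = ps.split_boxplot(table2_values, k=3.0)
        assert extreme.cutoff >= mild.cutoff
        assert extreme.small_pct <= mild.small_pct


class TestManualSplit:
    @pytest.mark.parametrize(
        "cutoff, expected_pct",
        [(2.5, 50.0), (0.0, 100.0), (4.0, 0.0)],  # mid / below min / at max (tie)
    )
    def test_cutoff_conventions(self, cutoff, expected_pct):
        r = ps.split_manual([1, 2, 3, 4], cutoff=cutoff)
        assert r.small_pct == pytest.approx(expected_pct)
        assert r.cutoff == cutoff


class TestDefaultSplit:
    def test_exact_normal_scores_give_half_percent(self):
        # a sample that IS its own theoretical quantiles: slope 1, median 0,
        # cutoff z(0.995); exactly the 10 of 2000 positions beyond 0.995 exceed it
        r = ps.split_default(normal_scores(2000))
        assert r.slope == pytest.approx(1.0, abs=1e-9)
        assert r.median_large == pytest.approx(0.0, abs=1e-12)
        assert r.cutoff == pytest.approx(norm.ppf(0.995), abs=1e-9)
        assert r.n_small == 10
        assert r.small_pct == pytest.approx(0.5)

    def test_affine_transform_preserves_split(self):
        base = normal_scores(2000)
        r0 = ps.split_default(base)
        r1 = ps.split_default(5.0 + 2.5 * base)
        assert r1.small_pct == pytest.approx(r0.small_pct)
        assert r1.cutoff == pytest.approx(5.0 + 2.5 * r0.cutoff)
        assert r1.slope == pytest.approx(2.5 * r0.slope)

    def test_explicit_region_matches_figure_workflow(self, table2_values):
        r = ps.split_default(table2_values, region=(58.0, 68.0))
        assert 3.9 * 0.8 < r.slope < 3.9 * 1.2  # recovers the large-component SD
        assert r.method == "default"

    def test_region_too_small(self):
        vals = np.concatenate([np.zeros(15), np.ones(15)])
        with pytest.raises(ValueError, match="regression region too small"):
            ps.split_default(vals, region=(0.4, 0.6))

    def test_degenerate_regression(self):
        vals = np.concatenate([np.zeros(30), np.linspace(10, 11, 30)])
        with pytest.raises(ValueError, match="degenerate regression"):
            ps.split_default(vals, region=(-0.5, 0.5))

    def test_needs_twenty_values(self):
        with pytest.raises(ValueError):
            ps.split_default(np.arange(19.0))


class TestSharedContracts:
    @pytest.mark.parametrize("method, params", [
        ("boxplot1.5", {}),
        ("boxplot3", {}),
        ("manual", {"cutoff": 70.0}),
        ("default", {}),
    ])
    def test_mask_is_strictly_above_cutoff(self, table2_values, method, params):
        r = ps.split(table2_values, method, **params)
        brute = int(np.sum(table2_values > r.cutoff))
        assert r.n_small == brute
        assert r.small_pct == pytest.approx(100.0 * brute / r.n_total)
        np.testing.assert_array_equal(r.small_mask, table2_values > r.cutoff)

    def test_unknown_method(self, table2_values):
        with pytest.raises(ValueError, match="unknown method"):
            ps.split(table2_values, "em-mixture")

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(-1000, 1000),
        b=st.floats(0.01, 100),
        seed=st.integers(0, 2**16),
    )
    def test_translation_scale_equivariance(self, a, b, seed):
        spec = ps.MixtureSpec(n_total=400, small_pct_true=3.0, seed=seed)
        x, _ = ps.simulate_mixture(spec)
        for method, params in [("boxplot1.5", {}), ("boxplot3", {}),
                               ("default", {}), ("manual", {"cutoff": 80.0})]:
            p2 = dict(params)
            if method == "manual":
                p2["cutoff"] = a + b * params["cutoff"]
            r0 = ps.split(x, method, **params)
            r1 = ps.split(a + b * x, method, **p2)
            assert r1.small_pct == pytest.approx(r0.small_pct)
            assert r1.cutoff == pytest.approx(a + b * r0.cutoff, rel=1e-9, abs=1e-6)

    def test_serialization_roundtrip(self, table2_values):
        import json
        d = ps.split_boxplot(table2_values, k=3.0).to_dict()
        again = json.loads(json.dumps(d))
        assert again["method"] == "boxplot3"
        assert set(again) >= {"cutoff", "small_pct", "n_total", "n_small", "q1", "q3", "iqr"}
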