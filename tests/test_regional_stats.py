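from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from conftest import make_test_cube
from paleocvd.occupations import Occupation
from paleocvd.regional_stats import (
    EAST_BOX,
    NORTHWEST_BOX,
    ansari_bradley,
    background_resample,
    coef_variation,
    compare_regions,
    mann_whitney,
    sensitivity_permutation,
)

# ---------------------------------------------------------------------------
# brute-force permutation oracles (independent of scipy internals)


def _mw_u(a, b):
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def mw_enumeration_p(a, b):
    pooled = np.concatenate([a, b])
    n1 = len(a)
    us = np.array(
        [
            _mw_u(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in combinations(range(len(pooled)), n1)
        ]
    )
    u = _mw_u(a, b)
    return min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))


def _ab_score(a, b):
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    return float(np.minimum(ranks, n + 1 - ranks)[: len(a)].sum())


def ab_enumeration_p(a, b):
    pooled = np.concatenate([a, b])
    n1 = len(a)
    sts = np.array(
        [
            _ab_score(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in combinations(range(len(pooled)), n1)
        ]
    )
    obs = _ab_score(a, b)
    return min(1.0, 2 * min((sts <= obs).mean(), (sts >= obs).mean()))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=4) + 0.5
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(
            mw_enumeration_p(a, b), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_tied_large_uses_approximation(self):
        rng = np.random.default_rng(3)
        a = np.round(rng.normal(size=30))
        b = np.round(rng.normal(size=30))
        res = mann_whitney(a, b)
        assert 0.0 <= res.p_value <= 1.0


class TestAnsariBradley:
    def test_identical_samples_p_one(self):
        res = ansari_bradley([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.normal(size=4), rng.normal(size=4) * 2
        res = ansari_bradley(a, b)
        assert res.p_value == pytest.approx(
            ab_enumeration_p(a, b), abs=1e-12
        )

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            ansari_bradley([1.0], [1.0, 2.0])

    def test_scale_difference_power(self):
        detections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=30)
            b = 10.0 * (rng.normal(size=30))
            if ansari_bradley(a, b).p_value < 0.05:
                detections += 1
        assert detections / 200 >= 0.95


class TestCoefVariation:
    def test_constant_zero(self):
        assert coef_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed(self):
        # {10, 20}: mean 15, sample sd = sqrt(50)
        assert coef_variation([10.0, 20.0]) == pytest.approx(
            100.0 * np.sqrt(50.0) / 15.0
        )

    def test_scale_invariant(self):
        v = [3.0, 9.0, 4.0]
        assert coef_variation(np.array(v) * 7.0) == pytest.approx(
            coef_variation(v)
        )

    def test_zero_mean_error(self):
        with pytest.raises(ValueError, match="zero-mean"):
            coef_variation([-1.0, 1.0])


def test_compare_regions_dispatch():
    data = {"EAST": [1.0, 2.0, 3.0], "NORTHWEST": [4.0, 5.0, 6.0]}
    res = compare_regions(data, test="MANN_WHITNEY")
    assert res.p_value == pytest.approx(0.1)
    with pytest.raises(ValueError):
        compare_regions({"EAST": [1.0]})


# ---------------------------------------------------------------------------
# resampling procedures


def _occ(i, region, lon, lat, lo, hi):
    return Occupation(
        site_id=f"{region[:2]}{i:02d}", layer_id="L1", region=region,
        lon=lon, lat=lat, age_min=lo, age_max=hi, age_mid=(lo + hi) / 2,
    )


@pytest.fixture
def noise_cube():
    """8x8 all-land white-noise cube, 200 slices, variable 'v'."""
    rng = np.random.default_rng(99)
    vals = rng.normal(size=(200, 8, 8))
    return make_test_cube({"v": vals}, np.ones((8, 8), bool), lon0=0.0,
                          lat0=0.0)


@pytest.fixture
def null_occs():
    """Occupations at well-separated cells, same generating distribution."""
    occs = []
    spots = [(0, 0), (0, 3), (0, 6), (3, 0), (3, 3), (3, 6), (6, 0), (6, 3)]
    for i, (r, c) in enumerate(spots):
        region = "EAST" if i % 2 == 0 else "NORTHWEST"
        occs.append(_occ(i, region, float(c), float(r), 20.0 + i, 80.0 + i))
    return occs


class TestSensitivity:
    def test_constant_cube_reproduces_mid(self, null_occs):
        vals = np.zeros((200, 8, 8))
        for i in range(8):
            vals[:, :, i] = i  # varies in space, constant in time
        cube = make_test_cube({"v": vals}, np.ones((8, 8), bool), lon0=0.0,
                              lat0=0.0)
        res = sensitivity_permutation(
            null_occs, cube, "v", n_iter=50, seed=0
        )
        np.testing.assert_allclose(res.statistics, res.mid_age_statistic)
        np.testing.assert_allclose(res.p_values, res.mid_age_p)
        assert res.percentile_of_mid_statistic == pytest.approx(50.0)

    def test_deterministic_under_seed(self, noise_cube, null_occs):
        r1 = sensitivity_permutation(null_occs, noise_cube, "v", n_iter=40,
                                     seed=7)
        r2 = sensitivity_permutation(null_occs, noise_cube, "v", n_iter=40,
                                     seed=7)
        np.testing.assert_array_equal(r1.statistics, r2.statistics)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)

    def test_input_order_invariant(self, noise_cube, null_occs):
        r1 = sensitivity_permutation(null_occs, noise_cube, "v", n_iter=40,
                                     seed=7)
        r2 = sensitivity_permutation(null_occs[::-1], noise_cube, "v",
                                     n_iter=40, seed=7)
        np.testing.assert_array_equal(r1.statistics, r2.statistics)

    def test_null_calibration(self, noise_cube, null_occs):
        res = sensitivity_permutation(null_occs, noise_cube, "v",
                                      n_iter=400, seed=11)
        assert res.n_significant / 400 <= 0.10


class TestBackground:
    def test_default_region_boxes(self):
        assert EAST_BOX == (30.0, 55.0, -9.0, 20.0)
        assert NORTHWEST_BOX == (-15.0, 35.0, 18.0, 39.0)

    def test_no_land_is_error(self, noise_cube):
        noise_cube.land_mask[:4, :4] = False
        with pytest.raises(ValueError, match="no land"):
            background_resample(
                noise_cube, (0.0, 2.9, 0.0, 2.9), [1.0, 2.0, 3.0], 0, 199,
                variable="v", n_iter=10, seed=0,
            )

    def test_null_calibration(self, noise_cube):
        from paleocvd.extraction import buffered_series

        rng = np.random.default_rng(5)
        sig = total = 0
        box = (0.0, 7.0, 0.0, 7.0)
        for draw in range(8):
            # observed drawn by the background mechanism itself
            cells = rng.integers(0, 8, size=(30, 2))
            ts = rng.integers(0, 200, size=30)
            obs = np.array(
                [
                    buffered_series(noise_cube, "v", r, c)[t]
                    for (r, c), t in zip(cells, ts)
                ]
            )
            res = background_resample(
                noise_cube, box, obs, 0, 199, variable="v", n_iter=50,
                seed=300 + draw,
            )
            sig += res.n_significant
            total += res.n_iter
        assert 0.0 <= sig / total <= 0.10

    def test_shifted_observed_detected(self, noise_cube):
        obs = np.random.default_rng(8).normal(size=30) + 5.0
        res = background_resample(
            noise_cube, (0.0, 7.0, 0.0, 7.0), obs, 0, 199, variable="v",
            n_iter=200, seed=2,
        )
        assert res.n_significant / 200 >= 0.95
        assert res.summary_direction == 1

    def test_deterministic_under_seed(self, noise_cube):
        obs = np.random.default_rng(9).normal(size=20)
        kwargs = dict(variable="v", n_iter=50, seed=13)
        r1 = background_resample(noise_cube, (0.0, 7.0, 0.0, 7.0), obs, 0,
                                 199, **kwargs)
        r2 = background_resample(noise_cube, (0.0, 7.0, 0.0, 7.0), obs, 0,
                                 199, **kwargs)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        np.testing.assert_array_equal(r1.directions, r2.directions)
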