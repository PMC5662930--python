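import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _bruteforce as bf
import rootzones as rz
from rootzones import posterior
from rootzones.costs import linear_cost_matrix
from rootzones.dp import credible_interval

from conftest import random_small_profile


def case(seed, T=10, min_len=2):
    rng = np.random.default_rng(seed)
    profile = random_small_profile(rng, T)
    cost = linear_cost_matrix(profile.positions, profile.lengths, min_len)
    return profile, cost


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("n_zones", [2, 3])
def test_posterior_quantities_match_enumeration(seed, n_zones):
    """Evidence, occupancy, change-point posteriors and max-profiles all
    equal their brute-force definitions on enumerable series."""
    profile, cost = case(seed, T=11)
    model = rz.PiecewiseLinearModel(profile, min_segment_length=2)
    assert model.log_evidence(n_zones) == pytest.approx(
        bf.evidence(cost, n_zones, 2), rel=1e-9
    )
    summary = model.posterior_summary(n_zones)
    np.testing.assert_allclose(
        summary.zone_occupancy, bf.zone_occupancy(cost, n_zones, 2), atol=1e-9
    )
    np.testing.assert_allclose(
        summary.changepoint_posteriors,
        bf.changepoint_posteriors(cost, n_zones, 2),
        atol=1e-9,
    )
    np.testing.assert_allclose(
        summary.segmentation_profiles,
        bf.max_assignment_profiles(cost, n_zones, 2),
        atol=1e-9,
    )


def test_segmentation_posteriors_are_normalized_likelihood_shares():
    profile, cost = case(3, T=10)
    model = rz.PiecewiseLinearModel(profile, min_segment_length=2)
    segs, weights = bf.posteriors(cost, 2, 2)
    tops = model.top_segmentations(2, len(segs))
    lz = model.log_evidence(2)
    for res, w in zip(tops, weights):
        assert posterior.segmentation_posterior(res, lz) == pytest.approx(w, rel=1e-9)
    total = sum(posterior.segmentation_posterior(r, lz) for r in tops)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_evidence_at_least_optimum():
    profile, _ = case(4, T=12)
    model = rz.PiecewiseLinearModel(profile, min_segment_length=2)
    for J in (1, 2, 3):
        assert model.log_evidence(J) >= model.fit(J).llf - 1e-12
    # J = 1: a single segmentation, so evidence equals its likelihood
    assert model.log_evidence(1) == pytest.approx(model.fit(1).llf, rel=1e-12)


def test_unique_feasible_segmentation_is_certain():
    """T = J * min_len leaves a single segmentation: posterior one and 0/1
    occupancy and max-profiles."""
    profile, _ = case(5, T=8)
    model = rz.PiecewiseLinearModel(profile, min_segment_length=4)
    res = model.fit(2)
    assert res.segmentation_posterior() == pytest.approx(1.0)
    summary = model.posterior_summary(2)
    assert set(np.unique(summary.zone_occupancy)) <= {0.0, 1.0}
    np.testing.assert_allclose(
        summary.segmentation_profiles, summary.zone_occupancy, atol=1e-12
    )


def test_occupancy_rows_and_endpoints(a10_profile):
    profile, _ = a10_profile
    occ = posterior.zone_occupancy_profiles(profile, 3)
    np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(occ[0], [1.0, 0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(occ[-1], [0.0, 0.0, 1.0], atol=1e-12)


def test_changepoint_posterior_support_respects_min_len():
    profile, cost = case(6, T=10)
    pmf = posterior.changepoint_posterior(profile, 2, 1, min_len=3)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(pmf[:3] == 0) and np.all(pmf[-2:] == 0)


def test_profiles_bounded_by_occupancy(a10_profile):
    profile, _ = a10_profile
    summary = posterior.posterior_summary(profile, 3)
    assert np.all(
        summary.segmentation_profiles <= summary.zone_occupancy + 1e-9
    )


class TestCredibleInterval:
    def test_point_mass(self):
        pmf = np.zeros(20)
        pmf[10] = 1.0
        assert credible_interval(pmf, 10, 0.5) == (10, 10)
        assert credible_interval(pmf, 10, 1.0) == (10, 10)

    def test_greedy_growth_example(self):
        pmf = np.zeros(15)
        pmf[10], pmf[11], pmf[12] = 0.5, 0.3, 0.2
        assert credible_interval(pmf, 10, 0.75) == (10, 11)
        # exhaustive check: [10, 11] is the smallest contiguous superset of
        # the MAP with mass >= 0.75
        spans = [
            (lo, hi)
            for lo in range(13)
            for hi in range(lo, 13)
            if lo <= 10 <= hi and pmf[lo : hi + 1].sum() >= 0.75
        ]
        assert min(spans, key=lambda s: s[1] - s[0]) == (10, 11)

    def test_full_coverage_spans_support(self):
        pmf = np.zeros(10)
        pmf[2:7] = 0.2
        assert credible_interval(pmf, 4, 1.0) == (2, 6)

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            credible_interval(np.array([1.0]), 0, 1.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_contains_map_and_reaches_coverage(self, data):
        n = data.draw(st.integers(3, 12))
        raw = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n).filter(
                lambda v: sum(v) > 0
            )
        )
        pmf = np.array(raw) / sum(raw)
        support = np.flatnonzero(pmf > 0)
        map_index = int(support[np.argmax(pmf[support])])
        coverage = data.draw(st.sampled_from([0.5, 0.8, 0.95]))
        lo, hi = credible_interval(pmf, map_index, coverage)
        assert lo <= map_index <= hi
        assert pmf[lo : hi + 1].sum() >= coverage - 1e-9


def test_posterior_concentrates_as_noise_vanishes():
    """Shrinking the generating noise drives the optimal segmentation's
    posterior toward one and the credible intervals toward single cells."""
    def zones(scale):
        # deliberate jumps at both limits so the change point is not
        # intrinsically ambiguous between adjacent cells
        return (
            rz.ZoneSpec("DZ", 300.0, 6.0, 0.0, 1.0 * scale),
            rz.ZoneSpec("EZ", 300.0, 12.0 - 0.06 * 300, 60.0, 3.0 * scale),
            rz.ZoneSpec("MZ", 500.0, 45.0, 0.0, 8.0 * scale),
        )

    posts, widths = [], []
    for scale in (1.0, 0.3, 0.05):
        spec = rz.ProfileSpec("c", zones(scale), n_files=1)
        profile, _ = rz.generate_profile(spec, seed=5)
        model = rz.PiecewiseLinearModel(profile)
        posts.append(model.fit(3).segmentation_posterior())
        summary = model.posterior_summary(3)
        widths.append(
            sum(iv.hi_index - iv.lo_index for iv in summary.intervals)
        )
    assert posts[0] < posts[-1] and posts[-1] > 0.9
    assert widths[-1] <= widths[0] and widths[-1] == 0


def test_intervals_contain_map(a10_profile):
    profile, _ = a10_profile
    summary = posterior.posterior_summary(profile, 3)
    for iv in summary.intervals:
        assert iv.lo_index <= iv.map_index <= iv.hi_index
        assert iv.lo_um <= iv.map_um <= iv.hi_um
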