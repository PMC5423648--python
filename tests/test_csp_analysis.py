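"""Combined-shift statistic, trajectory tracking, classification,
broadening detection and het-NOE ratios."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shiftbind.binding_core import ExchangeRegime
from shiftbind.csp_analysis import (
    CSPClass,
    CSPProfile,
    build_trajectories,
    classify_csp,
    combined_csp,
    detect_broadened,
    het_noe,
    profile_from_trajectories,
)
from shiftbind.errors import CapabilityError, DomainError, ValidationError
from shiftbind.synthetic_data import SimulationConfig, simulate_fast_exchange

from conftest import make_peak_series

FINITE = st.floats(min_value=-5, max_value=5, allow_nan=False)


class TestCombinedCsp:
    @pytest.mark.parametrize("dh,dn,expected", [
        (0.0, 0.0, 0.0),
        (0.1, 0.5, math.sqrt(0.1**2 + 0.1**2)),  # 0.14142
        (0.0, 0.25, 0.05),  # 15N-only: 0.25/5
    ])
    def test_reference_values(self, dh, dn, expected):
        assert combined_csp(dh, dn) == pytest.approx(expected, abs=1e-12)

    @given(dh=FINITE, dn=FINITE)
    def test_sign_symmetric_norm(self, dh, dn):
        v = combined_csp(dh, dn)
        assert v >= 0
        assert combined_csp(-dh, dn) == v
        assert combined_csp(dh, -dn) == v
        assert (v == 0) == (dh == 0 and dn == 0)
        assert combined_csp(2 * dh, 2 * dn) == pytest.approx(2 * v, rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(DomainError):
            combined_csp(float("nan"), 0.1)

    def test_scale_override(self):
        assert combined_csp(0.0, 0.25, n_scale=10.0) == pytest.approx(0.025)


class TestBuildTrajectories:
    def test_noiseless_generator_series_tracked_exactly(self):
        cfg = SimulationConfig(seed=7, shift_noise_sd=(0.0, 0.0),
                               intensity_noise_cv=0.0)
        series = simulate_fast_exchange(cfg)
        trajs = build_trajectories(series)
        assert set(trajs) == set(range(1, cfg.n_residues + 1))
        for i, point in enumerate(series.points):
            for pk in point.peaks:
                t = trajs[pk.residue_id]
                assert t.delta_h[i] == pk.delta_h
                assert t.delta_n[i] == pk.delta_n

    def test_crossing_paths_keep_identity(self):
        # two residues cross in 1H but stay > max_jump apart in combined
        # distance at every step thanks to a 15N offset
        n_pts = 11
        hs_a = np.linspace(8.0, 8.5, n_pts)
        hs_b = np.linspace(8.5, 8.0, n_pts)
        positions = [{1: (hs_a[i], 115.0), 2: (hs_b[i], 116.0)}
                     for i in range(n_pts)]
        series = make_peak_series(positions)
        trajs = build_trajectories(series, max_jump=0.1)
        assert np.allclose(trajs[1].delta_h, hs_a)
        assert np.allclose(trajs[2].delta_h, hs_b)
        oracle = exhaustive_tracking(positions, max_jump=0.1)
        for rid in (1, 2):
            assert np.allclose(trajs[rid].delta_h, oracle[rid])

    def test_six_peak_instance_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        start = {r: (rng.uniform(7, 9.5), rng.uniform(108, 128)) for r in range(6)}
        drift = {r: (rng.uniform(-0.3, 0.3), rng.uniform(-1.5, 1.5)) for r in range(6)}
        n_pts = 8
        positions = [
            {r: (start[r][0] + f * drift[r][0], start[r][1] + f * drift[r][1])
             for r in range(6)}
            for f in np.linspace(0, 1, n_pts)
        ]
        series = make_peak_series(positions)
        trajs = build_trajectories(series, max_jump=0.15)
        oracle = exhaustive_tracking(positions, max_jump=0.15)
        for rid in range(6):
            assert np.allclose(trajs[rid].delta_h, oracle[rid], equal_nan=True)

    def test_vanished_peak_marked_missing(self):
        positions = [{1: (8.0, 115.0), 2: (9.0, 120.0)}] * 3
        positions = positions + [{2: (9.0, 120.0)}] * 2  # residue 1 disappears
        series = make_peak_series(positions)
        trajs = build_trajectories(series, max_jump=0.05)
        assert np.isnan(trajs[1].delta_h[3:]).all()
        assert np.isfinite(trajs[2].delta_h).all()

    def test_duplicate_residue_rejected(self):
        positions = [{1: (8.0, 115.0)}]
        series = make_peak_series(positions)
        series.points[0].peaks.append(series.points[0].peaks[0])
        with pytest.raises(ValidationError, match="duplicate"):
            build_trajectories(series)


def exhaustive_tracking(positions, max_jump):
    """Brute-force oracle: at each point, choose the peak-to-residue
    assignment minimising total combined-shift displacement over all
    permutations, with per-residue gate."""
    rids = sorted(positions[0])
    pos = {r: positions[0][r] for r in rids}
    out = {r: [positions[0][r][0]] for r in rids}
    for point in positions[1:]:
        peaks = list(point.values())
        best, best_cost = None, np.inf
        k = min(len(rids), len(peaks))
        for subset in itertools.permutations(range(len(peaks)), k):
            cost, assign = 0.0, {}
            for r, j in zip(rids, subset):
                d = combined_csp(peaks[j][0] - pos[r][0], peaks[j][1] - pos[r][1])
                if d <= max_jump:
                    cost += d
                    assign[r] = peaks[j]
                else:
                    cost += 1e6
            if cost < best_cost:
                best_cost, best = cost, assign
        for r in rids:
            if best and r in best:
                pos[r] = best[r]
                out[r].append(best[r][0])
            else:
                out[r].append(np.nan)
    return {r: np.array(v) for r, v in out.items()}


class TestClassifyCsp:
    def test_identical_values_all_in_top_class(self):
        profile = CSPProfile(per_residue={r: 0.2 for r in range(1, 8)})
        classify_csp(profile)
        assert profile.sd == 0.0
        # inclusive ">= mean" boundary: every residue sits in both classes
        assert all(c is CSPClass.ABOVE_MEAN_PLUS_SD
                   for c in profile.class_map.values())

    def test_hand_computed_mean_and_sd(self):
        values = {r: 0.1 for r in range(1, 10)}
        values[10] = 1.0
        profile = classify_csp(CSPProfile(per_residue=values))
        assert profile.mean == pytest.approx(0.19)
        assert profile.sd == pytest.approx(0.2846, abs=2e-4)
        top = [r for r, c in profile.class_map.items()
               if c is CSPClass.ABOVE_MEAN_PLUS_SD]
        assert top == [10]
        above = [r for r, c in profile.class_map.items()
                 if c is not CSPClass.BELOW_MEAN]
        assert above == [10]

    def test_spiked_residues_recovered(self):
        rng = np.random.default_rng(8)
        values = {r: abs(rng.normal(0.05, 0.01)) for r in range(1, 19)}
        spiked = {19: 0.5, 20: 0.6}
        values.update(spiked)
        profile = classify_csp(CSPProfile(per_residue=values))
        top = {r for r, c in profile.class_map.items()
               if c is CSPClass.ABOVE_MEAN_PLUS_SD}
        assert top == set(spiked)

    def test_class_sets_are_nested(self):
        rng = np.random.default_rng(9)
        profile = classify_csp(CSPProfile(
            per_residue={r: float(v) for r, v in
                         enumerate(rng.gamma(2.0, 0.05, 40), 1)}))
        top = {r for r, c in profile.class_map.items()
               if c is CSPClass.ABOVE_MEAN_PLUS_SD}
        above = {r for r, c in profile.class_map.items()
                 if c is not CSPClass.BELOW_MEAN}
        assert top <= above
        for r in above:
            assert profile.per_residue[r] >= profile.mean

    def test_broadened_values_never_enter_statistics(self):
        trajs_cfg = SimulationConfig(seed=3, shift_noise_sd=(0.0, 0.0),
                                     intensity_noise_cv=0.0)
        series = simulate_fast_exchange(trajs_cfg)
        trajs = build_trajectories(series)
        full = classify_csp(profile_from_trajectories(trajs))
        dropped = classify_csp(profile_from_trajectories(trajs, broadened={1, 2}))
        assert 1 not in dropped.per_residue and 2 not in dropped.per_residue
        expect = np.mean([v for r, v in full.per_residue.items() if r not in (1, 2)])
        assert dropped.mean == pytest.approx(float(expect))

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            classify_csp(CSPProfile(per_residue={}))


BROAD_IDS = (125, 161, 162, 179)


def _broadened_config(**overrides):
    ids = tuple([76, 80, 91, 104, 110] + list(BROAD_IDS) +
                list(range(180, 191)))
    defaults = dict(n_residues=len(ids), residue_ids=ids,
                    broadened_ids=BROAD_IDS, seed=21)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestDetectBroadened:
    def test_attenuated_residue_set_recovered_exactly(self):
        series = simulate_fast_exchange(_broadened_config())
        flagged = detect_broadened(series, alpha=0.1)
        assert set(flagged) == set(BROAD_IDS)
        assert all(0 < i < len(series) for i in flagged.values())

    def test_clean_series_yields_empty_set(self):
        cfg = SimulationConfig(seed=13, shift_noise_sd=(0.0, 0.0),
                               intensity_noise_cv=0.0)
        series = simulate_fast_exchange(cfg)
        assert detect_broadened(series, alpha=0.1) == {}

    def test_global_dilution_absorbed_by_median_trend(self):
        cfg = SimulationConfig(seed=13, shift_noise_sd=(0.0, 0.0),
                               intensity_noise_cv=0.0)
        series = simulate_fast_exchange(cfg)
        for i, point in enumerate(series.points):
            for pk in point.peaks:
                pk.intensity *= 0.5 ** (i / (len(series) - 1))
        assert detect_broadened(series, alpha=0.1) == {}

    def test_flagged_set_grows_with_alpha(self):
        series = simulate_fast_exchange(_broadened_config(broadening_k=3.0))
        sets = [set(detect_broadened(series, alpha=a))
                for a in (0.02, 0.1, 0.3, 0.6)]
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_missing_intensities_raise_capability_error(self):
        positions = [{1: (8.0, 115.0), 2: (9.0, 120.0)}] * 5
        series = make_peak_series(positions)
        with pytest.raises(CapabilityError, match="shift-only"):
            detect_broadened(series)


class TestHetNoe:
    def test_equal_intensities_give_unit_noe(self):
        (rec,) = het_noe({5: 3.0}, {5: 3.0}, noise_sd=0.1)
        assert rec.noe == 1.0

    def test_hand_propagated_error(self):
        (rec,) = het_noe({1: 0.8}, {1: 1.0}, noise_sd=0.05)
        assert rec.noe == pytest.approx(0.8)
        assert rec.noe_err == pytest.approx(
            0.8 * math.sqrt((0.05 / 0.8) ** 2 + (0.05 / 1.0) ** 2), rel=1e-12)
        assert rec.noe_err == pytest.approx(0.064, abs=5e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            het_noe({1: 0.5}, {1: 0.0}, noise_sd=0.05)

    def test_mismatched_residue_sets_rejected(self):
        with pytest.raises(ValidationError):
            het_noe({1: 0.5, 2: 0.4}, {1: 1.0}, noise_sd=0.05)
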