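"""Percentage distributions, F_W, dF_W, and the recovery diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyspike as ps
from polyspike.distribution_metrics import percent_values

from test_quantification import make_profile
from conftest import brute_force_fw


def dist_from(values, fractions=None, window=None):
    prof = make_profile(values, fractions)
    frs = prof.values.index
    win = window or (int(frs.min()), int(frs.max()))
    return ps.percent_signal(prof, win)


class TestPercentSignal:
    def test_uniform(self):
        d = dist_from([1.0, 1.0, 1.0, 1.0])
        assert np.allclose(d.percent, 25.0)

    def test_single_positive_fraction(self):
        d = dist_from([0.0, 5.0, 0.0])
        assert np.allclose(d.percent, [0.0, 100.0, 0.0])

    def test_simple_proportions(self):
        d = dist_from([2.0, 3.0, 5.0])
        assert np.allclose(d.percent, [20.0, 30.0, 50.0])

    def test_window_excludes_outside_fractions(self):
        prof = make_profile([9.0, 1.0, 1.0, 1.0, 9.0], fractions=[1, 2, 3, 4, 5])
        d = ps.percent_signal(prof, window=(2, 4))
        assert list(d.fractions) == [2, 3, 4]
        assert np.allclose(d.percent, 100.0 / 3)

    def test_missing_fraction_renormalized_out(self):
        prof = make_profile([1.0, np.nan, 1.0], fractions=[2, 3, 4])
        d = ps.percent_signal(prof, window=(2, 4))
        assert list(d.fractions) == [2, 4]
        assert np.allclose(d.percent, 50.0)

    def test_explicit_fraction_subset(self):
        prof = make_profile(np.ones(20))
        d = ps.percent_signal(prof, window=(2, 16), fractions=range(2, 17, 2))
        assert list(d.fractions) == [2, 4, 6, 8, 10, 12, 14, 16]
        assert np.allclose(d.percent, 12.5)

    def test_all_zero_window_raises(self):
        prof = make_profile([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            ps.percent_signal(prof, window=(1, 3))

    def test_all_missing_window_raises(self):
        prof = make_profile([1.0, np.nan, np.nan], fractions=[1, 5, 6])
        with pytest.raises(ValueError, match="no observed"):
            ps.percent_signal(prof, window=(5, 6))

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=15),
        scale=st.floats(0.001, 1000.0),
    )
    def test_scale_invariance(self, values, scale):
        a = dist_from(values)
        b = dist_from([scale * v for v in values])
        assert np.allclose(a.percent, b.percent, rtol=1e-9)


class TestWeightedAverageFw:
    def test_point_mass(self):
        for k in (2, 10, 16):
            vals = np.zeros(15)
            vals[k - 2] = 1.0
            d = dist_from(vals, fractions=range(2, 17))
            assert ps.weighted_average_fw(d) == pytest.approx(k, abs=1e-12)

    def test_uniform_2_16(self):
        d = dist_from(np.ones(15), fractions=range(2, 17))
        assert ps.weighted_average_fw(d) == pytest.approx(9.0, abs=1e-12)

    def test_even_split_2_and_16(self):
        vals = np.zeros(15)
        vals[0] = vals[-1] = 1.0
        d = dist_from(vals, fractions=range(2, 17))
        assert ps.weighted_average_fw(d) == pytest.approx(9.0, abs=1e-12)

    def test_even_fraction_subset_uses_actual_numbers(self):
        prof = make_profile(np.ones(20))
        d = ps.percent_signal(prof, window=(2, 16), fractions=range(2, 17, 2))
        assert ps.weighted_average_fw(d) == pytest.approx(9.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        values=st.lists(st.floats(0.01, 10.0), min_size=3, max_size=15),
        a=st.integers(0, 13),
        frac=st.floats(0.05, 1.0),
    )
    def test_moving_mass_heavier_strictly_increases_fw(self, values, a, frac):
        v = np.zeros(15)
        v[: len(values)] = values
        a = a % len(values)
        bs = [b for b in range(a + 1, 15)]
        if not bs or v[a] <= 0:
            return
        b = bs[-1]
        moved = v.copy()
        m = frac * v[a]
        moved[a] -= m
        moved[b] += m
        fw0 = brute_force_fw(range(2, 17), v)
        fw1 = brute_force_fw(range(2, 17), moved)
        assert fw1 > fw0

    @settings(derandomize=True, max_examples=50)
    @given(values=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=15))
    def test_fw_bounded_by_window(self, values):
        d = dist_from(values, fractions=range(2, 2 + len(values)))
        fw = ps.weighted_average_fw(d)
        assert 2 - 1e-9 <= fw <= 2 + len(values) - 1 + 1e-9


class TestDeltaFw:
    def test_identical_distributions(self):
        assert ps.delta_fw(9.0, 9.0) == 0.0

    def test_subtraction(self):
        assert ps.delta_fw(11.2, 9.0) == pytest.approx(2.2)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            ps.delta_fw(np.nan, 9.0)

    def test_simulator_round_trip_zero_noise(self, noiseless_config):
        # pipeline dF_W equals the configured shift when nothing is random
        table, truth = ps.simulate_experiment(noiseless_config)
        norm = ps.normalize_profiles(ps.profiles_from_table(table))
        for r in ps.compute_shift_results(norm):
            assert r.delta_fw == pytest.approx(
                noiseless_config.shift_delta, abs=1e-9
            )

    def test_missing_condition_raises(self, noiseless_config):
        table, _ = ps.simulate_experiment(noiseless_config)
        table = table[table.treatment == "DMEM"]
        profiles = ps.profiles_from_table(table)
        with pytest.raises(ValueError, match="missing control/treated"):
            ps.compute_shift_results(profiles)


class TestFractionRecoveryReport:
    def test_constant_spikein_no_flags(self):
        prof = make_profile(np.full(10, 0.7), gene="RLP24")
        rep = ps.fraction_recovery_report([prof])
        assert not rep.flagged.any()
        assert np.allclose(rep.sample_cv, 0.0)

    def test_tenfold_outlier_flagged(self):
        vals = np.ones(10)
        vals[4] = 10.0
        rep = ps.fraction_recovery_report([make_profile(vals, gene="RLP24")])
        assert list(rep.loc[rep.flagged, "fraction"]) == [5]

    def test_simulated_losses_match_brute_force_scan(self):
        cfg = ps.SimulationConfig(loss_sigma=0.7, cq_sigma=0.0, seed=17)
        table, _ = ps.simulate_experiment(cfg)
        spikes = [p for p in ps.profiles_from_table(table) if p.gene == "RLP24"]
        rep = ps.fraction_recovery_report(spikes, fold_threshold=2.0)
        for p in spikes:
            sub = rep[
                (rep.sample_id == p.sample_id)
                & (rep.treatment == p.treatment)
                & (rep.replicate == p.replicate)
            ].set_index("fraction")
            med = float(np.median(p.values.dropna()))
            for f, v in p.values.dropna().items():
                expect = v / med > 2.0 or v / med < 0.5
                assert bool(sub.loc[f, "flagged"]) == expect

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ps.fraction_recovery_report([])


class TestCancellationTheorem:
    """Joint per-fraction losses leave normalized F_W unchanged; raw moves."""

    def test_joint_loss_invariance(self, rng):
        base = rng.uniform(0.1, 1.0, size=15)
        loss = rng.uniform(0.2, 5.0, size=15)
        spike = np.full(15, 0.9)
        raw_t = make_profile(base * loss, fractions=range(2, 17))
        raw_s = make_profile(spike * loss, fractions=range(2, 17), gene="RLP24")
        norm = ps.normalize_to_spikein(raw_t, raw_s)
        fw_norm = ps.weighted_average_fw(ps.percent_signal(norm, (2, 16)))
        fw_clean = brute_force_fw(range(2, 17), base)
        assert fw_norm == pytest.approx(fw_clean, abs=1e-9)
        fw_raw = ps.weighted_average_fw(ps.percent_signal(raw_t, (2, 16)))
        assert abs(fw_raw - fw_clean) > 1e-6
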