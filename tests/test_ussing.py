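"""Ussing-chamber analysis tests: Ohm's law, QC, plateaus, inhibitor deltas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmech.synthetic import UssingGenConfig, gen_ussing_cohort, gen_ussing_trace
from lungmech.ussing import (
    EventNotFoundError,
    PlateauNotFoundError,
    UssingTrace,
    amil_max,
    baseline_rte,
    detect_plateau,
    group_table,
    inhibitor_delta,
    process_trace,
    qc_filter,
    short_circuit_current,
)


def _trace(r_te=1283.0, **kwargs):
    n = kwargs.pop("n", 30)
    defaults = dict(
        time_s=np.arange(n) * 20.0,
        r_te_ohm_cm2=np.full(n, r_te),
        v_te_mV=np.full(n, 3.6),
    )
    defaults.update(kwargs)
    return UssingTrace(**defaults)


class TestShortCircuitCurrent:
    def test_control_group_values(self):
        # Ohm's law on the printed control plateau: 3.6 mV / 1283 Ohm*cm^2
        assert short_circuit_current(3.6, 1283.0) == pytest.approx(2.806, abs=1e-3)

    def test_zero_voltage(self):
        assert short_circuit_current(0.0, 500.0) == 0.0

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            short_circuit_current(3.6, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(v=st.floats(-20, 20), r=st.floats(10, 5000), c=st.floats(0.1, 10))
    def test_linearity_property(self, v, r, c):
        base = short_circuit_current(v, r)
        assert short_circuit_current(c * v, r) == pytest.approx(c * base, rel=1e-9, abs=1e-9)
        assert short_circuit_current(v, c * r) == pytest.approx(base / c, rel=1e-9, abs=1e-9)


class TestQcFilter:
    def test_strict_threshold(self):
        at = _trace(r_te=300.0)
        above = _trace(r_te=301.0)
        kept = qc_filter([at, above])
        assert kept == [above]

    def test_empty_input(self):
        assert qc_filter([]) == []

    def test_baseline_uses_pre_event_segment(self):
        r = np.concatenate([np.full(20, 800.0), np.full(20, 100.0)])
        v = np.full(40, 3.0)
        tr = UssingTrace(
            time_s=np.arange(40) * 20.0, r_te_ohm_cm2=r, v_te_mV=v,
            events=((20 * 20.0, "amiloride_apical"),),
        )
        assert baseline_rte(tr) == pytest.approx(800.0)


class TestDetectPlateau:
    def test_constant_series(self):
        res = detect_plateau(np.full(30, 3.6))
        assert res.start_index == 0
        assert res.mean == pytest.approx(3.6)

    def test_ramp_then_constant(self):
        y = np.concatenate([np.linspace(0, 3.6, 10), np.full(20, 3.6)])
        res = detect_plateau(y, window_n=6, rel_slope_tol=0.01)
        assert res.start_index >= 9  # window lies inside the constant segment
        assert res.mean == pytest.approx(3.6, rel=1e-6)

    def test_strictly_increasing_flags_absence(self):
        assert detect_plateau(np.linspace(0, 10, 40)) is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_plateau(np.ones(3), window_n=6)


class TestInhibitorDelta:
    def test_printed_control_decomposition(self):
        """V_base 3.6 mV, post-amiloride 1.3 mV -> delta_amil 2.3 mV."""
        cfg = UssingGenConfig(plateau_targets=(3.6, 1.3), noise_sd=0.0)
        trace = gen_ussing_trace(cfg)
        d = inhibitor_delta(trace, "amiloride_apical")
        assert d.pre_plateau == pytest.approx(3.6)
        assert d.post_plateau == pytest.approx(1.3)
        assert d.delta == pytest.approx(2.3)

    def test_equal_plateaus_give_zero_delta(self):
        cfg = UssingGenConfig(plateau_targets=(2.0, 2.0), initial_value=2.0, noise_sd=0.0)
        d = inhibitor_delta(gen_ussing_trace(cfg), "amiloride_apical")
        assert d.delta == pytest.approx(0.0, abs=1e-12)

    def test_noisy_delta_recovered_within_sampling_error(self):
        cfg = UssingGenConfig(plateau_targets=(3.6, 1.3), noise_sd=0.05, seed=9)
        d = inhibitor_delta(gen_ussing_trace(cfg), "amiloride_apical")
        # plateau means average >=6 samples of sigma=0.05 noise
        assert d.delta == pytest.approx(2.3, abs=3 * 0.05 / np.sqrt(6) * 2)

    def test_missing_event_flagged(self):
        trace = _trace()
        with pytest.raises(EventNotFoundError):
            inhibitor_delta(trace, "amiloride_apical")


class TestAmilMax:
    def _vc_cfg(self, **kwargs):
        defaults = dict(
            clamp_mode="voltage_clamp",
            initial_value=2.0,
            plateau_targets=(2.0, 7.5, 0.3),
            event_labels=("amphotericin_basolateral", "amiloride_basolateral"),
            event_times_s=(600.0, 1500.0),
            duration_s=2400.0,
            noise_sd=0.0,
        )
        defaults.update(kwargs)
        return UssingGenConfig(**defaults)

    def test_control_fixture(self):
        """Peak 7.5 after permeabilization, 0.3 post amiloride -> 7.2 uA/cm^2."""
        trace = gen_ussing_trace(self._vc_cfg())
        assert amil_max(trace) == pytest.approx(7.2, abs=1e-9)

    def test_flat_zero_trace(self):
        cfg = self._vc_cfg(initial_value=0.0, plateau_targets=(0.0, 0.0, 0.0))
        assert amil_max(gen_ussing_trace(cfg)) == 0.0

    def test_missing_events_flagged(self):
        n = 30
        trace = UssingTrace(
            time_s=np.arange(n) * 5.0,
            r_te_ohm_cm2=np.full(n, 1282.0),
            i_sc_uA_cm2=np.full(n, 5.0),
            clamp_mode="voltage_clamp",
        )
        with pytest.raises(EventNotFoundError):
            amil_max(trace)

    def test_requires_voltage_clamp(self):
        with pytest.raises(ValueError, match="voltage-clamp"):
            amil_max(_trace())


class TestProcessTrace:
    def test_additive_decomposition_invariant(self):
        """v_base - v_amil - delta_amil = 0 on every processed trace."""
        cfg = UssingGenConfig(plateau_targets=(3.6, 1.3), noise_sd=0.05)
        for trace in gen_ussing_cohort(cfg, 8, target_sds=(0.3, 0.1), seed=21):
            s = process_trace(trace)
            assert s.v_base_mV - s.v_amil_mV - s.delta_amil_mV == pytest.approx(0.0, abs=1e-12)
            assert s.qc_pass

    def test_cohort_group_means_recover_generating_means(self):
        """Sample means of a synthetic cohort match the configured truth within SEM."""
        control = UssingGenConfig(plateau_targets=(3.6, 1.3), noise_sd=0.05)
        pressure = UssingGenConfig(
            plateau_targets=(0.9, 0.21), noise_sd=0.05,
            pressure_cmH2O=12.5, pressure_side="basolateral", r_te_ohm_cm2=377.0,
        )
        summaries = [
            process_trace(t)
            for t in gen_ussing_cohort(control, 30, target_sds=(0.3, 0.1), seed=1)
            + gen_ussing_cohort(pressure, 30, target_sds=(0.1, 0.02), seed=2)
        ]
        table = group_table(summaries).set_index("pressure_cmH2O")
        for p, truth, sd in ((0.0, 2.3, 0.3), (12.5, 0.69, 0.1)):
            mean = table.loc[p, "delta_amil_mV_mean"]
            assert mean == pytest.approx(truth, abs=3 * sd / np.sqrt(30) + 0.02)

    def test_trace_without_events_is_flagged(self):
        s = process_trace(_trace())
        assert s.flags
        assert np.isnan(s.delta_amil_mV)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(pressure_cmH2O=13.0, pressure_side="basolateral"),
        dict(pressure_cmH2O=31.0, pressure_side="apical"),
        dict(events=((1e6, "amiloride_apical"),)),
        dict(events=((100.0, "unknown_drug"),)),
    ],
)
def test_invalid_traces_rejected(kwargs):
    with pytest.raises(ValueError):
        _trace(**kwargs)
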