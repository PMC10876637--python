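"""EPSC detection: noise estimation, sensitivity, amplitude fidelity,
merging, and the synaptic summary statistics."""

import numpy as np
import pytest

from patchkit import (
    DetectionParams,
    SynapticParams,
    detect_epscs,
    estimate_noise,
    event_statistics,
    large_event_rate,
    pooled_ecdf,
    simulate_synaptic_trace,
)
from patchkit.events import Ecdf
from patchkit.synaptic import EventList
from patchkit.trace import ModeError


def _noise_trace(sd, duration=30.0, seed=0):
    sp = SynapticParams(rate_hz=0.0, duration_s=duration, noise_sd_pA=sd)
    rec, _ = simulate_synaptic_trace(sp, seed=seed)
    return rec


def test_noise_estimate_recovers_sigma():
    rec = _noise_trace(2.0, seed=1)
    assert estimate_noise(rec) == pytest.approx(2.0, rel=0.10)


def test_noise_estimate_robust_to_sparse_large_events():
    sp = SynapticParams(rate_hz=0.5, duration_s=60.0, noise_sd_pA=2.0,
                        amp_logmean=np.log(100.0), amp_logsd=0.01)
    rec, _ = simulate_synaptic_trace(sp, seed=2)
    assert estimate_noise(rec) == pytest.approx(2.0, rel=0.15)


def test_noise_estimate_of_flat_trace_is_zero():
    rec = _noise_trace(0.0, duration=10.0)
    assert estimate_noise(rec) == pytest.approx(0.0, abs=1e-9)


def test_detects_well_separated_events_with_accurate_amplitudes():
    times = 1000.0 + np.arange(10) * 1000.0
    forced = EventList(times, np.full(10, 50.0), 12.0)
    sp = SynapticParams(rate_hz=0.0, duration_s=12.0, noise_sd_pA=2.0)
    rec, _ = simulate_synaptic_trace(sp, seed=3, forced_events=forced)
    det = detect_epscs(rec)
    assert len(det) == 10
    for t, a in zip(forced.times_ms, forced.amplitudes_pA):
        j = np.argmin(np.abs(det.times_ms - t))
        assert abs(det.times_ms[j] - t) < 5.0
        assert det.amplitudes_pA[j] == pytest.approx(a, rel=0.10)


def test_threshold_backend_detects_the_same_events():
    times = 1000.0 + np.arange(10) * 1000.0
    forced = EventList(times, np.full(10, 50.0), 12.0)
    sp = SynapticParams(rate_hz=0.0, duration_s=12.0, noise_sd_pA=2.0)
    rec, _ = simulate_synaptic_trace(sp, seed=3, forced_events=forced)
    det = detect_epscs(rec, DetectionParams(backend="threshold"))
    assert len(det) == 10


def test_flat_trace_yields_no_events():
    rec = _noise_trace(0.0, duration=10.0)
    assert len(detect_epscs(rec)) == 0


def test_noise_only_trace_yields_few_false_positives():
    rec = _noise_trace(3.0, duration=60.0, seed=4)
    det = detect_epscs(rec)
    assert len(det) / 60.0 <= 0.05


def test_close_events_are_merged_into_larger():
    forced = EventList([1000.0, 1003.0], [30.0, 60.0], 5.0)
    sp = SynapticParams(rate_hz=0.0, duration_s=5.0, noise_sd_pA=1.0)
    rec, _ = simulate_synaptic_trace(sp, seed=5, forced_events=forced)
    det = detect_epscs(rec)
    assert len(det) == 1
    assert det.amplitudes_pA[0] > 50.0


def test_detection_rejects_current_clamp():
    from patchkit import simulate_current_clamp_family, standard_neuron

    rec = simulate_current_clamp_family(standard_neuron())
    with pytest.raises(ModeError):
        detect_epscs(rec)


def test_event_statistics_and_rates():
    ev = EventList(np.linspace(0, 99_000, 50), np.full(50, 20.0), 100.0)
    stats = event_statistics(ev)
    assert stats["rate_hz"] == pytest.approx(0.5)
    ev2 = EventList([10.0, 20.0], [30.0, 50.0], 60.0)
    assert event_statistics(ev2)["mean_amp_pA"] == pytest.approx(40.0)
    empty = EventList([], [], 60.0)
    s = event_statistics(empty)
    assert s["rate_hz"] == 0.0 and np.isnan(s["mean_amp_pA"])
    with pytest.raises(ValueError):
        event_statistics(EventList([], [], 0.0))


def test_large_event_rate_uses_strict_threshold():
    ev = EventList([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 31.0, 45.0], 10.0)
    assert large_event_rate(ev) == pytest.approx(0.2)
    ev30 = EventList([1.0], [30.0], 10.0)
    assert large_event_rate(ev30) == 0.0  # exactly 30 pA is excluded
    evall = EventList([1.0, 2.0], [40.0, 50.0], 10.0)
    assert large_event_rate(evall) == pytest.approx(event_statistics(evall)["rate_hz"])


def test_pooled_ecdf_is_valid_cdf():
    a = EventList([1.0, 2.0, 3.0], [10.0, 20.0, 30.0], 10.0)
    e = pooled_ecdf([a])
    assert e(20.0) == pytest.approx(2.0 / 3.0)
    assert e(30.0) == 1.0
    assert e(0.0) == 0.0
    grid = np.linspace(0, 40, 100)
    vals = e(grid)
    assert np.all(np.diff(vals) >= 0)
    with pytest.raises(ValueError):
        pooled_ecdf([EventList([], [], 10.0)])


def test_scaled_amplitudes_shift_ecdf_left():
    # same sample scaled: strict pointwise dominance holds exactly
    rng = np.random.default_rng(6)
    amps = rng.lognormal(np.log(25), 0.5, 400)
    ea = Ecdf(amps)
    eb = Ecdf(amps * 0.6)
    grid = np.sort(np.concatenate([amps, amps * 0.6]))
    assert np.all(eb(grid) >= ea(grid) - 1e-12)


def test_ecdf_left_shift_on_independent_samples():
    from patchkit import ecdf_left_shift

    rng = np.random.default_rng(7)
    control = rng.lognormal(np.log(25), 0.5, 2000)
    case = rng.lognormal(np.log(15), 0.5, 1000)
    ok, violation, crit = ecdf_left_shift(case, control)
    assert ok and violation <= crit
    # reversed roles: the "case" is right-shifted, dominance must fail
    ok_rev, violation_rev, _ = ecdf_left_shift(control, case)
    assert not ok_rev and violation_rev > crit
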