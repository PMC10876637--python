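"""Feature extraction from current-clamp, membrane-test and voltage-step
recordings."""

from dataclasses import replace

import numpy as np
import pytest

from patchkit import (
    IVOptions,
    NA_BAND,
    K_BAND,
    Recording,
    SpikeCriteria,
    Sweep,
    compute_input_conductance,
    count_evoked_aps,
    detect_spikes,
    estimate_capacitance,
    extract_iv_table,
    simulate_membrane_test,
    simulate_voltage_clamp_family,
    standard_neuron,
    summarize_band,
    vc_step_protocol,
)
from patchkit.intrinsic import IVTable
from patchkit.trace import ModeError

FS = 20_000.0
DT = 1000.0 / FS


def _sweep(v, step_onset=0.0, step_dur=None):
    v = np.asarray(v, dtype=float)
    dur = step_dur if step_dur is not None else len(v) * DT
    return Sweep(np.zeros_like(v), v, step_level=0.0, step_onset_ms=step_onset,
                 step_dur_ms=dur)


def _triangle_trace(n_crossings=5, spacing_ms=50.0):
    """Sawtooth crossing 0 mV upward n times, spacing_ms apart."""
    period = int(spacing_ms / DT)
    one = np.concatenate([
        np.linspace(-60, 20, period // 2), np.linspace(20, -60, period - period // 2)
    ])
    return np.tile(one, n_crossings)


def test_flat_trace_has_no_spikes():
    times = detect_spikes(_sweep(np.full(4000, -60.0)))
    assert len(times) == 0


def test_triangle_wave_crossings_are_counted():
    times = detect_spikes(_sweep(_triangle_trace(5, 50.0)))
    assert len(times) == 5
    assert np.all(np.diff(times) >= 49.0)


def test_refractory_lockout_merges_near_crossings():
    # two upward 0-crossings 1 ms apart -> one spike with 2 ms lockout
    v = np.full(2000, -60.0)
    v[100:105] = 10.0   # crossing at 5 ms
    v[120:125] = 10.0   # crossing at 6 ms
    times = detect_spikes(_sweep(v), SpikeCriteria(min_interspike_ms=2.0))
    assert len(times) == 1


def test_spike_detection_rejects_voltage_clamp():
    with pytest.raises(ModeError):
        detect_spikes(_sweep(np.zeros(100)), mode="voltage_clamp")


def test_count_evoked_aps_sums_constructed_crossings():
    sweeps = []
    for _ in range(10):
        v = np.full(12000, -60.0)  # 600 ms
        v[3000:3100] = 10.0  # two crossings inside the 100–500 ms step window
        v[5000:5100] = 10.0
        sweeps.append(Sweep(np.zeros_like(v), v, step_level=0.0,
                            step_onset_ms=100.0, step_dur_ms=400.0))
    rec = Recording(FS, "current_clamp", sweeps)
    assert count_evoked_aps(rec) == 20


def test_count_evoked_aps_uses_first_32_sweeps():
    v = np.full(12000, -60.0)
    v[3000:3050] = 10.0
    sweeps = [Sweep(np.zeros_like(v), v, 0.0, 100.0, 400.0) for _ in range(40)]
    rec = Recording(FS, "current_clamp", sweeps)
    assert count_evoked_aps(rec) == 32


def test_capacitance_matches_ground_truth_and_scales():
    p = standard_neuron()
    est = estimate_capacitance(simulate_membrane_test(p))
    assert est == pytest.approx(p.Cm_pF, rel=0.02)
    p2 = replace(p, Cm_pF=2 * p.Cm_pF)
    est2 = estimate_capacitance(simulate_membrane_test(p2))
    assert est2 == pytest.approx(2 * est, rel=0.02)


def test_capacitance_from_analytic_rc_is_exact():
    p = standard_neuron(g_Na_nS=0, g_Kfast_nS=0, g_Kslow_nS=0)
    p = replace(p, Cm_pF=20.0, g_leak_nS=1.0)
    est = estimate_capacitance(simulate_membrane_test(p, step_mV=-10.0))
    assert est == pytest.approx(20.0, rel=1e-6)  # Q/ΔV = 200 fC / 10 mV


def test_input_conductance_closed_forms():
    # linear cell, g = 1 nS, E_rev = 0: I(−70) = −70 pA, I(−50) = −50 pA
    assert compute_input_conductance((-70.0, -50.0)) == pytest.approx(1.0)
    assert compute_input_conductance((-12.0, -12.0)) == 0.0


def test_input_conductance_recovers_simulated_leak():
    p = standard_neuron(g_Na_nS=0, g_Kfast_nS=0, g_Kslow_nS=0)
    p = replace(p, g_leak_nS=2.5)
    rec = simulate_voltage_clamp_family(p, vc_step_protocol())
    assert compute_input_conductance(rec) == pytest.approx(2.5, rel=0.01)


def test_leak_only_cell_has_vanishing_densities(leak_only_params):
    rec = simulate_voltage_clamp_family(leak_only_params, vc_step_protocol())
    iv = extract_iv_table(rec, leak_only_params.Cm_pF)
    for m in ("na_density", "kfast_density", "kslow_density"):
        assert np.abs(getattr(iv, m)).max() < 0.5


def test_density_band_means_scale_with_conductance(std_params):
    base = extract_iv_table(
        simulate_voltage_clamp_family(std_params, vc_step_protocol()), std_params.Cm_pF
    )
    na0 = summarize_band(base, NA_BAND, "na_density")
    ks0 = summarize_band(base, K_BAND, "kslow_density")
    half = extract_iv_table(
        simulate_voltage_clamp_family(std_params.scaled(g_Na_nS=0.5), vc_step_protocol()),
        std_params.Cm_pF,
    )
    assert summarize_band(half, NA_BAND, "na_density") == pytest.approx(0.5 * na0, rel=0.05)
    dbl = extract_iv_table(
        simulate_voltage_clamp_family(std_params.scaled(g_Kslow_nS=2.0), vc_step_protocol()),
        std_params.Cm_pF,
    )
    assert summarize_band(dbl, K_BAND, "kslow_density") == pytest.approx(2.0 * ks0, rel=0.05)


def test_summarize_band_arithmetic():
    iv = IVTable(
        np.array([-20.0, -10.0, 0.0]),
        np.array([-100.0, -80.0, -60.0]),
        np.zeros(3),
        np.zeros(3),
    )
    assert summarize_band(iv, (-20.0, 0.0), "na_density") == pytest.approx(-80.0)
    assert summarize_band(iv, (-20.0, 0.0), "kfast_density") == 0.0
    with pytest.raises(ValueError):
        summarize_band(iv, (50.0, 90.0), "na_density")


def test_iv_extraction_guards(std_params):
    rec = simulate_voltage_clamp_family(std_params, vc_step_protocol())
    with pytest.raises(ValueError):
        extract_iv_table(rec, 0.0)
    # no subthreshold steps available for the leak fit
    shallow = simulate_voltage_clamp_family(
        std_params, vc_step_protocol(start_mV=-50.0, n_steps=10)
    )
    with pytest.raises(ValueError, match="leak"):
        extract_iv_table(shallow, std_params.Cm_pF)
    with pytest.raises(ModeError):
        mt = simulate_membrane_test(std_params)
        extract_iv_table(mt, std_params.Cm_pF)


def test_leak_subtraction_can_be_disabled(std_params):
    rec = simulate_voltage_clamp_family(std_params, vc_step_protocol())
    iv_off = extract_iv_table(rec, std_params.Cm_pF, IVOptions(leak_subtract=False))
    iv_on = extract_iv_table(rec, std_params.Cm_pF)
    assert np.isnan(iv_off.leak_conductance_nS)
    # without subtraction the depolarized K densities include the leak
    assert summarize_band(iv_off, K_BAND, "kslow_density") > summarize_band(
        iv_on, K_BAND, "kslow_density"
    )
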