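"""Forward-model physics: passive closed forms, excitable behavior,
integration convergence, determinism."""

import numpy as np
import pytest

from patchkit import (
    simulate_current_clamp_family,
    simulate_membrane_test,
    simulate_voltage_clamp_family,
    standard_neuron,
    vc_step_protocol,
)
from patchkit.intrinsic import SpikeCriteria, count_evoked_aps
from patchkit.neuron import ConfigurationError, holding_current, steady_state_current
from patchkit.trace import cc_step_protocol


def _step_response(rec, level):
    """(baseline mean, steady-state mean) for the sweep at a given level."""
    sw = next(s for s in rec.sweeps if s.step_level == level)
    dt = rec.dt_ms
    on = int(round(sw.step_onset_ms / dt))
    off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
    base = sw.response[on - int(50 / dt) : on].mean()
    steady = sw.response[off - int(50 / dt) : off].mean()
    return base, steady


def test_voltage_clamp_leak_only_obeys_ohms_law(leak_only_params):
    # g_leak = 2 nS, hold −60 mV: ΔI = g·ΔV exactly at steady state
    rec = simulate_voltage_clamp_family(leak_only_params, vc_step_protocol())
    for level, dV in ((0.0, 60.0), (-90.0, -30.0)):
        base, steady = _step_response(rec, level)
        expected = leak_only_params.g_leak_nS * dV
        assert steady - base == pytest.approx(expected, rel=1e-3)


def test_voltage_clamp_excitable_transient_shape(std_params):
    # depolarizing step: early inward (negative) transient, sustained outward
    rec = simulate_voltage_clamp_family(std_params, vc_step_protocol())
    sw = next(s for s in rec.sweeps if s.step_level == -10.0)
    dt = rec.dt_ms
    on = int(round(sw.step_onset_ms / dt))
    base = sw.response[on - 100 : on].mean()
    early = sw.response[on + 10 : on + 200]  # 0.5–10 ms past the edge
    late = sw.response[on + 7000 : on + 8000]
    assert early.min() - base < -500.0
    assert late.mean() - base > 100.0


def test_voltage_clamp_closed_form_matches_fine_sampling(std_params):
    # closed-form gate solution: doubling the output rate reproduces the
    # same currents at the shared sample times to high precision
    coarse = simulate_voltage_clamp_family(std_params, vc_step_protocol())
    fine = simulate_voltage_clamp_family(
        std_params, vc_step_protocol(), sampling_rate_hz=40_000.0
    )
    for sc, sf in zip(coarse.sweeps, fine.sweeps):
        a, b = sc.response, sf.response[::2]
        # ignore the one-sample capacitive impulses (they scale with 1/dt)
        interior = np.ones(len(a), dtype=bool)
        dt = coarse.dt_ms
        for edge_ms in (sc.step_onset_ms, sc.step_onset_ms + sc.step_dur_ms):
            interior[int(round(edge_ms / dt))] = False
        scale = np.abs(a[interior]).max()
        assert np.abs(a[interior] - b[interior]).max() < 0.01 * scale


def test_current_clamp_passive_cell_follows_ohms_law(leak_only_params):
    rec = simulate_current_clamp_family(leak_only_params, cc_step_protocol())
    g = leak_only_params.g_leak_nS
    i_hold = holding_current(leak_only_params)
    for sw in rec.sweeps[:: 8]:
        dI = sw.step_level - i_hold
        _, steady = _step_response(rec, sw.step_level)
        assert steady - (-60.0) == pytest.approx(dI / g, rel=1e-3, abs=0.02)


def test_current_clamp_protocol_resolves_relative_start(std_params):
    rec = simulate_current_clamp_family(std_params, cc_step_protocol())
    i_hold = holding_current(std_params)
    assert rec.protocol.start_level == pytest.approx(i_hold - 12.0)
    assert rec.sweeps[1].step_level - rec.sweeps[0].step_level == pytest.approx(3.0)
    assert len(rec.sweeps) == 32


def test_no_sodium_no_spikes(leak_only_params, std_params):
    rec = simulate_current_clamp_family(std_params.scaled(g_Na_nS=0.0))
    assert count_evoked_aps(rec, SpikeCriteria()) == 0


def test_halving_sodium_does_not_increase_spike_count(std_params):
    full = count_evoked_aps(simulate_current_clamp_family(std_params))
    half = count_evoked_aps(simulate_current_clamp_family(std_params.scaled(g_Na_nS=0.5)))
    assert full >= 1
    assert half <= full


def test_current_clamp_integration_convergence(std_params):
    # halving the integrator step: subthreshold voltages agree pointwise to
    # <1% of the trace range, and the total spike count is unchanged
    rec1 = simulate_current_clamp_family(std_params, dt_internal_ms=0.025)
    rec2 = simulate_current_clamp_family(std_params, dt_internal_ms=0.0125)
    v1, v2 = rec1.sweeps[0].response, rec2.sweeps[0].response  # most hyperpolarized
    rng = v1.max() - v1.min()
    assert np.abs(v1 - v2).max() < 0.01 * max(rng, 1.0)
    assert count_evoked_aps(rec1) == count_evoked_aps(rec2)


def test_membrane_test_charge_equals_cm_dv(leak_only_params):
    from dataclasses import replace

    p = replace(leak_only_params, Cm_pF=20.0, g_leak_nS=1.0)
    rec = simulate_membrane_test(p, step_mV=-10.0)
    sw = rec.sweeps[0]
    dt = rec.dt_ms
    on = int(round(sw.step_onset_ms / dt))
    off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
    steady = sw.response[on + (off - on) // 2 : off].mean()
    base = sw.response[:on].mean()
    q = (sw.response[on:off] - steady).sum() * dt  # fC
    assert q == pytest.approx(20.0 * -10.0, rel=1e-6)  # Q = Cm·ΔV = −200 fC
    assert steady - base == pytest.approx(-10.0, rel=1e-6)  # g·ΔV = −10 pA


def test_membrane_test_series_resistance_time_constant():
    from dataclasses import replace

    p = standard_neuron(g_Na_nS=0, g_Kfast_nS=0, g_Kslow_nS=0)
    p = replace(p, Cm_pF=20.0, g_leak_nS=1.0, series_resistance_MOhm=10.0)
    rec = simulate_membrane_test(p, step_mV=-10.0)
    sw = rec.sweeps[0]
    dt = rec.dt_ms
    on = int(round(sw.step_onset_ms / dt))
    off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
    steady = sw.response[on + (off - on) // 2 : off].mean()
    tr = steady - sw.response[on:off]  # decaying positive transient
    # fit log-linear decay over the first 0.4 ms
    k = int(round(0.4 / dt))
    t = np.arange(k) * dt
    tau = -1.0 / np.polyfit(t, np.log(tr[:k]), 1)[0]
    # Rs·Cm reduced by the Rm divider: τ = Cm·Rs·Rm/(Rs+Rm) ≈ 0.198 ms
    assert tau == pytest.approx(0.198, rel=0.05)


def test_voltage_clamp_with_series_resistance_leak_cell(leak_only_params):
    from dataclasses import replace

    p = replace(leak_only_params, series_resistance_MOhm=10.0)
    rec = simulate_voltage_clamp_family(p, vc_step_protocol())
    base, steady = _step_response(rec, 0.0)
    rm = 1000.0 / p.g_leak_nS
    expected = 1000.0 * 60.0 / (10.0 + rm)  # ΔV over Rs+Rm, in pA
    assert steady - base == pytest.approx(expected, rel=0.02)


def test_simulation_noise_is_seed_deterministic(std_params):
    a = simulate_voltage_clamp_family(std_params, vc_step_protocol(), seed=5, noise_sd_pA=2.0)
    b = simulate_voltage_clamp_family(std_params, vc_step_protocol(), seed=5, noise_sd_pA=2.0)
    c = simulate_voltage_clamp_family(std_params, vc_step_protocol(), seed=6, noise_sd_pA=2.0)
    np.testing.assert_array_equal(a.sweeps[3].response, b.sweeps[3].response)
    assert not np.array_equal(a.sweeps[3].response, c.sweeps[3].response)


def test_unstable_holding_point_is_rejected():
    # a huge window current at −60 mV makes the resting I–V non-monotone
    p = standard_neuron(g_Na_nS=2000.0)
    from dataclasses import replace
    from patchkit.neuron import GateParams

    p = replace(p, m=GateParams(-62.0, 5.0, 0.15))
    with pytest.raises(ConfigurationError):
        holding_current(p)


def test_steady_state_current_is_pure_leak_for_leak_cell(leak_only_params):
    v = np.array([-80.0, -60.0, -40.0])
    np.testing.assert_allclose(
        steady_state_current(leak_only_params, v),
        leak_only_params.g_leak_nS * (v - leak_only_params.E_leak_mV),
    )
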