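"""Single-compartment conductance-based neuron forward model.

The model carries four ionic currents:

* leak  ``g_L (V − E_L)``
* transient sodium ``g_Na m³h (V − E_Na)`` (activation *m*, inactivation *h*)
* fast-inactivating potassium ``g_Kf a³b (V − E_K)`` (A-type-like: activation
  *a*, inactivation *b*) — produces the early outward peak
* slow non-inactivating potassium ``g_Ks n (V − E_K)`` — produces the
  sustained outward current at the end of a long depolarizing step

Each gate is first order, ``dx/dt = (x_∞(V) − x)/τ_x``, with a Boltzmann
steady state ``x_∞(V) = 1/(1 + exp(−(V − V_half)/k))`` (negative ``k`` gives
an inactivation gate) and a fixed time constant.  Fixed time constants keep
the gates exactly solvable under a clamped voltage: within each constant-
voltage segment ``x(t) = x_∞ + (x₀ − x_∞) e^{−t/τ}``, so voltage-clamp
families are computed in closed form when the series resistance is zero.
Current clamp integrates the full system with exponential-Euler updates at
dt = 0.025 ms (2× oversampling relative to the 20 kHz output grid) in a
numba kernel.

Units: mV, pA, nS, pF, ms; note nS·mV = pA and pF/nS = ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .trace import (
    ProtocolDescriptor,
    ProtocolError,
    Recording,
    Sweep,
    cc_step_protocol,
    membrane_test_protocol,
)

__all__ = [
    "GateParams",
    "NeuronParams",
    "standard_neuron",
    "gate_inf",
    "steady_state_current",
    "holding_current",
    "simulate_voltage_clamp_family",
    "simulate_current_clamp_family",
    "simulate_membrane_test",
    "NumericalError",
    "ConfigurationError",
    "ParameterError",
]

DT_INTERNAL_MS = 0.025  # current-clamp integrator step (2x oversampling at 20 kHz)


class NumericalError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GateParams:
    """Boltzmann steady state + fixed time constant of one gating variable."""

    vhalf_mV: float
    slope_mV: float  # negative slope -> inactivation gate
    tau_ms: float


@dataclass
class NeuronParams:
    Cm_pF: float = 25.0
    g_leak_nS: float = 2.0
    E_leak_mV: float = -65.0
    g_Na_nS: float = 90.0
    E_Na_mV: float = 60.0
    g_Kfast_nS: float = 40.0
    g_Kslow_nS: float = 30.0
    E_K_mV: float = -90.0
    m: GateParams = GateParams(-40.0, 5.0, 0.15)
    h: GateParams = GateParams(-50.0, -6.0, 4.0)
    a: GateParams = GateParams(-27.0, 12.0, 1.5)
    b: GateParams = GateParams(-65.0, -8.0, 30.0)
    n: GateParams = GateParams(-15.0, 10.0, 25.0)
    series_resistance_MOhm: float = 0.0

    def validate(self) -> None:
        if self.Cm_pF <= 0:
            raise ParameterError(f"Cm_pF must be > 0, got {self.Cm_pF}")
        for name in ("g_leak_nS", "g_Na_nS", "g_Kfast_nS", "g_Kslow_nS"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.series_resistance_MOhm < 0:
            raise ParameterError("series_resistance_MOhm must be >= 0")

    def scaled(self, **scales: float) -> "NeuronParams":
        """Return a copy with multiplicative scales applied, e.g.
        ``scaled(g_Na_nS=0.5)`` halves the sodium conductance."""
        changes = {}
        for name, s in scales.items():
            if not hasattr(self, name):
                raise ParameterError(f"unknown parameter {name!r}")
            changes[name] = getattr(self, name) * s
        return replace(self, **changes)


def standard_neuron(**overrides) -> NeuronParams:
    """The default excitable cell used throughout: fires on the upper current
    steps of the 3 pA family, shows a transient inward Na current peaking
    around −20..0 mV and early/sustained outward K currents."""
    return replace(NeuronParams(), **overrides)


GATE_NAMES = ("m", "h", "a", "b", "n")


def gate_inf(gate: GateParams, V: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-(V - gate.vhalf_mV) / gate.slope_mV))


def _gates_inf(p: NeuronParams, V):
    return {g: gate_inf(getattr(p, g), V) for g in GATE_NAMES}


def ionic_current(p: NeuronParams, V, m, h, a, b, n):
    """Total ionic current (pA, outward positive) at voltage V and gate states."""
    return (
        p.g_leak_nS * (V - p.E_leak_mV)
        + p.g_Na_nS * m**3 * h * (V - p.E_Na_mV)
        + p.g_Kfast_nS * a**3 * b * (V - p.E_K_mV)
        + p.g_Kslow_nS * n * (V - p.E_K_mV)
    )


def steady_state_current(p: NeuronParams, V):
    """Ionic current once every gate has relaxed to its steady state at V."""
    g = _gates_inf(p, V)
    return ionic_current(p, V, g["m"], g["h"], g["a"], g["b"], g["n"])


def holding_current(p: NeuronParams, V_hold_mV: float = -60.0) -> float:
    """Injected current holding the cell at ``V_hold_mV`` at rest.

    Raises :class:`ConfigurationError` if the steady-state I–V is not locally
    increasing there (no stable holding point).
    """
    dV = 0.5
    slope = (
        steady_state_current(p, V_hold_mV + dV) - steady_state_current(p, V_hold_mV - dV)
    ) / (2 * dV)
    if slope <= 0:
        raise ConfigurationError(
            f"steady-state I-V non-monotone at {V_hold_mV} mV; no stable holding current"
        )
    return float(steady_state_current(p, V_hold_mV))


# ---------------------------------------------------------------------------
# Voltage clamp (closed form per constant-voltage segment)
# ---------------------------------------------------------------------------


def _segment_currents(p: NeuronParams, V: float, x0: dict, n: int, dt: float):
    """Current waveform over one constant-voltage segment of ``n`` samples and
    the gate states at the segment's end (= start of the next segment)."""
    t_ms = np.arange(n) * dt
    gates = {}
    x_end = {}
    for name in GATE_NAMES:
        gp = getattr(p, name)
        xi = gate_inf(gp, V)
        gates[name] = xi + (x0[name] - xi) * np.exp(-t_ms / gp.tau_ms)
        x_end[name] = xi + (x0[name] - xi) * math.exp(-n * dt / gp.tau_ms)
    I = ionic_current(p, V, gates["m"], gates["h"], gates["a"], gates["b"], gates["n"])
    return I, x_end


def simulate_voltage_clamp_family(
    params: NeuronParams,
    protocol: ProtocolDescriptor,
    seed: int | None = None,
    *,
    sampling_rate_hz: float = 20_000.0,
    noise_sd_pA: float = 0.0,
) -> Recording:
    """Simulate one current sweep per voltage step of a vc_steps protocol.

    With zero series resistance the clamp is ideal: gate trajectories are the
    exact exponentials for each constant-voltage segment, and the capacitive
    transient collapses to a one-sample impulse of charge Cm·ΔV at each step
    edge.  A nonzero ``series_resistance_MOhm`` switches to explicit
    integration of the membrane voltage ODE.
    """
    params.validate()
    if protocol.kind != "vc_steps":
        raise ProtocolError(f"expected vc_steps protocol, got {protocol.kind!r}")
    dt = 1000.0 / sampling_rate_hz
    n_pre = int(round(protocol.pre_ms / dt))
    n_step = int(round(protocol.step_dur_ms / dt))
    n_post = int(round(protocol.post_ms / dt))
    levels = protocol.levels()
    hold = protocol.hold_level
    rng = np.random.default_rng(seed)

    sweeps = []
    x_hold = _gates_inf(params, hold)
    for level in levels:
        if params.series_resistance_MOhm > 0:
            resp = _vc_sweep_with_rs(params, hold, level, n_pre, n_step, n_post, dt)
        else:
            resp = np.empty(n_pre + n_step + n_post)
            I_pre, _ = _segment_currents(params, hold, x_hold, n_pre, dt)
            resp[:n_pre] = I_pre
            I_step, x1 = _segment_currents(params, level, x_hold, n_step, dt)
            resp[n_pre : n_pre + n_step] = I_step
            I_post, _ = _segment_currents(params, hold, x1, n_post, dt)
            resp[n_pre + n_step :] = I_post
            # ideal-clamp capacitive impulses at the edges (charge Cm*dV)
            dV = level - hold
            resp[n_pre] += params.Cm_pF * dV / dt
            resp[n_pre + n_step] -= params.Cm_pF * dV / dt
        if not np.all(np.isfinite(resp)):
            raise NumericalError(f"non-finite voltage-clamp response at dt={dt} ms")
        if noise_sd_pA > 0:
            resp = resp + rng.normal(0.0, noise_sd_pA, resp.shape)
        cmd = np.full(resp.shape, hold)
        cmd[n_pre : n_pre + n_step] = level
        sweeps.append(
            Sweep(cmd, resp, step_level=float(level), step_onset_ms=protocol.pre_ms,
                  step_dur_ms=protocol.step_dur_ms)
        )
    return Recording(
        sampling_rate_hz=sampling_rate_hz,
        mode="voltage_clamp",
        sweeps=sweeps,
        holding_level=hold,
        protocol=protocol,
        protocol_name="vc_steps",
    )


def _vc_sweep_with_rs(p, hold, level, n_pre, n_step, n_post, dt_out):
    """Imperfect clamp: integrate Cm dVm/dt = (Vcmd−Vm)/Rs − I_ion."""
    overs = max(1, int(round(dt_out / DT_INTERNAL_MS)))
    dt = dt_out / overs
    gs = 1000.0 / p.series_resistance_MOhm  # access conductance, nS
    x = _gates_inf(p, hold)
    # after a long hold Vm sits a small IR drop away from the command; the
    # pre-step segment lets any residual mismatch settle
    Vm = hold - steady_state_current(p, hold) / gs
    out = np.empty(n_pre + n_step + n_post)
    decay = {g: 1.0 - math.exp(-dt / getattr(p, g).tau_ms) for g in GATE_NAMES}
    n_tot = n_pre + n_step + n_post
    for j in range(n_tot):
        Vc = level if n_pre <= j < n_pre + n_step else hold
        for _ in range(overs):
            for gname in GATE_NAMES:
                xi = gate_inf(getattr(p, gname), Vm)
                x[gname] += (xi - x[gname]) * decay[gname]
            I_ion = ionic_current(p, Vm, x["m"], x["h"], x["a"], x["b"], x["n"])
            gna = p.g_Na_nS * x["m"] ** 3 * x["h"]
            gkf = p.g_Kfast_nS * x["a"] ** 3 * x["b"]
            gks = p.g_Kslow_nS * x["n"]
            gtot = p.g_leak_nS + gna + gkf + gks + gs
            Isum = (
                p.g_leak_nS * p.E_leak_mV + gna * p.E_Na_mV + (gkf + gks) * p.E_K_mV + gs * Vc
            )
            Vinf = Isum / gtot
            Vm = Vinf + (Vm - Vinf) * math.exp(-dt * gtot / p.Cm_pF)
        out[j] = gs * (Vc - Vm)
    return out


# ---------------------------------------------------------------------------
# Current clamp (numba exponential-Euler integrator)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cc_kernel(
    steps, I_hold, n_pre, n_step, n_post, overs, dt,
    Cm, gl, El, gNa, ENa, gKf, gKs, EK,
    m_vh, m_k, m_dec, h_vh, h_k, h_dec,
    a_vh, a_k, a_dec, b_vh, b_k, b_dec, n_vh, n_k, n_dec,
    V0, m0, h0, a0, b0, n0,
):  # pragma: no cover - exercised via simulate_current_clamp_family
    n_sw = steps.shape[0]
    n_out = n_pre + n_step + n_post
    V_out = np.empty((n_sw, n_out))
    for s in range(n_sw):
        V = V0
        m = m0
        h = h0
        a = a0
        b = b0
        n = n0
        for j in range(n_out):
            I_inj = steps[s] if n_pre <= j < n_pre + n_step else I_hold
            for _ in range(overs):
                m += (1.0 / (1.0 + math.exp(-(V - m_vh) / m_k)) - m) * m_dec
                h += (1.0 / (1.0 + math.exp(-(V - h_vh) / h_k)) - h) * h_dec
                a += (1.0 / (1.0 + math.exp(-(V - a_vh) / a_k)) - a) * a_dec
                b += (1.0 / (1.0 + math.exp(-(V - b_vh) / b_k)) - b) * b_dec
                n += (1.0 / (1.0 + math.exp(-(V - n_vh) / n_k)) - n) * n_dec
                gna = gNa * m * m * m * h
                gkf = gKf * a * a * a * b
                gks = gKs * n
                gtot = gl + gna + gkf + gks
                Isum = gl * El + gna * ENa + (gkf + gks) * EK + I_inj
                Vinf = Isum / gtot
                V = Vinf + (V - Vinf) * math.exp(-dt * gtot / Cm)
            V_out[s, j] = V
    return V_out


def simulate_current_clamp_family(
    params: NeuronParams,
    protocol: ProtocolDescriptor | None = None,
    seed: int | None = None,
    *,
    sampling_rate_hz: float = 20_000.0,
    noise_sd_mV: float = 0.0,
    dt_internal_ms: float = DT_INTERNAL_MS,
) -> Recording:
    """Simulate the 3 pA current-step family.

    The holding current keeping the cell at the protocol hold level (−60 mV)
    is solved first; a ``start_level`` of ``None`` in the protocol then
    resolves to ``holding_current − 12`` pA, the canonical first step.
    """
    params.validate()
    if protocol is None:
        protocol = cc_step_protocol()
    if protocol.kind != "cc_steps":
        raise ProtocolError(f"expected cc_steps protocol, got {protocol.kind!r}")
    V_hold = protocol.hold_level
    I_hold = holding_current(params, V_hold)
    if protocol.start_level is None:
        protocol = replace(protocol, start_level=I_hold - 12.0)
    dt_out = 1000.0 / sampling_rate_hz
    overs = max(1, int(round(dt_out / dt_internal_ms)))
    dt = dt_out / overs
    n_pre = int(round(protocol.pre_ms / dt_out))
    n_step = int(round(protocol.step_dur_ms / dt_out))
    n_post = int(round(protocol.post_ms / dt_out))
    levels = protocol.levels()
    x0 = _gates_inf(params, V_hold)
    dec = {g: 1.0 - math.exp(-dt / getattr(params, g).tau_ms) for g in GATE_NAMES}
    p = params
    V = _cc_kernel(
        np.asarray(levels, dtype=np.float64), I_hold, n_pre, n_step, n_post, overs, dt,
        p.Cm_pF, p.g_leak_nS, p.E_leak_mV, p.g_Na_nS, p.E_Na_mV,
        p.g_Kfast_nS, p.g_Kslow_nS, p.E_K_mV,
        p.m.vhalf_mV, p.m.slope_mV, dec["m"], p.h.vhalf_mV, p.h.slope_mV, dec["h"],
        p.a.vhalf_mV, p.a.slope_mV, dec["a"], p.b.vhalf_mV, p.b.slope_mV, dec["b"],
        p.n.vhalf_mV, p.n.slope_mV, dec["n"],
        V_hold, x0["m"], x0["h"], x0["a"], x0["b"], x0["n"],
    )
    if not np.all(np.isfinite(V)):
        raise NumericalError(f"non-finite membrane potential at dt={dt} ms")
    rng = np.random.default_rng(seed)
    sweeps = []
    for i, level in enumerate(levels):
        resp = V[i]
        if noise_sd_mV > 0:
            resp = resp + rng.normal(0.0, noise_sd_mV, resp.shape)
        cmd = np.full(resp.shape, I_hold)
        cmd[n_pre : n_pre + n_step] = level
        sweeps.append(
            Sweep(cmd, resp, step_level=float(level), step_onset_ms=protocol.pre_ms,
                  step_dur_ms=protocol.step_dur_ms)
        )
    return Recording(
        sampling_rate_hz=sampling_rate_hz,
        mode="current_clamp",
        sweeps=sweeps,
        holding_level=V_hold,
        protocol=protocol,
        protocol_name="cc_steps",
    )


# ---------------------------------------------------------------------------
# Membrane test
# ---------------------------------------------------------------------------


def simulate_membrane_test(
    params: NeuronParams,
    step_mV: float = -10.0,
    seed: int | None = None,
    *,
    protocol: ProtocolDescriptor | None = None,
    sampling_rate_hz: float = 20_000.0,
    noise_sd_pA: float = 0.0,
) -> Recording:
    """Analytic RC(+access resistance) current response to a small voltage step.

    The step is small and hyperpolarizing (default −10 mV from −70 mV), so
    voltage-gated channels stay shut and the cell is a passive RC: with ideal
    clamp the transient is a one-sample impulse of charge Cm·ΔV; with series
    resistance Rs the transient decays with τ = Cm·Rs·Rm/(Rs+Rm).
    """
    params.validate()
    if protocol is None:
        protocol = membrane_test_protocol(step_mV=step_mV)
    if protocol.kind != "membrane_test":
        raise ProtocolError(f"expected membrane_test protocol, got {protocol.kind!r}")
    if step_mV == 0:
        raise ParameterError("step_mV must be nonzero")
    dt = 1000.0 / sampling_rate_hz
    hold = protocol.hold_level
    n_pre = int(round(protocol.pre_ms / dt))
    n_step = int(round(protocol.step_dur_ms / dt))
    n_post = int(round(protocol.post_ms / dt))
    n_tot = n_pre + n_step + n_post
    Rm = 1000.0 / params.g_leak_nS  # MOhm
    Rs = params.series_resistance_MOhm
    if Rs > 0:
        tau = params.Cm_pF * Rs * Rm / (Rs + Rm) * 1e-3  # ms
        I_base = 1000.0 * (hold - params.E_leak_mV) / (Rs + Rm)
        dI_ss = 1000.0 * step_mV / (Rs + Rm)
        t = np.arange(n_step) * dt
        transient = 1000.0 * step_mV / Rs * np.exp(-t / tau) + dI_ss * (1 - np.exp(-t / tau))
        resp = np.full(n_tot, I_base)
        resp[n_pre : n_pre + n_step] = I_base + transient
        t2 = np.arange(n_post) * dt
        # relaxation back after the step
        resp[n_pre + n_step :] = I_base + (-1000.0 * step_mV / Rs) * np.exp(-t2 / tau) * (
            1 - math.exp(-n_step * dt / tau)
        )
    else:
        I_base = params.g_leak_nS * (hold - params.E_leak_mV)
        resp = np.full(n_tot, I_base)
        resp[n_pre : n_pre + n_step] = I_base + params.g_leak_nS * step_mV
        resp[n_pre] += params.Cm_pF * step_mV / dt
        if n_post > 0:
            resp[n_pre + n_step] -= params.Cm_pF * step_mV / dt
    cmd = np.full(n_tot, hold)
    cmd[n_pre : n_pre + n_step] = hold + step_mV
    rng = np.random.default_rng(seed)
    sweeps = []
    for _ in range(protocol.n_steps):
        r = resp.copy()
        if noise_sd_pA > 0:
            r += rng.normal(0.0, noise_sd_pA, r.shape)
        sweeps.append(
            Sweep(cmd.copy(), r, step_level=hold + step_mV, step_onset_ms=protocol.pre_ms,
                  step_dur_ms=protocol.step_dur_ms)
        )
    return Recording(
        sampling_rate_hz=sampling_rate_hz,
        mode="membrane_test",
        sweeps=sweeps,
        holding_level=hold,
        protocol=protocol,
        protocol_name="membrane_test",
    )
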