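"""Intrinsic-property features: evoked spikes, passive properties, IV tables.

The measurement conventions follow common practice for iPSC-derived neuron
studies: evoked excitability is the total number of action potentials over
the first 32 current steps of the 3 pA / 400 ms family; capacitance comes
from charge integration of the membrane-test transient (C = Q/ΔV); input
conductance is the two-point slope between −70 and −50 mV holding currents;
and Na/K currents are read from the voltage-step family after
passive-current subtraction (subthreshold-template by default), normalized
by capacitance into densities (pA/pF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trace import ModeError, ProtocolError, Recording, Sweep

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeCriteria",
    "IVOptions",
    "IVTable",
    "EstimationError",
    "detect_spikes",
    "count_evoked_aps",
    "estimate_capacitance",
    "compute_input_conductance",
    "extract_iv_table",
    "summarize_band",
    "NA_BAND",
    "K_BAND",
]

#: canonical comparison bands: Na −20..0 mV, K +50..+90 mV
NA_BAND = (-20.0, 0.0)
K_BAND = (50.0, 90.0)


class EstimationError(RuntimeError):
    """A quantity could not be resolved from the data (e.g. transient below
    the noise floor)."""


@dataclass
class SpikeCriteria:
    """Action-potential detection rule: upward crossings of a fixed voltage
    threshold with a refractory lockout; optionally gated on dV/dt."""

    threshold_mV: float = 0.0
    min_interspike_ms: float = 2.0
    dVdt_threshold: float | None = None  # mV/ms, optional extra gate

    def __post_init__(self) -> None:
        if self.min_interspike_ms <= 0:
            raise ValueError("min_interspike_ms must be > 0")


def detect_spikes(
    sweep: Sweep, criteria: SpikeCriteria | None = None, *,
    sampling_rate_hz: float = 20_000.0, mode: str = "current_clamp",
) -> np.ndarray:
    """Spike times (ms from sweep start) in one current-clamp sweep."""
    if mode != "current_clamp":
        raise ModeError(f"spike detection requires a current-clamp sweep, got mode {mode!r}")
    c = criteria or SpikeCriteria()
    v = np.asarray(sweep.response)
    dt = 1000.0 / sampling_rate_hz
    up = np.nonzero((v[:-1] < c.threshold_mV) & (v[1:] >= c.threshold_mV))[0] + 1
    if c.dVdt_threshold is not None and len(up):
        dvdt = np.gradient(v, dt)
        up = up[dvdt[up] >= c.dVdt_threshold]
    times = up * dt
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= c.min_interspike_ms:
            kept.append(t)
    return np.asarray(kept)


def count_evoked_aps(
    rec: Recording, criteria: SpikeCriteria | None = None, *, max_steps: int = 32
) -> int:
    """Total action potentials within the step windows of the first
    ``max_steps`` sweeps of a 3 pA current-step family."""
    rec.require_mode("current_clamp")
    if rec.protocol is not None and rec.protocol.kind != "cc_steps":
        raise ProtocolError(f"expected cc_steps protocol, got {rec.protocol.kind!r}")
    if not rec.sweeps:
        raise ProtocolError("recording has no sweeps")
    if len(rec.sweeps) < max_steps:
        logger.warning(
            "cc family has %d sweeps (< %d); counting over available sweeps",
            len(rec.sweeps), max_steps,
        )
    total = 0
    for sw in rec.sweeps[:max_steps]:
        times = detect_spikes(sw, criteria, sampling_rate_hz=rec.sampling_rate_hz)
        t0, t1 = sw.step_onset_ms, sw.step_onset_ms + sw.step_dur_ms
        total += int(np.sum((times >= t0) & (times <= t1)))
    return total


def estimate_capacitance(rec: Recording) -> float:
    """Capacitance (pF) by charge integration of the membrane-test transient.

    Per sweep, Q is the integral of (response − steady-state) over the step
    window and C = Q/ΔV; sweeps are averaged.  Raises
    :class:`EstimationError` when the transient does not rise above the
    baseline noise.
    """
    rec.require_mode("membrane_test")
    dt = rec.dt_ms
    if rec.protocol is None:
        raise ProtocolError("membrane-test recording lacks a protocol")
    step_mV = rec.sweeps[0].step_level - rec.protocol.hold_level
    if step_mV == 0:
        raise ValueError("membrane-test step_mV is zero")
    estimates = []
    for sw in rec.sweeps:
        on = int(round(sw.step_onset_ms / dt))
        off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
        steady = sw.response[on + (off - on) // 2 : off].mean()
        seg = sw.response[on:off] - steady
        q = seg.sum() * dt  # pA*ms = fC
        baseline = sw.response[:on]
        noise_sd = baseline.std() if len(baseline) > 3 else 0.0
        if np.abs(seg).max() < 3 * noise_sd:
            raise EstimationError("capacitive transient not resolvable above noise")
        estimates.append(q / step_mV)  # fC/mV = pF
    c = float(np.mean(estimates))
    if c <= 0:
        raise EstimationError(f"non-positive capacitance estimate ({c:.3g} pF)")
    return c


def compute_input_conductance(rec_or_pair) -> float:
    """Input conductance g_in = (I(−50) − I(−70)) / 20 mV, in nS.

    Accepts either a pair ``(I_at_-70_pA, I_at_-50_pA)`` or a voltage-clamp
    step Recording whose family includes −70 and −50 mV steps (steady-state
    current = mean of the last 50 ms of each step).
    """
    if isinstance(rec_or_pair, Recording):
        rec = rec_or_pair
        rec.require_mode("voltage_clamp")
        currents = {}
        dt = rec.dt_ms
        for sw in rec.sweeps:
            if sw.step_level in (-70.0, -50.0):
                off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
                i0 = off - int(round(50.0 / dt))
                currents[sw.step_level] = sw.response[i0:off].mean()
        if -70.0 not in currents or -50.0 not in currents:
            raise ValueError("recording lacks −70 and/or −50 mV steps")
        i70, i50 = currents[-70.0], currents[-50.0]
    else:
        i70, i50 = rec_or_pair
    return float((i50 - i70) / 20.0)


@dataclass
class IVOptions:
    """Windows and switches for IV-family feature extraction.

    The capacitive transient is blanked for ``blank_ms`` after each edge; the
    Na window extends 10 ms past onset, the fast-K window 25 ms (the early
    outward peak), and slow K averages the last ``kslow_window_ms`` of the
    step.

    ``leak_subtract`` selects the passive-current correction: ``"template"``
    (default) subtracts the averaged subthreshold-step waveform scaled per mV
    (P/N-style, removing leak, standing conductance and capacitive
    transient), ``"linear"``/``True`` subtracts a line fitted to the steady
    subthreshold currents, and ``False`` disables correction.
    """

    leak_subtract: bool | str = "template"
    leak_fit_range: tuple[float, float] = (-90.0, -70.0)
    blank_ms: float = 0.5
    na_window_ms: float = 10.0
    kfast_window_ms: float = 25.0
    kslow_window_ms: float = 50.0
    baseline_ms: float = 50.0


@dataclass
class IVTable:
    """Current densities (pA/pF) aligned to the voltage-step grid."""

    voltages_mV: np.ndarray
    na_density: np.ndarray
    kfast_density: np.ndarray
    kslow_density: np.ndarray
    leak_conductance_nS: float = np.nan  # fitted leak (NaN if not subtracted)

    def __post_init__(self) -> None:
        n = len(self.voltages_mV)
        if not (len(self.na_density) == len(self.kfast_density) == len(self.kslow_density) == n):
            raise ValueError("density arrays must match the voltage vector length")


def extract_iv_table(
    rec: Recording, capacitance_pF: float, options: IVOptions | None = None
) -> IVTable:
    """Extract Na / fast-K / slow-K current densities from a voltage-step
    family."""
    rec.require_mode("voltage_clamp")
    if rec.protocol is not None and rec.protocol.kind != "vc_steps":
        raise ProtocolError(f"expected vc_steps protocol, got {rec.protocol.kind!r}")
    if capacitance_pF <= 0:
        raise ValueError(f"capacitance must be > 0, got {capacitance_pF}")
    opt = options or IVOptions()
    dt = rec.dt_ms
    hold = rec.holding_level

    order = np.argsort([sw.step_level for sw in rec.sweeps])
    sweeps = [rec.sweeps[i] for i in order]
    volts = np.array([sw.step_level for sw in sweeps])

    baselines = {}
    steadies = {}
    for sw in sweeps:
        on = int(round(sw.step_onset_ms / dt))
        off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
        nb = int(round(opt.baseline_ms / dt))
        baselines[sw.step_level] = sw.response[max(0, on - nb) : on].mean()
        nk = int(round(opt.kslow_window_ms / dt))
        steadies[sw.step_level] = sw.response[off - nk : off].mean()

    g_leak = np.nan
    template = None
    if opt.leak_subtract:
        lo, hi = opt.leak_fit_range
        sel = (volts >= lo) & (volts <= hi)
        if sel.sum() < 2:
            raise ValueError(
                f"leak subtraction needs >=2 steps in {opt.leak_fit_range}; "
                f"disable leak_subtract or extend the family"
            )
        vv = volts[sel]
        ii = np.array([steadies[v] - baselines[v] for v in vv])
        g_leak = float(np.polyfit(vv - hold, ii, 1)[0])  # nS
        if opt.leak_subtract == "template":
            # subthreshold-template subtraction (P/N style): average the
            # baseline-subtracted waveform of the subthreshold steps,
            # normalized per mV of step, and scale it to each test step.
            # Unlike the steady-state linear fit this also removes the
            # instantaneous driving-force jump of channels already open at
            # the holding potential and the capacitive transient.
            waves = []
            for sw in sweeps:
                if not (lo <= sw.step_level <= hi) or sw.step_level == hold:
                    continue
                on = int(round(sw.step_onset_ms / dt))
                off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
                waves.append(
                    (sw.response[on:off] - baselines[sw.step_level])
                    / (sw.step_level - hold)
                )
            template = np.mean(waves, axis=0)  # pA per mV of step

    na = np.empty(len(sweeps))
    kf = np.empty(len(sweeps))
    ks = np.empty(len(sweeps))
    for i, sw in enumerate(sweeps):
        on = int(round(sw.step_onset_ms / dt))
        off = int(round((sw.step_onset_ms + sw.step_dur_ms) / dt))
        blank = int(round(opt.blank_ms / dt))
        step = sw.response[on:off] - baselines[sw.step_level]
        if template is not None:
            step = step - template * (sw.step_level - hold)
        elif opt.leak_subtract:
            step = step - g_leak * (sw.step_level - hold)
        na_win = step[blank : int(round(opt.na_window_ms / dt))]
        kf_win = step[blank : int(round(opt.kfast_window_ms / dt))]
        ks_win = step[-int(round(opt.kslow_window_ms / dt)) :]
        na[i] = min(na_win.min(), 0.0)  # inward only
        kf[i] = max(kf_win.max(), 0.0)  # outward only
        ks[i] = max(ks_win.mean(), 0.0)
    return IVTable(volts, na / capacitance_pF, kf / capacitance_pF, ks / capacitance_pF, g_leak)


def summarize_band(iv: IVTable, band: tuple[float, float], measure: str) -> float:
    """Mean density of ``measure`` over the voltage steps inside ``band``
    (inclusive); the canonical bands are ``NA_BAND`` (−20..0 mV) for
    ``na_density`` and ``K_BAND`` (+50..+90 mV) for the K measures."""
    lo, hi = band
    sel = (iv.voltages_mV >= lo) & (iv.voltages_mV <= hi)
    if not sel.any():
        raise ValueError(f"no voltage steps inside band {band}")
    return float(getattr(iv, measure)[sel].mean())
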