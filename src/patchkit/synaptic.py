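"""Generator for gap-free voltage-clamp traces with spontaneous EPSCs.

Events arrive as a homogeneous Poisson process; amplitudes are log-normal;
each event adds an inward (negative) deflection shaped as a unit-peak
bi-exponential kernel ``K(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)``.  The
baseline is the cell's holding current at −60 mV plus Gaussian noise
low-pass filtered at a configurable corner frequency and rescaled to the
requested standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .neuron import NeuronParams, ParameterError, standard_neuron, steady_state_current
from .trace import Recording, Sweep, gap_free_protocol

__all__ = ["SynapticParams", "EventList", "epsc_kernel", "simulate_synaptic_trace"]


@dataclass
class EventList:
    """Ground-truth or detected synaptic events of one trace.

    ``times_ms`` are event onsets, strictly ascending; ``amplitudes_pA`` are
    the positive magnitudes of the inward deflections.
    """

    times_ms: np.ndarray
    amplitudes_pA: np.ndarray
    trace_duration_s: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=np.float64)
        if len(self.times_ms) != len(self.amplitudes_pA):
            raise ValueError("times and amplitudes must have equal length")
        if len(self.times_ms) > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(self.amplitudes_pA <= 0):
            raise ValueError("amplitudes must be > 0")

    def __len__(self) -> int:
        return len(self.times_ms)


@dataclass
class SynapticParams:
    rate_hz: float = 1.5
    amp_logmean: float = float(np.log(22.0))  # log pA; median ~22 pA
    amp_logsd: float = 0.55
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 6.0
    noise_sd_pA: float = 3.0
    noise_corner_hz: float = 1000.0
    duration_s: float = 60.0

    def validate(self) -> None:
        if self.rate_hz < 0:
            raise ParameterError("rate_hz must be >= 0")
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ParameterError(
                f"need 0 < tau_rise ({self.tau_rise_ms}) < tau_decay ({self.tau_decay_ms})"
            )
        if self.noise_sd_pA < 0:
            raise ParameterError("noise_sd_pA must be >= 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")


def epsc_kernel(tau_rise_ms: float, tau_decay_ms: float, dt_ms: float,
                n_taus: float = 8.0) -> np.ndarray:
    """Unit-peak bi-exponential kernel sampled at dt, truncated at
    ``n_taus`` decay constants."""
    if not 0 < tau_rise_ms < tau_decay_ms:
        raise ParameterError("need 0 < tau_rise < tau_decay")
    n = int(round(n_taus * tau_decay_ms / dt_ms))
    t = np.arange(n) * dt_ms
    k = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    return k / k.max()


def filtered_noise(n: int, sd: float, corner_hz: float, fs_hz: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    pad = int(round(0.1 * fs_hz))  # discard the filter's startup transient
    white = rng.normal(0.0, 1.0, n + pad)
    if corner_hz < fs_hz / 2:
        b, a = signal.butter(2, corner_hz / (fs_hz / 2))
        x = signal.lfilter(b, a, white)[pad:]
    else:
        x = white[pad:]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_synaptic_trace(
    params: SynapticParams,
    sampling_rate_hz: float = 20_000.0,
    seed: int | None = None,
    *,
    neuron: NeuronParams | None = None,
    hold_mV: float = -60.0,
    forced_events: EventList | None = None,
) -> tuple[Recording, EventList]:
    """Simulate a gap-free −60 mV recording and return it with its exact
    ground-truth event list.

    ``forced_events`` bypasses the Poisson/log-normal draw and injects the
    given events instead (used to build fully controlled test traces).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate_hz
    n = int(round(params.duration_s * sampling_rate_hz))
    if neuron is None:
        neuron = standard_neuron()
    baseline = float(steady_state_current(neuron, hold_mV))

    if forced_events is not None:
        events = forced_events
    else:
        n_ev = rng.poisson(params.rate_hz * params.duration_s)
        times = np.sort(rng.uniform(0.0, params.duration_s * 1000.0, n_ev))
        # jitter exact ties apart (zero-probability event, but keep the
        # strict-ascending invariant airtight)
        while len(times) > 1 and np.any(np.diff(times) <= 0):
            times += np.arange(len(times)) * 1e-9
            times = np.sort(times)
        amps = rng.lognormal(params.amp_logmean, params.amp_logsd, n_ev)
        events = EventList(times, amps, params.duration_s)

    trace = np.full(n, baseline)
    trace += filtered_noise(n, params.noise_sd_pA, params.noise_corner_hz,
                            sampling_rate_hz, rng)
    if len(events):
        kern = epsc_kernel(params.tau_rise_ms, params.tau_decay_ms, dt)
        for t_ms, amp in zip(events.times_ms, events.amplitudes_pA):
            i0 = int(round(t_ms / dt))
            if i0 >= n:
                continue
            seg = min(len(kern), n - i0)
            trace[i0 : i0 + seg] -= amp * kern[:seg]

    proto = gap_free_protocol(params.duration_s, hold_mV)
    cmd = np.full(n, hold_mV)
    sweep = Sweep(cmd, trace, step_level=hold_mV, step_onset_ms=0.0,
                  step_dur_ms=params.duration_s * 1000.0)
    rec = Recording(
        sampling_rate_hz=sampling_rate_hz,
        mode="gap_free_vc",
        sweeps=[sweep],
        holding_level=hold_mV,
        protocol=proto,
        protocol_name="gap_free",
    )
    return rec, events
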