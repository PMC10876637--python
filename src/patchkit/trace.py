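"""Domain containers for patch-clamp recordings.

A :class:`Recording` holds an ordered family of :class:`Sweep` objects sharing
one sampling rate and one clamp mode.  The clamp mode fixes the units of the
command and response waveforms:

================  ==============  ===============
mode              command units   response units
================  ==============  ===============
current_clamp     pA (injected)   mV (membrane V)
voltage_clamp     mV (command V)  pA (current)
gap_free_vc       mV (command V)  pA (current)
membrane_test     mV (command V)  pA (current)
================  ==============  ===============

All times are milliseconds, currents pA, voltages mV, capacitances pF,
conductances nS, current densities pA/pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "PROTOCOL_KINDS",
    "Sweep",
    "Recording",
    "ProtocolDescriptor",
    "CellFeatureRow",
    "ValidationError",
    "FormatError",
    "ModeError",
    "ProtocolError",
    "validate_recording",
    "cc_step_protocol",
    "vc_step_protocol",
    "gap_free_protocol",
    "membrane_test_protocol",
    "feature_frame",
    "rows_from_frame",
]

MODES = ("current_clamp", "voltage_clamp", "gap_free_vc", "membrane_test")
PROTOCOL_KINDS = ("cc_steps", "vc_steps", "gap_free", "membrane_test")

#: clamp mode -> protocol kind expected by the analysis stages
MODE_TO_KIND = {
    "current_clamp": "cc_steps",
    "voltage_clamp": "vc_steps",
    "gap_free_vc": "gap_free",
    "membrane_test": "membrane_test",
}


class ValidationError(ValueError):
    """A container violates one of its documented invariants."""


class FormatError(ValueError):
    """An on-disk file does not follow the canonical layout."""


class ModeError(ValueError):
    """A recording's clamp mode does not match the requested analysis."""


class ProtocolError(ValueError):
    """A recording's protocol does not match the requested analysis."""


@dataclass
class ProtocolDescriptor:
    """Parametric description of a stimulus protocol.

    ``start_level`` may be ``None`` for cc_steps, meaning "resolve relative to
    the steady holding current" (the canonical rule: 12 pA below the holding
    current that keeps the cell at −60 mV); the simulator fills it in.
    """

    kind: str
    start_level: float | None
    increment: float
    n_steps: int
    step_dur_ms: float
    pre_ms: float
    post_ms: float
    hold_level: float

    def levels(self) -> np.ndarray:
        if self.start_level is None:
            raise ProtocolError("start_level unresolved (cc_steps relative protocol)")
        return self.start_level + self.increment * np.arange(self.n_steps)

    @property
    def sweep_duration_ms(self) -> float:
        return self.pre_ms + self.step_dur_ms + self.post_ms


def cc_step_protocol(
    start_level: float | None = None,
    *,
    increment: float = 3.0,
    n_steps: int = 32,
    step_dur_ms: float = 400.0,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    hold_level: float = -60.0,
) -> ProtocolDescriptor:
    """Current-step protocol: 3 pA increments, 400 ms steps, first step
    12 pA below the steady holding current (``start_level=None`` defers the
    resolution to the simulator, which solves for the holding current)."""
    return ProtocolDescriptor(
        "cc_steps", start_level, increment, n_steps, step_dur_ms, pre_ms, post_ms, hold_level
    )


def vc_step_protocol(
    *,
    start_mV: float = -90.0,
    increment_mV: float = 10.0,
    n_steps: int = 18,
    step_dur_ms: float = 400.0,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    hold_mV: float = -60.0,
) -> ProtocolDescriptor:
    """Voltage-step family spanning −90..+80 mV (default 10 mV grid) from a
    −60 mV hold, 400 ms steps."""
    return ProtocolDescriptor(
        "vc_steps", start_mV, increment_mV, n_steps, step_dur_ms, pre_ms, post_ms, hold_mV
    )


def gap_free_protocol(duration_s: float, hold_mV: float = -60.0) -> ProtocolDescriptor:
    return ProtocolDescriptor("gap_free", hold_mV, 0.0, 1, duration_s * 1000.0, 0.0, 0.0, hold_mV)


def membrane_test_protocol(
    *,
    step_mV: float = -10.0,
    hold_mV: float = -70.0,
    step_dur_ms: float = 100.0,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
    n_sweeps: int = 8,
) -> ProtocolDescriptor:
    """Repeated small hyperpolarizing square pulse used to read out the
    capacitive transient (Clampex-style membrane test)."""
    return ProtocolDescriptor(
        "membrane_test", hold_mV + step_mV, 0.0, n_sweeps, step_dur_ms, pre_ms, post_ms, hold_mV
    )


@dataclass
class Sweep:
    """One command/response pair on a regular time grid."""

    command: np.ndarray
    response: np.ndarray
    step_level: float
    step_onset_ms: float
    step_dur_ms: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.response)


@dataclass
class Recording:
    sampling_rate_hz: float
    mode: str
    sweeps: list[Sweep]
    holding_level: float = 0.0
    protocol: ProtocolDescriptor | None = None
    cell_id: str = ""
    line_id: str = ""
    group_label: str = ""
    protocol_name: str = ""

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.sweeps[0]) if self.sweeps else 0

    def time_ms(self) -> np.ndarray:
        """Time axis of one sweep, in ms from sweep start."""
        return np.arange(self.n_samples) * self.dt_ms

    def require_mode(self, *modes: str) -> None:
        if self.mode not in modes:
            raise ModeError(
                f"recording mode {self.mode!r} incompatible with analysis expecting {modes}"
            )


def validate_recording(rec: Recording) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    issues: list[str] = []
    if not np.isfinite(rec.sampling_rate_hz) or rec.sampling_rate_hz <= 0:
        issues.append(f"sampling_rate_hz must be > 0, got {rec.sampling_rate_hz}")
    if rec.mode not in MODES:
        issues.append(f"mode must be one of {MODES}, got {rec.mode!r}")
    if not rec.sweeps:
        issues.append("no sweeps")
        return issues
    n0 = len(rec.sweeps[0])
    for i, sw in enumerate(rec.sweeps):
        if len(sw.command) != len(sw.response):
            issues.append(
                f"sweep {i}: command length {len(sw.command)} != response length {len(sw.response)}"
            )
        if len(sw) != n0:
            issues.append(f"sweep {i}: length {len(sw)} differs from sweep 0 ({n0})")
        if rec.sampling_rate_hz > 0:
            dur = len(sw) / rec.sampling_rate_hz * 1000.0
            if sw.step_onset_ms + sw.step_dur_ms > dur + 1e-6:
                issues.append(
                    f"sweep {i}: step_onset_ms + step_dur_ms = "
                    f"{sw.step_onset_ms + sw.step_dur_ms:g} exceeds sweep duration {dur:g} ms"
                )
    proto = rec.protocol
    if proto is not None:
        if proto.kind not in PROTOCOL_KINDS:
            issues.append(f"protocol.kind must be one of {PROTOCOL_KINDS}, got {proto.kind!r}")
        if proto.n_steps < 1:
            issues.append(f"protocol.n_steps must be >= 1, got {proto.n_steps}")
        expected_kind = MODE_TO_KIND.get(rec.mode)
        if proto.kind in PROTOCOL_KINDS and expected_kind and proto.kind != expected_kind:
            issues.append(f"protocol.kind {proto.kind!r} inconsistent with mode {rec.mode!r}")
        # step-level consistency with the declared increment
        if proto.kind in ("cc_steps", "vc_steps") and len(rec.sweeps) >= 2:
            levels = np.array([sw.step_level for sw in rec.sweeps])
            incs = np.diff(levels)
            if proto.increment != 0 and not np.allclose(incs, proto.increment, atol=1e-6):
                issues.append(
                    f"sweep step levels increment by {incs[0]:g} but protocol declares "
                    f"increment {proto.increment:g}"
                )
        if proto.kind == "cc_steps":
            if not math.isclose(proto.increment, 3.0, abs_tol=1e-9):
                issues.append(f"cc_steps increment must be 3 pA, got {proto.increment:g}")
            if not math.isclose(proto.step_dur_ms, 400.0, abs_tol=1e-9):
                issues.append(f"cc_steps step_dur_ms must be 400, got {proto.step_dur_ms:g}")
    return issues


def check_valid(rec: Recording) -> None:
    issues = validate_recording(rec)
    if issues:
        raise ValidationError("; ".join(issues))


# ---------------------------------------------------------------------------
# Per-cell feature rows and their tabular form
# ---------------------------------------------------------------------------

SCALAR_FEATURES = (
    "evoked_ap_count",
    "epsc_rate_hz",
    "epsc_mean_amp_pA",
    "large_epsc_rate_hz",
    "capacitance_pF",
    "input_conductance_nS",
)

DENSITY_MEASURES = ("na_density", "kfast_density", "kslow_density")


@dataclass
class CellFeatureRow:
    """Scalar electrophysiological features of one cell plus its IV densities.

    Density arrays are pA/pF, indexed by ``voltages_mV`` (the voltage-step
    grid of the vc_steps protocol). ``epsc_mean_amp_pA`` is NaN when no EPSC
    was detected.
    """

    cell_id: str
    line_id: str
    group_label: str
    evoked_ap_count: float = np.nan
    epsc_rate_hz: float = np.nan
    epsc_mean_amp_pA: float = np.nan
    large_epsc_rate_hz: float = np.nan
    capacitance_pF: float = np.nan
    input_conductance_nS: float = np.nan
    voltages_mV: np.ndarray = field(default_factory=lambda: np.array([]))
    na_density: np.ndarray = field(default_factory=lambda: np.array([]))
    kfast_density: np.ndarray = field(default_factory=lambda: np.array([]))
    kslow_density: np.ndarray = field(default_factory=lambda: np.array([]))


def _density_col(measure: str, v: float) -> str:
    return f"{measure}_{int(round(v))}mV"


def feature_frame(rows: Iterable[CellFeatureRow]) -> pd.DataFrame:
    """Flatten feature rows into a DataFrame, one density column per voltage
    (e.g. ``na_density_-20mV``)."""
    records = []
    for r in rows:
        rec: dict[str, object] = {
            "cell_id": r.cell_id,
            "line_id": r.line_id,
            "group_label": r.group_label,
        }
        for name in SCALAR_FEATURES:
            rec[name] = getattr(r, name)
        for measure in DENSITY_MEASURES:
            arr = getattr(r, measure)
            for v, d in zip(r.voltages_mV, arr):
                rec[_density_col(measure, v)] = d
        records.append(rec)
    return pd.DataFrame.from_records(records)


def density_columns(frame: pd.DataFrame, measure: str) -> tuple[np.ndarray, list[str]]:
    """Voltages and column names for one density measure, voltage-ascending."""
    pairs = []
    prefix = measure + "_"
    for col in frame.columns:
        if col.startswith(prefix) and col.endswith("mV"):
            pairs.append((float(col[len(prefix):-2]), col))
    pairs.sort()
    return np.array([v for v, _ in pairs]), [c for _, c in pairs]


def rows_from_frame(frame: pd.DataFrame) -> list[CellFeatureRow]:
    rows = []
    volts, na_cols = density_columns(frame, "na_density")
    _, kf_cols = density_columns(frame, "kfast_density")
    _, ks_cols = density_columns(frame, "kslow_density")
    for _, rec in frame.iterrows():
        rows.append(
            CellFeatureRow(
                cell_id=str(rec["cell_id"]),
                line_id=str(rec["line_id"]),
                group_label=str(rec["group_label"]),
                **{name: float(rec[name]) for name in SCALAR_FEATURES},
                voltages_mV=volts,
                na_density=rec[na_cols].to_numpy(dtype=float) if len(na_cols) else np.array([]),
                kfast_density=rec[kf_cols].to_numpy(dtype=float) if len(kf_cols) else np.array([]),
                kslow_density=rec[ks_cols].to_numpy(dtype=float) if len(ks_cols) else np.array([]),
            )
        )
    return rows
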