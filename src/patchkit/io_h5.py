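"""Canonical HDF5 storage for recordings.

Layout (format_version 1):

* root attrs: ``format_version``, ``sampling_rate_hz``, ``mode``,
  ``holding_level``, ``cell_id``, ``line_id``, ``group_label``,
  ``protocol_name``
* ``/protocol`` attrs: the :class:`~patchkit.trace.ProtocolDescriptor` fields
* ``/sweeps/0000``, ``/sweeps/0001``, ... each with datasets ``command`` and
  ``response`` (float64) and attrs ``t0_ms``, ``step_level``,
  ``step_onset_ms``, ``step_dur_ms``

Datasets are written with ``track_times=False`` so identical recordings yield
identical files.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .trace import (
    FormatError,
    MODES,
    ProtocolDescriptor,
    Recording,
    Sweep,
    check_valid,
)

__all__ = ["write_recording", "read_recording", "recording_digest", "FORMAT_VERSION"]

FORMAT_VERSION = 1

_PROTO_FIELDS = (
    "kind",
    "start_level",
    "increment",
    "n_steps",
    "step_dur_ms",
    "pre_ms",
    "post_ms",
    "hold_level",
)


def recording_digest(rec: Recording) -> str:
    """Canonical content digest of a recording (sha256 over waveforms and
    metadata).  Used for provenance manifests: HDF5 object headers embed
    creation times, so raw file bytes are not run-stable, but the stored
    content is."""
    import hashlib

    h = hashlib.sha256()
    h.update(
        repr((
            float(rec.sampling_rate_hz), rec.mode, float(rec.holding_level),
            rec.cell_id, rec.line_id, rec.group_label, rec.protocol_name,
        )).encode()
    )
    if rec.protocol is not None:
        h.update(repr(tuple(getattr(rec.protocol, f) for f in _PROTO_FIELDS)).encode())
    for sw in rec.sweeps:
        h.update(repr((sw.t0_ms, sw.step_level, sw.step_onset_ms, sw.step_dur_ms)).encode())
        h.update(np.ascontiguousarray(sw.command, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(sw.response, dtype=np.float64).tobytes())
    return h.hexdigest()


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write *rec* to *path* in the canonical layout.

    Raises :class:`~patchkit.trace.ValidationError` if *rec* violates its
    invariants, and the usual OSError family for unwritable paths.
    """
    check_valid(rec)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate_hz"] = float(rec.sampling_rate_hz)
        f.attrs["mode"] = rec.mode
        f.attrs["holding_level"] = float(rec.holding_level)
        f.attrs["cell_id"] = rec.cell_id
        f.attrs["line_id"] = rec.line_id
        f.attrs["group_label"] = rec.group_label
        f.attrs["protocol_name"] = rec.protocol_name
        if rec.protocol is not None:
            g = f.create_group("protocol")
            for name in _PROTO_FIELDS:
                val = getattr(rec.protocol, name)
                if val is None:
                    val = np.nan
                g.attrs[name] = val
        sweeps = f.create_group("sweeps")
        for i, sw in enumerate(rec.sweeps):
            g = sweeps.create_group(f"{i:04d}")
            g.create_dataset("command", data=np.asarray(sw.command, dtype=np.float64),
                             track_times=False)
            g.create_dataset("response", data=np.asarray(sw.response, dtype=np.float64),
                             track_times=False)
            g.attrs["t0_ms"] = float(sw.t0_ms)
            g.attrs["step_level"] = float(sw.step_level)
            g.attrs["step_onset_ms"] = float(sw.step_onset_ms)
            g.attrs["step_dur_ms"] = float(sw.step_dur_ms)


def read_recording(path: str | os.PathLike) -> Recording:
    """Read a canonical recording file; validates before returning."""
    with h5py.File(path, "r") as f:
        for attr in ("sampling_rate_hz", "mode"):
            if attr not in f.attrs:
                raise FormatError(f"missing mandatory root attribute {attr!r}")
        mode = str(f.attrs["mode"])
        if mode not in MODES:
            raise FormatError(f"unknown mode {mode!r}")
        if "sweeps" not in f:
            raise FormatError("missing /sweeps group")
        protocol = None
        if "protocol" in f:
            attrs = f["protocol"].attrs
            kwargs = {}
            for name in _PROTO_FIELDS:
                if name not in attrs:
                    raise FormatError(f"missing protocol attribute {name!r}")
                val = attrs[name]
                kwargs[name] = str(val) if name == "kind" else val
            if np.isnan(float(kwargs["start_level"])):
                kwargs["start_level"] = None
            else:
                kwargs["start_level"] = float(kwargs["start_level"])
            for name in ("increment", "step_dur_ms", "pre_ms", "post_ms", "hold_level"):
                kwargs[name] = float(kwargs[name])
            kwargs["n_steps"] = int(kwargs["n_steps"])
            protocol = ProtocolDescriptor(**kwargs)
        sweeps = []
        for key in sorted(f["sweeps"].keys()):
            g = f["sweeps"][key]
            if "command" not in g or "response" not in g:
                raise FormatError(f"sweep {key}: missing command/response dataset")
            sweeps.append(
                Sweep(
                    command=g["command"][...],
                    response=g["response"][...],
                    step_level=float(g.attrs.get("step_level", np.nan)),
                    step_onset_ms=float(g.attrs.get("step_onset_ms", 0.0)),
                    step_dur_ms=float(g.attrs.get("step_dur_ms", 0.0)),
                    t0_ms=float(g.attrs.get("t0_ms", 0.0)),
                )
            )
        rec = Recording(
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            mode=mode,
            sweeps=sweeps,
            holding_level=float(f.attrs.get("holding_level", 0.0)),
            protocol=protocol,
            cell_id=str(f.attrs.get("cell_id", "")),
            line_id=str(f.attrs.get("line_id", "")),
            group_label=str(f.attrs.get("group_label", "")),
            protocol_name=str(f.attrs.get("protocol_name", "")),
        )
    check_valid(rec)
    return rec
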