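"""Pipeline orchestration: simulate → extract → compare → report.

A run directory contains::

    dataset/<group>/<line>/<cell>/<protocol>.h5   simulated recordings
    dataset/ground_truth_cells.csv                drawn per-cell parameters
    dataset/ground_truth_events.csv               true synaptic events
    dataset/manifest.json                         config echo, seed, hashes
    features.csv                                  one CellFeatureRow per cell
    events.csv                                    detected EPSCs per cell
    qc.json                                       per-cell extraction log
    report.json / report.md                       group comparisons
    ecdf_<group>.csv                              pooled amplitude ECDFs

Everything except log timestamps is a pure function of (config, seed); JSON
is written with sorted keys and CSVs with a fixed column order so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ALL_PROTOCOLS,
    CohortSpec,
    GroupSpec,
    ground_truth_row,
    iter_cohort,
)
from .events import (
    DetectionParams,
    Ecdf,
    detect_epscs,
    event_statistics,
    large_event_rate,
)
from .intrinsic import (
    IVOptions,
    SpikeCriteria,
    compute_input_conductance,
    count_evoked_aps,
    estimate_capacitance,
    extract_iv_table,
)
from .io_h5 import read_recording, recording_digest, write_recording
from .neuron import GateParams, NeuronParams
from .stats import StatsPlan, compare_groups, results_to_records, summary_markdown
from .synaptic import EventList, SynapticParams
from .trace import CellFeatureRow, Recording, feature_frame

logger = logging.getLogger("patchkit.pipeline")

__all__ = [
    "PipelineConfig",
    "load_config",
    "extract_cell_features",
    "cohort_feature_table",
    "run_simulate",
    "run_extract",
    "run_compare",
    "run_all",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    cohort: CohortSpec | None = None
    input_dir: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    spikes: SpikeCriteria = field(default_factory=SpikeCriteria)
    iv: IVOptions = field(default_factory=IVOptions)
    stats: StatsPlan = field(default_factory=StatsPlan)
    out_dir: str = "run"
    master_seed: int | None = None
    control_label: str = "control"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "master_seed": self.master_seed,
            "control_label": self.control_label,
            "log_level": self.log_level,
            "input_dir": self.input_dir,
            "detection": dataclasses.asdict(self.detection),
            "spikes": dataclasses.asdict(self.spikes),
            "iv": dataclasses.asdict(self.iv),
            "stats": dataclasses.asdict(self.stats),
        }
        d["iv"]["leak_fit_range"] = list(self.iv.leak_fit_range)
        d["stats"]["scalar_features"] = list(self.stats.scalar_features)
        d["stats"]["na_band"] = list(self.stats.na_band)
        d["stats"]["k_band"] = list(self.stats.k_band)
        if self.cohort is not None:
            d["cohort"] = _cohort_to_dict(self.cohort)
        return d


def _neuron_to_dict(p: NeuronParams) -> dict:
    d = {}
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        d[f.name] = [v.vhalf_mV, v.slope_mV, v.tau_ms] if isinstance(v, GateParams) else v
    return d


def _neuron_from_dict(d: dict | None) -> NeuronParams:
    p = NeuronParams()
    if not d:
        return p
    changes = {}
    for key, val in d.items():
        if key in ("m", "h", "a", "b", "n"):
            changes[key] = GateParams(*val)
        else:
            changes[key] = val
    return replace(p, **changes)


def _cohort_to_dict(spec: CohortSpec) -> dict:
    return {
        "master_seed": spec.master_seed,
        "protocols": list(spec.protocols),
        "sampling_rate_hz": spec.sampling_rate_hz,
        "vc_noise_sd_pA": spec.vc_noise_sd_pA,
        "cc_noise_sd_mV": spec.cc_noise_sd_mV,
        "mt_noise_sd_pA": spec.mt_noise_sd_pA,
        "groups": [
            {
                "group_label": g.group_label,
                "n_lines": g.n_lines,
                "cells_per_line": g.cells_per_line,
                "line_cv": g.line_cv,
                "cell_cv": g.cell_cv,
                "effects": dict(g.effects),
                "neuron": _neuron_to_dict(g.neuron),
                "synaptic": dataclasses.asdict(g.synaptic),
            }
            for g in spec.groups
        ],
    }


def _cohort_from_dict(d: dict) -> CohortSpec:
    groups = []
    for g in d.get("groups", []):
        groups.append(
            GroupSpec(
                group_label=g["group_label"],
                n_lines=int(g.get("n_lines", 3)),
                cells_per_line=int(g.get("cells_per_line", 20)),
                neuron=_neuron_from_dict(g.get("neuron")),
                synaptic=replace(SynapticParams(), **(g.get("synaptic") or {})),
                effects=dict(g.get("effects") or {}),
                line_cv=float(g.get("line_cv", 0.1)),
                cell_cv=float(g.get("cell_cv", 0.25)),
            )
        )
    return CohortSpec(
        groups=groups,
        master_seed=int(d.get("master_seed", 0)),
        protocols=tuple(d.get("protocols", ALL_PROTOCOLS)),
        sampling_rate_hz=float(d.get("sampling_rate_hz", 20_000.0)),
        vc_noise_sd_pA=float(d.get("vc_noise_sd_pA", 2.0)),
        cc_noise_sd_mV=float(d.get("cc_noise_sd_mV", 0.2)),
        mt_noise_sd_pA=float(d.get("mt_noise_sd_pA", 1.0)),
    )


def config_from_dict(d: dict) -> PipelineConfig:
    cfg = PipelineConfig(
        cohort=_cohort_from_dict(d["cohort"]) if d.get("cohort") else None,
        input_dir=d.get("input_dir"),
        out_dir=d.get("out_dir", "run"),
        master_seed=d.get("master_seed"),
        control_label=d.get("control_label", "control"),
        log_level=d.get("log_level", "INFO"),
    )
    if d.get("detection"):
        cfg.detection = replace(DetectionParams(), **d["detection"])
    if d.get("spikes"):
        cfg.spikes = replace(SpikeCriteria(), **d["spikes"])
    if d.get("iv"):
        iv = dict(d["iv"])
        if "leak_fit_range" in iv:
            iv["leak_fit_range"] = tuple(iv["leak_fit_range"])
        cfg.iv = replace(IVOptions(), **iv)
    if d.get("stats"):
        st = dict(d["stats"])
        for key in ("scalar_features", "na_band", "k_band"):
            if key in st:
                st[key] = tuple(st[key])
        cfg.stats = replace(StatsPlan(), **st)
    if cfg.master_seed is not None and cfg.cohort is not None:
        cfg.cohort.master_seed = int(cfg.master_seed)
    return cfg


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a pipeline configuration from YAML or JSON."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(d or {})


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


#: config keys that describe where a run lives, not what it computes
_NON_SCIENTIFIC_KEYS = ("out_dir", "input_dir", "log_level")


def _scientific_config(cfg: PipelineConfig) -> dict:
    d = cfg.to_dict()
    for key in _NON_SCIENTIFIC_KEYS:
        d.pop(key, None)
    return d


def _config_hash(cfg: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (paths and log level are
    excluded so identical analyses hash identically wherever they run)."""
    return _sha256_text(json.dumps(_scientific_config(cfg), sort_keys=True))


# ---------------------------------------------------------------------------
# Per-cell feature extraction
# ---------------------------------------------------------------------------


def extract_cell_features(
    recordings: dict[str, Recording],
    *,
    cell_id: str = "",
    line_id: str = "",
    group_label: str = "",
    spikes: SpikeCriteria | None = None,
    detection: DetectionParams | None = None,
    iv: IVOptions | None = None,
) -> tuple[CellFeatureRow, EventList | None, dict]:
    """Extract one cell's features from its protocol recordings.

    Returns the feature row, the detected EPSC list (None without a gap-free
    recording) and a QC dict recording noise, fitted leak and settings.
    """
    any_rec = next(iter(recordings.values()))
    row = CellFeatureRow(
        cell_id=cell_id or any_rec.cell_id,
        line_id=line_id or any_rec.line_id,
        group_label=group_label or any_rec.group_label,
    )
    qc: dict = {"cell_id": row.cell_id}
    events = None

    if "membrane_test" in recordings:
        row.capacitance_pF = estimate_capacitance(recordings["membrane_test"])
        qc["capacitance_pF"] = row.capacitance_pF
    if "cc_steps" in recordings:
        row.evoked_ap_count = count_evoked_aps(recordings["cc_steps"], spikes)
    if "vc_steps" in recordings:
        vc = recordings["vc_steps"]
        row.input_conductance_nS = compute_input_conductance(vc)
        cm = row.capacitance_pF
        if np.isfinite(cm) and cm > 0:
            table = extract_iv_table(vc, cm, iv)
            row.voltages_mV = table.voltages_mV
            row.na_density = table.na_density
            row.kfast_density = table.kfast_density
            row.kslow_density = table.kslow_density
            qc["leak_conductance_nS"] = table.leak_conductance_nS
        else:
            qc["iv_skipped"] = "no capacitance estimate"
    if "gap_free" in recordings:
        gf = recordings["gap_free"]
        det_qc: dict = {}
        events = detect_epscs(gf, detection, details=det_qc)
        qc.update(det_qc)
        stats = event_statistics(events)
        row.epsc_rate_hz = stats["rate_hz"]
        row.epsc_mean_amp_pA = stats["mean_amp_pA"]
        row.large_epsc_rate_hz = large_event_rate(events)
    qc["settings"] = {
        "spikes": dataclasses.asdict(spikes or SpikeCriteria()),
        "detection": dataclasses.asdict(detection or DetectionParams()),
        "iv": dataclasses.asdict(iv or IVOptions()),
    }
    return row, events, qc


def cohort_feature_table(
    spec: CohortSpec,
    *,
    spikes: SpikeCriteria | None = None,
    detection: DetectionParams | None = None,
    iv: IVOptions | None = None,
) -> tuple[pd.DataFrame, dict[str, EventList], pd.DataFrame]:
    """Simulate a cohort and extract features cell by cell, in memory.

    Returns (feature table, detected events per cell, ground-truth cell
    table).  Recordings are dropped after extraction, so minute-long gap-free
    traces for scores of cells stay within ordinary memory.
    """
    rows, truth_rows = [], []
    events: dict[str, EventList] = {}
    for cell in iter_cohort(spec):
        row, ev, _ = extract_cell_features(
            cell.recordings, cell_id=cell.cell_id, line_id=cell.line_id,
            group_label=cell.group_label, spikes=spikes, detection=detection, iv=iv,
        )
        rows.append(row)
        if ev is not None:
            events[cell.cell_id] = ev
        truth_rows.append(ground_truth_row(cell))
    return feature_frame(rows), events, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _events_frame(events: dict[str, EventList]) -> pd.DataFrame:
    recs = []
    for cell_id, ev in events.items():
        for t, a in zip(ev.times_ms, ev.amplitudes_pA):
            recs.append({"cell_id": cell_id, "time_ms": t, "amplitude_pA": a})
    return pd.DataFrame(recs, columns=["cell_id", "time_ms", "amplitude_pA"])


def run_simulate(config: PipelineConfig, out_dir: str | os.PathLike | None = None,
                 force: bool = False) -> Path:
    """Simulate the configured cohort into ``<out>/dataset`` and write the
    ground truth and manifest."""
    if config.cohort is None:
        raise ValueError("config has no cohort specification")
    if config.master_seed is None:
        raise ValueError("master_seed must be set for simulation")
    out = Path(out_dir or config.out_dir)
    dataset = out / "dataset"
    if dataset.exists() and any(dataset.iterdir()) and not force:
        raise FileExistsError(f"{dataset} exists and is non-empty (use force=True)")
    dataset.mkdir(parents=True, exist_ok=True)

    truth_rows = []
    event_recs = []
    files: dict[str, str] = {}
    for cell in iter_cohort(config.cohort):
        cell_dir = dataset / cell.group_label / cell.line_id / cell.cell_id
        cell_dir.mkdir(parents=True, exist_ok=True)
        for proto, rec in cell.recordings.items():
            path = cell_dir / f"{proto}.h5"
            write_recording(rec, path)
            files[str(path.relative_to(dataset))] = recording_digest(rec)
        truth_rows.append(ground_truth_row(cell))
        if cell.events is not None:
            for t, a in zip(cell.events.times_ms, cell.events.amplitudes_pA):
                event_recs.append({"cell_id": cell.cell_id, "time_ms": t, "amplitude_pA": a})
        logger.info("simulated %s", cell.cell_id)
    pd.DataFrame(truth_rows).to_csv(dataset / "ground_truth_cells.csv", index=False)
    pd.DataFrame(event_recs, columns=["cell_id", "time_ms", "amplitude_pA"]).to_csv(
        dataset / "ground_truth_events.csv", index=False
    )
    manifest = {
        "tool": "patchkit",
        "version": __version__,
        "master_seed": config.master_seed,
        "config": _scientific_config(config),
        "config_sha256": _config_hash(config),
        "files": dict(sorted(files.items())),
    }
    (dataset / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return dataset


def run_extract(config: PipelineConfig, dataset_dir: str | os.PathLike | None = None,
                out_dir: str | os.PathLike | None = None) -> pd.DataFrame:
    """Extract per-cell features from a dataset directory.

    A cell that fails extraction is logged in qc.json with its error and
    skipped; the cohort run continues.
    """
    out = Path(out_dir or config.out_dir)
    dataset = Path(dataset_dir or config.input_dir or out / "dataset")
    if not dataset.exists():
        raise FileNotFoundError(f"dataset directory {dataset} not found")
    out.mkdir(parents=True, exist_ok=True)

    cell_dirs = sorted(p.parent for p in dataset.glob("*/*/*/*.h5"))
    cell_dirs = list(dict.fromkeys(cell_dirs))
    rows = []
    qc_entries = []
    all_events: dict[str, EventList] = {}
    for cell_dir in cell_dirs:
        cell_id = cell_dir.name
        try:
            recordings = {
                p.stem: read_recording(p) for p in sorted(cell_dir.glob("*.h5"))
            }
            row, events, qc = extract_cell_features(
                recordings, spikes=config.spikes, detection=config.detection, iv=config.iv
            )
            rows.append(row)
            if events is not None:
                all_events[row.cell_id] = events
            qc["status"] = "ok"
            qc_entries.append(qc)
        except Exception as exc:  # fail-soft: record, continue
            logger.warning("cell %s failed extraction: %s", cell_id, exc)
            qc_entries.append({"cell_id": cell_id, "status": "failed", "error": str(exc)})
    features = feature_frame(rows)
    features.to_csv(out / "features.csv", index=False)
    _events_frame(all_events).to_csv(out / "events.csv", index=False)
    (out / "qc.json").write_text(json.dumps(qc_entries, sort_keys=True, indent=1, default=float))
    return features


def run_compare(config: PipelineConfig, features: pd.DataFrame | None = None,
                out_dir: str | os.PathLike | None = None) -> dict:
    """Compare groups and write report.json / report.md plus per-group
    pooled amplitude ECDF tables."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if features is None:
        path = out / "features.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found; run extract first")
        features = pd.read_csv(path, float_precision="round_trip")
    groups = list(dict.fromkeys(features["group_label"]))
    if len(groups) < 2:
        raise ValueError("comparison needs at least two groups")
    results = compare_groups(features, config.stats, control_label=config.control_label)

    # pooled amplitude ECDF per group, from the detected events table
    events_path = out / "events.csv"
    ecdfs = {}
    if events_path.exists():
        ev = pd.read_csv(events_path, float_precision="round_trip")
        cell_groups = features.set_index("cell_id")["group_label"]
        for grp in groups:
            cells = set(cell_groups[cell_groups == grp].index)
            amps = ev.loc[ev["cell_id"].isin(cells), "amplitude_pA"].to_numpy()
            if len(amps):
                e = Ecdf(amps)
                pd.DataFrame({"amplitude_pA": e.x, "cdf": e.y}).to_csv(
                    out / f"ecdf_{grp}.csv", index=False
                )
                ecdfs[grp] = e

    manifest_path = Path(config.input_dir or out / "dataset") / "manifest.json"
    manifest_hash = (
        _sha256_text(manifest_path.read_text()) if manifest_path.exists() else None
    )
    report = {
        "tool": "patchkit",
        "version": __version__,
        "config_sha256": _config_hash(config),
        "manifest_sha256": manifest_hash,
        "n_cells": int(len(features)),
        "groups": {g: int((features["group_label"] == g).sum()) for g in groups},
        "comparisons": results_to_records(results),
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1, default=float))
    (out / "report.md").write_text(
        "# Group comparison report\n\n"
        + f"{len(features)} cells in groups {groups}.\n\n"
        + summary_markdown(results)
        + "\n"
    )
    return report


def run_all(config: PipelineConfig, force: bool = False, resume: bool = False) -> Path:
    """Simulate (if configured), extract, and compare; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if config.cohort is not None:
            dataset = out / "dataset"
            if resume and (dataset / "manifest.json").exists():
                logger.info("resume: dataset present, skipping simulate")
            else:
                run_simulate(config, out, force=force)
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc
    try:
        if resume and (out / "features.csv").exists():
            logger.info("resume: features present, skipping extract")
            features = pd.read_csv(out / "features.csv", float_precision="round_trip")
        else:
            features = run_extract(config, out_dir=out)
    except Exception as exc:
        raise RuntimeError(f"extract stage failed: {exc}") from exc
    try:
        run_compare(config, features, out_dir=out)
    except Exception as exc:
        raise RuntimeError(f"compare stage failed: {exc}") from exc
    return out
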