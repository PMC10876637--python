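"""Hierarchical synthetic cohorts: groups → lines → cells.

Each cell's parameters are the group base values times the group's effect
multipliers times mean-one log-normal perturbations drawn at the line level
(shared by all cells of a line) and at the cell level.  Multiplicative
log-normal variability keeps every parameter positive and reproduces the
between-line / between-cell heterogeneity seen in iPSC-derived cohorts.

Seeding is hierarchical and content-addressed: every random draw comes from a
``numpy.random.SeedSequence`` keyed on ``(master_seed, group, line, cell,
purpose)``, so adding a cell or group never changes any other cell's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .neuron import (
    NeuronParams,
    simulate_current_clamp_family,
    simulate_membrane_test,
    simulate_voltage_clamp_family,
    standard_neuron,
    steady_state_current,
)
from .synaptic import EventList, SynapticParams, simulate_synaptic_trace
from .trace import Recording, cc_step_protocol, vc_step_protocol

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "CellBundle",
    "GroundTruth",
    "iter_cohort",
    "generate_cohort",
    "draw_cohort_features",
    "example_cohort_spec",
    "phenotype_cohort_spec",
]

#: neuron parameters receiving hierarchical perturbations
_PERTURBED_NEURON = ("Cm_pF", "g_leak_nS", "g_Na_nS", "g_Kfast_nS", "g_Kslow_nS")
#: effect-multiplier keys and the parameter they scale
EFFECT_KEYS = {
    "g_Na_scale": ("neuron", "g_Na_nS"),
    "g_Kfast_scale": ("neuron", "g_Kfast_nS"),
    "g_Kslow_scale": ("neuron", "g_Kslow_nS"),
    "g_leak_scale": ("neuron", "g_leak_nS"),
    "Cm_scale": ("neuron", "Cm_pF"),
    "rate_scale": ("synaptic", "rate_hz"),
    "amp_scale": ("synaptic", "amp"),
}

ALL_PROTOCOLS = ("cc_steps", "vc_steps", "gap_free", "membrane_test")


@dataclass
class GroupSpec:
    group_label: str
    n_lines: int = 3
    cells_per_line: int = 20
    neuron: NeuronParams = field(default_factory=standard_neuron)
    synaptic: SynapticParams = field(default_factory=SynapticParams)
    effects: dict = field(default_factory=dict)
    line_cv: float = 0.1
    cell_cv: float = 0.25

    def validate(self) -> None:
        if self.n_lines < 1 or self.cells_per_line < 1:
            raise ValueError("n_lines and cells_per_line must be >= 1")
        if self.line_cv < 0 or self.cell_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        for key, mult in self.effects.items():
            if key not in EFFECT_KEYS:
                raise ValueError(f"unknown effect multiplier {key!r}")
            if mult <= 0:
                raise ValueError(f"effect multiplier {key} must be > 0, got {mult}")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    master_seed: int = 0
    protocols: tuple = ALL_PROTOCOLS
    sampling_rate_hz: float = 20_000.0
    vc_noise_sd_pA: float = 2.0
    cc_noise_sd_mV: float = 0.2
    mt_noise_sd_pA: float = 1.0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            g.validate()
        for p in self.protocols:
            if p not in ALL_PROTOCOLS:
                raise ValueError(f"unknown protocol {p!r}")

    def n_cells(self) -> int:
        return sum(g.n_lines * g.cells_per_line for g in self.groups)


@dataclass
class CellBundle:
    """Everything generated for one cell."""

    cell_id: str
    line_id: str
    group_label: str
    neuron: NeuronParams
    synaptic: SynapticParams
    recordings: dict[str, Recording]
    events: EventList | None  # ground truth for the gap-free trace


@dataclass
class GroundTruth:
    cells: pd.DataFrame
    events: dict[str, EventList]


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognorm_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    s = _sigma(cv)
    return rng.lognormal(-0.5 * s * s, s, n)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)))


def _derive_seed(master_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)).generate_state(1)[0] % (2**31))


_N_PARAMS = len(_PERTURBED_NEURON) + 2  # + rate, amplitude


def _cell_params(
    spec: CohortSpec, gi: int, li: int, ci: int
) -> tuple[NeuronParams, SynapticParams]:
    group = spec.groups[gi]
    line_f = _lognorm_factor(_rng(spec.master_seed, gi, li, 7), group.line_cv, _N_PARAMS)
    cell_f = _lognorm_factor(_rng(spec.master_seed, gi, li, ci, 1), group.cell_cv, _N_PARAMS)
    factors = line_f * cell_f

    changes: dict[str, float] = {}
    for j, name in enumerate(_PERTURBED_NEURON):
        changes[name] = getattr(group.neuron, name) * factors[j]
    rate_f, amp_f = factors[-2], factors[-1]
    for key, mult in group.effects.items():
        kind, target = EFFECT_KEYS[key]
        if kind == "neuron":
            changes[target] = changes.get(target, getattr(group.neuron, target)) * mult
        elif target == "rate_hz":
            rate_f *= mult
        else:
            amp_f *= mult
    neuron = replace(group.neuron, **changes)
    syn = replace(
        group.synaptic,
        rate_hz=group.synaptic.rate_hz * rate_f,
        amp_logmean=group.synaptic.amp_logmean + float(np.log(amp_f)),
    )
    return neuron, syn


def true_input_conductance(p: NeuronParams) -> float:
    """Model slope conductance between −70 and −50 mV holds (nS)."""
    return float((steady_state_current(p, -50.0) - steady_state_current(p, -70.0)) / 20.0)


def iter_cohort(spec: CohortSpec) -> Iterator[CellBundle]:
    """Generate cells one at a time (recordings for a whole cohort can be
    large; streaming lets callers extract features and drop the traces)."""
    spec.validate()
    fs = spec.sampling_rate_hz
    for gi, group in enumerate(spec.groups):
        for li in range(group.n_lines):
            line_id = f"{group.group_label}_L{li}"
            for ci in range(group.cells_per_line):
                cell_id = f"{line_id}_C{ci:03d}"
                neuron, syn = _cell_params(spec, gi, li, ci)
                recs: dict[str, Recording] = {}
                events = None
                if "cc_steps" in spec.protocols:
                    recs["cc_steps"] = simulate_current_clamp_family(
                        neuron, cc_step_protocol(),
                        seed=_derive_seed(spec.master_seed, gi, li, ci, 11),
                        sampling_rate_hz=fs, noise_sd_mV=spec.cc_noise_sd_mV,
                    )
                if "vc_steps" in spec.protocols:
                    recs["vc_steps"] = simulate_voltage_clamp_family(
                        neuron, vc_step_protocol(),
                        seed=_derive_seed(spec.master_seed, gi, li, ci, 12),
                        sampling_rate_hz=fs, noise_sd_pA=spec.vc_noise_sd_pA,
                    )
                if "gap_free" in spec.protocols:
                    rec, events = simulate_synaptic_trace(
                        syn, fs, seed=_derive_seed(spec.master_seed, gi, li, ci, 13),
                        neuron=neuron,
                    )
                    recs["gap_free"] = rec
                if "membrane_test" in spec.protocols:
                    recs["membrane_test"] = simulate_membrane_test(
                        neuron, seed=_derive_seed(spec.master_seed, gi, li, ci, 14),
                        sampling_rate_hz=fs, noise_sd_pA=spec.mt_noise_sd_pA,
                    )
                for r in recs.values():
                    r.cell_id, r.line_id, r.group_label = cell_id, line_id, group.group_label
                yield CellBundle(cell_id, line_id, group.group_label, neuron, syn, recs, events)


def ground_truth_row(cell: CellBundle) -> dict:
    p, s = cell.neuron, cell.synaptic
    return {
        "cell_id": cell.cell_id,
        "line_id": cell.line_id,
        "group_label": cell.group_label,
        "Cm_pF": p.Cm_pF,
        "g_leak_nS": p.g_leak_nS,
        "g_Na_nS": p.g_Na_nS,
        "g_Kfast_nS": p.g_Kfast_nS,
        "g_Kslow_nS": p.g_Kslow_nS,
        "input_conductance_nS": true_input_conductance(p),
        "rate_hz": s.rate_hz,
        "amp_median_pA": float(np.exp(s.amp_logmean)),
        "amp_logsd": s.amp_logsd,
        "n_events": len(cell.events) if cell.events is not None else np.nan,
    }


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], GroundTruth]:
    """Materialize a full cohort in memory (small cohorts only; use
    :func:`iter_cohort` for large ones)."""
    recordings: list[Recording] = []
    rows = []
    events: dict[str, EventList] = {}
    for cell in iter_cohort(spec):
        recordings.extend(cell.recordings.values())
        rows.append(ground_truth_row(cell))
        if cell.events is not None:
            events[cell.cell_id] = cell.events
    return recordings, GroundTruth(pd.DataFrame(rows), events)


# ---------------------------------------------------------------------------
# Feature-level fast path (used for statistical calibration)
# ---------------------------------------------------------------------------

#: base values for the feature-level generator: typical control-cell features
FEATURE_BASES = {
    "evoked_ap_count": 90.0,
    "epsc_rate_hz": 1.5,
    "epsc_mean_amp_pA": 26.0,
    "large_epsc_rate_hz": 0.4,
    "capacitance_pF": 25.0,
    "input_conductance_nS": 2.2,
}

_CAL_VOLTAGES = {"na_density": (-20.0, -10.0, 0.0), "kfast_density": (50.0, 60.0, 70.0, 80.0),
                 "kslow_density": (50.0, 60.0, 70.0, 80.0)}
_CAL_DENSITY_BASE = {"na_density": -150.0, "kfast_density": 60.0, "kslow_density": 75.0}


def draw_cohort_features(
    groups: list[GroupSpec], seed: int | None = None
) -> pd.DataFrame:
    """Draw a per-cell feature table directly from the hierarchical
    log-normal model, without simulating traces.

    This is the calibration path: type-I-error studies of the statistical
    layer need thousands of cohorts, for which trace-level simulation adds
    nothing.  Scalar features are the canonical control-cell values times
    line- and cell-level perturbations; evoked AP counts are Poisson (integer,
    so rank ties occur, exercising the tie-corrected tests); IV densities get
    one shared magnitude factor per measure.
    """
    rng = np.random.default_rng(seed)
    records = []
    for group in groups:
        group.validate()
        scale = {
            "evoked_ap_count": group.effects.get("g_Na_scale", 1.0),
            "epsc_rate_hz": group.effects.get("rate_scale", 1.0),
            "epsc_mean_amp_pA": group.effects.get("amp_scale", 1.0),
            "large_epsc_rate_hz": group.effects.get("rate_scale", 1.0)
            * group.effects.get("amp_scale", 1.0),
            "capacitance_pF": group.effects.get("Cm_scale", 1.0),
            "input_conductance_nS": group.effects.get("g_leak_scale", 1.0),
        }
        names = list(FEATURE_BASES) + list(_CAL_DENSITY_BASE)
        for li in range(group.n_lines):
            line_f = {n: f for n, f in zip(names, _lognorm_factor(rng, group.line_cv, len(names)))}
            for ci in range(group.cells_per_line):
                cell_f = {n: f for n, f in zip(names, _lognorm_factor(rng, group.cell_cv, len(names)))}
                rec = {
                    "cell_id": f"{group.group_label}_L{li}_C{ci:03d}",
                    "line_id": f"{group.group_label}_L{li}",
                    "group_label": group.group_label,
                }
                for name, base in FEATURE_BASES.items():
                    val = base * scale[name] * line_f[name] * cell_f[name]
                    if name == "evoked_ap_count":
                        val = float(rng.poisson(val))
                    rec[name] = val
                for measure, base in _CAL_DENSITY_BASE.items():
                    f = line_f[measure] * cell_f[measure]
                    if measure == "na_density":
                        f *= group.effects.get("g_Na_scale", 1.0)
                    for v in _CAL_VOLTAGES[measure]:
                        jitter = rng.lognormal(0.0, 0.05)
                        rec[f"{measure}_{int(v)}mV"] = base * f * jitter
                records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Canonical cohort specs
# ---------------------------------------------------------------------------


def example_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """A control vs PD-like cohort mirroring the study design: 3 control
    lines vs 3 case lines, with reduced sodium conductance and reduced
    synaptic rate/amplitude in the case group."""
    return CohortSpec(
        groups=[
            GroupSpec("control", n_lines=3, cells_per_line=12),
            GroupSpec(
                "case", n_lines=3, cells_per_line=12,
                effects={"g_Na_scale": 0.5, "rate_scale": 0.5, "amp_scale": 0.6},
            ),
        ],
        master_seed=master_seed,
    )


def phenotype_cohort_spec(master_seed: int = 0, cells_per_line: int = 20,
                          duration_s: float = 45.0) -> CohortSpec:
    """60 cells per group (3 lines × 20), case effects g_Na ×0.5,
    EPSC rate ×0.5, EPSC amplitude ×0.6 — the canonical disease-like cohort
    used in the phenotype-reproduction studies.  Gap-free traces are 45 s per
    cell, long enough for stable per-cell rate and amplitude estimates at
    ~1.5 Hz while keeping replicated cohort studies cheap."""
    syn = SynapticParams(duration_s=duration_s)
    return CohortSpec(
        groups=[
            GroupSpec("control", n_lines=3, cells_per_line=cells_per_line, synaptic=syn),
            GroupSpec(
                "case", n_lines=3, cells_per_line=cells_per_line, synaptic=syn,
                effects={"g_Na_scale": 0.5, "rate_scale": 0.5, "amp_scale": 0.6},
            ),
        ],
        master_seed=master_seed,
    )
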