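"""Two-group statistics for per-cell feature tables.

Scalar features (evoked AP count, EPSC rate and amplitude, large-EPSC rate,
capacitance, input conductance) are compared with the Mann–Whitney U test;
current densities are compared per voltage step (and as band means) with
one-way ANOVA, preceded by Lilliefors-corrected Kolmogorov–Smirnov normality
checks and Levene's variance-homogeneity test.  Group summaries are
mean ± SEM (SD/√n).  Cells are the unit of analysis; within-line correlation
is not modeled (a documented limitation of this design).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .intrinsic import K_BAND, NA_BAND
from .trace import SCALAR_FEATURES, density_columns

__all__ = [
    "ComparisonResult",
    "StatsPlan",
    "mann_whitney_u",
    "one_way_anova",
    "ks_normality",
    "levene_test",
    "bh_adjust",
    "significance_stars",
    "compare_groups",
    "results_to_records",
    "summary_markdown",
]

EXACT_MWU_MAX_N = 16  # exact null enumeration below this total sample size


def _check_sample(x, name="sample", min_n=1):
    x = np.asarray(x, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {len(x)}")
    return x


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (midrank ties) with a two-sided p-value.

    The p-value is exact (full enumeration of the permutation null) when the
    pooled sample size is ≤ 16 and tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p).

    Degenerate inputs follow the convention: all groups identical and
    constant → (0, 1); zero within-group variance with real separation →
    (inf, 0).
    """
    groups = [_check_sample(g, f"group {i}", min_n=2) for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    grand = np.mean(np.concatenate(groups))
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (math.inf, 0.0)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(sps.f.sf(f, dfb, dfw))


def ks_normality(x) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality check with the Lilliefors correction
    (normal parameters estimated from the sample)."""
    x = _check_sample(x, "sample", min_n=5)
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)


def levene_test(groups, center: str = "median") -> tuple[float, float]:
    """Levene's variance-homogeneity test: one-way ANOVA on absolute
    deviations from the group centers.

    The default is the median-centered Brown–Forsythe variant, which keeps
    its nominal size on the skewed, strictly positive feature distributions
    this package produces; ``center="mean"`` gives the classical test.
    """
    groups = [_check_sample(g, f"group {i}", min_n=2) for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least two groups")
    w, p = sps.levene(*groups, center=center)
    return float(w), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001,
    **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


# ---------------------------------------------------------------------------
# Feature-table comparison
# ---------------------------------------------------------------------------


@dataclass
class StatsPlan:
    scalar_features: tuple = SCALAR_FEATURES
    na_band: tuple[float, float] = NA_BAND
    k_band: tuple[float, float] = K_BAND
    adjust_bh: bool = False  # optional BH over the per-step ANOVA p-values
    levene_center: str = "median"
    alpha: float = 0.05


@dataclass
class ComparisonResult:
    feature_name: str
    test_name: str
    statistic: float
    p_value: float
    n_control: int
    n_case: int
    mean_control: float
    sem_control: float
    mean_case: float
    sem_case: float
    direction: str
    stars: str
    control_label: str
    case_label: str
    adjusted_p: float | None = None
    assumptions: dict = field(default_factory=dict)


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return float("nan"), float("nan")
    sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return float(np.mean(x)), sem


def _direction(mean_case: float, mean_control: float, signed_measure: bool = False) -> str:
    """Direction of the case group relative to control.

    For signed inward currents (Na densities are negative) the comparison is
    on magnitudes, so "case < control" always reads as "smaller current /
    smaller feature in the case group".
    """
    if signed_measure:
        mean_case, mean_control = abs(mean_case), abs(mean_control)
    if np.isnan(mean_case) or np.isnan(mean_control) or mean_case == mean_control:
        return "case = control"
    return "case < control" if mean_case < mean_control else "case > control"


def _one_comparison(
    name: str, test: str, ctrl: np.ndarray, case: np.ndarray,
    control_label: str, case_label: str, plan: StatsPlan,
) -> ComparisonResult:
    ctrl = np.asarray(ctrl, dtype=float)
    case = np.asarray(case, dtype=float)
    ctrl_f, case_f = ctrl[np.isfinite(ctrl)], case[np.isfinite(case)]
    if test == "mann_whitney_u":
        stat, p = mann_whitney_u(ctrl_f, case_f)
    else:
        stat, p = one_way_anova([ctrl_f, case_f])
    mc, sc = _mean_sem(ctrl)
    mk, sk = _mean_sem(case)
    assumptions = {}
    if test == "anova":
        for label, vals in ((control_label, ctrl_f), (case_label, case_f)):
            if len(vals) >= 5 and np.std(vals) > 0:
                _, kp = ks_normality(vals)
                assumptions[f"ks_normality_p_{label}"] = kp
        if min(len(ctrl_f), len(case_f)) >= 2:
            _, lp = levene_test([ctrl_f, case_f], center=plan.levene_center)
            assumptions["levene_p"] = lp
    return ComparisonResult(
        feature_name=name,
        test_name=test,
        statistic=stat,
        p_value=p,
        n_control=len(ctrl_f),
        n_case=len(case_f),
        mean_control=mc,
        sem_control=sc,
        mean_case=mk,
        sem_case=sk,
        direction=_direction(mk, mc, signed_measure=name.startswith("na_density")),
        stars=significance_stars(p),
        control_label=control_label,
        case_label=case_label,
        assumptions=assumptions,
    )


def compare_groups(
    features: pd.DataFrame,
    plan: StatsPlan | None = None,
    control_label: str = "control",
) -> list[ComparisonResult]:
    """Compare every case group against the control group, feature by feature.

    Scalar features use the Mann–Whitney U test; IV densities get a one-way
    ANOVA per voltage step inside the canonical bands (Na: −20..0 mV,
    K: +50..+90 mV) plus a band-mean comparison, with normality and
    variance-homogeneity checks attached.
    """
    plan = plan or StatsPlan()
    if "group_label" not in features.columns:
        raise ValueError("feature table lacks a group_label column")
    labels = list(dict.fromkeys(features["group_label"]))
    if control_label not in labels:
        raise ValueError(f"control group {control_label!r} absent from table")
    case_labels = [g for g in labels if g != control_label]
    if not case_labels:
        raise ValueError("need at least one non-control group")
    for lbl in labels:
        if (features["group_label"] == lbl).sum() < 2:
            raise ValueError(f"group {lbl!r} has fewer than 2 cells")

    ctrl_tab = features[features["group_label"] == control_label]
    results: list[ComparisonResult] = []
    for case_label in case_labels:
        case_tab = features[features["group_label"] == case_label]
        for name in plan.scalar_features:
            if name not in features.columns:
                raise ValueError(f"feature column {name!r} missing from table")
            results.append(
                _one_comparison(
                    name, "mann_whitney_u",
                    ctrl_tab[name].to_numpy(), case_tab[name].to_numpy(),
                    control_label, case_label, plan,
                )
            )
        for measure, band in (
            ("na_density", plan.na_band),
            ("kfast_density", plan.k_band),
            ("kslow_density", plan.k_band),
        ):
            volts, cols = density_columns(features, measure)
            sel = [(v, c) for v, c in zip(volts, cols) if band[0] <= v <= band[1]]
            if not sel:
                continue
            step_results = []
            for v, col in sel:
                r = _one_comparison(
                    col, "anova",
                    ctrl_tab[col].to_numpy(), case_tab[col].to_numpy(),
                    control_label, case_label, plan,
                )
                step_results.append(r)
            if plan.adjust_bh:
                adj = bh_adjust([r.p_value for r in step_results])
                for r, a in zip(step_results, adj):
                    r.adjusted_p = float(a)
            results.extend(step_results)
            band_ctrl = ctrl_tab[[c for _, c in sel]].to_numpy().mean(axis=1)
            band_case = case_tab[[c for _, c in sel]].to_numpy().mean(axis=1)
            results.append(
                _one_comparison(
                    f"{measure}_band_mean", "anova", band_ctrl, band_case,
                    control_label, case_label, plan,
                )
            )
    return results


def results_to_records(results: list[ComparisonResult]) -> list[dict]:
    return [asdict(r) for r in results]


def summary_markdown(results: list[ComparisonResult]) -> str:
    """Markdown summary table: mean ± SEM per group, n, test, p, stars."""
    lines = [
        "| feature | control (mean ± SEM, n) | case (mean ± SEM, n) | test | p | |",
        "|---|---|---|---|---|---|",
    ]
    for r in results:
        lines.append(
            f"| {r.feature_name} [{r.case_label}] "
            f"| {r.mean_control:.4g} ± {r.sem_control:.3g} (n={r.n_control}) "
            f"| {r.mean_case:.4g} ± {r.sem_case:.3g} (n={r.n_case}) "
            f"| {r.test_name} | {r.p_value:.3g} | {r.stars} |"
        )
    return "\n".join(lines)
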