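"""Cohort-level diagnostic evaluation.

Tie-aware ROC/AUC, detection rates, OR-combination of a multi-marker
panel, and the nonparametric comparison battery (Wilcoxon signed-rank,
Mann-Whitney U, Spearman, Fisher exact, OLS linearity).

The AUC uses the half-credit tie convention,

    AUC = [#(case > control) + 0.5 #(case = control)] / (n_case n_control),

the Mann-Whitney U normalisation.  After full-specificity cutoff
subtraction every control scores exactly 0, so ties dominate and the
trapezoid-free rank formulation is the right one: a marker with
sensitivity s and all negatives at 0 has AUC = (1 + s) / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "StatResult",
    "MarkerDiagnostics",
    "DiagnosticReport",
    "roc_auc",
    "sensitivity_specificity",
    "combine_panel",
    "paired_wilcoxon",
    "mann_whitney",
    "spearman",
    "fisher_exact",
    "linearity_r2",
    "evaluate_cohort",
]


@dataclass
class StatResult:
    """A named test statistic with p-value and effect summary."""

    name: str
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _median_iqr(x: np.ndarray) -> dict:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q25), float(q75))}


def roc_auc(
    case_scores: Sequence[float], control_scores: Sequence[float],
    return_points: bool = False,
):
    """Tie-aware AUC (Mann-Whitney normalisation) and optional ROC points.

    Computed from joint ranks (midranks for ties), which is the half-credit
    pairwise count without the O(n_case * n_control) comparison.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_case = ranks[: cases.size].sum()
    u = r_case - cases.size * (cases.size + 1) / 2.0
    auc = u / (cases.size * controls.size)
    if not return_points:
        return float(auc)
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    fpr, tpr, thresholds = roc_curve(y, np.concatenate([cases, controls]))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), points


def sensitivity_specificity(
    calls: Sequence[bool], is_case: Sequence[bool]
) -> tuple[float, float]:
    """Detection rate among cases and negative rate among controls, in %."""
    calls = np.asarray(calls, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    if calls.shape != is_case.shape:
        raise ValueError("calls and labels must align")
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("need at least one case and one control")
    sens = 100.0 * calls[is_case].mean()
    spec = 100.0 * (~calls[~is_case]).mean()
    return float(sens), float(spec)


def combine_panel(per_marker_calls: Mapping[str, Mapping[str, bool]]) -> dict:
    """OR-combine per-marker calls into panel calls.

    ``per_marker_calls`` maps marker -> {sample_id -> call}.  All markers
    must cover the same sample set.  Returns the combined call per sample
    plus union/intersection counts.
    """
    markers = list(per_marker_calls)
    if not markers:
        raise ValueError("no markers supplied")
    sample_sets = [set(per_marker_calls[m]) for m in markers]
    if any(s != sample_sets[0] for s in sample_sets[1:]):
        raise ValueError("marker call tables cover different sample sets")
    samples = sorted(sample_sets[0])
    combined = {
        s: any(per_marker_calls[m][s] for m in markers) for s in samples
    }
    all_positive = {
        s: all(per_marker_calls[m][s] for m in markers) for s in samples
    }
    return {
        "calls": combined,
        "n_union": sum(combined.values()),
        "n_intersection": sum(all_positive.values()),
        "n_samples": len(samples),
    }


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    Zero differences are dropped; tied absolute differences get average
    ranks; p is exact for <= 25 non-zero pairs without ties, otherwise the
    tie-corrected normal approximation.  All pairs equal is degenerate
    (no signed-rank statistic exists) and is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return StatResult("wilcoxon_signed_rank", float("nan"), float("nan"),
                          effect={"note": "all paired differences are zero"},
                          n={"pairs": int(x.size), "nonzero": 0}, degenerate=True)
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return StatResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
        effect={"x": _median_iqr(x), "y": _median_iqr(y)},
        n={"pairs": int(x.size), "nonzero": int(nonzero.size)},
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U test for unpaired groups.

    Exact p when the smaller group has <= 8 observations and there are no
    cross-group ties; tie-corrected normal approximation otherwise.  The U
    statistic satisfies U = AUC * n_x * n_y with the half-credit tie
    convention of :func:`roc_auc`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # all values tied: U at its null mean
        return StatResult(
            "mann_whitney_u", x.size * y.size / 2.0, 1.0,
            effect={"x": _median_iqr(x), "y": _median_iqr(y)},
            n={"x": int(x.size), "y": int(y.size)},
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue),
        effect={"x": _median_iqr(x), "y": _median_iqr(y)},
        n={"x": int(x.size), "y": int(y.size)},
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (Pearson on midranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return StatResult(
        "spearman_r", float(res.statistic), float(res.pvalue),
        effect={"r": float(res.statistic)}, n={"pairs": int(x.size)},
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("every margin must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return StatResult(
        "fisher_exact", float(odds), float(p),
        effect={"table": t.tolist()}, n={"total": int(t.sum())},
    )


def linearity_r2(expected: Sequence[float], observed: Sequence[float]) -> float:
    """R^2 of the OLS fit of observed on expected MAF (linearity check)."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1:
        raise ValueError("expected values are constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


@dataclass
class MarkerDiagnostics:
    """Per-marker (or combined-panel) diagnostic summary."""

    name: str
    n_cases: int
    n_controls: int
    n_detected: int
    sensitivity: float  # %
    specificity: float  # %
    auc: float


@dataclass
class DiagnosticReport:
    """Cohort evaluation across markers and their OR-combination."""

    markers: dict[str, MarkerDiagnostics]
    combined: MarkerDiagnostics
    overlap: dict  # both / either / neither counts among cases
    paired_comparison: StatResult | None = None
    comparisons: list[StatResult] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (MarkerDiagnostics, StatResult)):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(asdict(self), indent=2, default=default)

    def to_text(self) -> str:
        rows = list(self.markers.values()) + [self.combined]
        lines = [
            f"{'marker':<14}{'cases':>6}{'detected':>9}{'sens %':>8}"
            f"{'spec %':>8}{'AUC':>7}"
        ]
        for m in rows:
            lines.append(
                f"{m.name:<14}{m.n_cases:>6}{m.n_detected:>9}"
                f"{m.sensitivity:>8.1f}{m.specificity:>8.1f}{m.auc:>7.3f}"
            )
        ov = self.overlap
        lines.append(
            f"case overlap: both={ov['both']} either={ov['either']} "
            f"neither={ov['neither']}"
        )
        return "\n".join(lines)


def evaluate_cohort(
    results: pd.DataFrame,
    case_group: str = "UBC",
    control_groups: Sequence[str] = ("control", "cystitis"),
) -> DiagnosticReport:
    """Assemble the diagnostic report from calibrated per-sample results.

    ``results`` needs columns sample_id, group, assay, corrected_maf, call.
    ROC scores are the corrected MAFs, so calibration controls sit at
    exactly 0 and ties carry half credit.  The combined panel ORs the
    per-marker calls and scores each sample by its maximum corrected MAF.
    For samples positive on exactly two markers, the paired MAF comparison
    (Wilcoxon signed-rank) is reported.
    """
    required = {"sample_id", "group", "assay", "corrected_maf", "call"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    markers = sorted(results["assay"].unique())
    is_case = lambda g: g == case_group  # noqa: E731
    per_marker: dict[str, MarkerDiagnostics] = {}
    marker_calls: dict[str, dict[str, bool]] = {}
    marker_scores: dict[str, pd.Series] = {}
    for marker in markers:
        sub = results[results["assay"] == marker].set_index("sample_id")
        cases = sub[sub["group"] == case_group]
        controls = sub[sub["group"].isin(control_groups)]
        auc = roc_auc(cases["corrected_maf"], controls["corrected_maf"])
        labels = pd.concat([cases, controls])
        sens, spec = sensitivity_specificity(
            labels["call"].astype(bool), labels["group"] == case_group
        )
        per_marker[marker] = MarkerDiagnostics(
            name=marker,
            n_cases=len(cases),
            n_controls=len(controls),
            n_detected=int(cases["call"].astype(bool).sum()),
            sensitivity=sens,
            specificity=spec,
            auc=auc,
        )
        marker_calls[marker] = cases["call"].astype(bool).to_dict()
        marker_scores[marker] = sub["corrected_maf"]

    combined_calls = combine_panel(marker_calls)
    # panel score: best corrected MAF across markers
    pivot = results.pivot_table(index="sample_id", columns="assay",
                                values="corrected_maf", aggfunc="first")
    panel_score = pivot.max(axis=1)
    meta = results.drop_duplicates("sample_id").set_index("sample_id")["group"]
    case_ids = meta[meta == case_group].index
    control_ids = meta[meta.isin(control_groups)].index
    combined_auc = roc_auc(panel_score.loc[case_ids], panel_score.loc[control_ids])
    combined_call_series = pd.Series(
        {s: any(marker_calls[m].get(s, False) for m in markers)
         for s in case_ids}
    )
    control_calls = (
        results[results["group"].isin(control_groups)]
        .groupby("sample_id")["call"].any()
    )
    combined = MarkerDiagnostics(
        name="+".join(markers),
        n_cases=len(case_ids),
        n_controls=len(control_ids),
        n_detected=int(combined_call_series.sum()),
        sensitivity=100.0 * combined_call_series.mean(),
        specificity=100.0 * (~control_calls.astype(bool)).mean(),
        auc=combined_auc,
    )

    n_both = combined_calls["n_intersection"]
    n_union = combined_calls["n_union"]
    overlap = {
        "both": int(n_both),
        "either": int(n_union),
        "neither": int(combined_calls["n_samples"] - n_union),
    }

    paired = None
    if len(markers) == 2 and n_both >= 2:
        m0, m1 = markers
        dual = [s for s in case_ids
                if marker_calls[m0].get(s) and marker_calls[m1].get(s)]
        paired = paired_wilcoxon(
            marker_scores[m0].loc[dual].to_numpy(),
            marker_scores[m1].loc[dual].to_numpy(),
        )

    return DiagnosticReport(
        markers=per_marker, combined=combined, overlap=overlap,
        paired_comparison=paired,
    )
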