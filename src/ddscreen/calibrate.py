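"""False-positive MAF cutoff calibration and replicate-variability analysis.

Known-negative (control) urine samples occasionally show mutant-channel
droplets.  Because the absolute false-positive copy number scales with DNA
input while the false-positive MAF does not, the blank cutoff is defined on
the MAF scale: the ROC operating point with full specificity on the control
cohort.  The cutoff is then *subtracted* from every sample's raw MAF
(clipped at zero), and a sample is called positive iff the corrected MAF is
greater than zero — which guarantees 100% specificity on the calibration
controls by construction.

The replicate-variability analysis quantifies the randomness signature of
false positives: the MAF of epsilon-driven false-positive wells fluctuates
far more across replicates (SD as % of mean) than the MAF of wells with
true mutant template.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .quantify import SampleResult

__all__ = [
    "CalibrationResult",
    "ReplicateRecord",
    "MafCutoff",
    "summarize_controls",
    "determine_cutoff",
    "apply_cutoff",
    "replicate_cv",
    "compare_replicate_variability",
]

#: Fallback offset (percentage points) above the control maximum when no
#: case value brackets it; the ROC midpoint convention needs both sides.
DEFAULT_DELTA = 0.05


@dataclass
class CalibrationResult:
    """Control-cohort false-positive summary and the chosen MAF cutoff."""

    control_median: float
    control_iqr: tuple[float, float]
    control_max: float
    cutoff: float
    achieved_specificity: float
    achieved_sensitivity: float | None = None
    n_controls: int = 0
    n_cases: int = 0
    delta: float = DEFAULT_DELTA


@dataclass
class ReplicateRecord:
    """Replicate MAF measurements of one sample and their dispersion."""

    sample_id: str
    group: str
    mafs: tuple[float, ...]
    cv_percent: float


def summarize_controls(control_mafs: Sequence[float]) -> tuple[float, tuple[float, float], float]:
    """Median, IQR and maximum of control-cohort MAFs.

    Quantiles use the weighted-average (linear interpolation) convention so
    printed summaries compare like-for-like with mainstream statistics
    packages.
    """
    arr = np.asarray(control_mafs, dtype=float)
    if arr.size == 0:
        raise ValueError("control MAF list is empty")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q25), float(q75)), float(arr.max())


class MafCutoff(BaseEstimator, ClassifierMixin):
    """Full-specificity MAF cutoff as a scikit-learn classifier.

    ``fit(control_mafs, case_mafs=None)`` chooses the smallest threshold
    with zero control values at or above it: the midpoint between the
    control maximum and the smallest case value exceeding it, or
    ``control_max + delta`` when no case brackets the maximum (or no cases
    are supplied).  ``predict(mafs)`` returns boolean positive calls and
    ``transform(mafs)`` the cutoff-subtracted corrected MAFs.
    """

    def __init__(self, delta: float = DEFAULT_DELTA):
        self.delta = delta

    def fit(self, X, y=None, case_mafs: Sequence[float] | None = None) -> "MafCutoff":
        controls = np.asarray(X, dtype=float).ravel()
        if controls.size == 0:
            raise ValueError("control MAF list is empty")
        med, iqr, cmax = summarize_controls(controls)
        cases = np.asarray(case_mafs, dtype=float).ravel() if case_mafs is not None else np.array([])
        above = cases[cases > cmax]
        if above.size:
            cutoff = (cmax + above.min()) / 2.0
        else:
            cutoff = cmax + self.delta
        sens = float(np.mean(cases > cutoff)) if cases.size else None
        self.cutoff_ = float(cutoff)
        self.result_ = CalibrationResult(
            control_median=med,
            control_iqr=iqr,
            control_max=cmax,
            cutoff=float(cutoff),
            achieved_specificity=float(np.mean(controls <= cutoff)),
            achieved_sensitivity=sens,
            n_controls=int(controls.size),
            n_cases=int(cases.size),
            delta=self.delta,
        )
        self.classes_ = np.array([False, True])
        return self

    def transform(self, X) -> np.ndarray:
        """Corrected MAFs: max(0, raw - cutoff)."""
        check_is_fitted(self, "cutoff_")
        raw = np.asarray(X, dtype=float)
        return np.clip(raw - self.cutoff_, 0.0, None)

    def predict(self, X) -> np.ndarray:
        """Positive call iff the corrected MAF is greater than zero."""
        return self.transform(X) > 0


def determine_cutoff(
    control_mafs: Sequence[float],
    case_mafs: Sequence[float] | None = None,
    delta: float = DEFAULT_DELTA,
) -> CalibrationResult:
    """Calibrate the full-specificity MAF cutoff from control-cohort MAFs."""
    est = MafCutoff(delta=delta).fit(control_mafs, case_mafs=case_mafs)
    return est.result_


def apply_cutoff(result: SampleResult, cutoff: float) -> SampleResult:
    """Subtract the cutoff from a sample's raw MAF and call it.

    corrected = max(0, raw - cutoff); positive iff corrected > 0.
    Returns a new ``SampleResult``; the input is left untouched.
    """
    corrected = max(0.0, result.raw_maf - cutoff)
    return _dc_replace(result, corrected_maf=corrected, call=corrected > 0)


def replicate_cv(replicate_mafs: Sequence[float]) -> float:
    """SD of replicate MAFs as percent of their mean (sample SD, n-1)."""
    arr = np.asarray(replicate_mafs, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("replicate mean must be positive")
    return float(100.0 * arr.std(ddof=1) / mean)


def compare_replicate_variability(
    control_cvs: Sequence[float], case_cvs: Sequence[float]
) -> dict:
    """Mann-Whitney U comparison of replicate CVs, controls vs cases.

    Returns the two-sided U test together with the medians/IQRs of both
    groups, the form in which replicate dispersion is usually reported.
    """
    ctrl = np.asarray(control_cvs, dtype=float)
    case = np.asarray(case_cvs, dtype=float)
    if ctrl.size == 0 or case.size == 0:
        raise ValueError("both CV lists must be non-empty")
    res = stats.mannwhitneyu(ctrl, case, alternative="two-sided")
    c25, c50, c75 = np.percentile(ctrl, [25, 50, 75])
    k25, k50, k75 = np.percentile(case, [25, 50, 75])
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "control_median": float(c50),
        "control_iqr": (float(c25), float(c75)),
        "case_median": float(k50),
        "case_iqr": (float(k25), float(k75)),
        "n_control": int(ctrl.size),
        "n_case": int(case.size),
    }
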