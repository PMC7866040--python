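"""Model evaluation: ROC curves, AUC with DeLong variance, paired
ROC-area comparison, sensitivity/specificity threshold tables and
standardized compound profiles.

Evaluation is in-sample (apparent performance) by default, matching how
small-cohort discriminant panels are typically reported; the AUC equals
the Mann-Whitney probability that a random case receives a higher
predicted probability than a random control, with ties counted 1/2, and
its standard error comes from the DeLong placement-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def percentage(count: int, n: int) -> float:
    """A classification percentage as printed in performance tables:
    100 * count / n rounded to 2 decimals."""
    return round(100.0 * count / n, 2)


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10[i] = fraction of controls below case i
    (ties 1/2); V01[j] = fraction of cases above control j."""
    sc = np.sort(controls)
    lo = np.searchsorted(sc, cases, side="left")
    hi = np.searchsorted(sc, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / controls.size
    ss = np.sort(cases)
    lo = np.searchsorted(ss, controls, side="left")
    hi = np.searchsorted(ss, controls, side="right")
    v01 = (ss.size - hi + 0.5 * (hi - lo)) / cases.size
    return v10, v01


@dataclass
class ROCAnalysis:
    """Empirical ROC over the unique predicted probabilities.

    The classification rule is ``p >= threshold -> case``, so the lowest
    threshold always gives 100% sensitivity.  Sensitivity/specificity are
    stored as percentages.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    n_cases: int
    n_controls: int

    def auc_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation CI from the DeLong standard error."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (
            max(0.0, self.auc - z * self.auc_se),
            min(1.0, self.auc + z * self.auc_se),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "sensitivity_pct": self.sensitivity,
                "specificity_pct": self.specificity,
            }
        )


def roc_curve(probabilities: np.ndarray, labels: np.ndarray) -> ROCAnalysis:
    """Empirical ROC analysis of predicted case probabilities."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if p.size != y.size:
        raise ValueError("probabilities and labels differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1)")
    cases = p[y == 1]
    controls = p[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")

    thresholds = np.unique(p)
    sc, ss = np.sort(controls), np.sort(cases)
    # p >= t -> case
    tp = cases.size - np.searchsorted(ss, thresholds, side="left")
    fp = controls.size - np.searchsorted(sc, thresholds, side="left")
    fn = cases.size - tp
    tn = controls.size - fp

    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    m, n = cases.size, controls.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    auc_se = float(np.sqrt(s10 / m + s01 / n))

    return ROCAnalysis(
        thresholds=thresholds,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=100.0 * tp / m,
        specificity=100.0 * tn / n,
        auc=auc,
        auc_se=auc_se,
        n_cases=m,
        n_controls=n,
    )


def performance_table(roc: ROCAnalysis, min_sensitivity: float = 0.0) -> pd.DataFrame:
    """Threshold table restricted to sensitivity >= ``min_sensitivity`` (%).

    One row per unique threshold, reporting the predicted-probability
    cutoff, sensitivity % with the count of correctly classified cases and
    specificity % with the count of correctly classified controls,
    percentages rounded to 2 decimals.
    """
    keep = roc.sensitivity >= min_sensitivity
    rows = []
    for i in np.flatnonzero(keep):
        rows.append(
            {
                "threshold": float(roc.thresholds[i]),
                "sensitivity_pct": percentage(int(roc.tp[i]), roc.n_cases),
                "n_cases_correct": int(roc.tp[i]),
                "specificity_pct": percentage(int(roc.tn[i]), roc.n_controls),
                "n_controls_correct": int(roc.tn[i]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold", "sensitivity_pct", "n_cases_correct",
            "specificity_pct", "n_controls_correct",
        ],
    )


def delong_compare(
    probabilities_a: np.ndarray,
    probabilities_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float]:
    """Paired DeLong test for equality of two correlated ROC areas.

    Both probability vectors must score the SAME subjects.  Returns
    (chi2, p) where chi2 = (AUC_A - AUC_B)^2 / var(AUC_A - AUC_B) and the
    p-value is from the chi-square reference with 1 degree of freedom.
    """
    pa = np.asarray(probabilities_a, dtype=float).ravel()
    pb = np.asarray(probabilities_b, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if pa.size != pb.size or pa.size != y.size:
        raise ValueError("paired comparison requires equal-length inputs")
    case = y == 1
    ctrl = y == 0
    m, n = int(case.sum()), int(ctrl.sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    v10a, v01a = _placements(pa[case], pa[ctrl])
    v10b, v01b = _placements(pb[case], pb[ctrl])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    d = auc_a - auc_b

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-15:
        return (0.0, 1.0) if abs(d) < 1e-12 else (float("inf"), 0.0)
    chi2 = d * d / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def standardized_profile(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    compounds: list[str] | None = None,
) -> pd.DataFrame:
    """Per-compound case profile standardized to the control distribution.

    z_case = (mean_case - mean_control) / sd_control; the control profile
    is identically 0 by construction.  A compound with zero control SD is
    flagged (z undefined).
    """
    if compounds is None:
        compounds = list(case_matrix.columns)
    rows = []
    for c in compounds:
        mc = float(control_matrix[c].mean())
        sd = float(control_matrix[c].std(ddof=1))
        if sd <= 0:
            rows.append(
                {"compound": c, "z_case": np.nan, "z_control": 0.0,
                 "zero_control_sd": True}
            )
            continue
        rows.append(
            {
                "compound": c,
                "z_case": (float(case_matrix[c].mean()) - mc) / sd,
                "z_control": 0.0,
                "zero_control_sd": False,
            }
        )
    return pd.DataFrame(rows)
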