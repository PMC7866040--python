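"""ROC/AUC, DeLong comparison, threshold tables, standardized profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from breathlasso import (
    delong_compare,
    percentage,
    performance_table,
    roc_curve,
    standardized_profile,
)


def _random_instance(rng, n_max=60):
    n = int(rng.integers(8, n_max))
    y = rng.integers(0, 2, n).astype(float)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    probs = np.round(rng.random(n), 2)  # rounding forces ties
    return probs, y


def test_auc_matches_independent_oracle_on_random_instances():
    """Mann-Whitney AUC with ties 1/2 equals the trapezoidal area under
    the empirical ROC (oracle: sklearn.metrics.roc_auc_score)."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    for _ in range(100):
        probs, y = _random_instance(rng)
        roc = roc_curve(probs, y)
        assert roc.auc == pytest.approx(roc_auc_score(y, probs), abs=1e-12)


def test_degenerate_aucs():
    y = np.r_[np.zeros(10), np.ones(10)]
    perfect = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)]
    assert roc_curve(perfect, y).auc == 1.0
    constant = np.full(20, 0.3)
    assert roc_curve(constant, y).auc == 0.5  # all ties -> chance
    rng = np.random.default_rng(1)
    null = roc_curve(rng.random(2000), rng.integers(0, 2, 2000).astype(float))
    assert null.auc == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError, match="case"):
        roc_curve(np.r_[0.1, 0.2], np.r_[1.0, 1.0])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_roc_monotonicity_and_count_conservation(seed):
    rng = np.random.default_rng(seed)
    probs, y = _random_instance(rng)
    roc = roc_curve(probs, y)
    assert np.all(np.diff(roc.thresholds) > 0)
    assert np.all(np.diff(roc.sensitivity) <= 0)
    assert np.all(np.diff(roc.specificity) >= 0)
    total = roc.tp + roc.fp + roc.tn + roc.fn
    assert np.all(total == roc.n_cases + roc.n_controls)
    assert 0.0 <= roc.auc <= 1.0
    assert roc.auc_se >= 0.0
    assert roc.sensitivity[0] == 100.0  # lowest threshold classifies all as cases


def test_performance_table_reproduces_printed_arithmetic():
    """Percentages are 100*count/n to 2 decimals, e.g. 31/36 correctly
    classified cases -> 86.11% and 38/45 controls -> 84.44%."""
    assert percentage(31, 36) == 86.11
    assert percentage(38, 45) == 84.44
    rng = np.random.default_rng(3)
    probs, y = _random_instance(rng)
    roc = roc_curve(probs, y)
    table = performance_table(roc, min_sensitivity=0.0)
    assert len(table) == np.unique(probs).size  # one row per threshold
    for _, row in table.iterrows():
        assert row["sensitivity_pct"] == percentage(
            int(row["n_cases_correct"]), roc.n_cases
        )
        assert row["specificity_pct"] == percentage(
            int(row["n_controls_correct"]), roc.n_controls
        )
    top = performance_table(roc, min_sensitivity=100.0)
    assert (top["sensitivity_pct"] == 100.0).all()


def test_delong_identical_and_symmetry():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 40).astype(float)
    y[:4] = [0, 0, 1, 1]
    pa = rng.random(40)
    chi2, p = delong_compare(pa, pa.copy(), y)
    assert chi2 == 0.0 and p == 1.0
    pb = rng.random(40)
    chi2_ab, p_ab = delong_compare(pa, pb, y)
    chi2_ba, p_ba = delong_compare(pb, pa, y)
    assert chi2_ab == pytest.approx(chi2_ba)
    assert p_ab == pytest.approx(p_ba)
    with pytest.raises(ValueError, match="equal-length"):
        delong_compare(pa, pb[:-1], y)


def test_delong_p_agrees_with_permutation_oracle():
    """On paired small instances, the DeLong chi2 p-value tracks a
    label-preserving swap (permutation) test of the AUC difference."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    n_perm = 2000
    for _ in range(8):
        n = 40
        y = np.r_[np.zeros(20), np.ones(20)]
        signal = y + rng.normal(0, 1.2, n)
        pa = 1 / (1 + np.exp(-(signal + rng.normal(0, 0.6, n))))
        pb = 1 / (1 + np.exp(-(signal + rng.normal(0, 0.6, n))))
        _, p_delong = delong_compare(pa, pb, y)
        observed = abs(roc_auc_score(y, pa) - roc_auc_score(y, pb))
        count = 0
        for _b in range(n_perm):
            swap = rng.random(n) < 0.5
            sa = np.where(swap, pb, pa)
            sb = np.where(swap, pa, pb)
            if abs(roc_auc_score(y, sa) - roc_auc_score(y, sb)) >= observed - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_delong == pytest.approx(p_perm, abs=0.05)


def test_standardized_profile_arithmetic():
    control = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 7.0]})
    case = pd.DataFrame({"a": [4.0, 4.0, 4.0], "b": [5.0, 5.0, 5.0]})
    prof = standardized_profile(case, control).set_index("compound")
    assert prof.loc["a", "z_case"] == pytest.approx((4 - 2) / 1.0)
    sd_b = control["b"].std(ddof=1)
    assert prof.loc["b", "z_case"] == pytest.approx((5 - 17 / 3) / sd_b)
    assert (prof["z_control"] == 0).all()
    same = standardized_profile(control, control)
    assert np.allclose(same["z_case"], 0.0)
    flat = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
    flagged = standardized_profile(case[["a"]], flat)
    assert flagged["zero_control_sd"].iloc[0]
    assert np.isnan(flagged["z_case"].iloc[0])


def test_profile_sign_matches_generating_effects(adk_cohort):
    """Pentane is drawn higher in lung-adenocarcinoma cases than controls,
    so its standardized profile is positive; M67 is drawn lower."""
    case = adk_cohort[adk_cohort["group"] == "lung_adk"]
    ctrl = adk_cohort[adk_cohort["group"] == "control"]
    cols = {c: f"alv_{c}" for c in ("pentane", "M67")}
    prof = standardized_profile(
        case[list(cols.values())].rename(columns={v: k for k, v in cols.items()}),
        ctrl[list(cols.values())].rename(columns={v: k for k, v in cols.items()}),
    ).set_index("compound")
    assert prof.loc["pentane", "z_case"] > 0
    assert prof.loc["M67", "z_case"] < 0


def test_auc_ci_is_normal_approximation():
    rng = np.random.default_rng(6)
    y = np.r_[np.zeros(30), np.ones(30)]
    probs = y * 0.4 + rng.random(60) * 0.6
    roc = roc_curve(probs, y)
    lo, hi = roc.auc_ci()
    assert lo <= roc.auc <= hi
    assert hi - lo == pytest.approx(2 * 1.959963984540054 * roc.auc_se, abs=1e-9)
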