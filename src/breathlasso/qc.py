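"""Sample- and compound-level quality control, plus predictor standardization.

Two QC rules precede modelling:

1. *Alveolar-origin check*: a breath sample whose CO2 percentage is below
   2% was either not crimped airtight or not a true end-expiratory sample;
   it is discarded.
2. *Environmental-contamination exclusion*: a compound whose concentration
   in the paired room-air sample is significantly HIGHER than in alveolar
   air (paired two-sided t-test, one-directional exclusion rule) reflects
   background pollution rather than physiology and is dropped from the
   predictor panel.

Predictors entering the penalized fits (compound concentrations, age, sex)
are standardized to mean 0 / sample SD 1 so that a single penalty treats
all variables comparably; the stored center/scale allow coefficients to be
reported back on the original ppb (or years / 0-1) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CO2_THRESHOLD = 2.0
DEFAULT_ALPHA = 0.05


@dataclass
class QCResult:
    """Outcome of the QC filters.

    ``discarded_samples`` maps subject id to a reason (``"low_co2"`` or
    ``"missing_co2"``); ``excluded_compounds`` maps compound label to its
    paired t statistic and p-value.
    """

    retained_samples: list[str] = field(default_factory=list)
    discarded_samples: dict[str, str] = field(default_factory=dict)
    retained_compounds: list[str] = field(default_factory=list)
    excluded_compounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "retained_samples": list(self.retained_samples),
            "discarded_samples": dict(self.discarded_samples),
            "retained_compounds": list(self.retained_compounds),
            "excluded_compounds": {
                c: {"t": t, "p": p} for c, (t, p) in self.excluded_compounds.items()
            },
        }


def filter_co2(
    cohort: pd.DataFrame, threshold: float = DEFAULT_CO2_THRESHOLD
) -> QCResult:
    """Discard samples whose CO2 percentage is strictly below ``threshold``.

    The boundary value (exactly 2.0%) is retained; a missing CO2 reading is
    discarded with reason ``"missing_co2"``.
    """
    result = QCResult()
    co2 = pd.to_numeric(cohort["co2_percent"], errors="coerce")
    for sid, value in zip(cohort["subject_id"], co2):
        if pd.isna(value):
            result.discarded_samples[str(sid)] = "missing_co2"
        elif value < threshold:
            result.discarded_samples[str(sid)] = "low_co2"
        else:
            result.retained_samples.append(str(sid))
    if any(r == "missing_co2" for r in result.discarded_samples.values()):
        warnings.warn("samples with missing CO2 were discarded", stacklevel=2)
    return result


def environmental_exclusion(
    cohort: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> QCResult:
    """Exclude compounds significantly more abundant in environmental air.

    Per compound, a paired two-sided t-test on the per-subject differences
    (environmental - alveolar); the compound is excluded iff the mean
    difference is positive AND p < ``alpha``.  The rule is one-directional:
    a compound more abundant in alveolar air is never excluded, however
    small its p-value.  With fewer than 3 paired observations the test is
    undefined and the compound is retained with a warning.
    """
    result = QCResult()
    compounds = [c[4:] for c in cohort.columns if c.startswith("alv_")]
    for c in compounds:
        diff = cohort[f"env_{c}"].to_numpy(float) - cohort[f"alv_{c}"].to_numpy(float)
        diff = diff[~np.isnan(diff)]
        if diff.size < 3:
            warnings.warn(
                f"{c}: fewer than 3 paired observations, test undefined; retained",
                stacklevel=2,
            )
            result.retained_compounds.append(c)
            continue
        if np.allclose(diff, 0.0):
            result.retained_compounds.append(c)
            continue
        t, p = stats.ttest_rel(
            cohort[f"env_{c}"].to_numpy(float), cohort[f"alv_{c}"].to_numpy(float)
        )
        if diff.mean() > 0 and p < alpha:
            result.excluded_compounds[c] = (float(t), float(p))
        else:
            result.retained_compounds.append(c)
    return result


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable center and scale (sample SD) on the original units."""

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise ValueError(f"non-positive scale for variables: {bad}")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.center.index] - self.center) / self.scale

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z[self.center.index] * self.scale + self.center

    def to_dict(self) -> dict:
        return {
            "center": {k: float(v) for k, v in self.center.items()},
            "scale": {k: float(v) for k, v in self.scale.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(
            center=pd.Series(d["center"], dtype=float),
            scale=pd.Series(d["scale"], dtype=float),
        )

    def subset(self, variables: list[str]) -> "StandardizationParams":
        return StandardizationParams(
            center=self.center[variables], scale=self.scale[variables]
        )


def standardize(
    X: pd.DataFrame, *, allow_constant: bool = False
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center to mean 0 and scale to sample SD 1 (ddof=1), column-wise.

    A constant column is rejected with its name unless ``allow_constant``,
    in which case it is centered and given scale 1 (it then contributes a
    zero column, hence a zero coefficient, to any penalized fit).
    """
    if len(X) < 2:
        raise ValueError("standardization needs at least 2 rows")
    center = X.mean()
    scale = X.std(ddof=1)
    constant = scale <= 0
    if constant.any():
        if not allow_constant:
            raise ValueError(
                f"constant column(s): {list(scale.index[constant])}"
            )
        scale = scale.mask(constant, 1.0)
    params = StandardizationParams(center=center, scale=scale)
    return params.transform(X), params
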