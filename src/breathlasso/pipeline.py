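"""Three-stage iterated adaptive-LASSO logistic modelling.

Stage 1 (screening) runs a cross-validated LASSO on all retained compounds
plus age and sex and keeps only the variables with nonzero coefficients,
discarding the coefficient values themselves.  Stage 2 refits a LASSO on
the screened set to generate per-variable penalty weights as inverse
absolute coefficients (1/|beta_j|, infinite for beta_j = 0).  Stage 3 is
the adaptive LASSO: a weighted-L1 fit on the screened set with those
weights, again with cross-validated lambda.  The two-step iterated scheme
has oracle selection properties in sparse high-dimensional settings, which
is why it is preferred over a single LASSO here.

Confidence intervals for the final coefficients come from a stratified
bootstrap: each resample refits the weight-generating and adaptive stages
(weights recomputed per resample, screened set and stage lambdas held
fixed) and percentile 2.5%/97.5% limits are taken over the resampled
original-scale coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .qc import StandardizationParams, standardize
from .solver import (
    CVPath,
    PenalizedFit,
    cv_select_lambda,
    fit_weighted_l1,
    predict_probability,
)

logger = logging.getLogger(__name__)

#: Case/control group composition per modelling contrast.
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "lung_adk": (("control",), ("lung_adk",)),
    "lung_sqcc": (("control",), ("lung_sqcc",)),
    "colon_adk": (("control",), ("colon_adk",)),
    "lung_any": (("control",), ("lung_adk", "lung_sqcc")),
    "adk_vs_sqcc": (("lung_sqcc",), ("lung_adk",)),
}


@dataclass
class PipelineConfig:
    """Tunable parameters of the full modelling pipeline."""

    contrast: str = "lung_adk"
    co2_threshold: float = 2.0
    alpha: float = 0.05
    folds: int = 50
    grid_size: int = 50
    tol: float = 1e-7
    max_iter: int = 10_000
    bootstrap: int = 200
    seed: int = 0
    screen: bool = True

    def __post_init__(self) -> None:
        for name in ("co2_threshold", "alpha", "folds", "grid_size", "tol",
                     "max_iter", "bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def design_matrix(cohort: pd.DataFrame, compounds: list[str]) -> pd.DataFrame:
    """Predictor table: alveolar concentration per retained compound + age + sex."""
    data = {c: cohort[f"alv_{c}"].to_numpy(float) for c in compounds}
    data["age"] = cohort["age"].to_numpy(float)
    data["sex"] = cohort["sex"].to_numpy(float)
    return pd.DataFrame(data, index=cohort.index)


def outcome_vector(cohort: pd.DataFrame, contrast: str) -> np.ndarray:
    """Binary outcome (1 = case) for the rows of a contrast-subset cohort."""
    controls, cases = CONTRASTS[contrast]
    groups = cohort["group"]
    if not groups.isin(controls + cases).all():
        raise ValueError("cohort contains groups outside the contrast")
    return groups.isin(cases).to_numpy().astype(float)


def subset_contrast(cohort: pd.DataFrame, contrast: str) -> pd.DataFrame:
    controls, cases = CONTRASTS[contrast]
    return cohort[cohort["group"].isin(controls + cases)].reset_index(drop=True)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class IteratedModel:
    """Output of the three-stage iterated procedure."""

    contrast: str
    variables: tuple[str, ...]  # full candidate set (compounds + age + sex)
    stage1_selected: tuple[str, ...]
    stage2_fit: PenalizedFit | None
    adaptive_weights: np.ndarray | None
    final_fit: PenalizedFit
    params: StandardizationParams
    cv_paths: dict[str, CVPath] = field(default_factory=dict)
    coefficient_cis: dict[str, tuple[float, float]] | None = None
    unstable_cis: tuple[str, ...] = ()
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0

    def selected_variables(self) -> list[str]:
        return self.final_fit.nonzero_variables()

    def coefficients(self) -> pd.DataFrame:
        """Final coefficients on standardized and original scales."""
        names = list(self.final_fit.variables or ())
        b0_orig, coef_orig = self.final_fit.coefficients_original_scale(
            self.params.subset(names)
        )
        rows = [
            {
                "variable": "intercept",
                "coef_std": self.final_fit.intercept,
                "coef_original": b0_orig,
            }
        ]
        for j, v in enumerate(names):
            rows.append(
                {
                    "variable": v,
                    "coef_std": float(self.final_fit.coef[j]),
                    "coef_original": float(coef_orig[j]),
                }
            )
        out = pd.DataFrame(rows)
        if self.coefficient_cis is not None:
            out["ci_low"] = [
                self.coefficient_cis.get(v, (np.nan, np.nan))[0]
                for v in out["variable"]
            ]
            out["ci_high"] = [
                self.coefficient_cis.get(v, (np.nan, np.nan))[1]
                for v in out["variable"]
            ]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Case probability for predictor rows on the original scale."""
        return predict_probability(self.final_fit, X, self.params)

    def to_dict(self) -> dict:
        d = {
            "contrast": self.contrast,
            "seed": self.seed,
            "variables": list(self.variables),
            "stage1_selected": list(self.stage1_selected),
            "adaptive_weights": None
            if self.adaptive_weights is None
            else [None if not np.isfinite(w) else float(w)
                  for w in self.adaptive_weights],
            "final_fit": self.final_fit.to_dict(),
            "stage2_fit": None if self.stage2_fit is None else self.stage2_fit.to_dict(),
            "standardization": self.params.to_dict(),
            "cv": {k: v.to_dict() for k, v in self.cv_paths.items()},
            "coefficient_cis": None
            if self.coefficient_cis is None
            else {k: [float(a), float(b)] for k, (a, b) in self.coefficient_cis.items()},
            "unstable_cis": list(self.unstable_cis),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        return d


def _intercept_only_fit(y: np.ndarray, variables: tuple[str, ...]) -> PenalizedFit:
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return PenalizedFit(
        intercept=float(np.log(ybar / (1 - ybar))),
        coef=np.zeros(len(variables)),
        lambda_=0.0,
        penalty_weights=np.ones(len(variables)),
        converged=True,
        n_iterations=0,
        variables=variables,
    )


def screen_variables(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 50,
    seed: int = 0,
    *,
    grid_size: int = 50,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> list[str]:
    """Stage-1 screening: CV LASSO with unit weights; return the names of
    the variables with nonzero coefficients (values discarded)."""
    Z, _ = standardize(X)
    A = np.ascontiguousarray(Z.to_numpy(float))
    path = cv_select_lambda(
        A, y, None, k=k, grid_size=grid_size, seed=seed, tol=tol, max_cycles=max_iter
    )
    fit = fit_weighted_l1(
        A, y, path.selected_lambda, None,
        variables=tuple(X.columns), tol=tol, max_cycles=max_iter,
    )
    selected = fit.nonzero_variables()
    if not selected:
        warnings.warn("screening selected no variables", stacklevel=2)
    logger.info(
        "screening: lambda=%.6g, %d/%d variables retained",
        path.selected_lambda, len(selected), X.shape[1],
    )
    return selected


def compute_adaptive_weights(stage2_fit: PenalizedFit) -> np.ndarray:
    """Adaptive penalty weights: 1/|beta_j|, infinite for beta_j = 0."""
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(stage2_fit.coef)
    if np.all(~np.isfinite(w)):
        warnings.warn(
            "all stage-2 coefficients zero: adaptive stage degenerates to "
            "intercept-only",
            stacklevel=2,
        )
    return w


def fit_iterated(
    X: pd.DataFrame,
    y: np.ndarray,
    config: PipelineConfig,
) -> IteratedModel:
    """Run screening -> weight-generating LASSO -> adaptive LASSO.

    ``X`` holds QC-passed predictors on the original scale (one column per
    retained compound, plus ``age`` and ``sex``); all are standardized
    internally.  Deterministic given (data, config).
    """
    y = np.asarray(y, dtype=float).ravel()
    variables = tuple(X.columns)
    Z, params = standardize(X)
    A = np.ascontiguousarray(Z.to_numpy(float))
    seeds = _stage_seeds(config.seed)
    cv_paths: dict[str, CVPath] = {}

    if config.screen:
        path1 = cv_select_lambda(
            A, y, None, k=config.folds, grid_size=config.grid_size,
            seed=seeds[0], tol=config.tol, max_cycles=config.max_iter,
        )
        fit1 = fit_weighted_l1(
            A, y, path1.selected_lambda, None, variables=variables,
            tol=config.tol, max_cycles=config.max_iter,
        )
        selected = tuple(fit1.nonzero_variables())
        cv_paths["screening"] = path1
        if not selected:
            warnings.warn("screening selected no variables", stacklevel=2)
    else:
        selected = variables

    n_cases = int(y.sum())
    n_controls = int(y.size - n_cases)

    if not selected:
        final = _intercept_only_fit(y, ())
        return IteratedModel(
            contrast=config.contrast, variables=variables, stage1_selected=(),
            stage2_fit=None, adaptive_weights=None, final_fit=final,
            params=params, cv_paths=cv_paths,
            n_cases=n_cases, n_controls=n_controls, seed=config.seed,
        )

    idx = [variables.index(v) for v in selected]
    A2 = np.ascontiguousarray(A[:, idx])

    path2 = cv_select_lambda(
        A2, y, None, k=config.folds, grid_size=config.grid_size,
        seed=seeds[1], tol=config.tol, max_cycles=config.max_iter,
    )
    fit2 = fit_weighted_l1(
        A2, y, path2.selected_lambda, None, variables=selected,
        tol=config.tol, max_cycles=config.max_iter,
    )
    cv_paths["weights"] = path2
    w_adapt = compute_adaptive_weights(fit2)

    if np.all(~np.isfinite(w_adapt)):
        final = _intercept_only_fit(y, selected)
    else:
        path3 = cv_select_lambda(
            A2, y, w_adapt, k=config.folds, grid_size=config.grid_size,
            seed=seeds[2], tol=config.tol, max_cycles=config.max_iter,
        )
        final = fit_weighted_l1(
            A2, y, path3.selected_lambda, w_adapt, variables=selected,
            tol=config.tol, max_cycles=config.max_iter,
        )
        cv_paths["adaptive"] = path3

    logger.info(
        "%s: %d screened, %d in final model (lambda=%.6g)",
        config.contrast, len(selected), len(final.nonzero_variables()),
        final.lambda_,
    )
    return IteratedModel(
        contrast=config.contrast,
        variables=variables,
        stage1_selected=selected,
        stage2_fit=fit2,
        adaptive_weights=w_adapt,
        final_fit=final,
        params=params,
        cv_paths=cv_paths,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=config.seed,
    )


def _stratified_resample(
    y: np.ndarray, rng: np.random.Generator, max_tries: int = 10
) -> np.ndarray:
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    for _ in range(max_tries):
        idx = np.concatenate(
            [rng.choice(cases, cases.size, replace=True),
             rng.choice(controls, controls.size, replace=True)]
        )
        if np.unique(y[idx]).size == 2:
            return idx
    raise ValueError("could not draw a two-class bootstrap resample")


def bootstrap_cis(
    X: pd.DataFrame,
    y: np.ndarray,
    model: IteratedModel,
    B: int = 200,
    seed: int = 0,
    *,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap 95% intervals for the final coefficients.

    Each of the ``B`` outcome-stratified resamples refits the
    weight-generating LASSO and the adaptive stage on the fixed screened
    set (penalty weights recomputed per resample; stage lambdas held at the
    full-data CV selections).  Intervals are on the original coefficient
    scale; a variable absent from a resample's model contributes 0 to that
    resample.  The result is also stored on ``model``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    y = np.asarray(y, dtype=float).ravel()
    sel = list(model.stage1_selected)
    rng = np.random.default_rng(seed)
    names = ["intercept"] + sel
    draws = np.zeros((B, len(names)))
    lam2 = model.stage2_fit.lambda_ if model.stage2_fit is not None else 0.0
    lam3 = model.final_fit.lambda_

    for b in range(B):
        idx = _stratified_resample(y, rng)
        yb = y[idx]
        if not sel:
            ybar = float(np.clip(yb.mean(), 1e-12, 1 - 1e-12))
            draws[b, 0] = np.log(ybar / (1 - ybar))
            continue
        Xb = X.iloc[idx][sel]
        Zb, pb = standardize(Xb, allow_constant=True)
        Ab = np.ascontiguousarray(Zb.to_numpy(float))
        fit2b = fit_weighted_l1(
            Ab, yb, lam2, None, variables=tuple(sel), tol=tol, max_cycles=max_iter
        )
        wb = compute_adaptive_weights(fit2b)
        if np.all(~np.isfinite(wb)):
            fit3b = _intercept_only_fit(yb, tuple(sel))
        else:
            fit3b = fit_weighted_l1(
                Ab, yb, lam3, wb, variables=tuple(sel), tol=tol, max_cycles=max_iter
            )
        b0_orig, coef_orig = fit3b.coefficients_original_scale(pb)
        draws[b, 0] = b0_orig
        draws[b, 1:] = coef_orig

    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    cis = {name: (float(lo[j]), float(hi[j])) for j, name in enumerate(names)}

    b0_pt, coef_pt = model.final_fit.coefficients_original_scale(
        model.params.subset(sel)
    )
    points = dict(zip(names, [b0_pt, *coef_pt]))
    unstable = tuple(
        name for name in names
        if not (cis[name][0] <= points[name] <= cis[name][1])
    )
    if unstable:
        logger.info("bootstrap-unstable intervals for: %s", ", ".join(unstable))
    model.coefficient_cis = cis
    model.unstable_cis = unstable
    return cis
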