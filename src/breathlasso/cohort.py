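"""Synthetic breath-volatolomics cohorts.

Generates subject-level case/control cohorts with the statistical structure
the downstream discriminant analysis assumes: per-compound alveolar
concentrations drawn from right-skewed log-normal distributions, paired
environmental (room-air) measurements, CO2 percentage for sample-quality
checks, and age/sex metadata.  The built-in reference scenario is
moment-matched to published median/mean concentration summaries for three
cancer contrasts (lung adenocarcinoma, lung squamous-cell carcinoma and
colon adenocarcinoma, each versus controls), so the full pipeline is
testable without access to raw patient data.

The log-normal family is used because breath concentrations are positive
and every effect-bearing compound summary shows its arithmetic mean above
(or very near) its median, i.e. right skew.  Matching a log-normal to a
printed (median, mean) pair is closed-form::

    log_mu    = ln(median)
    log_sigma = sqrt(2 * ln(mean / median))

since the log-normal median is exp(log_mu) and its mean is
exp(log_mu + log_sigma**2 / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ENVIRONMENTAL_EXCLUSION_SET, default_panel

GROUPS = ("control", "lung_adk", "lung_sqcc", "colon_adk")
CO2_THRESHOLD_PCT = 2.0

#: env_factor defaults: retained compounds sit well below alveolar levels,
#: the excluded subset well above (background contamination).
RETAINED_ENV_FACTOR = 0.35
CONTAMINATED_ENV_FACTOR = 3.0


@dataclass(frozen=True)
class CompoundDistribution:
    """Log-normal concentration model for one compound in one group.

    Parameters
    ----------
    compound:
        Panel label.
    log_mu, log_sigma:
        Location and scale on the natural-log ppb scale; the implied median
        is ``exp(log_mu)`` and the mean ``exp(log_mu + log_sigma**2/2)``.
    env_factor:
        Multiplicative environmental-to-alveolar concentration ratio (>0).
        Values above 1 mark a compound dominated by room-air contamination.
    """

    compound: str
    log_mu: float
    log_sigma: float
    env_factor: float = RETAINED_ENV_FACTOR

    def __post_init__(self) -> None:
        if self.log_sigma < 0:
            raise ValueError(f"{self.compound}: log_sigma must be >= 0")
        if self.env_factor <= 0:
            raise ValueError(f"{self.compound}: env_factor must be > 0")

    @property
    def median(self) -> float:
        return math.exp(self.log_mu)

    @property
    def mean(self) -> float:
        return math.exp(self.log_mu + 0.5 * self.log_sigma**2)


@dataclass(frozen=True)
class GroupSpec:
    """Sampling parameters for one subject group."""

    n: int
    age_range: tuple[float, float]
    male_fraction: float
    distributions: dict[str, CompoundDistribution]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be > 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high)")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort.

    ``qc_fail_fraction`` is the expected proportion of samples drawn with
    CO2 below the 2% alveolar-origin threshold (they emulate badly crimped
    vials or incomplete exhalation and are later discarded by QC).
    """

    groups: dict[str, GroupSpec]
    co2_mean: float = 4.5
    co2_sd: float = 0.7
    qc_fail_fraction: float = 0.0
    env_noise_sigma: float = 0.3
    compound_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must be in [0, 1]")
        if not 0.0 <= self.compound_correlation < 1.0:
            raise ValueError("compound_correlation must be in [0, 1)")
        panel = self.panel
        for name, g in self.groups.items():
            if tuple(g.distributions) != panel:
                raise ValueError(
                    f"group {name!r} does not reference the same compound "
                    "panel as the first group"
                )

    @property
    def panel(self) -> tuple[str, ...]:
        first = next(iter(self.groups.values()))
        return tuple(first.distributions)

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass(frozen=True)
class BreathSample:
    """One subject's paired alveolar/environmental record."""

    subject_id: str
    group: str
    age: float
    sex: int  # 0 = female, 1 = male
    co2_percent: float
    alveolar: dict[str, float]
    environmental: dict[str, float]


def fit_lognormal_from_summary(
    median: float,
    mean: float,
    *,
    compound: str = "compound",
    env_factor: float = RETAINED_ENV_FACTOR,
) -> CompoundDistribution:
    """Moment-match a log-normal to a printed (median, mean) summary pair.

    Raises
    ------
    ValueError
        If ``median <= 0`` or ``mean < median``: a log-normal always has
        mean >= median, so such a summary cannot be represented.
    """
    if median <= 0:
        raise ValueError(f"{compound}: median must be > 0, got {median}")
    if mean < median:
        raise ValueError(
            f"{compound}: arithmetic mean ({mean}) below median ({median}); "
            "a log-normal cannot produce mean < median"
        )
    log_mu = math.log(median)
    log_sigma = math.sqrt(2.0 * math.log(mean / median))
    return CompoundDistribution(compound, log_mu, log_sigma, env_factor)


def _robust_distribution(
    median: float, mean: float, *, compound: str, env_factor: float
) -> CompoundDistribution:
    # A few published mean/median pairs have mean marginally below the
    # median (near-symmetric distributions); use |ln(mean/median)| as the
    # skew estimate there instead of rejecting the pair.
    if mean >= median:
        return fit_lognormal_from_summary(
            median, mean, compound=compound, env_factor=env_factor
        )
    log_sigma = math.sqrt(2.0 * math.log(median / mean))
    return CompoundDistribution(compound, math.log(median), log_sigma, env_factor)


# ---------------------------------------------------------------------------
# Reference scenario: group structure and per-compound (median, mean)
# concentration summaries (ppb) for controls and the three case groups.
# ---------------------------------------------------------------------------

#: (n, (age_low, age_high), male_fraction)
REFERENCE_GROUPS: dict[str, tuple[int, tuple[float, float], float]] = {
    "control": (45, (43.0, 87.0), 30 / 45),
    "lung_adk": (36, (45.0, 85.0), 21 / 36),
    "lung_sqcc": (25, (55.0, 86.0), 13 / 25),
    "colon_adk": (52, (43.0, 89.0), 24 / 52),
}

#: Control-group (median, mean) ppb summaries for every compound that enters
#: at least one final discriminant model.
CONTROL_SUMMARIES: dict[str, tuple[float, float]] = {
    "acetic_acid": (1124.0, 1336.8),
    "ammonia": (160.6, 602.3),
    "M43": (1193.0, 1430.5),
    "acetaldehyde": (818.0, 1976.1),
    "M48": (6.8, 7.8),
    "M62": (8.7, 9.2),
    "M67": (34.4, 35.9),
    "pentane": (64.3, 64.5),
    "M93": (31.9, 35.7),
    "M98": (58.4, 67.1),
    "M103": (4.2, 7.1),
    "1,3-butadiene": (10.9, 11.8),
    "M74": (23.4, 31.6),
    "M105": (9.4, 9.9),
    "M121": (3.7, 5.1),
    "dinitrogen_oxide": (6438.0, 6311.9),
    "nitrous_acid": (21.3, 25.6),
    "M19": (350.4, 623.2),
    "M33": (46.1, 51.8),
    "M75": (6.7, 13.5),
    "M91": (6.7, 9.0),
    "M106": (9.4, 11.2),
    "M120": (3.2, 3.9),
}

#: Case-group (median, mean) ppb summaries per contrast; compounds absent
#: from a contrast's map behave as null compounds (case == control).
CASE_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "lung_adk": {
        "acetic_acid": (1872.8, 1855.5),
        "ammonia": (173.6, 171.1),
        "M43": (927.9, 1071.5),
        "acetaldehyde": (580.2, 1901.1),
        "M48": (6.3, 11.6),
        "M62": (8.9, 10.5),
        "M67": (27.2, 28.6),
        "pentane": (78.8, 85.6),
        "M93": (24.2, 26.9),
        "M98": (62.6, 65.0),
        "M103": (6.1, 14.4),
    },
    "lung_sqcc": {
        "acetic_acid": (2119.7, 2627.4),
        "ammonia": (219.9, 276.2),
        "M43": (1260.8, 1599.1),
        "acetaldehyde": (1362.2, 2120.2),
        "M48": (6.4, 8.1),
        "1,3-butadiene": (13.6, 27.6),
        "M74": (37.8, 58.9),
        "M105": (11.1, 15.2),
        "M121": (4.5, 5.1),
    },
    "colon_adk": {
        "dinitrogen_oxide": (7306.1, 7183.9),
        "nitrous_acid": (23.2, 24.3),
        "acetic_acid": (1015.1, 1155.9),
        "M19": (590.0, 708.7),
        "M33": (55.5, 81.1),
        "M43": (1650.7, 1906.7),
        "1,3-butadiene": (12.3, 16.3),
        "M67": (39.1, 42.9),
        "M74": (17.2, 46.9),
        "M75": (3.8, 8.7),
        "M91": (13.3, 14.9),
        "M106": (8.0, 20.3),
        "M120": (2.1, 3.2),
    },
}

#: (median, mean) levels cycled over null compounds so the unmodelled part
#: of the panel spans realistic trace-gas magnitudes.
_NULL_LEVELS: tuple[tuple[float, float], ...] = (
    (5.2, 6.1),
    (12.4, 14.8),
    (28.0, 33.5),
    (61.0, 70.2),
    (140.0, 168.0),
    (9.6, 11.5),
    (47.0, 52.9),
    (3.3, 4.2),
)


def _control_distributions() -> dict[str, CompoundDistribution]:
    dists: dict[str, CompoundDistribution] = {}
    for i, c in enumerate(default_panel()):
        env = (
            CONTAMINATED_ENV_FACTOR
            if c in ENVIRONMENTAL_EXCLUSION_SET
            else RETAINED_ENV_FACTOR
        )
        median, mean = CONTROL_SUMMARIES.get(c, _NULL_LEVELS[i % len(_NULL_LEVELS)])
        dists[c] = _robust_distribution(median, mean, compound=c, env_factor=env)
    return dists


def reference_cohort_spec(
    contrast: str | None = None,
    *,
    seed: int = 0,
    qc_fail_fraction: float = 0.0,
) -> CohortSpec:
    """The built-in reference cohort scenario.

    With ``contrast`` in ``{"lung_adk", "lung_sqcc", "colon_adk"}`` the spec
    contains controls plus that case group; with ``contrast=None`` it
    contains all four groups (158 subjects in total).  Case groups differ
    from controls only in the compounds of their discriminant panel; every
    other compound is null (identical case/control distribution).
    """
    if contrast is not None and contrast not in CASE_SUMMARIES:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CASE_SUMMARIES)}"
        )
    wanted = GROUPS if contrast is None else ("control", contrast)
    control = _control_distributions()
    groups: dict[str, GroupSpec] = {}
    for gname in wanted:
        n, age_range, male_fraction = REFERENCE_GROUPS[gname]
        dists = dict(control)
        for c, (median, mean) in CASE_SUMMARIES.get(gname, {}).items():
            dists[c] = _robust_distribution(
                median, mean, compound=c, env_factor=control[c].env_factor
            )
        groups[gname] = GroupSpec(
            n=n, age_range=age_range, male_fraction=male_fraction, distributions=dists
        )
    return CohortSpec(groups=groups, seed=seed, qc_fail_fraction=qc_fail_fraction)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort: one row per subject, columns = metadata + ``alv_*``/``env_*``.

    Reproducible bit-for-bit given ``spec`` (including its ``seed``).
    Alveolar concentrations are log-normal draws; the paired environmental
    record is ``env_factor * exp(log_mu + env_noise)`` with independent
    log-normal noise, so retained compounds sit below alveolar levels and
    contaminated ones above.  CO2 is drawn so that on average
    ``qc_fail_fraction`` of samples fall below the 2% threshold.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    rho = spec.compound_correlation
    frames = []
    for gname, g in spec.groups.items():
        n = g.n
        age = np.round(rng.uniform(g.age_range[0], g.age_range[1], size=n), 1)
        sex = (rng.random(n) < g.male_fraction).astype(int)

        fail = rng.random(n) < spec.qc_fail_fraction
        a = (CO2_THRESHOLD_PCT - spec.co2_mean) / spec.co2_sd
        co2 = stats.truncnorm.rvs(
            a, np.inf, loc=spec.co2_mean, scale=spec.co2_sd, size=n, random_state=rng
        )
        co2[fail] = rng.uniform(0.8, 1.99, size=int(fail.sum()))
        co2 = np.round(co2, 2)

        shared = rng.standard_normal(n)
        alv = np.empty((n, len(panel)))
        env = np.empty((n, len(panel)))
        for j, c in enumerate(panel):
            d = g.distributions[c]
            z = rng.standard_normal(n)
            if rho > 0:
                z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * z
            alv[:, j] = np.exp(d.log_mu + d.log_sigma * z)
            env[:, j] = d.env_factor * np.exp(
                d.log_mu + spec.env_noise_sigma * rng.standard_normal(n)
            )

        columns: dict[str, object] = {
            "subject_id": [f"{gname}_{i + 1:03d}" for i in range(n)],
            "group": gname,
            "age": age,
            "sex": sex,
            "co2_percent": co2,
        }
        columns.update({f"alv_{c}": alv[:, j] for j, c in enumerate(panel)})
        columns.update({f"env_{c}": env[:, j] for j, c in enumerate(panel)})
        frames.append(pd.DataFrame(columns))
    return pd.concat(frames, ignore_index=True)


def iter_samples(cohort: pd.DataFrame) -> list[BreathSample]:
    """View cohort rows as :class:`BreathSample` records."""
    compounds = [c[4:] for c in cohort.columns if c.startswith("alv_")]
    out = []
    for _, row in cohort.iterrows():
        out.append(
            BreathSample(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                co2_percent=float(row["co2_percent"]),
                alveolar={c: float(row[f"alv_{c}"]) for c in compounds},
                environmental={c: float(row[f"env_{c}"]) for c in compounds},
            )
        )
    return out
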