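"""Synthetic pediatric cohort generator.

Produces child-level tables with the statistical structure the downstream
analysis assumes: age- and sex-dependent Gaussian blood pressure with an
age-widening systolic spread, triplicate integer-mmHg readings, LMS-style
height and BMI distributions, a configurable overweight fraction, missing
weights, and boolean register-style exclusion flags.  Every draw is
reproducible from a single master seed; each variable gets its own
deterministic sub-stream so adding one knob never perturbs another
variable's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import round_half_away
from .errors import ConfigurationError

__all__ = [
    "BPModel",
    "HeightModel",
    "BMIModel",
    "WaistModel",
    "GeneratorConfig",
    "generate_cohort",
    "make_growth_reference",
    "COHORT_COLUMNS",
]

#: Fixed CSV column order for cohort tables.
COHORT_COLUMNS = [
    "id", "sex", "age_years", "height_cm", "weight_kg", "waist_cm",
    "origin_danish", "excl_medication", "excl_diagnosis",
    "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3", "heart_rate",
]

# Named sub-streams in fixed order; indices key the per-variable RNGs so
# the stream layout is stable across config changes.
_STREAMS = (
    "age", "sex", "height", "bmi", "waist", "sbp", "dbp",
    "readings", "heart_rate", "missing_weight",
    "flag_medication", "flag_diagnosis", "flag_non_danish",
)


def _rng(seed: int, name: str) -> np.random.Generator:
    idx = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


@dataclass(frozen=True)
class BPModel:
    """Gaussian blood-pressure model for one sex and outcome.

    True BP is ``intercept + age_slope*age + height_coef*height_z`` with
    residual SD ``sd_intercept + sd_slope*age``.
    """

    intercept: float
    age_slope: float
    sd_intercept: float
    sd_slope: float = 0.0
    height_coef: float = 0.0

    def mean(self, age, height_z=0.0):
        return self.intercept + self.age_slope * np.asarray(age, float) + self.height_coef * height_z

    def sd(self, age):
        return self.sd_intercept + self.sd_slope * np.asarray(age, float)

    def quantile(self, age, tau, height_z=0.0):
        """Closed-form conditional quantile; the generator's own oracle."""
        return self.mean(age, height_z) + norm.ppf(tau) * self.sd(age)


@dataclass(frozen=True)
class HeightModel:
    """Linear mean-height trajectory with an age-widening SD.

    The SD is interpolated linearly between ``sd_young_cm`` at age 4 and
    ``sd_old_cm`` at age 15 (the default band spans 3.6-8.5 cm).
    """

    base_cm: float
    slope_cm_per_year: float
    sd_young_cm: float = 3.6
    sd_old_cm: float = 8.5

    def mean(self, age):
        return self.base_cm + self.slope_cm_per_year * np.asarray(age, float)

    def sd(self, age):
        frac = (np.asarray(age, float) - 4.0) / 11.0
        return self.sd_young_cm + (self.sd_old_cm - self.sd_young_cm) * frac


@dataclass(frozen=True)
class BMIModel:
    """LMS-form BMI distribution with an age-linear median."""

    m_base: float = 15.5
    m_slope_per_year: float = 0.40
    L: float = -1.5
    S: float = 0.12

    def median(self, age):
        return self.m_base + self.m_slope_per_year * (np.asarray(age, float) - 4.0)

    def from_z(self, age, z):
        """Invert the LMS transform; argument clipped to stay positive."""
        arg = np.clip(1.0 + self.L * self.S * np.asarray(z, float), 0.05, None)
        return self.median(age) * arg ** (1.0 / self.L)

    def cutoff_z(self, bmi: float, age: float) -> float:
        """z-score of ``bmi`` at ``age`` under this model (L != 0 here)."""
        return ((bmi / float(self.median(age))) ** self.L - 1.0) / (self.L * self.S)


@dataclass(frozen=True)
class WaistModel:
    """Waist circumference via a Gaussian waist-to-height ratio."""

    whtr_mean: float = 0.45
    whtr_sd: float = 0.035


def _default_height():
    return {
        "F": HeightModel(base_cm=83.0, slope_cm_per_year=5.5),
        "M": HeightModel(base_cm=82.0, slope_cm_per_year=6.0),
    }


def _default_sbp():
    return {
        "F": BPModel(intercept=90.0, age_slope=1.4, sd_intercept=4.0, sd_slope=0.35),
        "M": BPModel(intercept=89.5, age_slope=1.5, sd_intercept=4.0, sd_slope=0.40),
    }


def _default_dbp():
    return {
        "F": BPModel(intercept=60.0, age_slope=0.6, sd_intercept=4.5, sd_slope=0.0),
        "M": BPModel(intercept=59.0, age_slope=0.6, sd_intercept=4.5, sd_slope=0.0),
    }


def _default_bmi():
    return {"F": BMIModel(), "M": BMIModel(m_base=15.7)}


@dataclass
class GeneratorConfig:
    """Full stochastic specification of a synthetic cohort."""

    n_children: int = 1700
    age_range: tuple[float, float] = (4.0, 16.0)
    sex_ratio: float = 0.5
    height_model: dict = field(default_factory=_default_height)
    bmi_model: dict = field(default_factory=_default_bmi)
    waist_model: WaistModel = field(default_factory=WaistModel)
    sbp_model: dict = field(default_factory=_default_sbp)
    dbp_model: dict = field(default_factory=_default_dbp)
    #: SD of one reading around the child's true BP.  Assumed default: the
    #: measuring device's repeat variability is not published, so 3 mmHg is
    #: a documented assumption, not an estimate.
    within_visit_sd: float = 3.0
    missing_weight_rate: float = 0.035
    overweight_rate: float = 0.10
    exclusion_flag_rates: dict = field(
        default_factory=lambda: {"medication": 0.03, "diagnosis": 0.02, "non_danish": 0.05}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 0:
            raise ConfigurationError("n_children must be >= 0")
        lo, hi = self.age_range
        if not (0.0 <= lo <= hi < 18.0):
            raise ConfigurationError("age_range must satisfy 0 <= lo <= hi < 18")
        for name, rate in [
            ("sex_ratio", self.sex_ratio),
            ("missing_weight_rate", self.missing_weight_rate),
            ("overweight_rate", self.overweight_rate),
            *((f"exclusion_flag_rates[{k}]", v) for k, v in self.exclusion_flag_rates.items()),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.within_visit_sd < 0:
            raise ConfigurationError("within_visit_sd must be >= 0")
        for sex in ("F", "M"):
            for name, models in [("sbp_model", self.sbp_model), ("dbp_model", self.dbp_model)]:
                m = models[sex]
                if m.sd_intercept < 0 or m.sd_slope < 0:
                    raise ConfigurationError(f"{name}[{sex}] residual SDs must be >= 0")
            h = self.height_model[sex]
            if h.sd_young_cm < 0 or h.sd_old_cm < 0:
                raise ConfigurationError(f"height_model[{sex}] SDs must be >= 0")


def _draw_ages(cfg: GeneratorConfig, n: int) -> np.ndarray:
    lo, hi = cfg.age_range
    if hi > lo:
        return _rng(cfg.seed, "age").uniform(lo, hi, size=n)
    return np.full(n, float(lo))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table, one row per child.

    Deterministic given ``config.seed``.  Each child's true SBP/DBP is drawn
    from the Gaussian model at their age and sex; three readings are the true
    value plus independent within-visit noise, rounded to integer mmHg.
    """
    config.validate()
    n = config.n_children
    cols = {c: [] for c in COHORT_COLUMNS}
    if n == 0:
        return pd.DataFrame(cols, columns=COHORT_COLUMNS)

    age = _draw_ages(config, n)
    female = _rng(config.seed, "sex").random(n) < config.sex_ratio
    sex = np.where(female, "F", "M")

    height_z = _rng(config.seed, "height").standard_normal(n)
    height = np.empty(n)
    for s in ("F", "M"):
        mask = sex == s
        hm = config.height_model[s]
        height[mask] = hm.mean(age[mask]) + hm.sd(age[mask]) * height_z[mask]
    height = np.round(height, 1)

    # BMI z shifted so P(z >= cutoff at BMI 25, age 18) == overweight_rate.
    bmi_z = _rng(config.seed, "bmi").standard_normal(n)
    bmi = np.empty(n)
    for s in ("F", "M"):
        mask = sex == s
        bm = config.bmi_model[s]
        zcut = bm.cutoff_z(25.0, 18.0)
        if config.overweight_rate <= 0.0:
            shift = zcut - 8.0
        elif config.overweight_rate >= 1.0:
            shift = zcut + 8.0
        else:
            shift = zcut - norm.ppf(1.0 - config.overweight_rate)
        bmi[mask] = bm.from_z(age[mask], bmi_z[mask] + shift)
    weight = np.round(bmi * (height / 100.0) ** 2, 1)

    whtr = (
        config.waist_model.whtr_mean
        + config.waist_model.whtr_sd * _rng(config.seed, "waist").standard_normal(n)
    )
    waist = np.round(whtr * height, 1)

    true_bp = {}
    for outcome, models in [("sbp", config.sbp_model), ("dbp", config.dbp_model)]:
        z = _rng(config.seed, outcome).standard_normal(n)
        vals = np.empty(n)
        for s in ("F", "M"):
            mask = sex == s
            m = models[s]
            vals[mask] = m.mean(age[mask], height_z[mask]) + m.sd(age[mask]) * z[mask]
        true_bp[outcome] = vals

    noise = _rng(config.seed, "readings").standard_normal((n, 6)) * config.within_visit_sd
    sbp_readings = round_half_away(true_bp["sbp"][:, None] + noise[:, :3])
    dbp_readings = round_half_away(true_bp["dbp"][:, None] + noise[:, 3:])

    hr = round_half_away(95.0 - 1.7 * age + 8.0 * _rng(config.seed, "heart_rate").standard_normal(n))

    weight_missing = _rng(config.seed, "missing_weight").random(n) < config.missing_weight_rate
    rates = config.exclusion_flag_rates
    medication = _rng(config.seed, "flag_medication").random(n) < rates.get("medication", 0.0)
    diagnosis = _rng(config.seed, "flag_diagnosis").random(n) < rates.get("diagnosis", 0.0)
    non_danish = _rng(config.seed, "flag_non_danish").random(n) < rates.get("non_danish", 0.0)

    df = pd.DataFrame(
        {
            "id": [f"C{i:05d}" for i in range(n)],
            "sex": sex,
            "age_years": np.round(age, 3),
            "height_cm": height,
            "weight_kg": np.where(weight_missing, np.nan, weight),
            "waist_cm": waist,
            "origin_danish": (~non_danish).astype(int),
            "excl_medication": medication.astype(int),
            "excl_diagnosis": diagnosis.astype(int),
            "sbp1": sbp_readings[:, 0],
            "sbp2": sbp_readings[:, 1],
            "sbp3": sbp_readings[:, 2],
            "dbp1": dbp_readings[:, 0],
            "dbp2": dbp_readings[:, 1],
            "dbp3": dbp_readings[:, 2],
            "heart_rate": hr,
        },
        columns=COHORT_COLUMNS,
    )
    return df


def make_growth_reference(config: GeneratorConfig, measure: str = "height") -> pd.DataFrame:
    """Emit a per-sex, per-integer-age LMS table consistent with the generator.

    ``measure="height"`` uses L=1 rows (z-scoring generated heights against
    the table yields standard-normal values); ``measure="bmi"`` emits the
    skewed BMI reference and always extends to age 18 so the overweight
    cutoff (BMI 25 at age 18) is computable.
    """
    config.validate()
    lo, hi = config.age_range
    ages = list(range(int(np.floor(lo)), int(np.ceil(hi)) + 1))
    if measure == "bmi":
        ages = list(range(ages[0], max(18, ages[-1]) + 1))
    rows = []
    for s in ("F", "M"):
        for a in ages:
            if measure == "height":
                hm = config.height_model[s]
                M = float(hm.mean(a))
                rows.append({"sex": s, "age_years": a, "L": 1.0, "M": round(M, 4),
                             "S": round(float(hm.sd(a)) / M, 6)})
            elif measure == "bmi":
                bm = config.bmi_model[s]
                rows.append({"sex": s, "age_years": a, "L": bm.L,
                             "M": round(float(bm.median(a)), 4), "S": bm.S})
            else:
                raise ConfigurationError(f"unknown growth measure: {measure!r}")
    return pd.DataFrame(rows, columns=["sex", "age_years", "L", "M", "S"])
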