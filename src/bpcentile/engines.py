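"""Percentile assignment and guideline classification engines.

A child's mean BP can be placed on a percentile scale under any of three
reference representations:

* ``lookup`` — a printed table of integer thresholds (e.g. the packaged
  Danish reference); returns a category {<90th, >=90th, >=95th}, never a
  continuous percentile, because interpolating between three printed columns
  would invent precision.
* ``gaussian_poly`` — the US-style published-equation form: a quartic
  polynomial in (age - 10) and height z-score with Gaussian residual.
* ``quantile_set`` — per-tau linear fits on the 5% grid, interpolated
  between bracketing taus and clamped to [2.5, 97.5] beyond the grid.

Guideline specs combine a reference with the age-dependent switch to fixed
mmHg cut-offs (AAP >= 13y: 130/80; ESC >= 16y: 130/85; ESH >= 16y: 140/90).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import prep
from .errors import ConfigurationError, CoverageError, RangeError
from .reference_fit import QuantileFitSet

__all__ = [
    "LookupReference",
    "GaussianPolynomialReference",
    "QuantileSetReference",
    "load_reference",
    "load_packaged_reference",
    "height_zscore",
    "percentile_of",
    "GuidelineSpec",
    "make_guideline",
    "classify",
    "classify_cohort",
]

CATEGORY_LT90 = "<90th"
CATEGORY_GE90 = ">=90th"
CATEGORY_GE95 = ">=95th"


def height_zscore(height_cm: float, age: float, sex: str, growth_ref: pd.DataFrame) -> float:
    """Height z-score against an LMS growth reference (age-interpolated)."""
    return prep.zscore_from_table(height_cm, age, sex, growth_ref)


@dataclass
class LookupReference:
    """Printed threshold table keyed by (outcome, sex, integer age, percentile)."""

    name: str
    percentiles: tuple
    values: dict  # values[outcome][sex][age(int)][percentile(int)] -> int mmHg
    age_coding: str = "completed"  # or "nearest"
    requires_height: bool = False

    def _age_row(self, age: float) -> int:
        if self.age_coding == "completed":
            return int(np.floor(age))
        if self.age_coding == "nearest":
            return int(round(age))
        raise ConfigurationError(f"unknown age_coding: {self.age_coding!r}")

    def ages(self, outcome: str, sex: str):
        return sorted(self.values[outcome][sex])

    def threshold(self, percentile: int, age: float, sex: str, outcome: str,
                  height_z: float = 0.0) -> float:
        row = self._age_row(age)
        try:
            return float(self.values[outcome][sex][row][int(percentile)])
        except KeyError:
            raise CoverageError(
                f"{self.name} has no {outcome} {percentile}th value for sex={sex}, age row {row}"
            ) from None

    def category(self, bp: float, age: float, sex: str, outcome: str) -> str:
        """Coarse percentile category; threshold boundaries are inclusive."""
        if 95 not in self.percentiles or 90 not in self.percentiles:
            raise ConfigurationError(f"{self.name} lacks 90th/95th columns for categorisation")
        p95 = self.threshold(95, age, sex, outcome)
        p90 = self.threshold(90, age, sex, outcome)
        if bp >= p95:
            return CATEGORY_GE95
        if bp >= p90:
            return CATEGORY_GE90
        return CATEGORY_LT90

    def to_dict(self) -> dict:
        return {
            "type": "lookup", "name": self.name, "age_coding": self.age_coding,
            "percentiles": list(self.percentiles),
            "values": {
                o: {s: {str(a): {str(p): v for p, v in row.items()}
                        for a, row in by_age.items()}
                    for s, by_age in by_sex.items()}
                for o, by_sex in self.values.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LookupReference":
        values = {
            o: {s: {int(a): {int(p): int(v) for p, v in row.items()}
                    for a, row in by_age.items()}
                for s, by_age in by_sex.items()}
            for o, by_sex in d["values"].items()
        }
        return cls(name=d.get("name", "lookup"), percentiles=tuple(d["percentiles"]),
                   values=values, age_coding=d.get("age_coding", "completed"))

    @classmethod
    def from_reference_table(cls, table: pd.DataFrame, name: str = "fitted") -> "LookupReference":
        values: dict = {}
        for _, r in table.iterrows():
            values.setdefault(r["outcome"], {}).setdefault(r["sex"], {}).setdefault(
                int(r["age"]), {}
            )[int(r["percentile"])] = int(r["value_mmhg"])
        pcts = tuple(sorted(table["percentile"].unique().tolist()))
        return cls(name=name, percentiles=pcts, values=values)


@dataclass
class GaussianPolynomialReference:
    """mu = alpha + sum_j beta_j (age-10)^j + sum_k gamma_k z_h^k; residual N(0, sigma)."""

    name: str
    params: dict  # params[outcome][sex] -> {alpha, beta: [4], gamma: [4], sigma}
    requires_height: bool = True

    def __post_init__(self):
        for outcome, by_sex in self.params.items():
            for sex, p in by_sex.items():
                if p["sigma"] <= 0:
                    raise ConfigurationError(f"sigma must be > 0 for {outcome}/{sex}")

    def _p(self, outcome: str, sex: str) -> dict:
        try:
            return self.params[outcome][sex]
        except KeyError:
            raise CoverageError(f"{self.name} has no parameters for {outcome}/{sex}") from None

    def mu(self, age: float, sex: str, outcome: str, height_z: float = 0.0) -> float:
        p = self._p(outcome, sex)
        a = age - 10.0
        val = p["alpha"]
        for j, b in enumerate(p["beta"], start=1):
            val += b * a ** j
        for k, g in enumerate(p["gamma"], start=1):
            val += g * height_z ** k
        return float(val)

    def percentile(self, bp: float, age: float, sex: str, outcome: str,
                   height_z: float = 0.0) -> float:
        p = self._p(outcome, sex)
        return float(100.0 * norm.cdf((bp - self.mu(age, sex, outcome, height_z)) / p["sigma"]))

    def threshold(self, percentile: float, age: float, sex: str, outcome: str,
                  height_z: float = 0.0) -> float:
        p = self._p(outcome, sex)
        return self.mu(age, sex, outcome, height_z) + norm.ppf(percentile / 100.0) * p["sigma"]

    def to_dict(self) -> dict:
        return {"type": "gaussian_poly", "name": self.name,
                "requires_height": self.requires_height, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianPolynomialReference":
        return cls(name=d.get("name", "gaussian_poly"), params=d["params"],
                   requires_height=bool(d.get("requires_height", True)))


#: Percentile clamp outside the fitted 5% grid.
_CLAMP_LO, _CLAMP_HI = 2.5, 97.5


@dataclass
class QuantileSetReference:
    """Reference backed by per-sex/outcome :class:`QuantileFitSet` objects."""

    name: str
    fits: dict  # fits[outcome][sex] -> QuantileFitSet
    requires_height: bool = False
    age_range: tuple = (4.0, 16.0)

    def _fit(self, outcome: str, sex: str) -> QuantileFitSet:
        try:
            return self.fits[outcome][sex]
        except KeyError:
            raise CoverageError(f"{self.name} has no fit for {outcome}/{sex}") from None

    def _check_age(self, age: float) -> None:
        lo, hi = self.age_range
        if not lo <= age < hi:
            raise RangeError(f"age {age} outside {self.name} range [{lo}, {hi})")

    def percentile(self, bp: float, age: float, sex: str, outcome: str,
                   height_z: float = 0.0) -> float:
        """Largest grid tau whose predicted quantile is <= bp, interpolated
        linearly between bracketing taus, clamped to [2.5, 97.5]."""
        self._check_age(age)
        fit = self._fit(outcome, sex)
        q = fit.predict_sorted(age)
        taus = np.asarray(fit.taus)
        if bp < q[0]:
            return _CLAMP_LO
        if bp >= q[-1]:
            return 100.0 * float(taus[-1]) if bp == q[-1] else _CLAMP_HI
        i = int(np.searchsorted(q, bp, side="right") - 1)
        if q[i + 1] == q[i]:
            return 100.0 * float(taus[i + 1])
        frac = (bp - q[i]) / (q[i + 1] - q[i])
        return 100.0 * float(taus[i] + frac * (taus[i + 1] - taus[i]))

    def threshold(self, percentile: float, age: float, sex: str, outcome: str,
                  height_z: float = 0.0) -> float:
        self._check_age(age)
        fit = self._fit(outcome, sex)
        taus = np.round(np.asarray(fit.taus) * 100, 1)
        idx = np.where(taus == round(float(percentile), 1))[0]
        if len(idx) == 0:
            raise ConfigurationError(f"percentile {percentile} not on the fitted tau grid")
        return float(fit.predict_sorted(age)[idx[0]])

    def to_dict(self) -> dict:
        return {
            "type": "quantile_set", "name": self.name, "age_range": list(self.age_range),
            "fits": {o: {s: f.to_dict() for s, f in by_sex.items()}
                     for o, by_sex in self.fits.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileSetReference":
        fits = {o: {s: QuantileFitSet.from_dict(f) for s, f in by_sex.items()}
                for o, by_sex in d["fits"].items()}
        return cls(name=d.get("name", "quantile_set"), fits=fits,
                   age_range=tuple(d.get("age_range", (4.0, 16.0))))


_REFERENCE_TYPES = {
    "lookup": LookupReference,
    "gaussian_poly": GaussianPolynomialReference,
    "quantile_set": QuantileSetReference,
}


def load_reference(source):
    """Build a reference model from a dict, JSON string, or JSON file path."""
    if isinstance(source, dict):
        d = source
    else:
        text = source if str(source).lstrip().startswith("{") else open(source).read()
        d = json.loads(text)
    try:
        cls = _REFERENCE_TYPES[d["type"]]
    except KeyError:
        raise ConfigurationError(f"unknown reference type: {d.get('type')!r}") from None
    return cls.from_dict(d)


def load_packaged_reference(name: str):
    """Load a reference shipped with the package (e.g. ``danish_2025``)."""
    text = resources.files("bpcentile.data").joinpath(f"{name}.json").read_text()
    return load_reference(json.loads(text))


def percentile_of(bp: float, age: float, sex: str, model, outcome: str,
                  height_z: float | None = None):
    """Percentile (continuous, 0-100) or category of ``bp`` under ``model``."""
    if getattr(model, "requires_height", False) and height_z is None:
        raise CoverageError(f"{model.name} requires a height z-score")
    z = 0.0 if height_z is None else float(height_z)
    if isinstance(model, LookupReference):
        return model.category(bp, age, sex, outcome)
    return model.percentile(bp, age, sex, outcome, height_z=z)


@dataclass
class GuidelineSpec:
    """A guideline's decision rule: percentile cut-off below an age switch,
    fixed mmHg thresholds at and above it.  All age boundaries inclusive."""

    name: str
    reference: object
    percentile_cutoff: float = 95.0
    fixed_threshold_age: float = 16.0
    fixed_sbp: float | None = None
    fixed_dbp: float | None = None
    evaluation_age_window: tuple = (4.0, 16.0)

    def __post_init__(self):
        lo, hi = self.evaluation_age_window
        if not lo < hi:
            raise ConfigurationError("evaluation_age_window must be an increasing pair")


_BUILTIN_GUIDELINES = {
    # name: (fixed_threshold_age, fixed_sbp, fixed_dbp, window)
    "aap": (13.0, 130.0, 80.0, (4.0, 13.0)),
    "esc": (16.0, 130.0, 85.0, (4.0, 16.0)),
    "esh": (16.0, 140.0, 90.0, (4.0, 16.0)),
    "danish": (16.0, None, None, (4.0, 16.0)),
}


def make_guideline(name: str, reference, evaluation_age_window=None) -> GuidelineSpec:
    """Builtin guideline shells (aap/esc/esh/danish) around a reference model.

    The AAP window stops at 13 because its percentile comparison applies to
    under-13s only; ESC/ESH switch to fixed thresholds at 16, beyond this
    cohort's ages, so their percentile rule covers the whole window.
    """
    key = name.lower()
    if key not in _BUILTIN_GUIDELINES:
        raise ConfigurationError(f"unknown guideline: {name!r}")
    age13, fsbp, fdbp, window = _BUILTIN_GUIDELINES[key]
    return GuidelineSpec(
        name=key, reference=reference, fixed_threshold_age=age13,
        fixed_sbp=fsbp, fixed_dbp=fdbp,
        evaluation_age_window=tuple(evaluation_age_window or window),
    )


def _positive_percentile(value, cutoff: float) -> bool:
    if isinstance(value, str):  # lookup category
        if cutoff == 95.0:
            return value == CATEGORY_GE95
        if cutoff == 90.0:
            return value in (CATEGORY_GE90, CATEGORY_GE95)
        raise ConfigurationError(f"lookup references support cut-offs 90/95, not {cutoff}")
    return value >= cutoff - 1e-9  # boundary equality is positive, despite fp round-trips


def classify(mean_sbp: float, mean_dbp: float, age: float, sex: str,
             guideline: GuidelineSpec, height_z: float | None = None):
    """Classify one child: (status 'positive'|'negative', basis 'percentile'|'fixed').

    Below the guideline's fixed-threshold age the child is positive iff the
    SBP and/or DBP percentile reaches the cut-off; at or above it, iff mean
    BP reaches the fixed mmHg thresholds.  Boundary equality is positive in
    both branches.
    """
    lo, hi = guideline.evaluation_age_window
    if not lo <= age < hi:
        raise RangeError(f"age {age} outside {guideline.name} evaluation window [{lo}, {hi})")
    if age >= guideline.fixed_threshold_age:
        if guideline.fixed_sbp is None or guideline.fixed_dbp is None:
            raise ConfigurationError(f"{guideline.name} has no fixed thresholds configured")
        pos = mean_sbp >= guideline.fixed_sbp or mean_dbp >= guideline.fixed_dbp
        return ("positive" if pos else "negative"), "fixed"
    cutoff = guideline.percentile_cutoff
    p_s = percentile_of(mean_sbp, age, sex, guideline.reference, "sbp", height_z)
    p_d = percentile_of(mean_dbp, age, sex, guideline.reference, "dbp", height_z)
    pos = _positive_percentile(p_s, cutoff) or _positive_percentile(p_d, cutoff)
    return ("positive" if pos else "negative"), "percentile"


def classify_cohort(prepared: pd.DataFrame, guideline: GuidelineSpec,
                    growth_ref: pd.DataFrame | None = None) -> pd.DataFrame:
    """Vectorised classification; children outside the evaluation window get
    status None so concordance analysis can exclude and count them."""
    needs_z = getattr(guideline.reference, "requires_height", False)
    rows = []
    for _, r in prepared.iterrows():
        z = None
        if needs_z:
            if growth_ref is None:
                raise CoverageError(f"{guideline.name} reference requires a growth reference")
            z = height_zscore(float(r["height_cm"]), float(r["age_years"]), r["sex"], growth_ref)
        try:
            status, basis = classify(
                float(r["mean_sbp"]), float(r["mean_dbp"]), float(r["age_years"]),
                r["sex"], guideline, height_z=z,
            )
        except RangeError:
            status, basis = None, "out_of_window"
        rows.append({"id": r["id"], "status": status, "basis": basis})
    return pd.DataFrame(rows, columns=["id", "status", "basis"])
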