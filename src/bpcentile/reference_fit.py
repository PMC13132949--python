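"""Model fitting for percentile reference construction.

Three model families are fitted to mean BP: ordinary least squares (adjusted
R-squared comparison), restricted cubic splines with quartile knots, and
linear quantile regression on the 19-point 5% grid.  Quantile fits are turned
into integer-mmHg reference tables with non-crossing enforced by isotonic
rearrangement, and a full-vs-simple (with/without height) model comparison
reports detection and reclassification fractions at the 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.optimize import linprog
from scipy.stats import norm

from ._util import round_half_away
from .errors import ConfigurationError, DataError, SingularityError

__all__ = [
    "TAU_GRID",
    "LinearModelFit",
    "SplineSpec",
    "QuantileFitSet",
    "fit_linear",
    "spline_spec_from_data",
    "spline_basis",
    "fit_quantile",
    "fit_quantile_set",
    "pinball_loss",
    "build_reference_table",
    "compare_models",
]

#: The 19-point 5% grid, 0.05 .. 0.95.
TAU_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name predictor columns that lie in the span of the remaining ones
        bad = []
        for j in range(1, design.shape[1]):  # column 0 is the intercept
            others = np.delete(design, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
            if np.allclose(others @ beta, design[:, j], atol=1e-8):
                bad.append(names[j - 1])
        raise SingularityError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass(frozen=True)
class LinearModelFit:
    predictors: tuple
    coefficients: dict
    intercept: float
    r2: float
    adj_r2: float
    residual_sd: float
    n: int


def fit_linear(y, X) -> LinearModelFit:
    """OLS fit with intercept; X may be a DataFrame, 2-D array, or empty.

    ``adj_r2 = 1 - (1 - r2)(n - 1)/(n - p - 1)`` with p the number of
    predictor columns; the intercept-only model has r2 = adj_r2 = 0.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and np.size(X) == 0) or (isinstance(X, (list, tuple)) and not X):
        Xm, names = np.empty((n, 0)), []
    else:
        Xm, names = _as_matrix(X)
    p = Xm.shape[1]
    if n < p + 2:
        raise DataError(f"need at least p + 2 = {p + 2} observations, got {n}")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(Xm)):
        raise DataError("fit_linear does not accept missing or non-finite values")
    design = np.column_stack([np.ones(n), Xm])
    _check_rank(design, names)

    res = sm.OLS(y, design).fit()
    fitted = res.fittedvalues
    ssr = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    adj = r2 if p == 0 else 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if p == 0:
        r2 = adj = 0.0
    return LinearModelFit(
        predictors=tuple(names),
        coefficients={nm: float(b) for nm, b in zip(names, res.params[1:])},
        intercept=float(res.params[0]),
        r2=r2,
        adj_r2=adj,
        residual_sd=float(np.sqrt(ssr / (n - p - 1))),
        n=n,
    )


@dataclass(frozen=True)
class SplineSpec:
    """Three-knot natural cubic spline placed at a variable's quartiles."""

    variable: str
    knots: tuple

    def __post_init__(self):
        k = self.knots
        if len(k) != 3 or not (k[0] < k[1] < k[2]):
            raise ConfigurationError("knots must be three strictly increasing values")


def spline_spec_from_data(x, variable: str = "x") -> SplineSpec:
    """Knots at the 1st quartile, median, and 3rd quartile (linear-interp quantiles)."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        raise DataError("need at least 3 distinct values to place spline knots")
    q = np.quantile(x, [0.25, 0.5, 0.75])
    if not (q[0] < q[1] < q[2]):
        # fall back to distinct quantile points on very discrete data
        raise DataError("quartile knots are not distinct; data too discrete for a spline")
    return SplineSpec(variable=variable, knots=tuple(q))


def spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Restricted (natural) cubic spline basis: [x, nonlinear term].

    With knots k1 < k2 < k3 the single nonlinear column is the Harrell form

        [(x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2)]
            / (k3 - k1)^2

    which is linear beyond the boundary knots and C2 everywhere.
    """
    x = np.asarray(x, dtype=float)
    k1, k2, k3 = spec.knots
    def pos3(v):
        return np.clip(v, 0.0, None) ** 3
    term = (
        pos3(x - k1)
        - pos3(x - k2) * (k3 - k1) / (k3 - k2)
        + pos3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, term])


def pinball_loss(y, fitted, tau: float) -> float:
    """Check loss: sum of u*(tau - 1[u < 0]) over residuals u = y - fitted."""
    u = np.asarray(y, dtype=float) - np.asarray(fitted, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile(y, X, tau: float):
    """Linear quantile regression by LP minimisation of the check loss.

    Returns ``(intercept, coefficients)`` where ``coefficients`` maps
    predictor name to slope.  Solved exactly with HiGHS on the dual program

        max { y'd : X'd = 0, d in [tau - 1, tau]^n }

    whose equality-constraint marginals recover the primal coefficients (a
    basic optimal vertex; any minimiser on the optimal face is acceptable).
    """
    if not 0.0 < tau < 1.0:
        raise ConfigurationError(f"tau must be in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and np.size(X) == 0) or (isinstance(X, (list, tuple)) and not X):
        Xm, names = np.empty((n, 0)), []
    else:
        Xm, names = _as_matrix(X)
    p = Xm.shape[1]
    if n < p + 2:
        raise DataError(f"need at least p + 2 = {p + 2} observations, got {n}")
    design = np.column_stack([np.ones(n), Xm])
    _check_rank(design, names)

    res = linprog(
        -y, A_eq=sp.csr_matrix(design.T), b_eq=np.zeros(p + 1),
        bounds=[(tau - 1.0, tau)] * n, method="highs",
    )
    if res.status != 0:
        raise DataError(f"quantile LP failed to solve: {res.message}")
    beta = -np.asarray(res.eqlin.marginals, dtype=float)
    return float(beta[0]), {nm: float(b) for nm, b in zip(names, beta[1:])}


@dataclass(frozen=True)
class QuantileFitSet:
    """Per-tau linear (intercept + age slope) quantile fits for one sex/outcome."""

    outcome: str  # "sbp" | "dbp"
    sex: str      # "F" | "M"
    taus: tuple = TAU_GRID
    intercepts: tuple = ()
    age_slopes: tuple = ()
    n: int = 0

    def __post_init__(self):
        if tuple(np.round(self.taus, 2)) != TAU_GRID:
            raise ConfigurationError("tau grid must be exactly 0.05, 0.10, ..., 0.95")
        if len(self.intercepts) != len(self.taus) or len(self.age_slopes) != len(self.taus):
            raise ConfigurationError("one (intercept, age slope) pair required per tau")

    def predict(self, age: float) -> np.ndarray:
        """Predicted quantile values across the tau grid (unsorted)."""
        return np.asarray(self.intercepts) + np.asarray(self.age_slopes) * float(age)

    def predict_sorted(self, age: float) -> np.ndarray:
        """Quantile curve after isotonic (sort) rearrangement across taus."""
        return np.sort(self.predict(age))

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "sex": self.sex,
            "taus": [float(t) for t in self.taus],
            "intercepts": [float(b) for b in self.intercepts],
            "age_slopes": [float(b) for b in self.age_slopes],
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileFitSet":
        return cls(
            outcome=d["outcome"], sex=d["sex"], taus=tuple(d["taus"]),
            intercepts=tuple(d["intercepts"]), age_slopes=tuple(d["age_slopes"]),
            n=int(d.get("n", 0)),
        )


def fit_quantile_set(age, y, outcome: str, sex: str, taus=TAU_GRID) -> QuantileFitSet:
    """Fit intercept + age-slope quantile regressions on the full tau grid."""
    age = np.asarray(age, dtype=float)
    X = pd.DataFrame({"age": age})
    intercepts, slopes = [], []
    for tau in taus:
        b0, coef = fit_quantile(y, X, tau)
        intercepts.append(b0)
        slopes.append(coef["age"])
    return QuantileFitSet(
        outcome=outcome, sex=sex, taus=tuple(taus),
        intercepts=tuple(intercepts), age_slopes=tuple(slopes), n=len(y),
    )


def build_reference_table(fits, ages, percentiles=(50, 90, 95)) -> pd.DataFrame:
    """Integer-mmHg reference table from per-sex quantile fit sets.

    Percentiles must sit on the 5% grid.  At each integer age the predicted
    quantiles are rearranged (sorted) across the tau grid before extraction,
    so within every (sex, age) the values are non-decreasing in percentile.
    Rounding is half away from zero; the unrounded value is retained.
    """
    fits = list(fits)
    for pct in percentiles:
        if pct % 5 != 0 or not 5 <= pct <= 95:
            raise ConfigurationError(f"percentile {pct} is not on the 5..95 5% grid")
    rows = []
    for fit in fits:
        tau_idx = {int(round(t * 100)): i for i, t in enumerate(fit.taus)}
        for a in ages:
            q = fit.predict_sorted(a)
            for pct in percentiles:
                raw = float(q[tau_idx[int(pct)]])
                rows.append({
                    "outcome": fit.outcome, "sex": fit.sex, "age": int(a),
                    "percentile": int(pct), "value_mmhg": round_half_away(raw),
                    "value_raw": round(raw, 4),
                })
    table = pd.DataFrame(rows, columns=["outcome", "sex", "age", "percentile", "value_mmhg", "value_raw"])
    table.attrs["percentiles"] = [int(p) for p in percentiles]
    return table


def _positivity(df, q95):
    """Positive iff mean SBP and/or mean DBP >= the model's 95th percentile."""
    return (df["mean_sbp"].to_numpy() >= q95["sbp"]) | (df["mean_dbp"].to_numpy() >= q95["dbp"])


def compare_models(prepared: pd.DataFrame, ages=None, tau: float = 0.95,
                   height_span_z: float = norm.ppf(0.95)) -> dict:
    """Full (age + sex + height-z) vs simple (age + sex) 95th-percentile models.

    Reports (i) adjusted R-squared per model and outcome, (ii) mean and max
    absolute gap in the predicted 95th percentile between median-height
    children and those at the 5th/95th height percentile, and (iii) the
    fraction of full-model positives detected by the simple model plus the
    overall reclassified fraction, with denominators.
    """
    df = prepared
    if "height_z" not in df.columns:
        raise DataError("compare_models requires a height_z column (z-scored height)")
    missing = df.index[df["height_z"].isna() | df["mean_sbp"].isna() | df["mean_dbp"].isna()]
    if len(missing):
        raise DataError(f"missing height or BP for ids: {list(df.loc[missing, 'id'])[:10]}")
    if ages is None:
        ages = sorted(int(a) for a in np.unique(np.floor(df["age_years"])))

    female = (df["sex"] == "F").astype(float).to_numpy()
    X_simple = pd.DataFrame({"age": df["age_years"].to_numpy(dtype=float), "female": female})
    X_full = X_simple.assign(height_z=df["height_z"].to_numpy(dtype=float))

    report = {"adj_r2": {}, "height_gap_mmhg": {}, "detection": {}}
    q95 = {"full": {}, "simple": {}}
    gaps = {}
    for outcome in ("sbp", "dbp"):
        y = df[f"mean_{outcome}"].to_numpy(dtype=float)
        report["adj_r2"][outcome] = {
            "full": round(fit_linear(y, X_full).adj_r2, 4),
            "simple": round(fit_linear(y, X_simple).adj_r2, 4),
        }
        b0_f, cf = fit_quantile(y, X_full, tau)
        b0_s, cs = fit_quantile(y, X_simple, tau)
        q95["full"][outcome] = (
            b0_f + cf["age"] * X_full["age"] + cf["female"] * female
            + cf["height_z"] * X_full["height_z"]
        ).to_numpy()
        q95["simple"][outcome] = (b0_s + cs["age"] * X_simple["age"] + cs["female"] * female).to_numpy()
        # linear in height-z, so the median-vs-5th/95th gap is |gamma| * z-span
        gap = abs(cf["height_z"]) * height_span_z
        gaps[outcome] = gap
        report["height_gap_mmhg"][outcome] = {
            "mean_abs": round(gap, 4),
            "max_abs": round(gap, 4),
            "height_coefficient": round(cf["height_z"], 4),
        }

    pos_full = _positivity(df, q95["full"])
    pos_simple = _positivity(df, q95["simple"])
    n_pos_full = int(pos_full.sum())
    detected = int((pos_full & pos_simple).sum())
    reclassified = int((pos_full != pos_simple).sum())
    report["detection"] = {
        "full_positive": n_pos_full,
        "detected_by_simple": detected,
        "detection_fraction_pct": round(100.0 * detected / n_pos_full, 2) if n_pos_full else None,
        "reclassified": reclassified,
        "reclassified_fraction_pct": round(100.0 * reclassified / len(df), 2),
        "n": int(len(df)),
    }
    report["tau"] = tau
    report["ages"] = [int(a) for a in ages]
    return report
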