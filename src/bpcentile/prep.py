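"""Raw child records -> analysis-ready records.

Covers the measurement protocol's mean-BP rule (average of the last two of
three readings, with one/two-reading fallbacks), LMS z-scoring against a
growth reference, overweight classification (BMI-SDS cutoff anchored at
BMI 25 at age 18, waist-to-height ratio >= 0.5 as fallback), and
deterministic exclusion filtering with a per-reason log.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, RangeError

__all__ = [
    "mean_bp",
    "lms_zscore",
    "lms_inverse",
    "lookup_lms",
    "zscore_from_table",
    "overweight_cutoff_z",
    "classify_weight",
    "prepare_cohort",
    "EXCLUSION_ORDER",
    "apply_exclusions",
]

#: Fixed precedence: data availability first, then register flags, then origin.
EXCLUSION_ORDER = ("no_bp", "unclassifiable_weight", "medication", "diagnosis", "non_danish_origin")


def mean_bp(readings) -> float:
    """Protocol mean of an ordered reading list.

    Three readings -> mean of the 2nd and 3rd; two -> their mean; one -> the
    reading itself.  Reading order is authoritative; no rounding.
    """
    r = [float(v) for v in readings]
    if len(r) == 0:
        raise DataError("mean_bp requires at least one reading")
    if len(r) > 3:
        raise DataError(f"mean_bp accepts at most 3 readings, got {len(r)}")
    if len(r) == 3:
        return (r[1] + r[2]) / 2.0
    return sum(r) / len(r)


def lms_zscore(x, L, M, S):
    """LMS (Cole) transform: z = ((x/M)^L - 1)/(L*S), or ln(x/M)/S when L=0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(np.asarray(M, float) <= 0) or np.any(np.asarray(S, float) <= 0):
        raise DataError("lms_zscore requires x > 0, M > 0, S > 0")
    L = np.asarray(L, dtype=float)
    ratio = x / M
    # |L| below ~1e-8 underflows in the power branch; use the L->0 log limit
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.abs(L) < 1e-8, np.log(ratio) / S, (ratio ** L - 1.0) / (L * S))
    if z.ndim == 0:
        return float(z)
    return z


def lms_inverse(z, L, M, S):
    """Measurement value at z-score ``z``: the inverse of :func:`lms_zscore`."""
    if L == 0.0:
        return M * math.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


def lookup_lms(table: pd.DataFrame, sex: str, age: float):
    """Interpolate (L, M, S) linearly in age for one sex.

    ``table`` has columns sex, age_years, L, M, S.  Ages outside the table's
    span raise :class:`RangeError`.
    """
    sub = table[table["sex"] == sex].sort_values("age_years")
    if sub.empty:
        raise RangeError(f"growth reference has no rows for sex {sex!r}")
    ages = sub["age_years"].to_numpy(dtype=float)
    if age < ages[0] or age > ages[-1]:
        raise RangeError(f"age {age} outside growth-reference range [{ages[0]}, {ages[-1]}]")
    L = float(np.interp(age, ages, sub["L"].to_numpy(dtype=float)))
    M = float(np.interp(age, ages, sub["M"].to_numpy(dtype=float)))
    S = float(np.interp(age, ages, sub["S"].to_numpy(dtype=float)))
    return L, M, S


def zscore_from_table(x: float, age: float, sex: str, table: pd.DataFrame) -> float:
    """z-score of ``x`` against an LMS table with age interpolation."""
    L, M, S = lookup_lms(table, sex, age)
    return float(lms_zscore(x, L, M, S))


def overweight_cutoff_z(bmi_reference: pd.DataFrame, sex: str,
                        bmi: float = 25.0, age: float = 18.0) -> float:
    """z that maps to ``bmi`` at ``age`` in the supplied reference.

    The IOTF convention anchors "overweight" at the centile passing through
    BMI 25 at age 18; the cutoff is computed from the supplied table rather
    than hard-coded, and is sex-specific.
    """
    return zscore_from_table(bmi, age, sex, bmi_reference)


def classify_weight(weight_kg, waist_cm, height_cm, bmi_sds, cutoff_z) -> str:
    """Overweight / normal / unclassifiable for one child.

    Weight present -> overweight iff BMI SDS >= cutoff; weight missing but
    waist present -> overweight iff waist/height >= 0.5 (boundary inclusive);
    both missing -> unclassifiable.
    """
    if weight_kg is not None and not (isinstance(weight_kg, float) and math.isnan(weight_kg)):
        return "overweight" if bmi_sds >= cutoff_z else "normal"
    if waist_cm is not None and not (isinstance(waist_cm, float) and math.isnan(waist_cm)):
        return "overweight" if waist_cm / height_cm >= 0.5 else "normal"
    return "unclassifiable"


def _readings(row, prefix: str) -> list[float]:
    vals = []
    for i in (1, 2, 3):
        v = row[f"{prefix}{i}"]
        if pd.isna(v):
            break
        vals.append(float(v))
    return vals


def prepare_cohort(cohort: pd.DataFrame, bmi_reference: pd.DataFrame,
                   overweight_bmi_at_18: float = 25.0) -> pd.DataFrame:
    """Derive mean BP, BMI, BMI SDS, WHtR, and weight class for every child.

    Missing weight/waist is a state, not an error; children with zero
    readings get missing mean BP (handled later by exclusion filtering).
    """
    out = cohort.copy()
    cutoffs = {s: overweight_cutoff_z(bmi_reference, s, overweight_bmi_at_18) for s in ("F", "M")}

    mean_s, mean_d, bmis, sdss, whtrs, classes = [], [], [], [], [], []
    for _, row in out.iterrows():
        sbp = _readings(row, "sbp")
        dbp = _readings(row, "dbp")
        mean_s.append(mean_bp(sbp) if sbp else np.nan)
        mean_d.append(mean_bp(dbp) if dbp else np.nan)

        height = float(row["height_cm"])
        weight = row["weight_kg"]
        waist = row["waist_cm"]
        if pd.isna(weight):
            bmi = np.nan
            sds = np.nan
        else:
            bmi = float(weight) / (height / 100.0) ** 2
            sds = zscore_from_table(bmi, float(row["age_years"]), row["sex"], bmi_reference)
        bmis.append(bmi)
        sdss.append(sds)
        whtrs.append(float(waist) / height if not pd.isna(waist) else np.nan)
        classes.append(
            classify_weight(
                None if pd.isna(weight) else float(weight),
                None if pd.isna(waist) else float(waist),
                height, sds, cutoffs[row["sex"]],
            )
        )

    out["mean_sbp"] = mean_s
    out["mean_dbp"] = mean_d
    out["bmi"] = np.round(bmis, 4)
    out["bmi_sds"] = np.round(sdss, 4)
    out["whtr"] = np.round(whtrs, 4)
    out["weight_class"] = classes
    out.attrs["overweight_cutoff_z"] = cutoffs
    return out


def apply_exclusions(prepared: pd.DataFrame, criteria=EXCLUSION_ORDER):
    """Partition a prepared cohort into included / excluded records.

    Each excluded record carries exactly one reason — the first matching
    criterion in the fixed precedence order.  Returns ``(table, log)`` where
    the log counts input, included, and per-reason exclusions.
    """
    unknown = set(criteria) - set(EXCLUSION_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown exclusion criteria: {sorted(unknown)}")

    out = prepared.copy()
    n = len(out)
    reason = pd.Series([None] * n, index=out.index, dtype=object)

    tests = {
        "no_bp": out["mean_sbp"].isna() | out["mean_dbp"].isna(),
        "unclassifiable_weight": out["weight_class"] == "unclassifiable",
        "medication": out["excl_medication"].astype(bool),
        "diagnosis": out["excl_diagnosis"].astype(bool),
        "non_danish_origin": ~out["origin_danish"].astype(bool),
    }
    for crit in EXCLUSION_ORDER:  # fixed precedence regardless of criteria order
        if crit in criteria:
            hit = tests[crit] & reason.isna()
            reason[hit] = crit

    out["exclusion_reason"] = reason
    out["included"] = reason.isna()
    log = {
        "input": int(n),
        "included": int(out["included"].sum()),
        "excluded_total": int((~out["included"]).sum()),
        "excluded_by_reason": {
            crit: int((reason == crit).sum()) for crit in EXCLUSION_ORDER if crit in criteria
        },
        "criteria": list(criteria),
    }
    if "overweight_cutoff_z" in prepared.attrs:
        log["overweight_cutoff_z"] = {
            k: round(v, 4) for k, v in prepared.attrs["overweight_cutoff_z"].items()
        }
    return out, log
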