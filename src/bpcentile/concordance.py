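"""Agreement between a benchmark reference and comparator guidelines.

Reclassification 2x2 tables at a percentile threshold, detection and false
negative/positive rates, per-age mmHg gaps between models' 95th-percentile
values, and Bland-Altman limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_away
from .errors import ConfigurationError, DataError

__all__ = [
    "ReclassTable",
    "build_reclass_table",
    "detection_rate",
    "fn_fp_rates",
    "diff_at_p95",
    "BlandAltmanStats",
    "bland_altman",
    "concordance_report",
    "format_reclass_text",
]


@dataclass(frozen=True)
class ReclassTable:
    """2x2 cross-classification: benchmark (rows) vs comparator (columns).

    a: both positive; b: benchmark-positive only; c: comparator-positive
    only; d: both negative.  ``excluded`` counts children dropped because
    either classifier's preconditions failed (e.g. outside the age window).
    """

    a: int
    b: int
    c: int
    d: int
    excluded: int = 0

    def __post_init__(self):
        for name in ("a", "b", "c", "d", "excluded"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d,
                "n": self.n, "excluded": self.excluded}


def _is_positive(label) -> bool | None:
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return None
    if isinstance(label, str):
        return label == "positive"
    return bool(label)


def build_reclass_table(benchmark_labels, comparator_labels) -> ReclassTable:
    """Cross-tabulate paired positivity labels over the same children.

    Labels may be booleans or 'positive'/'negative' strings; None/NaN marks
    a child one classifier could not evaluate — such pairs are excluded from
    the counts and tallied in ``excluded``.
    """
    bench = list(benchmark_labels)
    comp = list(comparator_labels)
    if len(bench) != len(comp):
        raise DataError(f"label vectors differ in length: {len(bench)} vs {len(comp)}")
    a = b = c = d = excluded = 0
    for lb, lc in zip(bench, comp):
        pb, pc = _is_positive(lb), _is_positive(lc)
        if pb is None or pc is None:
            excluded += 1
        elif pb and pc:
            a += 1
        elif pb:
            b += 1
        elif pc:
            c += 1
        else:
            d += 1
    return ReclassTable(a=a, b=b, c=c, d=d, excluded=excluded)


def detection_rate(table: ReclassTable):
    """Fraction of benchmark-positives the comparator also flags: 100*a/(a+b).

    Returns ``(unrounded_percent, rounded_percent)``; when a + b = 0 the rate
    is undefined and ``(nan, None)`` is returned rather than raising.
    """
    denom = table.a + table.b
    if denom == 0:
        return float("nan"), None
    pct = 100.0 * table.a / denom
    return pct, int(round_half_away(pct))


def fn_fp_rates(table: ReclassTable):
    """False negative and false positive rates: (100*b/n, 100*c/n)."""
    if table.n <= 0:
        raise DataError("fn_fp_rates requires a non-empty table")
    return 100.0 * table.b / table.n, 100.0 * table.c / table.n


def diff_at_p95(model_a, model_b, ages, sex: str, outcome: str = "sbp",
                height_z: float = 0.0) -> pd.DataFrame:
    """Signed (b - a) and absolute 95th-percentile gaps per integer age.

    Height is held at the growth reference's median (z = 0) unless another
    z is supplied.
    """
    rows = []
    for age in ages:
        va = float(model_a.threshold(95, float(age), sex, outcome, height_z=height_z))
        vb = float(model_b.threshold(95, float(age), sex, outcome, height_z=height_z))
        rows.append({"age": int(age), "sex": sex, "outcome": outcome,
                     "value_a": va, "value_b": vb,
                     "signed_diff": vb - va, "abs_diff": abs(vb - va)})
    return pd.DataFrame(rows, columns=["age", "sex", "outcome", "value_a", "value_b",
                                       "signed_diff", "abs_diff"])


@dataclass(frozen=True)
class BlandAltmanStats:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
                "loa_low": self.loa_low, "loa_high": self.loa_high, "n": self.n}


def bland_altman(pairs) -> BlandAltmanStats:
    """Limits of agreement for (benchmark, comparator) value pairs.

    Differences are comparator - benchmark; SD uses the n-1 denominator;
    limits are mean +/- 1.96 SD.  By default the pipeline feeds per-(age,
    sex) 95th-percentile threshold pairs, not per-child percentiles.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DataError("bland_altman requires at least 2 (benchmark, comparator) pairs")
    diffs = arr[:, 1] - arr[:, 0]
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanStats(mean_diff=mean, sd_diff=sd,
                            loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                            n=len(diffs))


def concordance_report(table: ReclassTable, per_sex: dict | None = None,
                       acceptable_detection_pct: float = 85.0) -> dict:
    """Summary combining the 2x2 table with detection / FN / FP rates.

    ``per_sex`` maps sex -> ReclassTable for the stratified breakdown; the
    85% detection bound is a configurable default, not policy.
    """
    raw, rounded = detection_rate(table)
    fn, fp = fn_fp_rates(table)
    report = {
        "table": table.to_dict(),
        "detection_rate_pct": None if rounded is None else round(raw, 2),
        "detection_rate_pct_rounded": rounded,
        "fn_rate_pct": round(fn, 2),
        "fp_rate_pct": round(fp, 2),
        "acceptable_detection_pct": acceptable_detection_pct,
        "threshold_pass": (rounded is not None and raw >= acceptable_detection_pct),
    }
    if per_sex:
        report["per_sex"] = {}
        for sex, t in per_sex.items():
            r_raw, r_round = detection_rate(t)
            report["per_sex"][sex] = {
                "table": t.to_dict(),
                "detection_rate_pct_rounded": r_round,
            }
    return report


def format_reclass_text(name: str, table: ReclassTable) -> str:
    """Human-readable 2x2 layout mirroring a reclassification table."""
    raw, rounded = detection_rate(table)
    det = "n/a" if rounded is None else f"{table.a}/({table.a} + {table.b}) = {rounded}%"
    lines = [
        f"Comparator: {name}",
        f"{'':>24}  comparator >=95th  comparator <95th",
        f"{'benchmark >=95th':>24}  {table.a:>17d}  {table.b:>16d}",
        f"{'benchmark <95th':>24}  {table.c:>17d}  {table.d:>16d}",
        f"Detection at >=95th: {det}",
        f"N = {table.n} (excluded: {table.excluded})",
    ]
    return "\n".join(lines)
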