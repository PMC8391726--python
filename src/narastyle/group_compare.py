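"""K-10 scoring, distress grouping and the two-sample comparison report.

The Kessler Psychological Distress Scale (K-10) sums ten ordinal items
(1-5) into a total of 10-50; respondents at or above the severe-distress
cutoff (default 30, boundary inclusive) form the HIGHER distress group,
the rest the LOWER group.  Every stylometric and emotion metric is then
compared between groups with a two-sample t test.

Two test variants are provided and both are always computable:

* ``welch`` — unequal variances, Satterthwaite degrees of freedom; the
  default, since short-text feature variances routinely differ between
  groups.
* ``pooled`` — classical equal-variance test, df = n1 + n2 - 2.

The sign convention is fixed: t carries the sign of
mean(HIGHER) - mean(LOWER).  A summary-statistic entry point and a
rounding-interval helper support reconciliation against published
reports that print only rounded group means and SDs.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError, ValidationError
from .stylometry import METRIC_ORDER, FeatureVector

#: Default K-10 total marking severe psychological distress (inclusive).
DEFAULT_K10_CUTOFF = 30

TEST_VARIANTS = ("welch", "pooled")


class Group(enum.Enum):
    HIGHER = "higher"
    LOWER = "lower"


@dataclass(frozen=True)
class K10Response:
    """A scored K-10 questionnaire response."""

    items: tuple[int, ...]
    total: int
    group: Group

    @classmethod
    def from_items(
        cls, items: Sequence[int], cutoff: int = DEFAULT_K10_CUTOFF
    ) -> "K10Response":
        total, group = score_k10(items, cutoff=cutoff)
        return cls(items=tuple(int(v) for v in items), total=total, group=group)


def score_k10(
    items: Sequence[int], cutoff: int = DEFAULT_K10_CUTOFF
) -> tuple[int, Group]:
    """Total score and distress group of ten K-10 items.

    HIGHER iff total >= cutoff; a respondent exactly at the cutoff is in
    the higher-distress group.
    """
    items = list(items)
    if len(items) != 10:
        raise ValidationError(f"K-10 requires exactly 10 items, got {len(items)}")
    for v in items:
        if int(v) != v or not (1 <= int(v) <= 5):
            raise ValidationError(f"K-10 item out of range 1..5: {v!r}")
    total = int(sum(int(v) for v in items))
    group = Group.HIGHER if total >= cutoff else Group.LOWER
    return total, group


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float


def two_sample_test_from_summaries(
    n1: int,
    m1: float,
    s1: float,
    n2: int,
    m2: float,
    s2: float,
    variant: str = "welch",
) -> TestResult:
    """Two-sample t test from group sizes, means and (sample) SDs.

    welch: SE^2 = s1^2/n1 + s2^2/n2 with Satterthwaite df; pooled:
    SE^2 = sp^2 (1/n1 + 1/n2) with df = n1 + n2 - 2.  The two-sided p
    comes from the t distribution.  Degenerate case s1 = s2 = 0 with
    m1 = m2 returns t = 0, p = 1.
    """
    if variant not in TEST_VARIANTS:
        raise InvalidInputError(f"variant must be one of {TEST_VARIANTS}")
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    if s1 < 0 or s2 < 0:
        raise InvalidInputError("standard deviations must be non-negative")

    diff = m1 - m2
    v1 = s1 * s1 / n1
    v2 = s2 * s2 / n2
    if variant == "welch":
        se2 = v1 + v2
        if se2 == 0.0:
            df = float(n1 + n2 - 2)
        else:
            df = se2 * se2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)

    if se2 == 0.0:
        if diff == 0.0:
            return TestResult(t=0.0, df=df, p=1.0)
        return TestResult(t=math.copysign(math.inf, diff), df=df, p=0.0)
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(t=t, df=df, p=p)


def two_sample_test(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sample t test on raw observations (x = HIGHER, y = LOWER)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("observations must be finite")
    return two_sample_test_from_summaries(
        x.size, float(x.mean()), float(x.std(ddof=1)),
        y.size, float(y.mean()), float(y.std(ddof=1)),
        variant=variant,
    )


def t_interval_from_rounded_summaries(
    n1: int,
    m1: float,
    s1: float,
    n2: int,
    m2: float,
    s2: float,
    decimals: int = 3,
    variant: str = "pooled",
) -> tuple[float, float]:
    """Range of t statistics consistent with rounded printed summaries.

    A report printing means and SDs to ``decimals`` places hides the
    unrounded values inside a half-width 0.5 * 10**-decimals box.  The t
    statistic is monotone in the mean difference and in each SD, so its
    extrema over the box occur at the corners; the returned closed
    interval is the set of t values any unrounded data consistent with
    the printout could have produced.
    """
    h = 0.5 * 10.0 ** (-decimals)
    ts = []
    for dm1, ds1, dm2, ds2 in itertools.product((-h, h), repeat=4):
        ts.append(
            two_sample_test_from_summaries(
                n1, m1 + dm1, max(s1 + ds1, 0.0),
                n2, m2 + dm2, max(s2 + ds2, 0.0),
                variant=variant,
            ).t
        )
    return min(ts), max(ts)


@dataclass(frozen=True)
class ComparisonRow:
    metric: str
    n_high: int
    mean_high: float
    sd_high: float
    n_low: int
    mean_low: float
    sd_low: float
    t: float
    df: float
    p: float
    test_variant: str
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class ComparisonTable:
    """Per-metric group comparison, one row per implemented metric."""

    rows: tuple[ComparisonRow, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "metric", "n_high", "mean_high", "sd_high",
            "n_low", "mean_low", "sd_low", "t", "df", "p",
        ]
        data = {c: [getattr(r, c) for r in self.rows] for c in cols}
        if any(r.p_adjusted is not None for r in self.rows):
            data["p_bh"] = [r.p_adjusted for r in self.rows]
        return pd.DataFrame(data)

    def row(self, metric: str) -> ComparisonRow:
        for r in self.rows:
            if r.metric == metric:
                return r
        raise KeyError(metric)


def compare_groups(
    features: Sequence[FeatureVector],
    groups: Sequence[Group],
    variant: str = "welch",
    *,
    adjust: bool = False,
    metadata: Optional[dict] = None,
) -> ComparisonTable:
    """Compare every metric between HIGHER and LOWER distress documents.

    Documents with a missing (NaN) value for a metric are dropped from
    that metric's row only; a row left with fewer than two documents in
    either group gets NaN statistics.  ``adjust=True`` adds a
    Benjamini-Hochberg column over the computable rows (the study design
    this mirrors applied no multiplicity correction, so it is off by
    default).
    """
    if variant not in TEST_VARIANTS:
        raise InvalidInputError(f"variant must be one of {TEST_VARIANTS}")
    if len(features) != len(groups):
        raise InvalidInputError("features and groups must align")
    high_idx = [i for i, g in enumerate(groups) if g == Group.HIGHER]
    low_idx = [i for i, g in enumerate(groups) if g == Group.LOWER]
    if not high_idx or not low_idx:
        raise InsufficientDataError("both distress groups must be non-empty")

    table = pd.DataFrame([f.as_dict() for f in features])
    rows: list[ComparisonRow] = []
    for metric in METRIC_ORDER:
        values = table[metric].to_numpy(dtype=float)
        x = values[high_idx]
        y = values[low_idx]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size >= 2 and y.size >= 2:
            res = two_sample_test(x, y, variant=variant)
            rows.append(
                ComparisonRow(
                    metric=metric,
                    n_high=int(x.size),
                    mean_high=float(x.mean()),
                    sd_high=float(x.std(ddof=1)),
                    n_low=int(y.size),
                    mean_low=float(y.mean()),
                    sd_low=float(y.std(ddof=1)),
                    t=res.t, df=res.df, p=res.p,
                    test_variant=variant,
                )
            )
        else:
            rows.append(
                ComparisonRow(
                    metric=metric,
                    n_high=int(x.size),
                    mean_high=float(x.mean()) if x.size else math.nan,
                    sd_high=float(x.std(ddof=1)) if x.size >= 2 else math.nan,
                    n_low=int(y.size),
                    mean_low=float(y.mean()) if y.size else math.nan,
                    sd_low=float(y.std(ddof=1)) if y.size >= 2 else math.nan,
                    t=math.nan, df=math.nan, p=math.nan,
                    test_variant=variant,
                )
            )

    if adjust:
        idx = [i for i, r in enumerate(rows) if math.isfinite(r.p)]
        if idx:
            adjusted = stats.false_discovery_control(
                [rows[i].p for i in idx], method="bh"
            )
            for i, padj in zip(idx, adjusted):
                r = rows[i]
                rows[i] = ComparisonRow(
                    **{**r.__dict__, "p_adjusted": float(padj)}
                )

    meta = dict(metadata or {})
    meta.setdefault("test_variant", variant)
    return ComparisonTable(rows=tuple(rows), metadata=meta)
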