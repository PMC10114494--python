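"""Metrics, uncertainty quantification and risk analysis.

Every other module reports its results through the functions here: Spearman
rank correlation and RMSE between predicted and reader-assessed density
scores, percentile-bootstrap confidence intervals, the two reader-level
aggregates (Av1: mean of per-reader metrics with its across-reader SD;
Av2: the metric recomputed on all pooled image/score pairs), and the
case-control top-vs-bottom density-quintile odds ratio.

Conventions
-----------
* A metric that is undefined on its input (e.g. Spearman on a constant
  vector) returns ``nan`` — an explicit "undefined" marker, never a silent 0.
* Bootstrap intervals are percentile intervals over resampled image-level
  pairs, deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricEntry",
    "MetricsReport",
    "OddsRatioResult",
    "spearman",
    "rmse",
    "bootstrap_ci",
    "aggregate_reader_metrics",
    "quintile_odds_ratio",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric cannot be computed even after bootstrap retries."""


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass
class MetricEntry:
    """One named metric value with optional CI and context tags."""

    name: str
    value: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("metric entry requires n > 0")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"value {self.value} for {self.name}"
                )


@dataclass
class MetricsReport:
    """A collection of metric entries, convertible to a tidy DataFrame."""

    entries: list[MetricEntry] = field(default_factory=list)

    def add(self, name: str, value: float, ci: tuple[float, float] | None = None,
            n: int = 1, **context) -> None:
        lo, hi = ci if ci is not None else (math.nan, math.nan)
        self.entries.append(MetricEntry(name, value, lo, hi, n, context))

    def __getitem__(self, name: str) -> MetricEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"metric": e.name, "value": e.value, "ci_low": e.ci_low,
                   "ci_high": e.ci_high, "n": e.n}
            row.update(e.context)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns ``nan`` when either vector is constant (the coefficient is
    undefined there — callers must handle the marker explicitly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("spearman expects two equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(stats.spearmanr(a, b).statistic)


def rmse(a: Sequence[float], b: Sequence[float]) -> float:
    """Root mean squared difference between two aligned vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("rmse expects two equal-length non-empty 1-D vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(a, b)`` over paired resamples.

    Pairs ``(a_i, b_i)`` are resampled with replacement ``n_boot`` times and
    the metric recomputed on each resample; the interval is the central
    ``level`` percent of the resulting distribution.  Resamples on which the
    metric is undefined (``nan``) are redrawn, up to ``max_retries`` extra
    draws in total; exceeding the cap raises :class:`UndefinedMetricError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("bootstrap_ci needs >= 2 aligned pairs")
    rng = np.random.default_rng(seed)
    n = a.size
    values = np.empty(n_boot)
    retries = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        v = metric(a[idx], b[idx])
        if np.isnan(v):
            retries += 1
            if retries > max_retries:
                raise UndefinedMetricError(
                    "metric undefined on too many bootstrap resamples")
            continue
        values[i] = v
        i += 1
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Reader-level aggregation
# ---------------------------------------------------------------------------

def aggregate_reader_metrics(
    per_reader: Sequence[tuple[str, float, int]],
    pooled_pairs: tuple[Sequence[float], Sequence[float]],
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Compute the two reader-level aggregates of a metric.

    ``Av1`` is the unweighted mean of the per-reader metric values; its
    uncertainty is the standard deviation across readers (sample SD, 0 for a
    single reader).  ``Av2`` recomputes the metric on the concatenation of all
    per-reader prediction/label pairs (which repeats images scored by more
    than one reader) with a bootstrap CI.  The two deliberately differ in
    general: Av2 is *not* the weighted mean of the per-reader metrics.

    Parameters
    ----------
    per_reader : sequence of (reader_id, metric_value, n)
    pooled_pairs : (predictions, labels) concatenated over all readers
    metric : the metric function to recompute on the pooled pairs
    """
    if len(per_reader) == 0:
        raise ValueError("aggregate_reader_metrics requires >= 1 reader")
    values = np.array([v for _, v, _ in per_reader], dtype=float)
    av1 = float(np.mean(values))
    av1_sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    a, b = (np.asarray(x, dtype=float) for x in pooled_pairs)
    av2 = float(metric(a, b))
    av2_ci = bootstrap_ci(metric, a, b, n_boot=n_boot, seed=seed)
    return {
        "av1": av1,
        "av1_sd": av1_sd,
        "av2": av2,
        "av2_ci": av2_ci,
        "n_readers": len(per_reader),
        "n_pooled": int(a.size),
    }


# ---------------------------------------------------------------------------
# Case-control quintile odds ratio
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool           # Haldane-Anscombe 0.5 added to all cells
    cells: dict               # cases/controls in top and bottom quintile


def quintile_odds_ratio(
    subject_scores: Sequence[float],
    case_flags: Sequence[bool],
    level: float = 95.0,
) -> OddsRatioResult:
    """Top-vs-bottom density-quintile odds ratio for case status.

    Quintile boundaries are taken from the *control* score distribution (the
    usual case-control convention, so that the reference population defines
    the exposure bands).  The odds ratio is

        OR = (cases_top / controls_top) / (cases_bottom / controls_bottom)

    with a normal-approximation CI on the log scale.  If any cell is zero the
    Haldane-Anscombe correction (add 0.5 to every cell) is applied and
    flagged in the result.
    """
    scores = np.asarray(subject_scores, dtype=float)
    flags = np.asarray(case_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and case flags must align")
    if not flags.any() or flags.all():
        raise ValueError("need both cases and controls")
    controls = scores[~flags]
    if np.unique(controls).size < 5:
        raise ValueError("degenerate control score distribution: "
                         "fewer than 5 distinct values")
    edges = np.percentile(controls, [20, 40, 60, 80])
    quintile = np.digitize(scores, edges)  # 0 = bottom, 4 = top
    top, bottom = quintile == 4, quintile == 0
    a = float(np.sum(flags & top))        # cases, top quintile
    b = float(np.sum(~flags & top))       # controls, top quintile
    c = float(np.sum(flags & bottom))     # cases, bottom quintile
    d = float(np.sum(~flags & bottom))    # controls, bottom quintile
    if min(b, d) == 0 and min(a, c) == 0:
        raise ValueError("no subjects in an extreme quintile")
    corrected = any(x == 0 for x in (a, b, c, d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - level / 100.0) / 2)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return OddsRatioResult(or_, lo, hi, corrected,
                           {"cases_top": a, "controls_top": b,
                            "cases_bottom": c, "controls_bottom": d})


# ---------------------------------------------------------------------------
# Standard two-metric report used across modules
# ---------------------------------------------------------------------------

def score_report(
    predictions: Sequence[float],
    labels: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    **context,
) -> MetricsReport:
    """Spearman + RMSE with bootstrap CIs — the report every module emits."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    report = MetricsReport()
    rc = spearman(predictions, labels)
    if np.isnan(rc):
        # constant input: record the undefined marker without a CI
        report.entries.append(MetricEntry("rank_corr", math.nan,
                                          n=predictions.size, context=context))
    else:
        lo, hi = bootstrap_ci(spearman, predictions, labels,
                              n_boot=n_boot, seed=seed)
        # percentile intervals can (rarely) fall just past the point estimate
        report.add("rank_corr", rc, ci=(min(lo, rc), max(hi, rc)),
                   n=predictions.size, **context)
    err = rmse(predictions, labels)
    lo, hi = bootstrap_ci(rmse, predictions, labels, n_boot=n_boot, seed=seed + 1)
    report.add("rmse", err, ci=(min(lo, err), max(hi, err)),
               n=predictions.size, **context)
    return report
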