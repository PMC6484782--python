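"""Aggregation-threshold statistics.

The central object is a hard threshold classifier ``f(x)``: a cell image
with normalized fluorescence ``x`` is labeled "aggregation" when
``x >= l`` and "no aggregation" otherwise.  The threshold ``l`` is fitted
by maximizing the prediction accuracy ``ACC = (TP + TN) / N`` over the
labeled single-cell dataset, with an exhaustive scan of every decision
boundary (midpoints between consecutive sorted unique fluorescence
values, plus the two degenerate all-one-class classifiers) — exact and
deterministic on this one-dimensional problem.  A bootstrap permutation
null quantifies the accuracy a random labeling would achieve with the
same fixed threshold.

The module also carries the companion single-cell statistics: the
aggregation delay (time spent within 1 normalized unit below the
threshold before inclusions appear), cell-cycle durations split at the
aggregation time point, the CV of fluorescence at aggregation, Student's
t test and the boxplot outlier rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import CellTrace

__all__ = ["AggregationDataset", "ClassifierFit", "classify", "fit_threshold",
           "bootstrap_random_accuracy", "make_dataset", "aggregation_delay",
           "cycle_durations", "aggregation_cv", "two_sample_t_test",
           "boxplot_outlier_filter", "NO_AGGREGATION", "AGGREGATION"]

NO_AGGREGATION = 0
AGGREGATION = 1


@dataclass
class AggregationDataset:
    """Labeled per-cell-per-time-point fluorescence levels."""

    x: np.ndarray          # normalized fluorescence
    y: np.ndarray          # 0 = no_aggregation, 1 = aggregation
    cell_id: np.ndarray
    time: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.cell_id = np.asarray(self.cell_id)
        self.time = np.asarray(self.time, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.cell_id) == len(self.time)):
            raise ValueError("dataset columns must have equal length")
        if len(self.x) and not np.all(np.isfinite(self.x)):
            raise ValueError("fluorescence levels must be finite")
        if len(self.y) and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class ClassifierFit:
    l: float               # fitted threshold, normalized units
    acc: float
    tp: int
    tn: int
    n: int


def classify(x, l: float):
    """Hard threshold rule: aggregation iff ``x >= l`` (boundary inclusive)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= l, AGGREGATION, NO_AGGREGATION)
    return out if out.ndim else int(out)


def make_dataset(traces: list[CellTrace]) -> AggregationDataset:
    """Label trace samples by the aggregation time point: every sample at
    ``t >= tA`` is "aggregation"; samples before tA — and every sample of a
    cell that never aggregated — are "no aggregation"."""
    xs, ys, cids, ts = [], [], [], []
    for tr in traces:
        ta = tr.aggregation_time
        for t, v in zip(tr.times, tr.gfp_norm):
            xs.append(v)
            ys.append(AGGREGATION if ta is not None and t >= ta else NO_AGGREGATION)
            cids.append(tr.cell_id)
            ts.append(t)
    return AggregationDataset(np.array(xs), np.array(ys), np.array(cids), np.array(ts))


def fit_threshold(dataset: AggregationDataset) -> ClassifierFit:
    """Accuracy-maximizing threshold by exhaustive scan.

    Candidates are -inf (everything labeled aggregation), the midpoints
    between consecutive sorted unique fluorescence values, and +inf
    (everything labeled no-aggregation).  Ties are broken by the smallest
    candidate threshold.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    order = np.argsort(dataset.x, kind="stable")
    x = dataset.x[order]
    y = dataset.y[order]
    n = len(x)
    uniq = np.unique(x)
    cands = np.concatenate(([-np.inf], (uniq[1:] + uniq[:-1]) / 2.0, [np.inf]))
    # for threshold l: predictions are "aggregation" for x >= l.
    # split index s = first position with x >= l  ->  TN = sum(y[:s] == 0),
    # TP = sum(y[s:] == 1); both from cumulative sums of the sorted labels.
    cum_pos = np.concatenate(([0], np.cumsum(y)))          # positives among x < l
    total_pos = cum_pos[-1]
    splits = np.searchsorted(x, cands, side="left")
    tn = splits - cum_pos[splits]
    tp = total_pos - cum_pos[splits]
    acc = (tp + tn) / n
    best = int(np.argmax(acc))          # argmax returns the first (smallest) maximizer
    return ClassifierFit(l=float(cands[best]), acc=float(acc[best]),
                         tp=int(tp[best]), tn=int(tn[best]), n=n)


def bootstrap_random_accuracy(dataset: AggregationDataset, fit: ClassifierFit,
                              n_resamples: int = 10_000, seed: int = 0) -> float:
    """Mean accuracy of the fitted threshold on label-permuted datasets.

    Each resample permutes the class labels uniformly across data points
    and is scored with the FIXED fitted threshold (no re-fitting).  Under
    a uniform permutation the number of "aggregation" labels that land on
    predicted-aggregation points is exactly hypergeometric, so that count
    is sampled directly — one draw per resample, identical in law to
    materializing the permuted dataset.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    n_pos = int(dataset.y.sum())                    # aggregation labels
    n_flag = int(np.sum(dataset.x >= fit.l))        # predicted aggregation
    m = rng.hypergeometric(n_pos, n - n_pos, n_flag, size=n_resamples)
    acc = (2.0 * m + n - n_flag - n_pos) / n
    return float(acc.mean())


def aggregation_delay(trace: CellTrace) -> float:
    """Minutes before tA during which fluorescence stayed within 1
    normalized unit below the level reached at the aggregation time point."""
    if trace.aggregation_time is None:
        raise ValueError("trace has no aggregation time point")
    times = np.asarray(trace.times)
    values = np.asarray(trace.gfp_norm)
    i_a = int(np.argmin(np.abs(times - trace.aggregation_time)))
    threshold = values[i_a]
    j = i_a
    while j > 0 and values[j - 1] >= threshold - 1.0:
        j -= 1
    return float(times[i_a] - times[j])


def cycle_durations(trace: CellTrace) -> tuple[list[float], list[float]]:
    """Bud-to-bud cell-cycle durations, split at the aggregation time.

    Intervals ending at or before tA count as "before"; intervals that end
    after tA (including those straddling it) count as "after".  Fewer than
    two bud events yields two empty lists.
    """
    buds = sorted(trace.bud_events)
    if len(buds) < 2:
        return [], []
    ta = trace.aggregation_time
    before, after = [], []
    for t0, t1 in zip(buds[:-1], buds[1:]):
        (before if ta is None or t1 <= ta else after).append(t1 - t0)
    return before, after


def aggregation_cv(values) -> float:
    """Sample coefficient of variation (SD with n-1 over mean)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(values.std(ddof=1) / mean)


def two_sample_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t test (pooled variance; Welch behind a flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if math.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def boxplot_outlier_filter(values) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolated
    quartiles).  With fewer than 4 values the input is returned unchanged
    with a warning."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values: boxplot rule not applied", stacklevel=2)
        return values
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]
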