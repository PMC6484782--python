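"""Single-cell and population analysis of inclusion clearance.

After the galactose-to-glucose switch, per-cell fluorescence stays flat
until the cell buds again; thereafter each division dilutes it.  The
quantities measured per cell are the time to first bud (TFB), the mean
fluorescence over [0, TFB], the cell-cycle durations, and the percentage
drop of fluorescence across each budded phase.  A one-parameter dilution
model — a fixed fractional drop at every division, 38% as derived from
the 0.61 daughter/mother size ratio of asymmetric budding division —
predicts the fluorescence at each division; its error is the elementwise
percentage difference.  Population-level readouts are the pointwise mean
trace with its half-time t_1/2, Conover-Iman rank-sum multiple
comparisons across treatments, and the Pearson correlation between TFB
and the inclusion-disappearance time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traces import CellTrace

__all__ = ["ClearanceRecord", "time_to_first_bud", "mean_fluor_before_tfb",
           "drop_at_division", "dilution_model_predict", "derive_shed_fraction",
           "model_prediction_error", "population_average", "conover_iman",
           "tfb_clearance_correlation", "analyze_clearance_trace"]


@dataclass
class ClearanceRecord:
    cell_id: int
    treatment: str
    tfb: float                      # min
    tfb_censored: bool
    mean_fluor_tfb: float           # clearance-normalized, starts ~1
    cycle_durations: list[float] = field(default_factory=list)
    drops_at_division: list[float] = field(default_factory=list)   # %
    clearance_time: float | None = None
    predicted_divisions: list[float] = field(default_factory=list)


def time_to_first_bud(trace: CellTrace, duration: float | None = None,
                      ) -> tuple[float, bool]:
    """(TFB, censored): time of the first bud event, or the experiment
    duration with the censored flag when the cell never budded."""
    if trace.bud_events:
        return float(min(trace.bud_events)), False
    if duration is None:
        duration = trace.times[-1] if trace.times else 0.0
    return float(duration), True


def mean_fluor_before_tfb(trace: CellTrace, tfb: float) -> float:
    """Mean clearance-normalized fluorescence over samples in [0, tfb]."""
    times = np.asarray(trace.times)
    values = np.asarray(trace.gfp_norm)
    sel = times <= tfb
    if not sel.any():
        raise ValueError("no samples before the time to first bud")
    return float(values[sel].mean())


def drop_at_division(trace: CellTrace) -> list[float]:
    """Percentage fluorescence decrease across each budded phase.

    Uses the boundary samples: the last sample at/before the bud event
    (fluorescence at the start of the budded phase) and the first sample
    at/after the division (phase end, after the dilution has been
    realized).  Phases with nonpositive starting fluorescence are skipped
    with a warning; phases whose division falls beyond the trace are
    ignored.
    """
    times = np.asarray(trace.times)
    values = np.asarray(trace.gfp_norm)
    drops = []
    divisions = sorted(trace.division_events)
    for b in sorted(trace.bud_events):
        later = [d for d in divisions if d > b]
        if not later:
            continue
        d = later[0]
        i0 = max(0, int(np.searchsorted(times, b, side="right")) - 1)
        i1 = int(np.searchsorted(times, d, side="left"))
        if i1 >= len(times):
            continue
        f_start, f_end = values[i0], values[i1]
        if f_start <= 0:
            warnings.warn("nonpositive fluorescence at budded-phase start; "
                          "phase skipped", stacklevel=2)
            continue
        drops.append(float(100.0 * (f_start - f_end) / f_start))
    return drops


def dilution_model_predict(f0: float, n_divisions: int,
                           shed: float = 0.38) -> list[float]:
    """Predicted fluorescence after each of ``n_divisions`` divisions:
    ``f0 * (1 - shed)**i`` for i = 1..n."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if not 0.0 < shed < 1.0:
        raise ValueError("shed fraction must lie in (0, 1)")
    return [f0 * (1.0 - shed) ** i for i in range(1, n_divisions + 1)]


def derive_shed_fraction(daughter_ratio: float = 0.61) -> float:
    """Percentage of fluorescence lost at division implied by the
    daughter/mother size ratio r: 100 * r / (1 + r) (38% for r = 0.61,
    assuming the mother's mass is constant during the budded phase)."""
    if daughter_ratio <= 0:
        raise ValueError("daughter_ratio must be positive")
    return 100.0 * daughter_ratio / (1.0 + daughter_ratio)


def model_prediction_error(measured, predicted) -> np.ndarray:
    """Elementwise percentage difference 100 * (measured - predicted) /
    predicted between observed and model-predicted division fluorescence."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have equal length")
    if np.any(predicted <= 0):
        raise ValueError("predicted values must be positive")
    return 100.0 * (measured - predicted) / predicted


def population_average(traces: list[CellTrace],
                       ) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Pointwise mean trace and half-time t_1/2.

    Only cells present from the beginning to the end of the experiment are
    averaged (all traces must share the full sampling grid).  t_1/2 is the
    first time the mean falls to half its initial value, linearly
    interpolated between samples; ``None`` if never reached.
    """
    if not traces:
        raise ValueError("need at least one full-length trace")
    n_max = max(len(tr) for tr in traces)
    full = [tr for tr in traces if len(tr) == n_max]
    times = np.asarray(full[0].times)
    mean = np.mean([tr.gfp_norm for tr in full], axis=0)
    target = 0.5 * mean[0]
    below = np.nonzero(mean <= target)[0]
    if len(below) == 0:
        return times, mean, None
    i = int(below[0])
    if i == 0:
        return times, mean, float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = mean[i - 1], mean[i]
    t_half = t0 + (v0 - target) / (v0 - v1) * (t1 - t0)
    return times, mean, float(t_half)


def conover_iman(groups: list, adjust: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Conover-Iman multiple comparisons using rank sums.

    Ranks are shared across all groups (Kruskal-Wallis ranking, midranks
    for ties); the pairwise statistic is
    ``t = (Rbar_i - Rbar_j) / sqrt(S2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    with ``S2 = (sum r^2 - N (N+1)^2 / 4) / (N - 1)`` and H the (tie
    corrected) Kruskal-Wallis statistic; p-values are two-sided Student's
    t with N - k degrees of freedom, unadjusted by default
    (``adjust="bonferroni"`` multiplies by the number of pairs).

    Returns (t matrix, p matrix); the p matrix is symmetric with unit
    diagonal.  If every value is identical all p-values are 1.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.ptp(pooled) == 0:
        return np.zeros((k, k)), np.ones((k, k))
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    rbar = np.array([ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)])
    H = float(stats.kruskal(*groups).statistic)
    S2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    df = N - k
    scale = S2 * (N - 1 - H) / df
    scale = max(scale, 1e-12)
    t = np.zeros((k, k))
    p = np.ones((k, k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            tij = (rbar[i] - rbar[j]) / se
            pij = 2.0 * stats.t.sf(abs(tij), df)
            if adjust == "bonferroni":
                pij = min(1.0, pij * n_pairs)
            t[i, j], t[j, i] = tij, -tij
            p[i, j] = p[j, i] = pij
    return t, p


def tfb_clearance_correlation(records: list[ClearanceRecord],
                              ) -> tuple[float, float]:
    """Pearson correlation between TFB and inclusion-disappearance time
    (censored TFBs and cells without a disappearance time are excluded)."""
    pairs = [(r.tfb, r.clearance_time) for r in records
             if not r.tfb_censored and r.clearance_time is not None]
    if len(pairs) < 3:
        raise ValueError("need at least 3 uncensored paired records")
    tfb, ct = map(np.asarray, zip(*pairs))
    if np.ptp(tfb) == 0 or np.ptp(ct) == 0:
        raise ValueError("zero variance in TFB or clearance time")
    r, p = stats.pearsonr(tfb, ct)
    return float(r), float(p)


def analyze_clearance_trace(trace: CellTrace, treatment: str,
                            duration: float | None = None,
                            shed: float = 0.38) -> ClearanceRecord:
    """Compose the per-cell clearance readouts into one record."""
    tfb, censored = time_to_first_bud(trace, duration)
    mean_f = mean_fluor_before_tfb(trace, tfb)
    buds = sorted(trace.bud_events)
    cycles = [t1 - t0 for t0, t1 in zip(buds[:-1], buds[1:])]
    drops = drop_at_division(trace)
    predicted = dilution_model_predict(mean_f, len(trace.division_events), shed)
    return ClearanceRecord(
        cell_id=trace.cell_id, treatment=treatment, tfb=tfb,
        tfb_censored=censored, mean_fluor_tfb=mean_f,
        cycle_durations=cycles, drops_at_division=drops,
        clearance_time=trace.clearance_time, predicted_divisions=predicted)
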