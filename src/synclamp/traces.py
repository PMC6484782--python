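"""Single-cell trace container and tidy-CSV round trip.

A :class:`CellTrace` is one cell's time series of normalized GFP
fluorescence sampled every ``T`` minutes, together with its budding /
division events, the aggregation time point ``tA`` (first time inclusions
are visible) when present, and how the trace ended (experiment end or the
cell being pushed out of the field of view).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["cell_id", "parent_id", "time_min", "gfp_norm", "mcherry", "phase", "event"]


@dataclass
class CellTrace:
    cell_id: int
    parent_id: int | None = None
    times: list[float] = field(default_factory=list)       # min, strictly increasing
    gfp_norm: list[float] = field(default_factory=list)    # normalized units
    mcherry: list[float] = field(default_factory=list)     # a.u.
    phases: list[str] = field(default_factory=list)        # "unbudded" | "budded"
    bud_events: list[float] = field(default_factory=list)
    division_events: list[float] = field(default_factory=list)
    aggregation_time: float | None = None
    clearance_time: float | None = None      # inclusion-disappearance time (clearance runs)
    end_reason: str = "experiment_end"       # or "left_fov"

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        """Duration covered by the trace in minutes (0 for < 2 samples)."""
        return self.times[-1] - self.times[0] if len(self.times) >= 2 else 0.0

    def value_at(self, t: float) -> float:
        """gfp_norm at the sample closest to time ``t``."""
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        return self.gfp_norm[i]


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Flatten traces into the tidy table (one row per cell per time point).

    The ``event`` column marks bud/division/aggregation events at the sample
    whose time matches the event time (events between samples are attached
    to the following sample; coincident events are ';'-joined).
    """
    rows = []
    for tr in traces:
        events: list[tuple[float, str]] = (
            [(t, "bud") for t in tr.bud_events]
            + [(t, "division") for t in tr.division_events]
            + ([(tr.aggregation_time, "aggregation")]
               if tr.aggregation_time is not None else []))
        events.sort()
        for i, t in enumerate(tr.times):
            prev_t = tr.times[i - 1] if i > 0 else -math.inf
            here = [name for et, name in events if prev_t < et <= t]
            label = ";".join(here) if here else "none"
            rows.append((tr.cell_id, -1 if tr.parent_id is None else tr.parent_id,
                         t, tr.gfp_norm[i], tr.mcherry[i] if tr.mcherry else float("nan"),
                         tr.phases[i] if tr.phases else "unbudded", label))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_traces(traces: list[CellTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[CellTrace]:
    """Rebuild traces from the tidy CSV (events recovered from the event column)."""
    df = pd.read_csv(path)
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        pid = int(g["parent_id"].iloc[0])
        tr = CellTrace(cell_id=int(cid), parent_id=None if pid < 0 else pid)
        tr.times = g["time_min"].astype(float).tolist()
        tr.gfp_norm = g["gfp_norm"].astype(float).tolist()
        tr.mcherry = g["mcherry"].astype(float).tolist()
        tr.phases = g["phase"].astype(str).tolist()
        for t, ev in zip(tr.times, g["event"]):
            for name in str(ev).split(";"):
                if name == "bud":
                    tr.bud_events.append(t)
                elif name == "division":
                    tr.division_events.append(t)
                elif name == "aggregation":
                    tr.aggregation_time = t
        out.append(tr)
    return out
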