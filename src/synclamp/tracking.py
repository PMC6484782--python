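"""Frame-to-frame identity assignment, lineage and trace filtering.

Cell identities are propagated between consecutive frames by solving the
optimal linear assignment that minimizes total centroid displacement
(Hungarian algorithm on a padded cost matrix whose pad cost acts as the
gating distance).  Births are new centroids left unmatched; losses are
previous centroids left unmatched (cells pushed out of the field of
view).  Lineage assigns each birth the nearest tracked cell as mother.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .traces import CellTrace

__all__ = ["Assignment", "Track", "link_frames", "track_movie",
           "build_lineage", "filter_traces", "MIN_LEVEL"]

#: strain-dependent minimum expression level for trace selection (n.u.)
MIN_LEVEL = {"WT": 16.0, "A53T": 10.0, "A53T_dpdr5": 10.0}


@dataclass
class Assignment:
    pairs: list[tuple[int, int]]   # (index in prev, index in curr)
    births: list[int]              # indices in curr with no predecessor
    losses: list[int]              # indices in prev with no successor


def link_frames(prev, curr, max_disp: float = 20.0) -> Assignment:
    """Minimum-total-displacement one-to-one matching of two centroid sets.

    Any pairing farther than ``max_disp`` is broken: the padded square cost
    matrix offers every centroid an unmatched option at cost ``max_disp``,
    so a link is only made when it is cheaper than declaring a loss plus a
    birth.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    prev = np.asarray(prev, dtype=float).reshape(-1, 2)
    curr = np.asarray(curr, dtype=float).reshape(-1, 2)
    n_p, n_c = len(prev), len(curr)
    if n_p == 0 or n_c == 0:
        return Assignment([], list(range(n_c)), list(range(n_p)))
    big = 1e9
    size = n_p + n_c
    cost = np.zeros((size, size))
    d = cdist(prev, curr)
    cost[:n_p, :n_c] = np.where(d <= max_disp, d, big)
    cost[:n_p, n_c:] = big
    cost[n_p:, :n_c] = big
    cost[:n_p, n_c:][np.arange(n_p), np.arange(n_p)] = max_disp  # prev -> lost
    cost[n_p:, :n_c][np.arange(n_c), np.arange(n_c)] = max_disp  # birth -> curr
    rows, cols = linear_sum_assignment(cost)
    pairs, births, losses = [], [], []
    for i, j in zip(rows, cols):
        if i < n_p and j < n_c and d[i, j] <= max_disp:
            pairs.append((int(i), int(j)))
        elif i < n_p and j >= n_c:
            losses.append(int(i))
        elif i >= n_p and j < n_c:
            births.append(int(j))
    return Assignment(pairs, sorted(births), sorted(losses))


@dataclass
class Track:
    track_id: int
    start_frame: int
    positions: list[tuple[float, float]] = field(default_factory=list)
    end_frame: int | None = None   # frame after which the track was lost

    def position_at(self, frame: int) -> tuple[float, float] | None:
        i = frame - self.start_frame
        if 0 <= i < len(self.positions):
            return self.positions[i]
        return None


def track_movie(frames_centroids: list, max_disp: float = 20.0) -> list[Track]:
    """Chain link_frames over a movie into tracks (ids assigned at birth)."""
    tracks: list[Track] = []
    active: dict[int, Track] = {}
    for f, cents in enumerate(frames_centroids):
        cents = np.asarray(cents, dtype=float).reshape(-1, 2)
        if f == 0:
            for j, c in enumerate(cents):
                t = Track(track_id=j, start_frame=0, positions=[tuple(c)])
                tracks.append(t)
                active[j] = t
            continue
        prev_ids = sorted(active)
        prev_pos = [active[i].positions[-1] for i in prev_ids]
        asg = link_frames(prev_pos, cents, max_disp)
        matched_curr = set()
        for i, j in asg.pairs:
            active[prev_ids[i]].positions.append(tuple(cents[j]))
            matched_curr.add(j)
        for i in asg.losses:
            active[prev_ids[i]].end_frame = f - 1
            del active[prev_ids[i]]
        for j in asg.births:
            t = Track(track_id=len(tracks), start_frame=f, positions=[tuple(cents[j])])
            tracks.append(t)
            active[t.track_id] = t
    return tracks


def build_lineage(tracks: list[Track], max_mother_dist: float = 30.0,
                  ) -> dict[int, int | None]:
    """Mother assignment for every track: nearest already-tracked cell at
    the birth frame, within ``max_mother_dist``; ties broken by the lower
    track id.  Tracks present from frame 0, or births with no candidate in
    range, get ``None`` (unknown parent).  The result is a forest."""
    parents: dict[int, int | None] = {}
    for t in tracks:
        if t.start_frame == 0:
            parents[t.track_id] = None
            continue
        bx, by = t.positions[0]
        best: tuple[float, int] | None = None
        for other in tracks:
            # only cells already present before the birth frame can be mothers
            if other.track_id == t.track_id or other.start_frame >= t.start_frame:
                continue
            pos = other.position_at(t.start_frame)
            if pos is None:
                continue
            dist = float(np.hypot(pos[0] - bx, pos[1] - by))
            if dist <= max_mother_dist:
                key = (dist, other.track_id)
                if best is None or key < best:
                    best = key
        parents[t.track_id] = best[1] if best is not None else None
    return parents


def filter_traces(traces: list[CellTrace], min_duration: float = 500.0,
                  min_level: float = 16.0) -> list[CellTrace]:
    """Trace selection used for the single-cell aggregation datasets.

    Keeps traces spanning strictly more than ``min_duration`` minutes whose
    peak normalized fluorescence reaches ``min_level`` (16 n.u. for the WT
    strain, 10 n.u. for the A53T mutant).
    """
    if min_duration <= 0:
        raise ValueError("min_duration must be > 0")
    kept = []
    for tr in traces:
        if tr.span > min_duration and len(tr.gfp_norm) and max(tr.gfp_norm) >= min_level:
            kept.append(tr)
    return kept
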