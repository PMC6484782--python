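"""Stochastic simulator of a budding-yeast population expressing an
inducible aggregation-prone protein.

The plant stands in for cells + microfluidic chamber + microscope in the
closed control loop.  Per-cell dynamics are deliberately simple:

* ``gfp`` is the cell's total fluorescence content; production is linear
  in the galactose fraction ``u`` (``production_rate_gal * u +
  basal_rate``), scales with cell volume, and is multiplied by a static
  per-cell lognormal extrinsic-noise factor; loss is first order
  (``maturation_or_decay_rate``) with the exact exponential update of the
  linear ODE over each internal step;
* the *measured* normalized fluorescence is the concentration
  ``gfp / volume_proxy``.  The volume proxy grows from 1 to
  ``1 / (1 - shed)`` (1.61 for the default 38% shed fraction) across the
  budded phase — the 0.61 daughter/mother size ratio of asymmetric
  budding division — so with production off the measured signal falls by
  the shed fraction across each budded phase (division dilution), while
  under active production it stays smooth through divisions;
* at division the mother sheds ``division_shed_fraction`` of its
  fluorescence content to the daughter (total content conserved exactly)
  and both return to concentration-matched volumes (mother 1, daughter
  0.61);
* a cell forms inclusions ("aggregates") once its measured normalized
  fluorescence has stayed at or above its own sampled threshold for a
  sampled delay; aggregation switches the cycle mean to the slower
  post-aggregation value and arrests a small fraction of cells.

Cells grow in a monolayer chamber of finite capacity: mothers are
trapped, daughters join the population only while there is room and are
otherwise pushed out of the field of view at birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import PlantParams, TREATMENTS
from .traces import CellTrace

__all__ = [
    "CellState", "InputSchedule", "Population",
    "step_cell", "apply_division", "simulate_population", "simulate_clearance",
]


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw parameterized by its arithmetic mean and CV."""
    if cv <= 0.0:
        return mean
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(math.log(mean) - 0.5 * s2, math.sqrt(s2)))


@dataclass
class CellState:
    """State of one simulated cell (fluorescence in normalized units)."""

    cell_id: int
    parent_id: int | None = None
    birth_time: float = 0.0
    gfp: float = 0.0
    mcherry: float = 100.0
    volume_proxy: float = 1.0
    phase: str = "unbudded"
    cycle_clock: float = 0.0
    cycle_duration: float = 110.0
    per_cell_threshold: float = math.inf
    aggregated: bool = False
    aggregation_time: float | None = None
    position: tuple[float, float] = (0.0, 0.0)
    radius: float = 8.0
    # internal bookkeeping
    prod_factor: float = 1.0      # extrinsic noise: static production multiplier
    agg_delay: float = 0.0        # sampled time-above-threshold before aggregation
    time_above: float = 0.0
    arrested: bool = False
    clock_abs: float = 0.0        # absolute simulation time of this cell

    def __post_init__(self) -> None:
        if self.gfp < 0:
            raise ValueError("gfp must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.aggregated and self.aggregation_time is None:
            raise ValueError("aggregated cell must carry an aggregation_time")

    @property
    def concentration(self) -> float:
        """Measured normalized fluorescence: content per unit volume."""
        return self.gfp / self.volume_proxy


def _sample_cycle(params: PlantParams, rng: np.random.Generator, post: bool,
                  factor: float = 1.0) -> float:
    mean = (params.cycle_mean_post if post else params.cycle_mean_pre) * factor
    return max(20.0, float(rng.normal(mean, params.cycle_sd)))


def new_cell(params: PlantParams, rng: np.random.Generator, cell_id: int,
             parent_id: int | None = None, birth_time: float = 0.0,
             gfp: float = 0.0, position: tuple[float, float] | None = None,
             arena: tuple[int, int] = (256, 256)) -> CellState:
    """Sample a fresh cell: its own threshold, extrinsic factor, delay, cycle."""
    if position is None:
        margin = 20.0
        position = (float(rng.uniform(margin, arena[1] - margin)),
                    float(rng.uniform(margin, arena[0] - margin)))
    delay = (float(rng.exponential(params.aggregation_delay_mean))
             if params.aggregation_delay_mean > 0 else 0.0)
    return CellState(
        cell_id=cell_id, parent_id=parent_id, birth_time=birth_time, gfp=gfp,
        mcherry=_lognormal(rng, params.mcherry_mean, params.extrinsic_noise_cv),
        cycle_duration=_sample_cycle(params, rng, post=False),
        per_cell_threshold=_lognormal(rng, params.threshold_mean, params.threshold_cv),
        position=position, radius=float(rng.uniform(6.0, 10.0)),
        prod_factor=_lognormal(rng, 1.0, params.extrinsic_noise_cv),
        agg_delay=delay, clock_abs=birth_time,
    )


def step_cell(cell: CellState, u: float, dt: float, params: PlantParams,
              rng: np.random.Generator) -> tuple[CellState, list[str]]:
    """Advance one cell by ``dt`` minutes under galactose fraction ``u``.

    Returns the (mutated) cell and the events raised during the step:
    ``"bud"``, ``"aggregation"`` and/or ``"division_due"`` (the caller is
    responsible for actually dividing via :func:`apply_division`).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    events: list[str] = []

    p = ((params.production_rate_gal * u + params.basal_rate)
         * cell.prod_factor * cell.volume_proxy)
    d = params.maturation_or_decay_rate
    if d > 0.0:
        ss = p / d
        cell.gfp = ss + (cell.gfp - ss) * math.exp(-d * dt)
    else:
        cell.gfp += p * dt
    cell.clock_abs += dt

    if not cell.aggregated:
        if cell.concentration >= cell.per_cell_threshold:
            cell.time_above += dt
            if cell.time_above >= cell.agg_delay:
                cell.aggregated = True
                cell.aggregation_time = cell.clock_abs
                events.append("aggregation")
                if rng.random() < params.arrest_fraction:
                    cell.arrested = True
        else:
            cell.time_above = 0.0

    if not cell.arrested:
        cell.cycle_clock += dt
        unbudded_span = (1.0 - params.budded_fraction) * cell.cycle_duration
        if cell.phase == "unbudded" and cell.cycle_clock >= unbudded_span:
            cell.phase = "budded"
            events.append("bud")
        # volume schedule: newborns grow back to 1 across G1; budded cells
        # grow toward 1/(1-shed) so division leaves concentration continuous
        if cell.phase == "unbudded":
            remaining = unbudded_span - cell.cycle_clock
            if cell.volume_proxy < 1.0:
                if remaining > dt:
                    cell.volume_proxy = math.exp(
                        math.log(cell.volume_proxy) * (1.0 - dt / remaining))
                else:
                    cell.volume_proxy = 1.0
        else:
            v_target = 1.0 / (1.0 - params.division_shed_fraction)
            remaining = cell.cycle_duration - cell.cycle_clock
            if remaining > dt:
                lv = math.log(cell.volume_proxy)
                cell.volume_proxy = math.exp(
                    lv + (math.log(v_target) - lv) * dt / remaining)
            else:
                cell.volume_proxy = v_target
        if cell.cycle_clock >= cell.cycle_duration:
            events.append("division_due")
    return cell, events


def apply_division(cell: CellState, params: PlantParams, rng: np.random.Generator,
                   daughter_id: int, arena: tuple[int, int] = (256, 256),
                   neighbors: list[CellState] | None = None,
                   ) -> tuple[CellState, CellState]:
    """Divide a budded cell; total fluorescence is conserved exactly.

    The daughter receives ``division_shed_fraction`` of the mother's
    fluorescence, a fresh cycle clock and its own sampled threshold,
    extrinsic factor and aggregation delay.  The newborn is placed adjacent
    to the mother; when ``neighbors`` are given, the angle with the most
    clearance is chosen (buds grow into free space in the monolayer).
    """
    if cell.phase != "budded":
        raise ValueError("division requires a cell in the budded phase")
    shed = params.division_shed_fraction
    d_gfp = shed * cell.gfp
    off = cell.radius + 7.0

    def place(angle: float) -> tuple[float, float]:
        return (min(max(cell.position[0] + off * math.cos(angle), 12.0),
                    arena[1] - 12.0),
                min(max(cell.position[1] + off * math.sin(angle), 12.0),
                    arena[0] - 12.0))

    base = rng.uniform(0.0, 2.0 * math.pi)
    if neighbors:
        candidates = [place(base + k * math.pi / 8.0) for k in range(16)]
        pos = max(candidates,
                  key=lambda p: min((math.hypot(p[0] - n.position[0],
                                                p[1] - n.position[1])
                                     for n in neighbors if n is not cell),
                                    default=math.inf))
    else:
        pos = place(base)
    daughter = new_cell(params, rng, daughter_id, parent_id=cell.cell_id,
                        birth_time=cell.clock_abs, gfp=d_gfp, position=pos,
                        arena=arena)
    daughter.volume_proxy = shed / (1.0 - shed)   # the 0.61 newborn/mother ratio
    cell.gfp = cell.gfp - d_gfp
    cell.volume_proxy = 1.0
    cell.phase = "unbudded"
    cell.cycle_clock = 0.0
    cell.cycle_duration = _sample_cycle(params, rng, post=cell.aggregated)
    return cell, daughter


@dataclass
class InputSchedule:
    """Piecewise-constant galactose schedule: list of (duration min, u)."""

    segments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for dur, u in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if not 0.0 <= u <= 1.0:
                raise ValueError("u must lie in [0, 1]")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def u_at(self, t: float) -> float:
        """Input at time ``t``; the last segment extends beyond the end."""
        acc = 0.0
        for dur, u in self.segments:
            acc += dur
            if t < acc:
                return u
        return self.segments[-1][1]


class Population:
    """A chamber of cells advanced minute-by-minute and sampled every T min.

    Mothers are trapped in the monolayer; daughters join only while the
    chamber capacity allows and otherwise leave the field of view at birth.
    """

    def __init__(self, params: PlantParams, n_initial: int,
                 rng: np.random.Generator, arena: tuple[int, int] = (256, 256)):
        if n_initial <= 0:
            raise ValueError("empty initial population")
        self.params = params
        self.rng = rng
        self.arena = arena
        self.cells: list[CellState] = []
        self._traces: dict[int, CellTrace] = {}
        self._next_id = 0
        self.time = 0.0
        for _ in range(n_initial):
            c = new_cell(params, rng, self._next_id, arena=arena)
            # desynchronise: uniform cycle age, volume consistent with phase
            c.cycle_clock = float(rng.uniform(0.0, c.cycle_duration))
            unbudded_span = (1.0 - params.budded_fraction) * c.cycle_duration
            if c.cycle_clock >= unbudded_span:
                c.phase = "budded"
                progress = ((c.cycle_clock - unbudded_span)
                            / (c.cycle_duration - unbudded_span))
                c.volume_proxy = (1.0 / (1.0 - params.division_shed_fraction)
                                  ) ** progress
            self.cells.append(c)
            self._traces[c.cell_id] = CellTrace(cell_id=c.cell_id, parent_id=None)
            self._next_id += 1

    # -- dynamics -----------------------------------------------------------
    def advance(self, u: float, minutes: float, dt: float = 1.0) -> None:
        """Advance every cell by ``minutes`` using internal steps of ``dt``."""
        n_steps = int(round(minutes / dt))
        params, rng = self.params, self.rng
        for _ in range(n_steps):
            self.time += dt
            newborn: list[CellState] = []
            for cell in self.cells:
                _, events = step_cell(cell, u, dt, params, rng)
                tr = self._traces[cell.cell_id]
                if "bud" in events:
                    tr.bud_events.append(self.time)
                if "aggregation" in events:
                    tr.aggregation_time = cell.aggregation_time
                if "division_due" in events:
                    _, daughter = apply_division(cell, params, rng, self._next_id,
                                                 arena=self.arena,
                                                 neighbors=self.cells)
                    self._next_id += 1
                    tr.division_events.append(self.time)
                    dtr = CellTrace(cell_id=daughter.cell_id,
                                    parent_id=cell.cell_id)
                    self._traces[daughter.cell_id] = dtr
                    if len(self.cells) + len(newborn) < params.chamber_capacity:
                        newborn.append(daughter)
                    else:
                        dtr.end_reason = "left_fov"
            self.cells.extend(newborn)

    # -- measurement --------------------------------------------------------
    def record_sample(self, with_noise: bool = True) -> None:
        """Record one sample per cell, applying the per-sampling-period
        multiplicative lognormal jitter to the fluorescence state first."""
        cv = self.params.sample_noise_cv
        if with_noise and cv > 0:
            s2 = math.log1p(cv * cv)
            factors = self.rng.lognormal(-0.5 * s2, math.sqrt(s2), size=len(self.cells))
        else:
            factors = np.ones(len(self.cells))
        jit = self.params.position_jitter_px
        if with_noise and jit > 0 and self.cells:
            steps = self.rng.normal(0.0, jit, size=(len(self.cells), 2))
            h, w = self.arena
            for cell, (dx, dy) in zip(self.cells, steps):
                cell.position = (min(max(cell.position[0] + dx, 12.0), w - 12.0),
                                 min(max(cell.position[1] + dy, 12.0), h - 12.0))
        for cell, f in zip(self.cells, factors):
            cell.gfp *= float(f)
            tr = self._traces[cell.cell_id]
            tr.times.append(self.time)
            tr.gfp_norm.append(cell.concentration)
            tr.mcherry.append(cell.mcherry)
            tr.phases.append(cell.phase)

    def mean_gfp(self) -> float:
        """Population-mean measured (normalized) fluorescence."""
        return float(np.mean([c.concentration for c in self.cells]))

    def traces(self) -> list[CellTrace]:
        return list(self._traces.values())

    def ground_truth(self) -> dict:
        thresholds = {tr.cell_id: None for tr in self._traces.values()}
        for c in self.cells:
            thresholds[c.cell_id] = c.per_cell_threshold
        return {
            "thresholds": thresholds,
            "parents": {tr.cell_id: tr.parent_id for tr in self._traces.values()},
            "aggregation_times": {tr.cell_id: tr.aggregation_time
                                  for tr in self._traces.values()},
        }


def simulate_population(params: PlantParams, schedule_or_controller,
                        duration: float, sample_period: float = 5.0,
                        n_initial: int = 20,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[CellTrace], dict]:
    """Run the plant under a schedule (or a controller callable).

    ``schedule_or_controller`` is an :class:`InputSchedule` or a callable
    ``f(t, y_mean) -> u`` evaluated once per sampling period.  Returns the
    per-cell traces (sampled every ``sample_period`` minutes) and a
    ground-truth dictionary (per-cell thresholds, parentage, aggregation
    times).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    T = sample_period
    if duration <= 0 or abs(duration / T - round(duration / T)) > 1e-9:
        raise ValueError("duration must be a positive multiple of the sample period")
    pop = Population(params, n_initial, rng)
    pop.record_sample()
    n_periods = int(round(duration / T))
    for k in range(n_periods):
        t = k * T
        if isinstance(schedule_or_controller, InputSchedule):
            u = schedule_or_controller.u_at(t)
        else:
            u = float(schedule_or_controller(t, pop.mean_gfp()))
        pop.advance(u, T)
        pop.record_sample()
    return pop.traces(), pop.ground_truth()


def simulate_clearance(params: PlantParams, treatment: str, n_cells: int,
                       duration: float, sample_period: float = 5.0,
                       rng: np.random.Generator | None = None) -> list[CellTrace]:
    """Simulate an inclusion-clearance experiment for one treatment.

    Cells start with inclusions and clearance-normalized fluorescence ~1.
    Production is off after the galactose-to-glucose switch and GFP is
    stable, so the measured fluorescence stays flat through every unbudded
    phase and declines by the shed fraction (division dilution through
    volume growth) across each budded phase.  The time to first bud is
    drawn with the treatment's multiplier; MG132 additionally lengthens the
    cell cycle.  Inclusions are scored as dissolved when the normalized
    fluorescence falls below ``clearance_disappear_level``.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    T = sample_period
    shed = params.division_shed_fraction
    mult = params.clearance_tfb_multiplier[treatment]
    cyc_factor = params.mg132_cycle_factor if treatment == "MG132" else 1.0
    s2 = math.log1p(params.sample_noise_cv ** 2)
    times = np.arange(0.0, duration + 0.5 * T, T)

    traces: list[CellTrace] = []
    for cid in range(n_cells):
        f0 = max(0.5, float(rng.normal(1.0, 0.03)))
        tfb = _lognormal(rng, params.tfb_base_mean * mult, params.tfb_cv)
        # bud/division event times: cycle = bud-to-bud interval, division
        # closes the budded phase that opens each cycle
        buds, divisions = [], []
        b = tfb
        while b <= duration:
            buds.append(b)
            c = max(20.0, float(rng.normal(params.cycle_mean_pre * cyc_factor,
                                           params.cycle_sd)))
            d = b + params.budded_fraction * c
            if d <= duration:
                divisions.append(d)
            b += c
        # dilution exponent: completed divisions plus the fractional volume
        # growth of the budded phase in progress at each sample time
        div_arr = np.asarray(divisions)
        exponent = np.asarray(np.searchsorted(div_arr, times, side="right"),
                              dtype=float)
        for b_t, d_t in zip(buds, divisions):
            inside = (times >= b_t) & (times < d_t)
            exponent[inside] += (times[inside] - b_t) / (d_t - b_t)
        if buds and (not divisions or buds[-1] > divisions[-1]):
            b_t = buds[-1]
            d_t = b_t + params.budded_fraction * params.cycle_mean_pre * cyc_factor
            inside = times >= b_t
            exponent[inside] += np.minimum((times[inside] - b_t) / (d_t - b_t), 1.0)
        values = f0 * (1.0 - shed) ** exponent
        if params.sample_noise_cv > 0:
            values = values * rng.lognormal(-0.5 * s2, math.sqrt(s2), size=len(times))
        phases = np.full(len(times), "unbudded", dtype=object)
        for b_t, d_t in zip(buds, divisions + [duration + T]):
            phases[(times >= b_t) & (times < d_t)] = "budded"

        tr = CellTrace(cell_id=cid, parent_id=None)
        tr.times = times.tolist()
        tr.gfp_norm = values.tolist()
        tr.mcherry = [params.mcherry_mean] * len(times)
        tr.phases = phases.tolist()
        tr.bud_events = buds
        tr.division_events = divisions
        tr.aggregation_time = 0.0  # inclusions present from the start
        level = params.clearance_disappear_level
        exact = f0 * (1.0 - shed) ** np.arange(1, len(divisions) + 1)
        below = np.nonzero(exact < level)[0]
        tr.clearance_time = float(div_arr[below[0]]) if len(below) else None
        traces.append(tr)
    return traces
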