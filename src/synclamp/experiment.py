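"""Closed-loop experiment harness.

Wires the stochastic plant to the MPC controller (optionally through the
render -> segment -> quantify -> normalize imaging path), mirroring the
automated platform's loop: measure fluorescence every sampling period,
update the Kalman state estimate, compute the optimal galactose pulse,
and actuate the (shared) medium.  Also provides the cohort generator
used for the aggregation-threshold studies: a stepwise multi-level
closed-loop experiment from which labeled single-cell datasets are
extracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import aggregation as agg
from .control import (ControllerConfig, KalmanState, identify_model,
                      kalman_step, mpc_step)
from .imaging import detect_cells, quantify
from .params import PlantParams
from .plant import CellState, Population, step_cell
from .render import render_frame
from .tracking import MIN_LEVEL, filter_traces
from .traces import CellTrace

__all__ = ["ExperimentConfig", "ExperimentRecord", "CohortResult",
           "run_closed_loop", "identify_plant_model",
           "generate_aggregation_cohort", "load_config", "save_config",
           "NINE_LEVEL_RAMP", "THREE_LEVEL_SINGLE_CELL"]

MODES = ("population_control", "single_cell_control", "open_loop", "clearance")

#: stepwise nine-level induction profile (level n.u., 500 min each)
NINE_LEVEL_RAMP = [(500.0, float(v)) for v in (2, 4, 6, 8, 10, 12, 14, 16, 18)]
#: three-plateau single-cell profile (n.u.)
THREE_LEVEL_SINGLE_CELL = [(500.0, 6.0), (500.0, 10.0), (500.0, 14.0)]


@dataclass
class ExperimentConfig:
    mode: str = "population_control"
    strain: str = "WT"
    reference: list[tuple[float, float]] = field(
        default_factory=lambda: [(2000.0, 4.0)])   # (duration min, level n.u.)
    treatment: str = "untreated"
    seed: int = 0
    sample_period: float = 5.0
    calibration_min: float = 15.0   # initial glucose phase before control starts
    n_initial: int = 20
    measurement_path: str = "ground_truth"   # or "imaged"
    # preview the future reference over the prediction horizon (anticipatory
    # MPC); off by default so output transitions begin at each step
    reference_preview: bool = False
    plant_overrides: dict = field(default_factory=dict)
    controller_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.measurement_path not in ("ground_truth", "imaged"):
            raise ValueError("measurement_path must be 'ground_truth' or 'imaged'")
        T = self.sample_period
        for dur, level in self.reference:
            if level < 0:
                raise ValueError("reference levels must be >= 0")
            if abs(dur / T - round(dur / T)) > 1e-9:
                raise ValueError("reference durations must be multiples of T")

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.reference)

    def yref_at(self, t: float) -> float:
        acc = 0.0
        for dur, level in self.reference:
            acc += dur
            if t < acc:
                return level
        return self.reference[-1][1]


@dataclass
class ExperimentRecord:
    config: ExperimentConfig
    traces: list[CellTrace]
    ground_truth: dict
    controller_log: pd.DataFrame
    summary: dict


def identify_plant_model(params: PlantParams, T: float = 5.0):
    """Identify the controller's LTI model from a simulator step response.

    A single noise-free, non-dividing reference cell (threshold and cycle
    disabled) is driven with a two-step input profile and the response is
    fitted by :func:`synclamp.control.identify_model`.  Deterministic.
    """
    clean = replace(params, extrinsic_noise_cv=0.0, sample_noise_cv=0.0)
    cell = CellState(cell_id=0, per_cell_threshold=math.inf, arrested=True)
    rng = np.random.default_rng(0)
    u_profile = [0.0] * 10 + [1.0] * 90 + [0.3] * 60
    ys = []
    for u in u_profile:
        ys.append(cell.gfp)
        for _ in range(int(round(T))):
            step_cell(cell, u, 1.0, clean, rng)
    return identify_model(np.asarray(u_profile), np.asarray(ys), T=T)


def _measure_imaged(pop: Population, rng: np.random.Generator,
                    controlled_pos=None):
    """Population (or single-cell) readout through the imaging pipeline."""
    frame = render_frame(pop.cells, rng=rng, time=pop.time)
    seg = detect_cells(frame.phase)
    vals = quantify(frame, seg)
    ratios = [(g / r, c) for (g, r), c in zip(vals, seg.centroids) if r > 1.0]
    if not ratios:
        return 0.0, None
    if controlled_pos is None:
        return float(np.mean([v for v, _ in ratios])), None
    dists = [math.hypot(c[0] - controlled_pos[0], c[1] - controlled_pos[1])
             for _, c in ratios]
    i = int(np.argmin(dists))
    return float(ratios[i][0]), ratios[i][1]


def run_closed_loop(config: ExperimentConfig) -> ExperimentRecord:
    """Run one closed-loop (or open-loop) experiment against the simulator.

    Per sampling period: measure the population mean (or the controlled
    cell, chosen randomly at the end of the calibration phase in
    single-cell mode), Kalman-update the state estimate, compute the MPC
    input and apply it to the plant.  All cells share the actuated medium.
    """
    params = PlantParams.for_strain(config.strain, seed=config.seed,
                                    **config.plant_overrides)
    ctrl = ControllerConfig(T=config.sample_period, **config.controller_overrides)
    T = config.sample_period
    rng = np.random.default_rng(config.seed)
    ident = identify_plant_model(params, T=T)
    model = ident.model

    pop = Population(params, config.n_initial, rng)
    pop.record_sample()
    ks = KalmanState()
    u_prev = 0.0
    controlled_id: int | None = None
    controlled_pos = None
    n_cal = int(round(config.calibration_min / T))
    n_periods = int(round(config.duration / T))
    N = ctrl.horizon_steps
    rows = []
    events = []

    for k in range(n_periods):
        t = k * T
        if config.mode == "single_cell_control" and k == n_cal:
            # "the cell to be controlled was chosen randomly" at calibration end
            controlled_id = int(rng.choice([c.cell_id for c in pop.cells]))
        # -- measure ------------------------------------------------------
        if config.measurement_path == "imaged":
            want_single = (config.mode == "single_cell_control"
                           and controlled_id is not None)
            if want_single and controlled_pos is None:
                cell = next(c for c in pop.cells if c.cell_id == controlled_id)
                controlled_pos = cell.position
            y, pos = _measure_imaged(pop, rng,
                                     controlled_pos if want_single else None)
            if want_single:
                if pos is None:
                    events.append((t, "controlled cell lost; re-selected nearest"))
                else:
                    controlled_pos = pos
        else:
            if config.mode == "single_cell_control" and controlled_id is not None:
                match = [c for c in pop.cells if c.cell_id == controlled_id]
                if not match:   # left the field of view: re-select nearest
                    events.append((t, "controlled cell lost; re-selected"))
                    controlled_id = pop.cells[0].cell_id
                    match = [pop.cells[0]]
                y = match[0].concentration
            else:
                y = pop.mean_gfp()
        # -- control ------------------------------------------------------
        if config.mode == "open_loop" or k < n_cal:
            u = 0.0
            y_est = float(model.C @ ks.x)
        else:
            ks = kalman_step(model, ks, u_prev, y, ctrl)
            y_est = float(model.C @ ks.x)
            if config.reference_preview:
                yref_h = [config.yref_at(t + i * T) for i in range(N)]
            else:
                yref_h = [config.yref_at(t)] * N
            u = mpc_step(model, ks, ctrl, yref_h, u_prev)
        rows.append((t, y, y_est, config.yref_at(t), u, u * T))
        pop.advance(u, T)
        pop.record_sample()
        u_prev = u

    log = pd.DataFrame(rows, columns=["time_min", "y_meas", "y_est",
                                      "yref", "u", "d_min"])
    summary = {
        "mode": config.mode, "strain": config.strain, "seed": config.seed,
        "controlled_cell": controlled_id,
        "model_rmse": ident.rmse,
        "events": events,
        "plateau_means": _plateau_means(config, log),
    }
    return ExperimentRecord(config=config, traces=pop.traces(),
                            ground_truth=pop.ground_truth(),
                            controller_log=log, summary=summary)


def _plateau_means(config: ExperimentConfig, log: pd.DataFrame,
                   settle_fraction: float = 0.4) -> list[dict]:
    """Time-averaged measured output per reference plateau (after allowing
    the first ``settle_fraction`` of each plateau for the transient)."""
    out = []
    t0 = 0.0
    for dur, level in config.reference:
        t_start = t0 + settle_fraction * dur
        sel = (log["time_min"] >= t_start) & (log["time_min"] < t0 + dur)
        out.append({"level": level, "t_start": t0, "t_end": t0 + dur,
                    "mean_y": float(log.loc[sel, "y_meas"].mean())})
        t0 += dur
    return out


# -- aggregation cohorts ----------------------------------------------------

@dataclass
class CohortResult:
    strain: str
    seed: int
    traces: list[CellTrace]          # selected aggregated cells (paper-style)
    dataset: agg.AggregationDataset
    fit: agg.ClassifierFit
    fluor_at_aggregation: np.ndarray
    record: ExperimentRecord


def generate_aggregation_cohort(strain: str, n_cells: int, seed: int,
                                reference=None,
                                measurement_path: str = "ground_truth",
                                ) -> CohortResult:
    """Run a stepwise multi-level closed-loop experiment and extract the
    labeled single-cell aggregation dataset.

    Mirrors the study design: trace selection keeps cells longer than
    500 min that reach the strain's minimum level; of those, the first
    ``n_cells`` that formed inclusions constitute the dataset, with every
    sample labeled by its position relative to the cell's ground-truth
    aggregation time.
    """
    if reference is None:
        reference = NINE_LEVEL_RAMP
    n_initial = int(math.ceil(n_cells * 1.6))
    config = ExperimentConfig(
        mode="population_control", strain=strain, reference=list(reference),
        seed=seed, n_initial=n_initial, measurement_path=measurement_path,
        plant_overrides={"chamber_capacity": n_initial})
    record = run_closed_loop(config)
    kept = filter_traces(record.traces, min_duration=500.0,
                         min_level=MIN_LEVEL[strain])
    aggregated = [tr for tr in kept if tr.aggregation_time is not None]
    aggregated.sort(key=lambda tr: tr.cell_id)
    selected = aggregated[:n_cells]
    dataset = agg.make_dataset(selected)
    fit = agg.fit_threshold(dataset)
    fluor_at_ta = np.array([tr.value_at(tr.aggregation_time) for tr in selected])
    return CohortResult(strain=strain, seed=seed, traces=selected,
                        dataset=dataset, fit=fit,
                        fluor_at_aggregation=fluor_at_ta, record=record)


# -- config file round trip -------------------------------------------------

def save_config(config: ExperimentConfig, path) -> None:
    data = {
        "mode": config.mode, "strain": config.strain,
        "reference": [[float(d), float(v)] for d, v in config.reference],
        "treatment": config.treatment, "seed": config.seed,
        "sample_period": config.sample_period,
        "calibration_min": config.calibration_min,
        "n_initial": config.n_initial,
        "measurement_path": config.measurement_path,
        "plant_overrides": config.plant_overrides,
        "controller_overrides": config.controller_overrides,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"malformed config file: {path}")
    if "reference" in data:
        data["reference"] = [(float(d), float(v)) for d, v in data["reference"]]
    try:
        return ExperimentConfig(**data)
    except TypeError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from None
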