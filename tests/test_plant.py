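"""Unit and property tests for the cell-population simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synclamp.params import PlantParams
from synclamp.plant import (CellState, InputSchedule, apply_division, new_cell,
                            simulate_clearance, simulate_population, step_cell)
from synclamp.traces import read_traces, traces_to_frame, write_traces


def noise_free(strain="WT", **kw):
    return PlantParams.for_strain(strain, extrinsic_noise_cv=0.0,
                                  sample_noise_cv=0.0, **kw)


def fixed_cell(**kw):
    defaults = dict(cell_id=0, per_cell_threshold=math.inf, arrested=True)
    defaults.update(kw)
    return CellState(**defaults)


class TestStepCell:
    def test_no_induction_fixed_point(self, rng):
        params = noise_free(basal_rate=0.0)
        cell = fixed_cell()
        for _ in range(200):
            step_cell(cell, 0.0, 1.0, params, rng)
        assert cell.gfp == 0.0

    def test_matches_linear_ode_closed_form(self, rng):
        # u=1, no division, no noise: gfp(t) = (p/d) (1 - exp(-d t))
        params = noise_free()
        p, d = params.production_rate_gal, params.maturation_or_decay_rate
        cell = fixed_cell()
        t = 0.0
        for _ in range(600):
            step_cell(cell, 1.0, 1.0, params, rng)
            t += 1.0
            expected = (p / d) * (1.0 - math.exp(-d * t))
            assert cell.gfp == pytest.approx(expected, rel=1e-6)
        # approaching the steady state p/d
        assert cell.gfp == pytest.approx(p / d, rel=0.01)

    def test_unreachable_threshold_never_aggregates(self, rng):
        params = noise_free()
        cell = fixed_cell(arrested=False)
        for _ in range(2000):
            step_cell(cell, 1.0, 1.0, params, rng)
        assert not cell.aggregated and cell.aggregation_time is None

    def test_negative_dt_rejected(self, rng):
        with pytest.raises(ValueError):
            step_cell(fixed_cell(), 0.5, -1.0, noise_free(), rng)

    def test_u_outside_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            step_cell(fixed_cell(), 1.5, 1.0, noise_free(), rng)

    def test_monotone_in_u_pointwise(self, rng):
        """Zero-noise runs: raising u never lowers gfp at any sampled time."""
        params = noise_free()
        lo, hi = fixed_cell(arrested=False), fixed_cell(arrested=False)
        hi.cycle_duration = lo.cycle_duration
        r1, r2 = np.random.default_rng(0), np.random.default_rng(0)
        for _ in range(500):
            step_cell(lo, 0.4, 1.0, params, r1)
            step_cell(hi, 0.7, 1.0, params, r2)
            assert hi.gfp >= lo.gfp


class TestDivision:
    def test_shed_split_and_conservation(self, rng):
        params = noise_free()
        cell = fixed_cell(gfp=1.0, phase="budded")
        mother, daughter = apply_division(cell, params, rng, daughter_id=1)
        assert daughter.gfp == pytest.approx(0.38)
        assert mother.gfp == pytest.approx(0.62)
        assert mother.gfp + daughter.gfp == 1.0   # exact conservation

    def test_zero_fluorescence(self, rng):
        cell = fixed_cell(gfp=0.0, phase="budded")
        mother, daughter = apply_division(cell, noise_free(), rng, 1)
        assert mother.gfp == 0.0 and daughter.gfp == 0.0

    def test_two_successive_divisions(self, rng):
        params = noise_free()
        cell = fixed_cell(gfp=10.0, phase="budded")
        mother, _ = apply_division(cell, params, rng, 1)
        mother.phase = "budded"
        mother, _ = apply_division(mother, params, rng, 2)
        assert mother.gfp == pytest.approx(10.0 * 0.62 ** 2)  # 3.844

    def test_requires_budded_phase(self, rng):
        with pytest.raises(ValueError):
            apply_division(fixed_cell(gfp=1.0), noise_free(), rng, 1)

    def test_daughter_gets_newborn_volume_ratio(self, rng):
        """Newborn/mother volume ratio is shed/(1-shed) = 0.61."""
        cell = fixed_cell(gfp=1.0, phase="budded")
        mother, daughter = apply_division(cell, noise_free(), rng, 1)
        assert mother.volume_proxy == 1.0
        assert daughter.volume_proxy == pytest.approx(0.38 / 0.62, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(gfp=st.floats(0.0, 1e3), shed=st.floats(0.01, 0.99))
    def test_conservation_property(self, gfp, shed):
        params = noise_free(division_shed_fraction=shed)
        cell = fixed_cell(gfp=gfp, phase="budded")
        before = cell.gfp
        mother, daughter = apply_division(cell, params,
                                          np.random.default_rng(0), 1)
        assert mother.gfp + daughter.gfp == before


class TestSampledHeterogeneity:
    def test_threshold_cv_matches_parameter(self):
        params = PlantParams.for_strain("A53T")   # CV = 0.28
        rng = np.random.default_rng(7)
        draws = np.array([new_cell(params, rng, i).per_cell_threshold
                          for i in range(10_000)])
        cv = draws.std(ddof=1) / draws.mean()
        assert cv == pytest.approx(params.threshold_cv, rel=0.05)
        assert draws.mean() == pytest.approx(params.threshold_mean, rel=0.02)
        assert (draws > 0).all()


class TestSimulatePopulation:
    def test_glucose_only_never_aggregates(self):
        params = PlantParams.for_strain("WT", seed=0)
        traces, gt = simulate_population(params, InputSchedule([(500.0, 0.0)]),
                                         500.0, n_initial=10)
        assert all(tr.aggregation_time is None for tr in traces)

    def test_constant_galactose_drives_aggregation(self):
        params = PlantParams.for_strain("A53T", seed=1)
        traces, gt = simulate_population(params, InputSchedule([(1500.0, 1.0)]),
                                         1500.0, n_initial=30)
        n_agg = sum(tr.aggregation_time is not None for tr in traces)
        assert n_agg >= 10
        founders = [tr for tr in traces if tr.parent_id is None]
        mean_final = np.mean([tr.gfp_norm[-1] for tr in founders])
        assert mean_final > params.threshold_mean

    def test_fixed_seed_reproducible(self, tmp_path):
        params = PlantParams.for_strain("WT", seed=42)
        out = []
        for _ in range(2):
            traces, _ = simulate_population(params, InputSchedule([(200.0, 0.8)]),
                                            200.0, n_initial=8)
            path = tmp_path / "t.csv"
            write_traces(traces, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_population(PlantParams(), InputSchedule([(10.0, 0.0)]),
                                10.0, n_initial=0)

    def test_duration_must_match_period(self):
        with pytest.raises(ValueError):
            simulate_population(PlantParams(), InputSchedule([(12.0, 0.0)]),
                                12.0, n_initial=2)


class TestSchedule:
    def test_lookup_and_validation(self):
        s = InputSchedule([(10.0, 0.2), (5.0, 1.0)])
        assert s.u_at(0.0) == 0.2 and s.u_at(9.9) == 0.2
        assert s.u_at(10.0) == 1.0 and s.u_at(99.0) == 1.0
        with pytest.raises(ValueError):
            InputSchedule([(10.0, 1.5)])
        with pytest.raises(ValueError):
            InputSchedule([(-5.0, 0.5)])


class TestSimulateClearance:
    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            simulate_clearance(PlantParams(), "aspirin", 5, 500.0)

    def test_expected_dilution_per_division(self):
        params = PlantParams.for_strain("A53T_dpdr5", seed=0,
                                        sample_noise_cv=0.0)
        traces = simulate_clearance(params, "untreated", 40, 900.0,
                                    rng=np.random.default_rng(0))
        for tr in traces:
            n_div = len(tr.division_events)
            if n_div == 0:
                continue
            # value after the last division ~ f0 * 0.62**n
            t_after = tr.division_events[-1]
            i = int(np.searchsorted(tr.times, t_after))
            f0 = tr.gfp_norm[0]
            assert tr.gfp_norm[i] == pytest.approx(f0 * 0.62 ** n_div, rel=0.02)

    def test_flat_before_first_bud(self):
        params = PlantParams.for_strain("A53T_dpdr5", seed=0,
                                        sample_noise_cv=0.0)
        traces = simulate_clearance(params, "untreated", 20, 800.0,
                                    rng=np.random.default_rng(1))
        for tr in traces:
            tfb = min(tr.bud_events) if tr.bud_events else 800.0
            pre = [v for t, v in zip(tr.times, tr.gfp_norm) if t <= tfb]
            assert np.allclose(pre, pre[0])

    def test_rapamycin_buds_before_untreated(self):
        params = PlantParams.for_strain("A53T_dpdr5", seed=0)
        rng = np.random.default_rng(2)
        rapa = simulate_clearance(params, "rapamycin", 100, 1200.0, rng=rng)
        untr = simulate_clearance(params, "untreated", 100, 1200.0, rng=rng)
        med = lambda trs: np.median([min(tr.bud_events) if tr.bud_events
                                     else 1200.0 for tr in trs])
        assert med(rapa) < med(untr)


class TestTraceRoundTrip:
    def test_csv_round_trip_preserves_series_and_events(self, tmp_path):
        params = PlantParams.for_strain("WT", seed=3)
        traces, _ = simulate_population(params, InputSchedule([(300.0, 1.0)]),
                                        300.0, n_initial=6)
        path = tmp_path / "traces.csv"
        write_traces(traces, path)
        back = read_traces(path)
        orig = {tr.cell_id: tr for tr in traces}
        assert set(tr.cell_id for tr in back) == set(orig)
        for tr in back:
            if not tr.times:
                continue
            ref = orig[tr.cell_id]
            assert np.allclose(tr.gfp_norm, ref.gfp_norm)
            assert len(tr.bud_events) == len(ref.bud_events)

    def test_tidy_frame_columns(self):
        params = PlantParams.for_strain("WT", seed=3)
        traces, _ = simulate_population(params, InputSchedule([(50.0, 0.5)]),
                                        50.0, n_initial=3)
        df = traces_to_frame(traces)
        assert list(df.columns) == ["cell_id", "parent_id", "time_min",
                                    "gfp_norm", "mcherry", "phase", "event"]
        labels = {e for ev in df["event"] for e in str(ev).split(";")}
        assert labels.issubset({"none", "bud", "division", "aggregation"})
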