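"""Tests for assignment, lineage construction and trace filtering."""

import itertools

import numpy as np
import pytest

from synclamp.params import PlantParams
from synclamp.plant import Population
from synclamp.tracking import (build_lineage, filter_traces, link_frames,
                               track_movie)
from synclamp.traces import CellTrace


def brute_force_assignment(prev, curr):
    """Minimum-total-displacement perfect matching by exhaustive permutation."""
    n = len(prev)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(n)):
        cost = sum(np.hypot(prev[i][0] - curr[j][0], prev[i][1] - curr[j][1])
                   for i, j in enumerate(perm))
        if cost < best_cost:
            best, best_cost = perm, cost
    return best, best_cost


class TestLinkFrames:
    def test_identical_sets_identity_assignment(self):
        pts = [(10.0, 10.0), (50.0, 50.0), (90.0, 10.0)]
        asg = link_frames(pts, pts, max_disp=20.0)
        assert asg.pairs == [(0, 0), (1, 1), (2, 2)]
        assert not asg.births and not asg.losses

    def test_empty_current_frame_all_lost(self):
        asg = link_frames([(1.0, 1.0), (5.0, 5.0)], [], max_disp=10.0)
        assert asg.losses == [0, 1] and not asg.pairs

    def test_jittered_cells_match_nearest_neighbor_truth(self, rng):
        prev = [(20.0 + 30.0 * i, 40.0) for i in range(4)]
        curr = [(x + rng.uniform(-3, 3), y + rng.uniform(-3, 3))
                for x, y in prev]
        asg = link_frames(prev, curr, max_disp=15.0)
        assert sorted(asg.pairs) == [(i, i) for i in range(4)]

    def test_gate_breaks_long_links(self):
        asg = link_frames([(0.0, 0.0)], [(100.0, 0.0)], max_disp=10.0)
        assert not asg.pairs
        assert asg.births == [0] and asg.losses == [0]

    def test_unbalanced_counts_yield_birth(self):
        prev = [(10.0, 10.0)]
        curr = [(11.0, 10.0), (80.0, 80.0)]
        asg = link_frames(prev, curr, max_disp=15.0)
        assert asg.pairs == [(0, 0)] and asg.births == [1]

    def test_matches_brute_force_on_random_instances(self, rng):
        """Hungarian solution equals the exhaustive-permutation optimum for
        all random instances with n <= 6 (200 trials)."""
        for _ in range(200):
            n = int(rng.integers(2, 7))
            prev = rng.uniform(0, 100, (n, 2))
            curr = prev + rng.uniform(-5, 5, (n, 2))
            asg = link_frames(prev, curr, max_disp=1e6)
            cost = sum(np.hypot(*(prev[i] - curr[j])) for i, j in asg.pairs)
            _, best_cost = brute_force_assignment(prev.tolist(), curr.tolist())
            assert len(asg.pairs) == n
            assert cost == pytest.approx(best_cost, abs=1e-9)

    def test_max_disp_must_be_positive(self):
        with pytest.raises(ValueError):
            link_frames([(0.0, 0.0)], [(1.0, 1.0)], max_disp=0.0)


class TestTrackMovie:
    def test_no_identity_switches_under_small_displacement(self):
        """Simulator movie with centroid wobble far below the gate: every
        reconstructed track follows exactly one simulated cell."""
        params = PlantParams.for_strain("WT", seed=9, chamber_capacity=12)
        rng = np.random.default_rng(9)
        pop = Population(params, 8, rng)
        frames, truth_ids = [], []
        for _ in range(40):
            pop.advance(0.5, 5.0)
            pop.record_sample()
            frames.append([c.position for c in pop.cells])
            truth_ids.append([c.cell_id for c in pop.cells])
        tracks = track_movie(frames, max_disp=20.0)
        for t in tracks:
            followed = set()
            for k, (x, y) in enumerate(t.positions):
                f = t.start_frame + k
                d = [np.hypot(x - px, y - py) for px, py in frames[f]]
                followed.add(truth_ids[f][int(np.argmin(d))])
            assert len(followed) == 1, "identity switch detected"


class TestBuildLineage:
    def test_single_cell_forest_of_one(self):
        tracks = track_movie([[(10.0, 10.0)], [(10.5, 10.0)]], max_disp=5.0)
        parents = build_lineage(tracks)
        assert parents == {0: None}

    def test_equidistant_mothers_tie_break_by_lower_id(self):
        frames = [
            [(10.0, 10.0), (30.0, 10.0)],
            [(10.0, 10.0), (30.0, 10.0), (20.0, 10.0)],   # birth equidistant
        ]
        tracks = track_movie(frames, max_disp=5.0)
        parents = build_lineage(tracks, max_mother_dist=15.0)
        assert parents[2] == 0

    def test_out_of_range_birth_has_unknown_parent(self):
        frames = [[(10.0, 10.0)], [(10.0, 10.0), (200.0, 200.0)]]
        tracks = track_movie(frames, max_disp=5.0)
        parents = build_lineage(tracks, max_mother_dist=30.0)
        assert parents[1] is None

    def test_three_generations_well_separated_exact(self):
        """Constructed movie, one lineage per spatial cluster, 3 generations:
        every reconstructed parent equals the known truth."""
        # founders at x=40/140/240; daughter buds at +16 px, granddaughter
        # at +16 px beyond the daughter — clusters never approach each other
        frames = []
        for f in range(9):
            frame = []
            for cx in (40.0, 140.0, 240.0):
                frame.append((cx, 60.0))                   # founder
                if f >= 3:
                    frame.append((cx + 16.0, 60.0))        # daughter
                if f >= 6:
                    frame.append((cx + 16.0, 76.0))        # granddaughter
            frames.append(frame)
        tracks = track_movie(frames, max_disp=10.0)
        parents = build_lineage(tracks, max_mother_dist=20.0)
        by_birth = {(t.start_frame, t.positions[0]): t.track_id for t in tracks}
        for t in tracks:
            x, y = t.positions[0]
            if t.start_frame == 0:
                assert parents[t.track_id] is None
            elif t.start_frame == 3:      # daughters: parent is the founder
                assert parents[t.track_id] == by_birth[(0, (x - 16.0, y))]
            else:                          # granddaughters: parent = daughter
                assert parents[t.track_id] == by_birth[(3, (x, y - 16.0))]

    def test_recovers_most_simulator_parentage(self):
        """Crowded simulator movie: nearest-cell mother assignment agrees
        with the ground-truth lineage for most births (the heuristic is
        ambiguous once siblings and grandmothers pack the neighbourhood)."""
        params = PlantParams.for_strain("WT", seed=4, chamber_capacity=40,
                                        position_jitter_px=0.2)
        rng = np.random.default_rng(4)
        pop = Population(params, 4, rng)
        # spread the founders far apart so mother assignment is unambiguous
        for i, c in enumerate(pop.cells):
            c.position = (40.0 + 60.0 * i, 128.0)
        frames, id_frames = [], []
        for _ in range(70):
            pop.advance(0.6, 5.0)
            pop.record_sample()
            frames.append([c.position for c in pop.cells])
            id_frames.append([c.cell_id for c in pop.cells])
        truth_parents = pop.ground_truth()["parents"]
        tracks = track_movie(frames, max_disp=20.0)
        parents = build_lineage(tracks, max_mother_dist=25.0)
        # map each track to the simulator cell it follows at its birth frame
        def sim_id(track):
            x, y = track.positions[0]
            f = track.start_frame
            d = [np.hypot(x - px, y - py) for px, py in frames[f]]
            return id_frames[f][int(np.argmin(d))]
        checked, correct = 0, 0
        for t in tracks:
            if t.start_frame == 0 or parents[t.track_id] is None:
                continue
            child = sim_id(t)
            mother_track = next(tr for tr in tracks
                                if tr.track_id == parents[t.track_id])
            recon = sim_id_at(mother_track, t.start_frame, frames, id_frames)
            checked += 1
            correct += int(truth_parents[child] == recon)
        assert checked >= 5
        assert correct / checked >= 0.8


def sim_id_at(track, frame, frames, id_frames):
    x, y = track.positions[frame - track.start_frame]
    d = [np.hypot(x - px, y - py) for px, py in frames[frame]]
    return id_frames[frame][int(np.argmin(d))]


class TestFilterTraces:
    @staticmethod
    def make_trace(span, peak, cell_id=0):
        tr = CellTrace(cell_id=cell_id)
        n = int(span // 5) + 1
        tr.times = [5.0 * i for i in range(n)]
        tr.gfp_norm = list(np.linspace(0.0, peak, n))
        return tr

    def test_duration_filter_is_strict(self):
        short = self.make_trace(499.0, 20.0)        # 495-min span after floor
        long = self.make_trace(505.0, 20.0, 1)
        kept = filter_traces([short, long], min_duration=500.0, min_level=16.0)
        assert [tr.cell_id for tr in kept] == [1]

    def test_level_threshold_boundary(self):
        low = self.make_trace(600.0, 15.9)
        exact = self.make_trace(600.0, 16.0, 1)
        kept = filter_traces([low, exact], min_level=16.0)
        assert [tr.cell_id for tr in kept] == [1]

    def test_empty_input_empty_output(self):
        assert filter_traces([], min_level=10.0) == []
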