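"""Trajectory linking, splits, qualification filters and droplet records."""

import itertools
import math

import numpy as np
import pytest

from spraymode import (BlobObservation, EnsembleSettings, GroupSpec,
                       RenderSettings, RoiBounds, Trajectory, VolumeModel,
                       detect_stack, focal_filter, impact_velocity, link,
                       make_record, render_frames, roi_filter, sample_ensemble)
from spraymode.linking import _gate_radius_px


def blob(frame, row, col, area=100, extent=10, sharp=50.0):
    return BlobObservation(frame, (row, col), area, extent, sharp)


def traj(obs, tid=0, qualified=False, parent=None):
    return Trajectory(tid, list(obs), parent_id=parent, qualified=qualified)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

class TestLink:
    def test_single_droplet_single_trajectory(self, narrow_geometry):
        frames = [[blob(f, 100.0, 50.0 + 30 * f)] for f in range(12)]
        out = link(frames, narrow_geometry)
        assert len(out) == 1
        assert len(out[0]) == 12

    def test_two_far_droplets_never_cross(self, narrow_geometry):
        gate = _gate_radius_px(narrow_geometry, 20.0)
        frames = [[blob(f, 30.0, 50.0 + 30 * f),
                   blob(f, 30.0 + 2.5 * gate, 50.0 + 30 * f)]
                  for f in range(8)]
        out = link(frames, narrow_geometry)
        assert len(out) == 2
        assert all(len(t) == 8 for t in out)

    def test_split_produces_children_with_parent_id(self, narrow_geometry):
        """Hand-traced split: a 100-px parent vanishes and 60 + 45 px
        blobs appear inside its gate (sum 105 <= 130)."""
        frames = [
            [blob(0, 100.0, 50.0, area=100)],
            [blob(1, 100.0, 80.0, area=100)],
            [blob(2, 90.0, 110.0, area=60), blob(2, 110.0, 110.0, area=45)],
            [blob(3, 85.0, 140.0, area=60), blob(3, 115.0, 140.0, area=45)],
        ]
        out = link(frames, narrow_geometry)
        parents = [t for t in out if t.parent_id is None]
        children = [t for t in out if t.parent_id is not None]
        assert len(parents) == 1 and len(children) == 2
        assert len(parents[0]) == 2
        assert {c.parent_id for c in children} == {parents[0].trajectory_id}
        assert all(len(c) == 2 for c in children)

    def test_oversized_pair_is_not_a_split(self, narrow_geometry):
        """Two new blobs whose areas sum far above the parent's are new
        droplets, not split children."""
        frames = [
            [blob(0, 100.0, 50.0, area=50)],
            [blob(1, 100.0, 80.0, area=50)],
            [blob(2, 90.0, 110.0, area=60), blob(2, 110.0, 110.0, area=60)],
        ]
        out = link(frames, narrow_geometry, area_tol=0.3)
        assert all(t.parent_id is None for t in out)

    def test_blob_partition_property(self, narrow_geometry, rng):
        frames = []
        for f in range(10):
            frames.append([blob(f, float(rng.uniform(0, 200)),
                                float(rng.uniform(0, 900)),
                                area=int(rng.integers(10, 200)))
                           for _ in range(5)])
        out = link(frames, narrow_geometry)
        seen = set()
        for t in out:
            for o in t.observations:
                key = id(o)
                assert key not in seen
                seen.add(key)
        assert len(seen) == 50

    def test_axial_positions_non_decreasing(self, narrow_geometry, rng):
        frames = []
        for f in range(12):
            frames.append([blob(f, float(rng.uniform(0, 200)),
                                float(rng.uniform(0, 900))) for _ in range(4)])
        for t in link(frames, narrow_geometry):
            cols = [o.centroid[1] for o in t.observations]
            assert all(b - a >= -1.0 for a, b in zip(cols, cols[1:]))


def oracle_assignment(prev, nxt, gate, axis=1, slack=1.0):
    """Exhaustive minimum-total-distance assignment between two frames.

    Among all feasible matchings (within the gate, no backward axial
    motion beyond ``slack``) of maximum cardinality, returns the one
    with the smallest total Euclidean distance, as a set of (i, j).
    """
    feasible = {}
    for i, a in enumerate(prev):
        for j, b in enumerate(nxt):
            d = math.hypot(b.centroid[0] - a.centroid[0],
                           b.centroid[1] - a.centroid[1])
            if d <= gate and b.centroid[axis] - a.centroid[axis] >= -slack:
                feasible[(i, j)] = d
    idx_prev = range(len(prev))
    idx_next = list(range(len(nxt)))
    for r in range(min(len(prev), len(nxt)), 0, -1):
        best_cost, best_pairs = None, None
        for combo_p in itertools.combinations(idx_prev, r):
            for perm_n in itertools.permutations(idx_next, r):
                pairs = tuple(zip(combo_p, perm_n))
                if any(p not in feasible for p in pairs):
                    continue
                cost = sum(feasible[p] for p in pairs)
                if best_cost is None or cost < best_cost:
                    best_cost, best_pairs = cost, pairs
        if best_cost is not None:
            return frozenset(best_pairs), best_cost
    return frozenset(), 0.0


class TestGreedyMatchesExhaustiveOracle:
    def random_scene(self, rng):
        """A spray-like two-frame scene: <= 5 droplets moving axially.

        Droplets are separated by more than twice the largest per-frame
        displacement in the scene — the sparse regime frame-to-frame
        nearest-neighbour tracking is designed for (closer spacing than
        the motion makes any distance-based association ill-posed).
        """
        n = int(rng.integers(1, 6))
        # velocities first: mostly slow primaries, some fast satellites
        vels = [max(9.0, float(rng.normal(52, 23)))
                if rng.uniform() < 0.9 else
                min(310.0, float(rng.normal(256, 62))) for _ in range(n)]
        min_sep = 2.05 * max(vels)
        prev, nxt = [], []
        for v_px in vels:
            for _ in range(200):
                row = float(rng.uniform(15, 185))
                col = float(rng.uniform(60, 860))
                if all(math.hypot(row - p.centroid[0],
                                  col - p.centroid[1]) > min_sep
                       for p in prev):
                    break
            else:
                continue        # no room left at this separation
            area = int(rng.integers(10, 400))
            prev.append(blob(0, row, col, area=area))
            if rng.uniform() < 0.9:   # some droplets leave the scene
                nxt.append(blob(1, row + float(rng.normal(0, 0.3)),
                                col + v_px, area=area))
        order = rng.permutation(len(nxt))
        return prev, [nxt[i] for i in order]

    def test_greedy_attains_exhaustive_optimum_on_100_scenes(self, narrow_geometry, rng):
        """Greedy linking matches the exhaustive minimal-total-distance
        assignment: same number of links and the same (minimal) total
        displacement on every scene."""
        gate = _gate_radius_px(narrow_geometry, 20.0)
        for _ in range(100):
            prev, nxt = self.random_scene(rng)
            out = link([prev, nxt], narrow_geometry)
            greedy_pairs = set()
            for t in out:
                if len(t) == 2:
                    greedy_pairs.add((prev.index(t.observations[0]),
                                      nxt.index(t.observations[1])))
            oracle_pairs, cost = oracle_assignment(prev, nxt, gate)
            assert len(greedy_pairs) == len(oracle_pairs)
            greedy_cost = sum(
                math.hypot(nxt[j].centroid[0] - prev[i].centroid[0],
                           nxt[j].centroid[1] - prev[i].centroid[1])
                for i, j in greedy_pairs)
            assert greedy_cost == pytest.approx(cost, abs=1e-9)


# ---------------------------------------------------------------------------
# qualification filters
# ---------------------------------------------------------------------------

class TestRoiFilter:
    ROI = RoiBounds(1.0, 3.5)

    def px(self, geo, mm):
        return geo.px_from_axial_mm(mm)

    def test_full_traversal_qualifies(self, narrow_geometry):
        g = narrow_geometry
        t = traj([blob(0, 100, self.px(g, 0.5)), blob(1, 100, self.px(g, 3.8))])
        roi_filter([t], self.ROI, g)
        assert t.qualified

    def test_starting_inside_roi_is_rejected(self, narrow_geometry):
        g = narrow_geometry
        t = traj([blob(0, 100, self.px(g, 1.2)), blob(1, 100, self.px(g, 3.8))])
        roi_filter([t], self.ROI, g)
        assert not t.qualified

    def test_child_inherits_parent_entry(self, narrow_geometry):
        g = narrow_geometry
        parent = traj([blob(0, 100, self.px(g, 0.6)),
                       blob(1, 100, self.px(g, 1.4))], tid=1)
        child = traj([blob(2, 100, self.px(g, 2.2)),
                      blob(3, 100, self.px(g, 3.7))], tid=2, parent=1)
        roi_filter([parent, child], self.ROI, g)
        assert child.qualified       # entry 0.6 mm via parent, exit 3.7 mm
        assert not parent.qualified  # parent never leaves the ROI


class TestFocalFilter:
    def test_exact_mode_keeps_in_focus(self):
        ts = [traj([blob(0, 0, 0), blob(1, 0, 10)], tid=i) for i in range(2)]
        kept = focal_filter(ts, mode="exact",
                            z_offsets_mm={0: 0.0, 1: 0.4})
        assert [t.trajectory_id for t in kept] == [0]

    def test_sharpness_band_keeps_near_reference(self):
        sharp = traj([blob(0, 0, 0, sharp=50.0), blob(1, 0, 10, sharp=52.0)], tid=0)
        blurry = traj([blob(0, 50, 0, sharp=12.0), blob(1, 50, 10, sharp=11.0)], tid=1)
        kept = focal_filter([sharp, blurry], sharpness_band=0.4)
        assert [t.trajectory_id for t in kept] == [0]

    def test_single_frame_sharpness_dip_tolerated(self):
        """A transient overlap or noise dip in one frame does not reject an
        otherwise in-focus trajectory (median rule)."""
        t = traj([blob(0, 0, 0, sharp=50.0), blob(1, 0, 10, sharp=8.0),
                  blob(2, 0, 20, sharp=51.0)], tid=0)
        assert focal_filter([t], sharpness_band=0.4,
                            reference_sharpness=50.0) == [t]

    def test_sharpness_vs_exact_agreement_on_synthetic(self, narrow_geometry):
        """The sharpness proxy reproduces the ground-truth +-0.25 mm focal
        band for >= 90% of trajectories."""
        ens = sample_ensemble(
            [GroupSpec("a", 1.0, 0.5, 3.0, 1.0, 1.0)],
            0.05, 120.0, narrow_geometry, seed=4,
            settings=EnsembleSettings(split_fraction=0.0, lateral_sd_mm=0.15))
        frames, truth = render_frames(ens, narrow_geometry,
                                      RenderSettings(rng_seed=4), duration_s=0.05)
        blobs = detect_stack(frames, narrow_geometry)
        trajs = link(blobs, narrow_geometry)
        trajs = [t for t in trajs if len(t) >= 2]
        assert len(trajs) >= 50
        # map each trajectory to the nearest ground-truth droplet's z
        tg = truth.groupby("frame")
        z_of = {}
        for t in trajs:
            o = t.observations[0]
            cand = tg.get_group(o.frame_index)
            d = np.hypot(cand.row_px - o.centroid[0], cand.col_px - o.centroid[1])
            z_of[t.trajectory_id] = float(cand.z_offset_mm[d.idxmin()])
        exact = {t.trajectory_id for t in focal_filter(
            trajs, mode="exact", z_offsets_mm=z_of)}
        sharp = {t.trajectory_id for t in focal_filter(trajs, sharpness_band=0.4)}
        agree = sum((t.trajectory_id in exact) == (t.trajectory_id in sharp)
                    for t in trajs)
        assert agree / len(trajs) >= 0.9


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

class TestImpactVelocity:
    def test_displacement_to_speed(self, narrow_geometry):
        t = traj([blob(0, 100.0, 50.0), blob(1, 100.0, 50.0 + 53.57)])
        assert impact_velocity(t, narrow_geometry) == pytest.approx(3.0, rel=5e-3)

    def test_zero_displacement(self, narrow_geometry):
        t = traj([blob(0, 100.0, 50.0), blob(1, 100.0, 50.0)])
        assert impact_velocity(t, narrow_geometry) == 0.0

    def test_250_px_is_14_m_s(self, narrow_geometry):
        t = traj([blob(0, 100.0, 50.0), blob(1, 100.0, 300.0)])
        assert impact_velocity(t, narrow_geometry) == pytest.approx(14.0, rel=5e-3)

    def test_single_observation_rejected(self, narrow_geometry):
        with pytest.raises(ValueError):
            impact_velocity(traj([blob(0, 0, 0)]), narrow_geometry)

    def test_roi_clip_uses_last_two_inside_the_band(self, narrow_geometry):
        g = narrow_geometry
        obs = [blob(0, 100, g.px_from_axial_mm(3.0)),
               blob(1, 100, g.px_from_axial_mm(3.3)),
               blob(2, 100, g.px_from_axial_mm(3.9))]
        t = traj(obs)
        roi = RoiBounds(1.0, 3.5)
        # unclipped: 0.6 mm/frame = 6 m/s; clipped: 0.3 mm/frame = 3 m/s
        assert impact_velocity(t, g) == pytest.approx(6.0, rel=1e-2)
        assert impact_velocity(t, g, clip_roi=roi) == pytest.approx(3.0, rel=1e-2)


class TestMakeRecord:
    MODEL = VolumeModel(5.6095)

    def test_volume_from_first_observation(self, narrow_geometry):
        t = traj([blob(0, 100, 50, area=385, extent=22),
                  blob(1, 100, 103.57, area=385, extent=22)], qualified=True)
        rec = make_record(t, narrow_geometry, self.MODEL)
        assert rec is not None
        assert rec.volume_nl == pytest.approx(1.0, rel=0.15)
        assert rec.velocity_m_s == pytest.approx(3.0, rel=1e-2)

    def test_too_fast_record_dropped(self, narrow_geometry):
        # 375 px/frame -> 21 m/s, above the 20 m/s trackable maximum
        t = traj([blob(0, 100, 50, area=385, extent=22),
                  blob(1, 100, 425, area=385, extent=22)], qualified=True)
        assert make_record(t, narrow_geometry, self.MODEL) is None

    def test_too_small_record_dropped(self, narrow_geometry):
        # a 9-ish px blob is ~3 pl, below the 4.2 pl floor
        t = traj([blob(0, 100, 50, area=8, extent=3),
                  blob(1, 100, 80, area=8, extent=3)], qualified=True)
        assert make_record(t, narrow_geometry, self.MODEL) is None

    def test_unqualified_rejected(self, narrow_geometry):
        t = traj([blob(0, 0, 0), blob(1, 0, 10)])
        with pytest.raises(ValueError):
            make_record(t, narrow_geometry, self.MODEL)

    def test_fabricated_impact_velocity_dropped(self, narrow_geometry):
        """A slow trajectory whose final link jumps far (a mislink) is
        rejected by the velocity-consistency check."""
        obs = [blob(f, 100, 50.0 + 30 * f, area=100, extent=11)
               for f in range(6)]
        obs.append(blob(6, 100, 50.0 + 30 * 5 + 200, area=100, extent=11))
        t = traj(obs, qualified=True)
        assert make_record(t, narrow_geometry, self.MODEL) is None
        assert make_record(t, narrow_geometry, self.MODEL,
                           velocity_consistency=None) is not None

    def test_merged_entry_falls_back_to_consistent_observation(self, narrow_geometry):
        """A first observation inflated by an overlapping droplet is
        replaced by the earliest area-consistent observation."""
        obs = [blob(0, 100, 50, area=800, extent=30)] + \
              [blob(f, 100, 50.0 + 30 * f, area=385, extent=22)
               for f in range(1, 6)]
        t = traj(obs, qualified=True)
        rec = make_record(t, narrow_geometry, self.MODEL)
        assert rec is not None
        assert rec.volume_nl == pytest.approx(1.0, rel=0.15)


class TestSyntheticRecovery:
    def _records_and_truth(self, narrow_geometry, seed):
        ens = sample_ensemble(
            [GroupSpec("a", 1.0, 0.4, 3.0, 1.0, 1.0)],
            0.05, 45.0, narrow_geometry, seed=seed,
            settings=EnsembleSettings(split_fraction=0.0, z_sd_mm=0.0,
                                      lateral_sd_mm=0.3),
            fractions_basis="evaluable")
        frames, truth = render_frames(ens, narrow_geometry,
                                      RenderSettings(rng_seed=seed),
                                      duration_s=0.05)
        blobs = detect_stack(frames, narrow_geometry)
        trajs = link(blobs, narrow_geometry)
        from spraymode import roi_from_geometry
        roi_filter(trajs, roi_from_geometry(narrow_geometry), narrow_geometry)
        return ens, truth, trajs

    def test_trajectory_count_and_velocity_recovery(self, narrow_geometry):
        """On split-free in-focus sequences the tracker recovers ~every
        droplet, and impact velocities match ground truth to < 10%
        median absolute relative error."""
        counts, errors = [], []
        for seed in (0, 1, 2):
            ens, truth, trajs = self._records_and_truth(narrow_geometry, seed)
            qualified = [t for t in trajs if t.qualified and len(t) >= 2]
            counts.append(len(qualified) / len(ens))
            tg = truth.groupby("frame")
            for t in qualified:
                o = t.observations[-1]
                cand = tg.get_group(o.frame_index)
                d = np.hypot(cand.row_px - o.centroid[0],
                             cand.col_px - o.centroid[1])
                true_v = float(cand.velocity_m_s[d.idxmin()])
                errors.append(abs(impact_velocity(t, narrow_geometry) - true_v)
                              / true_v)
        assert np.mean(counts) >= 0.95
        assert np.median(errors) < 0.10

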