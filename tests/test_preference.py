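"""Zone occupancy, SOP arithmetic, informed-choice window, arena SOP."""

import numpy as np
import pandas as pd
import pytest

from kinpref.preference import (
    STATE_INVALID,
    STATE_NEUTRAL,
    STATE_RELATED,
    STATE_UNRELATED,
    ZoneGeometry,
    ZoneOccupancy,
    arena_sop,
    compute_sop,
    default_interval_edges,
    informed_choice_window,
    interval_sop,
    zone_occupancy,
)
from kinpref.trajio import ChoiceTank, TrajectorySet, TrialDesign

TANK = ChoiceTank()
ZONES = ZoneGeometry.from_choice_tank(TANK)
FPS = 10.0


def choice_design(side=("related", "unrelated")):
    table = pd.DataFrame(
        {
            "family": ["famA", "famA", "famB"],
            "sex": ["female", "male", "male"],
            "mating_status": ["virgin", "experienced", "experienced"],
        },
        index=["focal", "rel", "unrel"],
    )
    return TrialDesign(
        individuals=table,
        focal_id="focal",
        stimulus_side={"left": side[0], "right": side[1]},
    )


def focal_traj(xys):
    pos = np.asarray(xys, dtype=float)[:, None, :]
    return TrajectorySet(pos, FPS, ["focal"], TANK)


LEFT = (TANK.main_x0 + 2.5, 12.0)
RIGHT = (TANK.main_x1 - 2.5, 12.0)
MID = (20.0, 12.0)


def occ_from(timeline):
    return ZoneOccupancy.from_timeline(np.asarray(timeline), FPS)


class TestZoneOccupancy:
    def test_parked_in_related_zone_whole_trial(self):
        n = int(1800 * FPS)
        traj = focal_traj([LEFT] * n)
        occ = zone_occupancy(traj, ZONES, choice_design())
        assert occ.t_related == pytest.approx(1800.0)
        assert occ.t_unrelated == 0.0
        assert compute_sop(occ).value == 1.0

    def test_mirrored_trajectory_with_swapped_sides_is_identical(self):
        xys = [LEFT, LEFT, MID, RIGHT, MID, LEFT]
        mirrored = [(TANK.width_cm - x, y) for x, y in xys]
        occ_a = zone_occupancy(focal_traj(xys), ZONES, choice_design())
        occ_b = zone_occupancy(
            focal_traj(mirrored), ZONES, choice_design(side=("unrelated", "related"))
        )
        assert occ_a.t_related == occ_b.t_related
        assert occ_a.t_unrelated == occ_b.t_unrelated
        np.testing.assert_array_equal(occ_a.timeline, occ_b.timeline)

    def test_out_of_tank_centroid_flagged_invalid(self):
        xys = [LEFT, (120.0, 12.0), MID]
        traj = TrajectorySet(
            np.asarray(xys, dtype=float)[:, None, :], FPS, ["focal"], TANK
        )
        occ = zone_occupancy(traj, ZONES, choice_design())
        assert occ.timeline[1] == STATE_INVALID
        assert occ.valid_frames == 2

    def test_zone_membership_boundaries(self):
        # outer edge (wall shared with the stimulus compartment) inclusive,
        # inner edge half-open against the neutral region
        side = ZONES.side_of(np.array([[TANK.main_x0, 5.0]]))
        assert side[0] == 0
        inner = ZONES.side_of(np.array([[TANK.main_x0 + 5.0, 5.0]]))
        assert inner[0] == STATE_NEUTRAL
        right_wall = ZONES.side_of(np.array([[TANK.main_x1, 5.0]]))
        assert right_wall[0] == 1

    def test_missing_stimulus_side_rejected(self):
        design = choice_design()
        design.stimulus_side = None
        with pytest.raises(ValueError):
            zone_occupancy(focal_traj([MID]), ZONES, design)


class TestComputeSOP:
    def test_equal_times_give_zero(self):
        occ = occ_from([STATE_RELATED] * 5 + [STATE_UNRELATED] * 5)
        assert compute_sop(occ).value == 0.0

    def test_fifteen_vs_five_minutes_gives_half(self):
        occ = ZoneOccupancy(
            t_related=15 * 60.0,
            t_unrelated=5 * 60.0,
            t_neutral=10 * 60.0,
            first_entry_related=0,
            first_entry_unrelated=100,
            trial_duration_s=1800.0,
            valid_frames=18000,
            frame_rate=FPS,
        )
        assert compute_sop(occ).value == pytest.approx(0.5)

    def test_no_zone_time_is_undefined_flagged(self):
        occ = occ_from([STATE_NEUTRAL] * 10)
        score = compute_sop(occ)
        assert not score.defined
        assert np.isnan(score.value)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            ZoneOccupancy(
                t_related=-1.0,
                t_unrelated=0.0,
                t_neutral=0.0,
                first_entry_related=None,
                first_entry_unrelated=None,
                trial_duration_s=10.0,
                valid_frames=0,
                frame_rate=FPS,
            )

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            timeline = rng.choice(3, size=200, p=[0.4, 0.3, 0.3])
            occ = occ_from(timeline)
            swapped = timeline.copy()
            swapped[timeline == STATE_RELATED] = STATE_UNRELATED
            swapped[timeline == STATE_UNRELATED] = STATE_RELATED
            s1, s2 = compute_sop(occ), compute_sop(occ_from(swapped))
            assert s1.value == pytest.approx(-s2.value)


class TestInformedChoice:
    def test_window_starts_at_later_first_entry(self):
        timeline = np.full(1000, STATE_NEUTRAL)
        timeline[100] = STATE_RELATED
        timeline[500] = STATE_UNRELATED
        timeline[600:] = STATE_RELATED
        occ = occ_from(timeline)
        win, usable = informed_choice_window(occ, min_window_s=10.0)
        assert usable
        assert len(win.timeline) == 500  # frames 500..999
        assert win.t_unrelated == pytest.approx(1 / FPS)

    def test_unvisited_zone_flags_trial(self):
        timeline = np.full(1000, STATE_NEUTRAL)
        timeline[100:200] = STATE_RELATED
        win, usable = informed_choice_window(occ_from(timeline))
        assert not usable and win is None

    def test_too_late_second_entry_flags_trial(self):
        timeline = np.full(1000, STATE_NEUTRAL)
        timeline[0] = STATE_RELATED
        timeline[995] = STATE_UNRELATED
        win, usable = informed_choice_window(occ_from(timeline), min_window_s=60.0)
        assert not usable

    def test_window_independent_of_pre_window_occupancy(self):
        rng = np.random.default_rng(11)
        post = rng.choice(3, size=500)
        post[0] = STATE_UNRELATED  # first unrelated-zone visit anchors the window
        expected = compute_sop(occ_from(post)).value
        for _ in range(5):
            # pre-window occupancy varies freely over related/neutral states
            pre = rng.choice([STATE_RELATED, STATE_NEUTRAL], size=300)
            pre[0] = STATE_RELATED
            occ = occ_from(np.concatenate([pre, post]))
            win, usable = informed_choice_window(occ, min_window_s=10.0)
            assert usable
            assert compute_sop(win).value == pytest.approx(expected)


class TestIntervalSOP:
    def test_single_interval_equals_total(self):
        rng = np.random.default_rng(8)
        timeline = rng.choice(3, size=600)
        occ = occ_from(timeline)
        total = compute_sop(occ)
        scores = interval_sop(occ, [0.0, occ.trial_duration_s])
        assert scores[0].value == pytest.approx(total.value)

    def test_opposed_intervals(self):
        timeline = np.array([STATE_RELATED] * 100 + [STATE_UNRELATED] * 100)
        occ = occ_from(timeline)
        scores = interval_sop(occ, [0.0, 10.0, 20.0])
        assert scores[0].value == 1.0
        assert scores[1].value == -1.0

    def test_occupancy_concatenation_conserved(self):
        rng = np.random.default_rng(21)
        timeline = rng.choice(3, size=900)
        occ = occ_from(timeline)
        edges = default_interval_edges(occ.trial_duration_s, 3)
        parts = [
            ZoneOccupancy.from_timeline(
                timeline[int(a * FPS) : int(b * FPS)], FPS
            )
            for a, b in zip(edges, edges[1:])
        ]
        assert sum(p.t_related for p in parts) == pytest.approx(occ.t_related)
        assert sum(p.t_unrelated for p in parts) == pytest.approx(occ.t_unrelated)

    def test_empty_zone_interval_is_undefined(self):
        timeline = np.array([STATE_NEUTRAL] * 100 + [STATE_RELATED] * 100)
        scores = interval_sop(occ_from(timeline), [0.0, 10.0, 20.0])
        assert not scores[0].defined
        assert scores[1].value == 1.0

    def test_bad_edges_rejected(self):
        occ = occ_from([STATE_RELATED] * 100)
        with pytest.raises(ValueError):
            interval_sop(occ, [0.0])
        with pytest.raises(ValueError):
            interval_sop(occ, [0.0, 100.0])


def arena_assoc_table(durations):
    rows = []
    for (a, b), dur in durations.items():
        rows.append(
            {
                "arena_id": "a0",
                "id_a": a,
                "id_b": b,
                "association_duration_s": dur,
            }
        )
    return pd.DataFrame(rows)


def mixed_design():
    rows = []
    for fam, tag in (("famA", "a"), ("famB", "b")):
        for k, sex in enumerate(["female", "female", "male", "male"]):
            rows.append(
                {
                    "individual_id": f"{tag}{k}",
                    "family": fam,
                    "sex": sex,
                    "mating_status": "virgin" if k % 2 == 0 else "experienced",
                }
            )
    return TrialDesign(
        individuals=pd.DataFrame(rows).set_index("individual_id"), arena_id="a0"
    )


def same_sex_design():
    rows = []
    k = 0
    for fam in ("famA", "famB", "famC", "famD"):
        for _ in range(2):
            rows.append(
                {
                    "individual_id": f"s{k}",
                    "family": fam,
                    "sex": "female",
                    "mating_status": "virgin",
                }
            )
            k += 1
    return TrialDesign(
        individuals=pd.DataFrame(rows).set_index("individual_id"), arena_id="a0"
    )


class TestArenaSOP:
    def test_balanced_association_gives_zero(self):
        design = mixed_design()
        # focal a0 (female, famA): related males a2, a3; unrelated b2, b3
        durations = {("a0", m): 120.0 for m in ("a2", "a3", "b2", "b3")}
        score = arena_sop(arena_assoc_table(durations), "a0", design, "mixed-sex")
        assert score.value == 0.0
        assert score.basis == "arena-association"

    def test_sibling_only_association_is_plus_one(self):
        design = same_sex_design()
        durations = {("s0", f"s{k}"): 0.0 for k in range(1, 8)}
        durations[("s0", "s1")] = 300.0
        score = arena_sop(arena_assoc_table(durations), "s0", design, "same-sex")
        assert score.value == 1.0

    def test_uniform_association_exposes_one_vs_six_asymmetry(self):
        design = same_sex_design()
        durations = {("s0", f"s{k}"): 60.0 for k in range(1, 8)}
        score = arena_sop(arena_assoc_table(durations), "s0", design, "same-sex")
        assert score.value == pytest.approx(-5.0 / 7.0)

    def test_per_capita_variant_removes_asymmetry(self):
        design = same_sex_design()
        durations = {("s0", f"s{k}"): 60.0 for k in range(1, 8)}
        score = arena_sop(
            arena_assoc_table(durations), "s0", design, "same-sex", per_capita=True
        )
        assert score.value == pytest.approx(0.0)

    def test_no_association_is_undefined(self):
        design = same_sex_design()
        durations = {("s0", f"s{k}"): 0.0 for k in range(1, 8)}
        score = arena_sop(arena_assoc_table(durations), "s0", design, "same-sex")
        assert not score.defined

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            arena_sop(arena_assoc_table({}), "s0", same_sex_design(), "weird")
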