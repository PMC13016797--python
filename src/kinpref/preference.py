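"""Zone occupancy and strength-of-preference (SOP) scoring.

In a dichotomous-choice trial a focal fish swims in the main compartment of a
three-compartment tank; the 24 x 5 cm strips abutting the two stimulus
compartments are the *association zones*.  Time in the zone adjacent to the
related stimulus (``T_R``) versus the unrelated one (``T_UR``) gives the
strength of preference

    SOP = (T_R - T_UR) / (T_R + T_UR)

ranging from -1 (exclusive preference for the unrelated stimulus, i.e.
inbreeding avoidance) through 0 (no bias) to +1 (exclusive kin preference).
The same index applies to free-swimming arenas with association durations in
place of zone times.

Zone states are coded on an integer timeline: 0 = related zone,
1 = unrelated zone, 2 = neutral, -1 = invalid frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajio import ChoiceTank, TrajectorySet, TrialDesign

__all__ = [
    "STATE_RELATED",
    "STATE_UNRELATED",
    "STATE_NEUTRAL",
    "STATE_INVALID",
    "Rect",
    "ZoneGeometry",
    "ZoneOccupancy",
    "SOPScore",
    "zone_occupancy",
    "compute_sop",
    "informed_choice_window",
    "interval_sop",
    "arena_sop",
]

STATE_RELATED = 0
STATE_UNRELATED = 1
STATE_NEUTRAL = 2
STATE_INVALID = -1


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass(frozen=True)
class ZoneGeometry:
    """Left and right association zones inside the main compartment.

    Zone membership is centroid-based, inclusive on the zone's outer edge
    (the wall shared with the stimulus compartment) and half-open against the
    neutral region, so the two zones and the neutral region partition the
    main compartment.
    """

    left: Rect
    right: Rect

    def __post_init__(self) -> None:
        if self.left.x1 > self.right.x0:
            raise ValueError("association zones must be disjoint")

    @classmethod
    def from_choice_tank(cls, tank: ChoiceTank, zone_depth_cm: float = 5.0) -> "ZoneGeometry":
        return cls(
            left=Rect(tank.main_x0, 0.0, tank.main_x0 + zone_depth_cm, tank.depth_cm),
            right=Rect(tank.main_x1 - zone_depth_cm, 0.0, tank.main_x1, tank.depth_cm),
        )

    def side_of(self, xy: np.ndarray) -> np.ndarray:
        """Per-frame side codes: 0 = left zone, 1 = right zone, 2 = neutral."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        in_y = (y >= self.left.y0) & (y <= self.left.y1)
        in_left = (x >= self.left.x0) & (x < self.left.x1) & in_y
        in_right = (x > self.right.x0) & (x <= self.right.x1) & in_y
        out = np.full(x.shape, STATE_NEUTRAL, dtype=int)
        out[in_left] = 0
        out[in_right] = 1
        return out


@dataclass
class ZoneOccupancy:
    """Occupancy totals plus the full per-frame zone timeline for one trial."""

    t_related: float
    t_unrelated: float
    t_neutral: float
    first_entry_related: int | None
    first_entry_unrelated: int | None
    trial_duration_s: float
    valid_frames: int
    frame_rate: float
    timeline: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("t_related", "t_unrelated", "t_neutral"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_timeline(cls, timeline: np.ndarray, frame_rate: float) -> "ZoneOccupancy":
        timeline = np.asarray(timeline, dtype=int)
        n_r = int(np.sum(timeline == STATE_RELATED))
        n_u = int(np.sum(timeline == STATE_UNRELATED))
        n_n = int(np.sum(timeline == STATE_NEUTRAL))

        def first(code: int) -> int | None:
            idx = np.flatnonzero(timeline == code)
            return int(idx[0]) if len(idx) else None

        return cls(
            t_related=n_r / frame_rate,
            t_unrelated=n_u / frame_rate,
            t_neutral=n_n / frame_rate,
            first_entry_related=first(STATE_RELATED),
            first_entry_unrelated=first(STATE_UNRELATED),
            trial_duration_s=len(timeline) / frame_rate,
            valid_frames=n_r + n_u + n_n,
            frame_rate=frame_rate,
            timeline=timeline,
        )

    @property
    def t_zone(self) -> float:
        """Total time in either association zone (s)."""
        return self.t_related + self.t_unrelated

    @property
    def zone_fraction(self) -> float:
        return self.t_zone / self.trial_duration_s


@dataclass(frozen=True)
class SOPScore:
    """Strength of preference in [-1, 1]; ``value`` is NaN when undefined.

    Undefined scores (no zone/association time at all) are flagged and must
    be excluded listwise downstream, never coerced to zero.
    """

    value: float
    window: str = "total-trial"  # total-trial | informed-choice | interval
    basis: str = "dichotomous-zones"  # dichotomous-zones | arena-association
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"SOP {self.value} outside [-1, 1]")


def zone_occupancy(
    traj: TrajectorySet,
    zones: ZoneGeometry,
    design: TrialDesign,
    focal_id: str | None = None,
) -> ZoneOccupancy:
    """Classify each frame of the focal's trajectory into zone states.

    Side labels are mapped to related/unrelated via the trial's
    ``stimulus_side`` assignment.  Frames with a missing centroid, or one
    outside the tank beyond 2% tolerance, are flagged invalid and drop out of
    both numerator and denominator.
    """
    if design.stimulus_side is None:
        raise ValueError("design has no stimulus_side mapping")
    focal = focal_id or design.focal_id
    if focal is None:
        raise ValueError("no focal individual specified")
    j = traj.index_of(focal)
    xy = traj.positions[:, j, :]
    valid = np.isfinite(xy).all(axis=1)
    valid &= traj.geometry.contains(xy, tol_frac=0.02) | ~valid

    side = zones.side_of(xy)  # 0 left, 1 right, 2 neutral
    side_label = {0: "left", 1: "right"}
    timeline = np.full(len(xy), STATE_NEUTRAL, dtype=int)
    for code in (0, 1):
        rel = design.stimulus_side[side_label[code]]
        timeline[side == code] = STATE_RELATED if rel == "related" else STATE_UNRELATED
    timeline[~valid] = STATE_INVALID
    return ZoneOccupancy.from_timeline(timeline, traj.frame_rate)


def compute_sop(occ: ZoneOccupancy, window: str = "total-trial") -> SOPScore:
    """SOP = (T_R - T_UR) / (T_R + T_UR); undefined when both are zero."""
    t_r, t_u = occ.t_related, occ.t_unrelated
    if t_r < 0 or t_u < 0:
        raise ValueError("negative zone times")
    denom = t_r + t_u
    if denom == 0:
        return SOPScore(value=float("nan"), window=window, defined=False)
    return SOPScore(value=(t_r - t_u) / denom, window=window)


def informed_choice_window(
    occ: ZoneOccupancy, min_window_s: float = 60.0
) -> tuple[ZoneOccupancy | None, bool]:
    """Restrict occupancy to frames after both zones have been visited.

    Returns ``(windowed_occupancy, usable)``.  Trials where either zone is
    never entered, or where the window left after the later first entry is
    shorter than ``min_window_s``, are flagged unusable (``(None, False)``)
    rather than raising — mirroring per-trial exclusion, not failure.
    """
    if occ.timeline is None:
        raise ValueError("occupancy carries no timeline")
    fr, fu = occ.first_entry_related, occ.first_entry_unrelated
    if fr is None or fu is None:
        return None, False
    start = max(fr, fu)
    remaining = (len(occ.timeline) - start) / occ.frame_rate
    if remaining < min_window_s:
        return None, False
    return ZoneOccupancy.from_timeline(occ.timeline[start:], occ.frame_rate), True


def interval_sop(
    occ: ZoneOccupancy, edges_s: Sequence[float]
) -> list[SOPScore]:
    """SOP per interval ``[edges[k], edges[k+1])``; empty zone time => undefined."""
    if occ.timeline is None:
        raise ValueError("occupancy carries no timeline")
    edges = list(edges_s)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("interval edges must be strictly increasing, length >= 2")
    if edges[0] < 0 or edges[-1] > occ.trial_duration_s + 1e-9:
        raise ValueError("interval edges outside trial")
    out = []
    for a, b in zip(edges, edges[1:]):
        i0 = int(round(a * occ.frame_rate))
        i1 = int(round(b * occ.frame_rate))
        sub = ZoneOccupancy.from_timeline(occ.timeline[i0:i1], occ.frame_rate)
        out.append(compute_sop(sub, window="interval"))
    return out


def default_interval_edges(trial_duration_s: float, n_intervals: int = 3) -> list[float]:
    """Successive equal intervals (default: 10-min thirds of a 30-min trial)."""
    return [trial_duration_s * k / n_intervals for k in range(n_intervals + 1)]


def arena_sop(
    assoc: pd.DataFrame,
    focal: str,
    design: TrialDesign,
    experiment: str,
    per_capita: bool = False,
) -> SOPScore:
    """SOP from summed association durations in a free-swimming arena.

    ``experiment='mixed-sex'``: partners are the focal's opposite-sex
    arena-mates, split 2 related vs 2 unrelated.  ``experiment='same-sex'``:
    all 7 same-sex partners, split 1 related (the sibling) vs 6 unrelated.
    Durations are raw sums over each partner set; ``per_capita=True`` divides
    by the set size instead (off by default, so the 1-vs-6 asymmetry of the
    same-sex design is preserved).
    """
    if experiment not in {"mixed-sex", "same-sex"}:
        raise ValueError(f"unknown experiment {experiment!r}")
    table = design.individuals
    focal_sex = table.loc[focal, "sex"]
    partners = []
    for ind in design.ids:
        if ind == focal:
            continue
        if experiment == "mixed-sex" and table.loc[ind, "sex"] == focal_sex:
            continue
        if experiment == "same-sex" and table.loc[ind, "sex"] != focal_sex:
            continue
        partners.append(ind)
    related = [p for p in partners if design.related(focal, p)]
    unrelated = [p for p in partners if not design.related(focal, p)]
    if not related or not unrelated:
        raise ValueError("empty related or unrelated partner set for focal")

    def total(partner_set: list[str]) -> float:
        mask = (
            ((assoc["id_a"] == focal) & assoc["id_b"].isin(partner_set))
            | ((assoc["id_b"] == focal) & assoc["id_a"].isin(partner_set))
        )
        return float(assoc.loc[mask, "association_duration_s"].sum())

    t_r, t_u = total(related), total(unrelated)
    if per_capita:
        t_r /= len(related)
        t_u /= len(unrelated)
    if t_r + t_u == 0:
        return SOPScore(float("nan"), window="total-trial", basis="arena-association", defined=False)
    return SOPScore((t_r - t_u) / (t_r + t_u), window="total-trial", basis="arena-association")
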