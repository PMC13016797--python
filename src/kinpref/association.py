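"""Pairwise association detection from free-swimming trajectories.

Two fish are *associated* at a frame when their centroids are within a
threshold radius — two mean body lengths (2 x 1.76 cm = 3.52 cm) in the
study design, i.e. close enough to reflect active social or sexual
engagement rather than passive proximity.  Frame-wise Euclidean distance
matrices are thresholded and summed into per-dyad associated-frame counts
and durations, labelled with the dyad's relatedness, sex and mating-status
classes.

Boundary rule: distance exactly equal to the radius counts as associated
(``<=``), a measure-zero choice that keeps exact-geometry tests simple.
Frames where either member is missing are excluded from that dyad's
numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajio import TrajectorySet, TrialDesign

__all__ = [
    "AssociationThreshold",
    "derive_threshold",
    "frame_distance_matrix",
    "detect_associations",
    "dyad_census",
    "extract_bouts",
]

ASSOCIATION_COLUMNS = [
    "arena_id",
    "id_a",
    "id_b",
    "associated_frames",
    "valid_frames",
    "total_frames",
    "association_duration_s",
    "relatedness_class",
    "sex_class",
    "status_class",
]


@dataclass(frozen=True)
class AssociationThreshold:
    radius_cm: float
    basis: str = "fixed"  # fixed | body-length-multiple
    multiplier: float | None = None
    mean_body_length_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.radius_cm > 0:
            raise ValueError("radius must be positive")
        if self.basis == "body-length-multiple":
            if self.multiplier is None or self.mean_body_length_cm is None:
                raise ValueError("body-length-multiple basis needs multiplier and body length")
            expected = self.multiplier * self.mean_body_length_cm
            if abs(self.radius_cm - expected) > 1e-9:
                raise ValueError("radius != multiplier * mean_body_length")


def derive_threshold(mean_body_length_cm: float, multiplier: float = 2.0) -> AssociationThreshold:
    """Association radius as a multiple of mean body length (default 2)."""
    if not mean_body_length_cm > 0:
        raise ValueError("mean body length must be positive")
    if not multiplier > 0:
        raise ValueError("multiplier must be positive")
    return AssociationThreshold(
        radius_cm=multiplier * mean_body_length_cm,
        basis="body-length-multiple",
        multiplier=multiplier,
        mean_body_length_cm=mean_body_length_cm,
    )


def frame_distance_matrix(traj: TrajectorySet, frame: int) -> np.ndarray:
    """Symmetric Euclidean distance matrix (cm) at one frame.

    Rows/columns of a missing individual are NaN; the diagonal is 0 for
    present individuals.
    """
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
    xy = traj.positions[frame]
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    missing = ~np.isfinite(xy).all(axis=1)
    d[missing, :] = np.nan
    d[:, missing] = np.nan
    return d


def _pair_class(values: tuple[str, str], order: Sequence[str]) -> str:
    a, b = sorted(values, key=order.index)
    return f"{a}-{b}"


def detect_associations(
    traj: TrajectorySet, thr: AssociationThreshold, design: TrialDesign
) -> pd.DataFrame:
    """Per-dyad association totals for one arena trial.

    Returns one row per unordered dyad with associated-frame counts,
    valid-frame counts (both members present), the duration in seconds, and
    the dyad's relatedness / sex / mating-status classes from the design.
    """
    ids = traj.individual_ids
    if set(ids) != set(design.ids):
        extra = sorted(set(ids) ^ set(design.ids))
        raise ValueError(f"trajectory/design individual mismatch: {extra}")
    pos = traj.positions
    valid = traj.valid_mask()
    table = design.individuals

    rows = []
    for i, j in combinations(range(len(ids)), 2):
        both = valid[:, i] & valid[:, j]
        diff = pos[:, i, :] - pos[:, j, :]
        dist = np.hypot(diff[:, 0], diff[:, 1])
        assoc = int(np.sum(both & (dist <= thr.radius_cm)))
        a, b = ids[i], ids[j]
        rows.append(
            {
                "arena_id": design.arena_id,
                "id_a": a,
                "id_b": b,
                "associated_frames": assoc,
                "valid_frames": int(both.sum()),
                "total_frames": traj.n_frames,
                "association_duration_s": assoc / traj.frame_rate,
                "relatedness_class": "related" if design.related(a, b) else "unrelated",
                "sex_class": _pair_class(
                    (table.loc[a, "sex"], table.loc[b, "sex"]), ("female", "male")
                ),
                "status_class": _pair_class(
                    (table.loc[a, "mating_status"], table.loc[b, "mating_status"]),
                    ("virgin", "experienced"),
                ),
            }
        )
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def dyad_census(
    designs: TrialDesign | Iterable[TrialDesign], subset: str = "all"
) -> int:
    """Number of unordered dyads in a subset, summed over arenas.

    ``subset`` is one of ``all``, ``opposite-sex``, ``same-sex``.
    """
    if subset not in {"all", "opposite-sex", "same-sex"}:
        raise ValueError(f"unknown subset {subset!r}")
    if isinstance(designs, TrialDesign):
        designs = [designs]
    total = 0
    for d in designs:
        sexes = d.individuals["sex"]
        for a, b in combinations(d.ids, 2):
            same = sexes.loc[a] == sexes.loc[b]
            if subset == "all" or (subset == "same-sex") == same:
                total += 1
    return total


def extract_bouts(
    associated: np.ndarray, min_frames: int = 1, merge_gap_frames: int = 0
) -> list[tuple[int, int]]:
    """Contiguous association bouts as half-open frame ranges.

    Off by default in the analysis (every qualifying frame counts on its
    own); provided for bout-level summaries.  Gaps of at most
    ``merge_gap_frames`` non-associated frames are bridged first, then bouts
    shorter than ``min_frames`` are dropped.
    """
    x = np.asarray(associated, dtype=bool).copy()
    if merge_gap_frames > 0:
        idx = np.flatnonzero(x)
        for a, b in zip(idx, idx[1:]):
            if 1 < b - a <= merge_gap_frames + 1:
                x[a:b] = True
    bouts = []
    i = 0
    n = len(x)
    while i < n:
        if not x[i]:
            i += 1
            continue
        j = i
        while j < n and x[j]:
            j += 1
        if j - i >= min_frames:
            bouts.append((i, j))
        i = j
    return bouts
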