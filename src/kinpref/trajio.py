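"""Trajectory and trial-metadata ingestion.

Multi-animal trackers emit one centroid per individual per video frame, in
pixel coordinates.  This module turns those tables into calibrated
:class:`TrajectorySet` arrays (cm, frame-indexed), validates them against the
arena geometry, repairs short tracking gaps, and carries the per-trial design
metadata (family structure, sex, mating status, stimulus-side assignment,
body measurements) that every downstream stage keys on.

Conventions: the coordinate origin is the tank's lower-left corner for the
rectangular choice tank and the arena centre for circular arenas; frames are
0-based and frame ``k`` covers the half-open interval ``[k/fps, (k+1)/fps)``
seconds.  Trajectories are in cm; body measurements stay in mm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircularArena",
    "ChoiceTank",
    "TrajectorySet",
    "TrialDesign",
    "GapPolicy",
    "GapRepairReport",
    "read_trajectories",
    "read_trajectories_wide",
    "read_trial_design",
    "write_trajectories",
    "repair_gaps",
    "trait_differences",
]

TRAIT_COLUMNS = ("body_length_mm", "body_area_mm2", "orange_area_mm2")


@dataclass(frozen=True)
class CircularArena:
    """Cylindrical free-swimming arena, origin at the centre."""

    radius_cm: float
    center: tuple[float, float] = (0.0, 0.0)

    def contains(self, xy: np.ndarray, tol_frac: float = 0.02) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        d = np.hypot(xy[..., 0] - self.center[0], xy[..., 1] - self.center[1])
        return d <= self.radius_cm * (1.0 + tol_frac)


@dataclass(frozen=True)
class ChoiceTank:
    """Three-compartment dichotomous-choice tank (origin: lower-left corner).

    The main compartment sits between two stimulus compartments; thin
    barriers take up the residual width.  Default dimensions follow the
    40 x 24 cm footprint with a 27 cm main compartment and 6 cm stimulus
    compartments.
    """

    width_cm: float = 40.0
    depth_cm: float = 24.0
    main_width_cm: float = 27.0
    stimulus_width_cm: float = 6.0

    @property
    def main_x0(self) -> float:
        gap = (self.width_cm - self.main_width_cm - 2 * self.stimulus_width_cm) / 2.0
        return self.stimulus_width_cm + gap

    @property
    def main_x1(self) -> float:
        return self.main_x0 + self.main_width_cm

    def contains(self, xy: np.ndarray, tol_frac: float = 0.02) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        tx = self.width_cm * tol_frac
        ty = self.depth_cm * tol_frac
        return (
            (xy[..., 0] >= -tx)
            & (xy[..., 0] <= self.width_cm + tx)
            & (xy[..., 1] >= -ty)
            & (xy[..., 1] <= self.depth_cm + ty)
        )


Geometry = CircularArena | ChoiceTank


@dataclass
class TrajectorySet:
    """Calibrated per-frame centroid positions for one trial.

    ``positions`` has shape ``(n_frames, n_individuals, 2)`` in cm with NaN
    marking frames where the tracker lost an individual.
    """

    positions: np.ndarray
    frame_rate: float
    individual_ids: list[str]
    geometry: Geometry
    calibration_px_per_cm: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError(
                f"positions must be (n_frames, n_individuals, 2), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.individual_ids):
            raise ValueError("individual_ids length does not match positions")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.calibration_px_per_cm > 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual {individual_id!r}") from None

    def valid_mask(self) -> np.ndarray:
        """(n_frames, n_individuals) boolean: both coordinates finite."""
        return np.isfinite(self.positions).all(axis=2)


@dataclass
class TrialDesign:
    """Per-trial metadata: who is in the trial and how they relate.

    ``individuals`` is a DataFrame indexed by individual id with columns
    ``family``, ``sex`` ('female'/'male'), ``mating_status``
    ('virgin'/'experienced') and optional trait columns (mm / mm^2):
    ``body_length_mm``, ``body_area_mm2``, ``orange_area_mm2``.

    Two individuals are related (full siblings, r ~ 0.5) iff they share a
    family; otherwise unrelated (r ~ 0).
    """

    individuals: pd.DataFrame
    arena_id: str | None = None
    focal_id: str | None = None
    stimulus_side: Mapping[str, str] | None = None  # {'left'/'right': 'related'/'unrelated'}
    breach_flag: bool = False

    def __post_init__(self) -> None:
        req = {"family", "sex", "mating_status"}
        missing = req - set(self.individuals.columns)
        if missing:
            raise ValueError(f"individuals table missing columns {sorted(missing)}")
        bad_sex = set(self.individuals["sex"]) - {"female", "male"}
        if bad_sex:
            raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
        bad_status = set(self.individuals["mating_status"]) - {"virgin", "experienced"}
        if bad_status:
            raise ValueError(f"unknown mating_status labels {sorted(bad_status)}")
        if self.stimulus_side is not None:
            sides = dict(self.stimulus_side)
            if set(sides) != {"left", "right"} or set(sides.values()) != {
                "related",
                "unrelated",
            }:
                raise ValueError(
                    "stimulus_side must map {'left','right'} onto {'related','unrelated'}"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.individuals.index)

    def related(self, a: str, b: str) -> bool:
        fam = self.individuals["family"]
        return bool(fam.loc[a] == fam.loc[b]) and a != b

    def relatedness(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return 0.5 if self.related(a, b) else 0.0

    def relatedness_matrix(self) -> pd.DataFrame:
        ids = self.ids
        fam = self.individuals["family"].to_numpy()
        mat = np.where(fam[:, None] == fam[None, :], 0.5, 0.0)
        np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=ids, columns=ids)

    def stimulus_ids(self) -> dict[str, str]:
        """For a choice trial: map 'related'/'unrelated' to the stimulus id."""
        if self.focal_id is None:
            raise ValueError("design has no focal individual")
        fam = self.individuals["family"]
        out: dict[str, str] = {}
        for ind in self.ids:
            if ind == self.focal_id:
                continue
            key = "related" if fam.loc[ind] == fam.loc[self.focal_id] else "unrelated"
            if key in out:
                raise ValueError(f"more than one {key} stimulus in design")
            out[key] = ind
        if set(out) != {"related", "unrelated"}:
            raise ValueError("choice design needs exactly one related and one unrelated stimulus")
        return out


@dataclass(frozen=True)
class GapPolicy:
    """How to treat tracker dropouts.

    Runs of missing frames no longer than ``max_interp_frames`` are filled by
    per-coordinate linear interpolation; longer runs stay missing and the
    affected frames are excluded from zone and dyadic computations
    (numerator and denominator alike).
    """

    max_interp_frames: int = 5
    action_beyond: str = "drop-frame-for-individual"

    def __post_init__(self) -> None:
        if self.max_interp_frames < 0:
            raise ValueError("max_interp_frames must be >= 0")
        if self.action_beyond not in {"drop-frame-for-individual", "drop-frame-for-dyad"}:
            raise ValueError(f"unknown action_beyond {self.action_beyond!r}")


@dataclass
class GapRepairReport:
    interpolated: dict[str, int] = field(default_factory=dict)
    flagged: dict[str, int] = field(default_factory=dict)

    @property
    def total_interpolated(self) -> int:
        return sum(self.interpolated.values())

    @property
    def total_flagged(self) -> int:
        return sum(self.flagged.values())

    def is_empty(self) -> bool:
        return self.total_interpolated == 0 and self.total_flagged == 0


def read_trajectories(
    source: pd.DataFrame | str | Path,
    *,
    calibration_px_per_cm: float,
    frame_rate: float,
    geometry: Geometry,
    containment_tol: float = 0.02,
) -> TrajectorySet:
    """Build a calibrated :class:`TrajectorySet` from a long-form table.

    The table dialect is ``frame, individual_id, x_px, y_px`` (comma
    separated, empty fields = missing position).  Every individual must have
    exactly one record per frame; frames must be the contiguous integers
    ``0..n_frames-1``.
    """
    if not calibration_px_per_cm > 0:
        raise ValueError("calibration must be positive")
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, comment="#")
    else:
        df = source.copy()
    req = {"frame", "individual_id", "x_px", "y_px"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")

    dup = df.duplicated(subset=["frame", "individual_id"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["frame", "individual_id"]].drop_duplicates()
        first = bad.iloc[0]
        raise ValueError(
            f"duplicate (frame, individual) records, first at frame "
            f"{int(first['frame'])} individual {first['individual_id']!r}"
        )

    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, frames.astype(int)):
        raise ValueError("frame index must be integer")
    df = df.assign(frame=frames.astype(int))
    ids = sorted(df["individual_id"].astype(str).unique())
    uniq = np.sort(df["frame"].unique())
    n_frames = len(uniq)
    expected = np.arange(n_frames)
    if not np.array_equal(uniq, expected):
        off = uniq[uniq != expected[: len(uniq)]] if len(uniq) else uniq
        first_bad = int(off[0]) if len(off) else int(uniq[0])
        raise ValueError(f"frame index not contiguous from 0; offending frame {first_bad}")
    counts = df.groupby("individual_id")["frame"].count()
    ragged = counts[counts != n_frames]
    if len(ragged):
        ind = ragged.index[0]
        have = set(df.loc[df["individual_id"] == ind, "frame"])
        miss = sorted(set(range(n_frames)) - have)
        raise ValueError(
            f"ragged table: individual {ind!r} lacks a record for frame {miss[0]}"
        )

    pos = np.full((n_frames, len(ids), 2), np.nan)
    for j, ind in enumerate(ids):
        sub = df[df["individual_id"].astype(str) == ind].sort_values("frame")
        pos[:, j, 0] = sub["x_px"].to_numpy(dtype=float)
        pos[:, j, 1] = sub["y_px"].to_numpy(dtype=float)
    pos /= calibration_px_per_cm

    traj = TrajectorySet(
        positions=pos,
        frame_rate=frame_rate,
        individual_ids=ids,
        geometry=geometry,
        calibration_px_per_cm=calibration_px_per_cm,
    )
    valid = traj.valid_mask()
    inside = geometry.contains(pos, tol_frac=containment_tol)
    bad = valid & ~inside
    if bad.any():
        f, i = np.argwhere(bad)[0]
        raise ValueError(
            f"position outside arena geometry beyond {containment_tol:.0%} tolerance "
            f"at frame {int(f)}, individual {ids[int(i)]!r}"
        )
    return traj


def read_trajectories_wide(
    source: pd.DataFrame | str | Path,
    *,
    calibration_px_per_cm: float,
    frame_rate: float,
    geometry: Geometry,
    containment_tol: float = 0.02,
) -> TrajectorySet:
    """Read the wide per-frame dialect: ``frame, <id>_x, <id>_y, ...``.

    Column pairs ``<id>_x`` / ``<id>_y`` (pixel units) define the individual
    set; validation and calibration follow :func:`read_trajectories`.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, comment="#")
    else:
        df = source.copy()
    if "frame" not in df.columns:
        raise ValueError("wide trajectory table needs a 'frame' column")
    ids = sorted(
        c[:-2] for c in df.columns if c.endswith("_x") and f"{c[:-2]}_y" in df.columns
    )
    if not ids:
        raise ValueError("no <id>_x / <id>_y column pairs found")
    long = df.melt(id_vars="frame", var_name="col", value_name="v")
    long["individual_id"] = long["col"].str[:-2]
    long["axis"] = long["col"].str[-1]
    long = long[long["individual_id"].isin(ids)]
    wide = long.pivot_table(
        index=["frame", "individual_id"], columns="axis", values="v", dropna=False
    ).reset_index()
    wide = wide.rename(columns={"x": "x_px", "y": "y_px"})
    return read_trajectories(
        wide[["frame", "individual_id", "x_px", "y_px"]],
        calibration_px_per_cm=calibration_px_per_cm,
        frame_rate=frame_rate,
        geometry=geometry,
        containment_tol=containment_tol,
    )


def read_trial_design(path: str | Path, **kwargs) -> TrialDesign:
    """Read a per-trial metadata table (one row per individual).

    The CSV must carry ``individual_id`` plus the TrialDesign columns
    (``family``, ``sex``, ``mating_status`` and optional traits); extra
    keyword arguments (``focal_id``, ``arena_id``, ``stimulus_side``) pass
    through to :class:`TrialDesign`, whose validation is strict.
    """
    table = pd.read_csv(path, comment="#")
    if "individual_id" not in table.columns:
        raise ValueError("design table needs an 'individual_id' column")
    return TrialDesign(individuals=table.set_index("individual_id"), **kwargs)


def write_trajectories(traj: TrajectorySet, path: str | Path | None = None) -> str | None:
    """Write a TrajectorySet in the long-form dialect (positions in px).

    Inverse of :func:`read_trajectories` under the stored calibration; if
    ``path`` is None the CSV text is returned.
    """
    n_frames, n_ind, _ = traj.positions.shape
    px = traj.positions * traj.calibration_px_per_cm
    frames = np.repeat(np.arange(n_frames), n_ind)
    inds = np.tile(np.asarray(traj.individual_ids, dtype=object), n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "individual_id": inds,
            "x_px": px[:, :, 0].ravel(),
            "y_px": px[:, :, 1].ravel(),
        }
    )
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(path, index=False)
    return None


def _fill_runs(x: np.ndarray, max_len: int) -> tuple[np.ndarray, int, int]:
    """Linear-interpolate NaN runs of length <= max_len with valid endpoints.

    Returns (filled, n_interpolated, n_flagged)."""
    x = x.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x, 0, 0
    n = len(x)
    n_interp = 0
    n_flag = 0
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= max_len:
            x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
            n_interp += run
        else:
            n_flag += run
        i = j
    return x, n_interp, n_flag


def repair_gaps(
    traj: TrajectorySet, policy: GapPolicy = GapPolicy()
) -> tuple[TrajectorySet, GapRepairReport]:
    """Fill short tracking gaps by linear interpolation; flag long ones.

    Idempotent: a second pass is a no-op.  Gaps touching the first or last
    frame are never filled (no endpoint to interpolate from).
    """
    pos = traj.positions.copy()
    report = GapRepairReport()
    for j, ind in enumerate(traj.individual_ids):
        total_i = 0
        total_f = 0
        # a frame is a gap if either coordinate is missing; fill both together
        missing = ~np.isfinite(pos[:, j, :]).all(axis=1)
        pos[missing, j, :] = np.nan
        for c in range(2):
            filled, n_i, n_f = _fill_runs(pos[:, j, c], policy.max_interp_frames)
            pos[:, j, c] = filled
            if c == 0:
                total_i, total_f = n_i, n_f
        if total_i:
            report.interpolated[ind] = total_i
        if total_f:
            report.flagged[ind] = total_f
    out = replace(traj, positions=pos)
    return out, report


def trait_differences(design: TrialDesign) -> pd.Series:
    """Related-stimulus trait minus unrelated-stimulus trait, per trait.

    Positive values mean the related stimulus is larger.  Traits missing for
    either stimulus yield NaN (never silently zero).
    """
    stim = design.stimulus_ids()
    table = design.individuals
    out = {}
    for col in TRAIT_COLUMNS:
        if col not in table.columns:
            out[col] = np.nan
            continue
        r = table.loc[stim["related"], col]
        u = table.loc[stim["unrelated"], col]
        out[col] = float(r - u) if pd.notna(r) and pd.notna(u) else np.nan
    return pd.Series(out, name="trait_difference")


def trait_difference_table(designs: Iterable[TrialDesign]) -> pd.DataFrame:
    """Stack :func:`trait_differences` over a cohort of choice trials."""
    rows = []
    for d in designs:
        s = trait_differences(d)
        s["focal_id"] = d.focal_id
        rows.append(s)
    return pd.DataFrame(rows).set_index("focal_id")
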