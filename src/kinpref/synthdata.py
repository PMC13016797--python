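"""Synthetic trials with the statistical structure the analysis assumes.

Three generators stand in for the study's raw recordings:

* a three-state Markov chain (related zone / unrelated zone / neutral) for
  the focal's zone occupancy in a dichotomous-choice trial — only occupancy
  totals and visit order feed the analysis, so no mechanistic swimming is
  modelled; the expected SOP of a generated trial is ``2 * bias_b - 1`` by
  construction;
* a biased correlated random walk in a circular arena for multi-individual
  free-swimming trajectories, with a signed pairwise attraction matrix
  entering the heading update as a normalized weighted resultant;
* overdispersed (negative binomial) behaviour counts per
  arena x mating-status x relatedness cell with log-linear effects and an
  arena-level random intercept.

All generators take explicit integer seeds; one master seed spawns
per-trial streams deterministically via :func:`spawn_seeds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preference import (
    STATE_NEUTRAL,
    STATE_RELATED,
    STATE_UNRELATED,
    ZoneOccupancy,
)
from .trajio import CircularArena, TrajectorySet

__all__ = [
    "ZoneSimParams",
    "ArenaSimParams",
    "BehaviorSimParams",
    "simulate_zone_trial",
    "simulate_arena",
    "simulate_behavior_counts",
    "simulate_behavior_events",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class ZoneSimParams:
    """Parameters of the zone-occupancy chain.

    ``p_zone`` is the stationary probability of being in either association
    zone; ``bias_b`` is the related-zone share of zone time (0.5 = no
    preference); ``switch_rate`` is the expected number of state switches
    per minute.
    """

    trial_duration: float = 1800.0  # s
    frame_rate: float = 10.0  # frames/s
    p_zone: float = 0.68
    bias_b: float = 0.5
    switch_rate: float = 2.0  # switches / min
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trial_duration", "frame_rate", "p_zone", "bias_b", "switch_rate"):
            _check_finite(name, getattr(self, name))
        if not 0.0 <= self.p_zone <= 1.0:
            raise ValueError(f"p_zone must be in [0, 1], got {self.p_zone}")
        if not 0.0 <= self.bias_b <= 1.0:
            raise ValueError(f"bias_b must be in [0, 1], got {self.bias_b}")
        if not self.trial_duration > 0:
            raise ValueError("trial_duration must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution over (related, unrelated, neutral)."""
        return np.array(
            [
                self.p_zone * self.bias_b,
                self.p_zone * (1.0 - self.bias_b),
                1.0 - self.p_zone,
            ]
        )


def simulate_zone_trial(params: ZoneSimParams) -> tuple[ZoneOccupancy, np.ndarray]:
    """Sample one dichotomous-choice trial as a 3-state Markov chain.

    The chain redraws its state from the stationary distribution with a
    per-frame probability calibrated so the expected switch count matches
    ``switch_rate``; between redraws the state is held.  The stationary
    distribution therefore holds exactly at every frame, including frame 0.
    Returns the occupancy summary and the full state timeline
    (0 = related zone, 1 = unrelated zone, 2 = neutral).
    """
    pi = params.stationary
    n_frames = int(round(params.trial_duration * params.frame_rate))
    rng = np.random.default_rng(params.seed)

    # P(switch | redraw) = 1 - sum(pi^2); solve redraw prob from switch_rate
    p_switch_given_redraw = 1.0 - float(np.sum(pi**2))
    switches_per_frame = params.switch_rate / 60.0 / params.frame_rate
    if p_switch_given_redraw <= 0:
        alpha = 0.0
    else:
        alpha = min(1.0, switches_per_frame / p_switch_given_redraw)

    draws = rng.choice(3, size=n_frames, p=pi)
    redraw = rng.random(n_frames) < alpha
    redraw[0] = True  # initial state from stationarity
    # state at frame t = draw at the most recent redraw frame <= t
    last_redraw = np.maximum.accumulate(np.where(redraw, np.arange(n_frames), -1))
    states = draws[last_redraw]
    occ = ZoneOccupancy.from_timeline(states, params.frame_rate)
    return occ, states


@dataclass(frozen=True)
class ArenaSimParams:
    """Biased correlated-random-walk parameters for a circular arena.

    The default arena matches a 36 cm diameter cylinder holding 8 fish.
    Movement statistics (speed, persistence) are generic small-fish
    placeholders, not fitted kinematics.  ``attraction`` is a signed
    (n x n) matrix with zero diagonal; each individual's heading is pulled
    toward the attraction-weighted resultant of unit vectors to the others,
    scaled by ``attraction_gain``.
    """

    n_individuals: int = 8
    arena_radius: float = 18.0  # cm
    speed_mean: float = 5.0  # cm/s
    speed_sd: float = 1.5  # cm/s
    heading_persistence: float = 0.8  # 0..1
    attraction: np.ndarray | None = None
    attraction_gain: float = 1.0
    frame_rate: float = 10.0
    duration: float = 1800.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        for name in ("arena_radius", "speed_mean", "speed_sd", "frame_rate", "duration"):
            _check_finite(name, getattr(self, name))
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.arena_radius > 0 or not self.frame_rate > 0 or not self.duration > 0:
            raise ValueError("arena_radius, frame_rate and duration must be positive")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValueError("heading_persistence must be in [0, 1]")
        a = self.attraction_matrix()
        if a.shape != (self.n_individuals, self.n_individuals):
            raise ValueError(
                f"attraction matrix must be {self.n_individuals}x{self.n_individuals}, "
                f"got {a.shape}"
            )
        if np.any(np.diag(a) != 0):
            raise ValueError("attraction matrix must have zero diagonal")

    def attraction_matrix(self) -> np.ndarray:
        if self.attraction is None:
            return np.zeros((self.n_individuals, self.n_individuals))
        return np.asarray(self.attraction, dtype=float)


def simulate_arena(
    params: ArenaSimParams, individual_ids: Sequence[str] | None = None
) -> TrajectorySet:
    """Simulate free-swimming trajectories for one arena trial.

    Per step each individual's direction is the normalized sum of its
    persistence-weighted previous heading, a social pull, and a random unit
    vector weighted by ``1 - persistence``; step length is a
    truncated-normal speed times the frame interval.  The social pull points
    along the normalized attraction-weighted resultant of unit vectors
    toward the others and has magnitude ``attraction_gain`` times the
    individual's mean absolute attraction weight, so relative weights steer
    *which* partners are approached while the overall weight level sets how
    strongly the group coheres.  The boundary reflects specularly (speed
    preserved).  Output has no missing frames and all positions inside the
    arena.
    """
    n = params.n_individuals
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration * params.frame_rate))
    dt = 1.0 / params.frame_rate
    R = params.arena_radius
    A = params.attraction_matrix()
    kappa = params.heading_persistence

    # uniform start positions in the disc, uniform headings
    r0 = R * np.sqrt(rng.random(n))
    th0 = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r0 * np.cos(th0), r0 * np.sin(th0)])
    ang = rng.uniform(0, 2 * np.pi, n)
    heading = np.column_stack([np.cos(ang), np.sin(ang)])

    out = np.empty((n_frames, n, 2))
    out[0] = pos
    has_attraction = np.any(A != 0)
    mean_abs_w = np.abs(A).sum(axis=1) / max(n - 1, 1)
    pull_strength = params.attraction_gain * mean_abs_w
    for t in range(1, n_frames):
        direction = kappa * heading
        if has_attraction:
            diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = p_j - p_i
            dist = np.hypot(diff[..., 0], diff[..., 1])
            np.fill_diagonal(dist, np.inf)
            unit = diff / dist[..., None]
            resultant = np.einsum("ij,ijk->ik", A, unit)
            norm = np.hypot(resultant[:, 0], resultant[:, 1])
            nz = norm > 1e-12
            resultant[nz] /= norm[nz, None]
            direction = direction + pull_strength[:, None] * resultant
        noise_ang = rng.uniform(0, 2 * np.pi, n)
        direction = direction + (1.0 - kappa) * np.column_stack(
            [np.cos(noise_ang), np.sin(noise_ang)]
        )
        dnorm = np.hypot(direction[:, 0], direction[:, 1])
        degenerate = dnorm < 1e-12
        if degenerate.any():
            ang2 = rng.uniform(0, 2 * np.pi, int(degenerate.sum()))
            direction[degenerate] = np.column_stack([np.cos(ang2), np.sin(ang2)])
            dnorm[degenerate] = 1.0
        direction /= dnorm[:, None]

        speed = np.clip(rng.normal(params.speed_mean, params.speed_sd, n), 0.0, None)
        new = pos + direction * (speed * dt)[:, None]

        # specular reflection at the circular wall
        rho = np.hypot(new[:, 0], new[:, 1])
        outside = rho > R
        if outside.any():
            radial = new[outside] / rho[outside, None]
            new[outside] = radial * np.clip(2 * R - rho[outside], 0.0, R)[:, None]
            h = direction[outside]
            direction[outside] = h - 2 * np.sum(h * radial, axis=1)[:, None] * radial
        heading = direction
        pos = new
        out[t] = pos

    ids = list(individual_ids) if individual_ids is not None else [f"ind{i}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("individual_ids length must equal n_individuals")
    return TrajectorySet(
        positions=out,
        frame_rate=params.frame_rate,
        individual_ids=ids,
        geometry=CircularArena(radius_cm=R),
    )


@dataclass(frozen=True)
class BehaviorSimParams:
    """Negative-binomial behaviour-count generator.

    Cell mean = ``base_rate * exp(b_arena + effect_relatedness * unrelated +
    effect_status * virgin)`` with ``b_arena ~ N(0, arena_sd)``.  Effects are
    log rate ratios for the non-reference level (unrelated vs related; virgin
    vs experienced).  ``dispersion`` is the NB size parameter
    (variance = mu + mu^2 / dispersion); ``inf`` gives the Poisson limit.
    """

    base_rate: float = 10.0
    effect_relatedness: float = 0.0
    effect_status: float = 0.0
    dispersion: float = 2.0
    arena_sd: float = 0.3
    n_arenas: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_rate > 0:
            raise ValueError("base_rate must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if self.arena_sd < 0:
            raise ValueError("arena_sd must be non-negative")
        if self.n_arenas < 1:
            raise ValueError("n_arenas must be >= 1")
        for name in ("effect_relatedness", "effect_status"):
            _check_finite(name, getattr(self, name))


def default_cells(n_arenas: int) -> pd.DataFrame:
    """The study's aggregation cells: arena x mating status x relatedness."""
    rows = [
        {"arena_id": f"arena{a:02d}", "mating_status": s, "relatedness": r}
        for a in range(n_arenas)
        for s in ("experienced", "virgin")
        for r in ("related", "unrelated")
    ]
    return pd.DataFrame(rows)


def simulate_behavior_counts(
    params: BehaviorSimParams, cells: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw one NB count per aggregation cell.

    ``cells`` must carry ``arena_id``, ``mating_status`` and ``relatedness``
    columns; by default the fully crossed design over ``params.n_arenas``
    arenas is used (4 cells per arena, 48 for the 12-arena study design).
    """
    if cells is None:
        cells = default_cells(params.n_arenas)
    if len(cells) == 0:
        raise ValueError("empty cell design")
    req = {"arena_id", "mating_status", "relatedness"}
    if not req <= set(cells.columns):
        raise ValueError(f"cell design missing columns {sorted(req - set(cells.columns))}")
    rng = np.random.default_rng(params.seed)
    arenas = pd.unique(cells["arena_id"])
    b_arena = dict(zip(arenas, rng.normal(0.0, params.arena_sd, len(arenas))))
    eta = (
        np.log(params.base_rate)
        + cells["arena_id"].map(b_arena).to_numpy()
        + params.effect_relatedness * (cells["relatedness"] == "unrelated").to_numpy()
        + params.effect_status * (cells["mating_status"] == "virgin").to_numpy()
    )
    mu = np.exp(eta)
    if math.isinf(params.dispersion):
        counts = rng.poisson(mu)
    else:
        p = params.dispersion / (params.dispersion + mu)
        counts = rng.negative_binomial(params.dispersion, p)
    out = cells.copy()
    out["count"] = counts.astype(int)
    return out


def simulate_behavior_events(
    params: BehaviorSimParams,
    behavior: str,
    designs: Sequence,
    actor_sex: str,
    trial_duration_s: float = 1800.0,
) -> pd.DataFrame:
    """Expand simulated cell counts into an observer-style event log.

    For each (arena, status, relatedness) cell a count is drawn as in
    :func:`simulate_behavior_counts`, then scattered into individual events
    with a uniformly chosen actor of the given sex and status, a recipient of
    the opposite sex matching the relatedness class, and a uniform onset.
    Aggregating the returned log recovers the cell counts exactly.
    """
    rng = np.random.default_rng(params.seed)
    cells = pd.DataFrame(
        [
            {"arena_id": d.arena_id, "mating_status": s, "relatedness": r}
            for d in designs
            for s in ("experienced", "virgin")
            for r in ("related", "unrelated")
        ]
    )
    counted = simulate_behavior_counts(params, cells)
    by_arena = {d.arena_id: d for d in designs}
    rows = []
    for _, cell in counted.iterrows():
        d = by_arena[cell["arena_id"]]
        table = d.individuals
        actors = [
            i
            for i in d.ids
            if table.loc[i, "sex"] == actor_sex
            and table.loc[i, "mating_status"] == cell["mating_status"]
        ]
        for _ in range(int(cell["count"])):
            actor = actors[rng.integers(len(actors))]
            recips = [
                i
                for i in d.ids
                if table.loc[i, "sex"] != actor_sex
                and (
                    d.related(actor, i)
                    if cell["relatedness"] == "related"
                    else not d.related(actor, i)
                )
            ]
            if not recips:
                raise ValueError(
                    f"no {cell['relatedness']} opposite-sex recipient for {actor}"
                )
            rows.append(
                {
                    "arena_id": cell["arena_id"],
                    "actor": actor,
                    "recipient": recips[rng.integers(len(recips))],
                    "behavior": behavior,
                    "onset_s": float(rng.uniform(0, trial_duration_s)),
                    "duration_s": 0.0,
                }
            )
    cols = ["arena_id", "actor", "recipient", "behavior", "onset_s", "duration_s"]
    return pd.DataFrame(rows, columns=cols)
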