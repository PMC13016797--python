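"""Observer-scored behavioural events and their aggregation into model cells.

Female sexual behaviours are orienting, approaching and gliding (gliding —
a smooth approach toward a displaying male — being the strongest
precopulatory acceptance signal); male behaviours are pursuing, sigmoid
displays, successful matings and forced mating attempts.  Successful
matings and forced attempts are merged into a single ``mating`` response
before modelling.

Dyad-level counts are mostly zero, so events are aggregated at the group
level: one cell per arena x actor mating status x actor-recipient
relatedness, yielding 48 cells per behaviour for the 12-arena study design.
Empty cells are emitted with count 0 so the cell structure is invariant to
the event list.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trajio import TrialDesign

__all__ = [
    "FEMALE_BEHAVIORS",
    "MALE_BEHAVIORS",
    "MODELED_BEHAVIORS",
    "validate_events",
    "aggregate_counts",
    "pool_behaviors",
]

FEMALE_BEHAVIORS = ("orienting", "approaching", "gliding")
MALE_BEHAVIORS = ("pursuing", "sigmoid", "mating", "forced-mating")
# responses actually modelled, after merging mating + forced-mating
MODELED_BEHAVIORS = {
    "female": ("orienting", "approaching", "gliding"),
    "male": ("pursuing", "sigmoid", "mating"),
}
_MERGE = {"forced-mating": "mating"}

EVENT_COLUMNS = ["arena_id", "actor", "recipient", "behavior", "onset_s", "duration_s"]

CELL_KEYS = ["arena_id", "mating_status", "relatedness"]


def validate_events(
    events: pd.DataFrame,
    designs: Mapping[str, TrialDesign],
    trial_duration_s: float | None = None,
) -> pd.DataFrame:
    """Check an event log against the trial designs.

    Rejects events with unknown arenas or individuals, actor == recipient,
    a behaviour inconsistent with the actor's sex, or an onset outside the
    trial; the offending event's row index is reported.
    """
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    sex_catalog = {"female": set(FEMALE_BEHAVIORS), "male": set(MALE_BEHAVIORS)}
    for idx, ev in events.iterrows():
        if ev["arena_id"] not in designs:
            raise ValueError(f"event {idx}: unknown arena {ev['arena_id']!r}")
        d = designs[ev["arena_id"]]
        for who in ("actor", "recipient"):
            if ev[who] not in d.ids:
                raise ValueError(
                    f"event {idx}: unknown individual {ev[who]!r} in arena {ev['arena_id']!r}"
                )
        if ev["actor"] == ev["recipient"]:
            raise ValueError(f"event {idx}: actor equals recipient ({ev['actor']!r})")
        sex = d.individuals.loc[ev["actor"], "sex"]
        if ev["behavior"] not in sex_catalog[sex]:
            raise ValueError(
                f"event {idx}: behavior {ev['behavior']!r} not valid for a {sex} actor"
            )
        if trial_duration_s is not None and not 0 <= ev["onset_s"] <= trial_duration_s:
            raise ValueError(f"event {idx}: onset {ev['onset_s']} outside trial")
    return events


def aggregate_counts(
    events: pd.DataFrame,
    designs: Mapping[str, TrialDesign] | Sequence[TrialDesign],
    actor_sex: str,
    validate: bool = True,
) -> pd.DataFrame:
    """Count events per (arena x actor status x pair relatedness x behaviour).

    Relatedness of a directed behaviour is classed by the actor-recipient
    pair (related iff same family).  All cells of the fully crossed design
    are emitted, zero-filled, for every modelled behaviour of ``actor_sex``;
    mating and forced-mating events both count toward ``mating``.
    """
    if actor_sex not in MODELED_BEHAVIORS:
        raise ValueError(f"actor_sex must be 'female' or 'male', got {actor_sex!r}")
    if not isinstance(designs, Mapping):
        designs = {d.arena_id: d for d in designs}
    if validate:
        validate_events(events, designs)

    behaviors = MODELED_BEHAVIORS[actor_sex]
    cells = pd.DataFrame(
        [
            {"arena_id": aid, "mating_status": s, "relatedness": r, "behavior": b}
            for aid in designs
            for s in ("experienced", "virgin")
            for r in ("related", "unrelated")
            for b in behaviors
        ]
    )
    if len(events):
        ev = events.copy()
        ev["behavior"] = ev["behavior"].replace(_MERGE)
        ev = ev[ev["behavior"].isin(behaviors)]

        def actor_status(row: pd.Series) -> str:
            return designs[row["arena_id"]].individuals.loc[row["actor"], "mating_status"]

        def pair_rel(row: pd.Series) -> str:
            d = designs[row["arena_id"]]
            return "related" if d.related(row["actor"], row["recipient"]) else "unrelated"

        if len(ev):
            ev["mating_status"] = ev.apply(actor_status, axis=1)
            ev["relatedness"] = ev.apply(pair_rel, axis=1)
            # keep only events whose actor matches the requested sex
            sexes = {
                aid: d.individuals["sex"] for aid, d in designs.items()
            }
            ev = ev[
                ev.apply(lambda r: sexes[r["arena_id"]].loc[r["actor"]] == actor_sex, axis=1)
            ]
        if len(ev):
            counted = (
                ev.groupby(CELL_KEYS + ["behavior"]).size().rename("count").reset_index()
            )
            cells = cells.merge(counted, on=CELL_KEYS + ["behavior"], how="left")
            cells["count"] = cells["count"].fillna(0).astype(int)
            return cells
    cells["count"] = 0
    return cells


def pool_behaviors(counts: pd.DataFrame | Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-behaviour cell tables for a pooled fit.

    Accepts the long table from :func:`aggregate_counts` or an iterable of
    per-behaviour tables; validates that every behaviour covers the same
    cells, so the pooled model's behaviour-type random effect sees a
    balanced layout.
    """
    if isinstance(counts, pd.DataFrame):
        stacked = counts.copy()
    else:
        parts = list(counts)
        if not parts:
            raise ValueError("no behaviour tables to pool")
        stacked = pd.concat(parts, ignore_index=True)
    req = set(CELL_KEYS + ["behavior", "count"])
    missing = req - set(stacked.columns)
    if missing:
        raise ValueError(f"cell tables missing columns {sorted(missing)}")
    key_sets = {
        b: frozenset(map(tuple, sub[CELL_KEYS].itertuples(index=False)))
        for b, sub in stacked.groupby("behavior")
    }
    ref = None
    for b, keys in key_sets.items():
        if ref is None:
            ref = keys
        elif keys != ref:
            raise ValueError(f"behavior {b!r} has mismatched cell keys")
    return stacked.reset_index(drop=True)
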