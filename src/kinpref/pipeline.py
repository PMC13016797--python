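"""End-to-end orchestration of the three experiments.

Experiment 1: dichotomous mate choice — a focal fish chooses between a
related and an unrelated opposite-sex stimulus; zone occupancy gives SOP
scores which feed a one-sample t test and LMMs with sex, mating status and
stimulus trait differences as fixed effects and family origin random.

Experiment 2: free-swimming mixed-sex arenas (8 fish: two families, each
contributing a virgin and an experienced individual of each sex) —
observer-scored sexual behaviours aggregated to arena x status x relatedness
cells and modelled as NB GLMMs, plus dyadic association-duration GLMMs.

Experiment 3: free-swimming same-sex arenas (2 siblings + 2 each from 3
unrelated families) — dyadic association GLMM with relatedness and sex.

Cross-experiment: Spearman rank correlations of per-individual SOPs between
designs, per sex.

A :class:`Scenario` holds the synthetic study conditions (defaults follow
the study design: 96 choice trials with 7 acclimation breaches, 12 arenas
per free-swimming experiment, 24 full-sib families); a :class:`RunConfig`
adds the master seed, analysis settings and output directory.  Identical
config + seed reproduce outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import synthdata as sd
from .association import derive_threshold, detect_associations, dyad_census
from .inference import (
    MixedModelResult,
    ModelSpec,
    TTestResult,
    SpearmanResult,
    fdr_adjust_families,
    fit_mixed_model,
    fit_nb_glmm_batch,
    likelihood_ratio_anova,
    one_sample_t,
    spearman_consistency,
    tukey_pairwise,
)
from .preference import (
    STATE_NEUTRAL,
    STATE_RELATED,
    STATE_UNRELATED,
    ZoneGeometry,
    arena_sop,
    compute_sop,
    default_interval_edges,
    informed_choice_window,
    interval_sop,
    zone_occupancy,
)
from .trajio import ChoiceTank, TrajectorySet, TrialDesign, trait_differences

__all__ = [
    "Scenario",
    "RunConfig",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
    "run_cross_experiment",
    "run_all",
]

BEHAVIORS = ("orienting", "approaching", "gliding", "pursuing", "sigmoid", "mating", "forced-mating")


@dataclass(frozen=True)
class Scenario:
    """Synthetic study conditions.

    Defaults reproduce the study design: 24 full-sib families x 4 focals
    (one per sex x mating status), 96 choice trials of which 7 carry
    acclimation-breach flags and 1 never enters one zone; 12 mixed-sex and
    12 same-sex arenas of 8 fish.  Preference effects default to the null
    (no kin bias) with the body-size effect on SOP and the status effects on
    behaviour counts set to the magnitudes the choice/arena analyses report;
    movement parameters are generic small-fish placeholders.
    """

    # families / individuals
    n_families: int = 24
    # experiment 1
    exp1_n_breaches: int = 7
    exp1_n_ic_unusable: int = 1
    exp1_trial_duration_s: float = 1800.0
    exp1_frame_rate: float = 10.0
    p_zone_female: float = 0.68
    p_zone_male: float = 0.58
    switch_rate_per_min: float = 2.0
    bias_b: float = 0.5
    sop_slope_body_length: float = 0.05  # SOP units per mm of length difference
    sop_family_sd: float = 0.05
    sop_sex_effect: float = 0.0  # added for male focals, SOP scale
    sop_status_effect: float = 0.0  # added for virgin focals
    latent_pref_sd: float = 0.0  # per-individual kin preference shared across experiments
    # morphology (mm / mm^2); SDs chosen so stimulus-pair trait differences
    # match the reported mean absolute differences
    body_length_mean_mm: float = 17.6
    body_length_sd_female_mm: float = 0.940
    body_length_sd_male_mm: float = 1.737
    body_area_mean_mm2: float = 80.0
    body_area_sd_female_mm2: float = 5.49
    body_area_sd_male_mm2: float = 13.39
    orange_area_mean_mm2: float = 12.0
    orange_area_sd_mm2: float = 1.108
    # free-swimming arenas
    n_arenas: int = 12
    arena_duration_s: float = 1800.0
    arena_frame_rate: float = 10.0
    arena_radius_cm: float = 18.0
    speed_mean_cms: float = 5.0
    speed_sd_cms: float = 1.5
    heading_persistence: float = 0.8
    attraction_gain: float = 0.1
    base_attraction: float = 1.0
    attraction_virgin_virgin: float = -0.5
    attraction_male_male: float = -0.6
    attraction_female_female: float = 0.0
    attraction_related: float = 0.0
    # association threshold
    mean_body_length_cm: float = 1.76
    threshold_multiplier: float = 2.0
    # behaviour counts (per arena x status x relatedness cell per trial)
    behavior_base_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "orienting": 20.0,
            "approaching": 15.0,
            "gliding": 2.0,
            "pursuing": 30.0,
            "sigmoid": 10.0,
            "mating": 2.0,
            "forced-mating": 1.0,
        }
    )
    behavior_relatedness_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "orienting": -0.21,
            "approaching": -0.26,
            "gliding": -0.55,
            "pursuing": 0.04,
            "sigmoid": -0.15,
            "mating": 0.02,
            "forced-mating": 0.02,
        }
    )
    behavior_status_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "orienting": 0.08,
            "approaching": 0.01,
            "gliding": 1.33,
            "pursuing": -0.22,
            "sigmoid": 0.14,
            "mating": -0.61,
            "forced-mating": -0.61,
        }
    )
    behavior_dispersion: float = 2.0
    behavior_arena_sd: float = 0.3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Mapping):
                d[k] = dict(v)
        return d

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "Scenario":
        base = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        merged = {}
        for key, value in overrides.items():
            current = getattr(base, key)
            if isinstance(current, Mapping) and isinstance(value, Mapping):
                merged[key] = {**dict(current), **dict(value)}
            else:
                merged[key] = value
        return dataclasses.replace(base, **merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class RunConfig:
    scenario: Scenario = field(default_factory=Scenario)
    master_seed: int = 0
    outdir: Path | None = None
    ic_min_window_s: float = 60.0
    n_sop_intervals: int = 3
    per_capita_arena_sop: bool = False
    alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario.to_dict(),
                "ic_min_window_s": self.ic_min_window_s,
                "n_sop_intervals": self.n_sop_intervals,
                "per_capita_arena_sop": self.per_capita_arena_sop,
                "alpha": self.alpha,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def write_table(self, name: str, df: pd.DataFrame) -> None:
        if self.outdir is None:
            return
        self.outdir.mkdir(parents=True, exist_ok=True)
        path = Path(self.outdir) / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# kinpref seed={self.master_seed} config={self.config_hash()}\n")
            df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# population construction

def build_population(scenario: Scenario, seed: int) -> pd.DataFrame:
    """One row per individual: 4 per family (sex x mating status), with traits."""
    rng = np.random.default_rng(seed)
    rows = []
    for fam in range(scenario.n_families):
        for sex in ("female", "male"):
            for status in ("virgin", "experienced"):
                sl = (
                    scenario.body_length_sd_female_mm
                    if sex == "female"
                    else scenario.body_length_sd_male_mm
                )
                sa = (
                    scenario.body_area_sd_female_mm2
                    if sex == "female"
                    else scenario.body_area_sd_male_mm2
                )
                rows.append(
                    {
                        "individual_id": f"fam{fam:02d}_{sex[0]}{status[0]}",
                        "family": f"fam{fam:02d}",
                        "sex": sex,
                        "mating_status": status,
                        "body_length_mm": rng.normal(scenario.body_length_mean_mm, sl),
                        "body_area_mm2": rng.normal(scenario.body_area_mean_mm2, sa),
                        "orange_area_mm2": (
                            rng.normal(
                                scenario.orange_area_mean_mm2, scenario.orange_area_sd_mm2
                            )
                            if sex == "male"
                            else np.nan
                        ),
                        "latent_pref": rng.normal(0.0, scenario.latent_pref_sd)
                        if scenario.latent_pref_sd > 0
                        else 0.0,
                    }
                )
    return pd.DataFrame(rows).set_index("individual_id")


# ---------------------------------------------------------------------------
# experiment 1

@dataclass
class Exp1Result:
    trials: pd.DataFrame
    n_total: int
    n_breach_excluded: int
    n_analyzed: int
    n_ic_analyzed: int
    ttest_total: TTestResult
    models: dict[str, MixedModelResult]
    log: list[str]


def _states_to_trajectory(
    states: np.ndarray,
    frame_rate: float,
    stimulus_side: Mapping[str, str],
    focal_id: str,
) -> TrajectorySet:
    """Place the focal at zone/neutral anchor points so occupancy scoring
    recovers the simulated state sequence through the geometric path."""
    tank = ChoiceTank()
    zones = ZoneGeometry.from_choice_tank(tank)
    mid_y = tank.depth_cm / 2.0
    left_anchor = ((zones.left.x0 + zones.left.x1) / 2.0, mid_y)
    right_anchor = ((zones.right.x0 + zones.right.x1) / 2.0, mid_y)
    neutral_anchor = ((tank.main_x0 + tank.main_x1) / 2.0, mid_y)
    side_anchor = {"left": left_anchor, "right": right_anchor}
    rel_anchor = {
        stimulus_side["left"]: side_anchor["left"],
        stimulus_side["right"]: side_anchor["right"],
    }
    anchors = np.array(
        [rel_anchor["related"], rel_anchor["unrelated"], neutral_anchor]
    )
    pos = anchors[states][:, None, :]
    return TrajectorySet(
        positions=pos,
        frame_rate=frame_rate,
        individual_ids=[focal_id],
        geometry=tank,
    )


def _exp1_trial_designs(
    scenario: Scenario, pop: pd.DataFrame
) -> list[TrialDesign]:
    """One choice trial per individual: related stimulus = opposite-sex
    sibling (experienced), unrelated = same slot from the next family."""
    designs = []
    n_fam = scenario.n_families
    for focal_id, row in pop.iterrows():
        fam_num = int(row["family"][3:])
        other_sex = "male" if row["sex"] == "female" else "female"
        related_id = f"fam{fam_num:02d}_{other_sex[0]}e"
        unrel_fam = (fam_num + 1) % n_fam
        unrelated_id = f"fam{unrel_fam:02d}_{other_sex[0]}e"
        table = pop.loc[[focal_id, related_id, unrelated_id]].drop(columns="latent_pref")
        designs.append(
            TrialDesign(individuals=table, focal_id=focal_id, arena_id=f"trial_{focal_id}")
        )
    return designs


def run_experiment1(cfg: RunConfig) -> Exp1Result:
    scenario = cfg.scenario
    seeds = sd.spawn_seeds(cfg.master_seed, 2)
    pop = build_population(scenario, seeds[0])
    designs = _exp1_trial_designs(scenario, pop)
    n_total = len(designs)
    rng = np.random.default_rng(seeds[1])
    trial_seeds = sd.spawn_seeds(seeds[1], n_total)
    fam_effect = {
        f"fam{k:02d}": e
        for k, e in enumerate(rng.normal(0.0, scenario.sop_family_sd, scenario.n_families))
    }

    # plant the study's exclusion structure: breach flags by status/sex
    # composition (3 virgin males, 2 experienced males, 2 experienced
    # females), then one further trial whose related zone is never entered
    breach_ids: list[str] = []
    for sex, status, k in (("male", "virgin", 3), ("male", "experienced", 2), ("female", "experienced", 2)):
        cand = [
            d.focal_id
            for d in designs
            if pop.loc[d.focal_id, "sex"] == sex
            and pop.loc[d.focal_id, "mating_status"] == status
        ]
        breach_ids += cand[:k]
    breach_ids = breach_ids[: scenario.exp1_n_breaches]
    non_breach = [d.focal_id for d in designs if d.focal_id not in breach_ids]
    ic_unusable_ids = set(non_breach[: scenario.exp1_n_ic_unusable])

    zones = ZoneGeometry.from_choice_tank(ChoiceTank())
    rows = []
    log = [f"experiment 1: {n_total} trials generated"]
    for k, design in enumerate(designs):
        focal = design.focal_id
        info = pop.loc[focal]
        diffs = trait_differences(design)
        target = (
            (2.0 * scenario.bias_b - 1.0)
            + fam_effect[info["family"]]
            + info["latent_pref"]
            + scenario.sop_slope_body_length * diffs["body_length_mm"]
            + (scenario.sop_sex_effect if info["sex"] == "male" else 0.0)
            + (scenario.sop_status_effect if info["mating_status"] == "virgin" else 0.0)
        )
        bias = float(np.clip((1.0 + target) / 2.0, 0.0, 1.0))
        p_zone = (
            scenario.p_zone_female if info["sex"] == "female" else scenario.p_zone_male
        )
        if focal in ic_unusable_ids:
            bias = 0.0  # related zone never visited: unusable IC window
        params = sd.ZoneSimParams(
            trial_duration=scenario.exp1_trial_duration_s,
            frame_rate=scenario.exp1_frame_rate,
            p_zone=p_zone,
            bias_b=bias,
            switch_rate=scenario.switch_rate_per_min,
            seed=trial_seeds[k],
        )
        _, states = sd.simulate_zone_trial(params)
        side = ("related", "unrelated") if trial_seeds[k] % 2 == 0 else ("unrelated", "related")
        design.stimulus_side = {"left": side[0], "right": side[1]}
        traj = _states_to_trajectory(states, params.frame_rate, design.stimulus_side, focal)
        occ = zone_occupancy(traj, zones, design)
        sop_total = compute_sop(occ)
        ic_occ, ic_usable = informed_choice_window(occ, cfg.ic_min_window_s)
        sop_ic = compute_sop(ic_occ, window="informed-choice") if ic_usable else None
        edges = default_interval_edges(occ.trial_duration_s, cfg.n_sop_intervals)
        interval_scores = interval_sop(occ, edges)
        row = {
            "focal_id": focal,
            "family": info["family"],
            "sex": info["sex"],
            "mating_status": info["mating_status"],
            "breach": focal in breach_ids,
            "body_length_diff_mm": diffs["body_length_mm"],
            "body_area_diff_mm2": diffs["body_area_mm2"],
            "orange_area_diff_mm2": diffs["orange_area_mm2"],
            "zone_time_s": occ.t_zone,
            "zone_fraction": occ.zone_fraction,
            "sop_total": sop_total.value if sop_total.defined else np.nan,
            "ic_usable": ic_usable,
            "sop_ic": sop_ic.value if (sop_ic and sop_ic.defined) else np.nan,
        }
        for i, s in enumerate(interval_scores):
            row[f"sop_interval_{i + 1}"] = s.value if s.defined else np.nan
        rows.append(row)
    trials = pd.DataFrame(rows)

    analyzed = trials[~trials["breach"]].copy()
    log.append(
        f"acclimation-breach exclusion: {len(trials)} -> {len(analyzed)} "
        f"({int(trials['breach'].sum())} removed)"
    )
    defined = analyzed.dropna(subset=["sop_total"])
    ttest = one_sample_t(defined["sop_total"])
    ic = analyzed[analyzed["ic_usable"]].dropna(subset=["sop_ic"])
    log.append(f"informed-choice exclusion: {len(analyzed)} -> {len(ic)}")

    levels = {
        "sex": ("female", "male"),
        "mating_status": ("experienced", "virgin"),
    }
    models: dict[str, MixedModelResult] = {}
    models["overall"] = fit_mixed_model(
        ModelSpec(
            response="sop_total",
            family="gaussian",
            fixed_effects=("body_length_diff_mm", "sex", "mating_status"),
            random_effects=("family",),
            alpha=cfg.alpha,
            factor_levels=levels,
        ),
        defined,
    )
    females = defined[defined["sex"] == "female"]
    models["female"] = fit_mixed_model(
        ModelSpec(
            response="sop_total",
            family="gaussian",
            fixed_effects=("body_length_diff_mm", "orange_area_diff_mm2", "mating_status"),
            random_effects=("family",),
            alpha=cfg.alpha,
            factor_levels=levels,
        ),
        females,
    )
    males = defined[defined["sex"] == "male"]
    models["male"] = fit_mixed_model(
        ModelSpec(
            response="sop_total",
            family="gaussian",
            fixed_effects=("body_length_diff_mm", "mating_status"),
            random_effects=("family",),
            alpha=cfg.alpha,
            factor_levels=levels,
        ),
        males,
    )

    cfg.write_table("exp1_sop_trials", trials)
    return Exp1Result(
        trials=trials,
        n_total=n_total,
        n_breach_excluded=int(trials["breach"].sum()),
        n_analyzed=len(analyzed),
        n_ic_analyzed=len(ic),
        ttest_total=ttest,
        models=models,
        log=log,
    )


# ---------------------------------------------------------------------------
# free-swimming arenas

def _attraction_matrix(scenario: Scenario, design: TrialDesign, pop: pd.DataFrame) -> np.ndarray:
    ids = design.ids
    n = len(ids)
    table = design.individuals
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            w = scenario.base_attraction
            sexes = {table.loc[a, "sex"], table.loc[b, "sex"]}
            if sexes == {"male"}:
                w += scenario.attraction_male_male
            elif sexes == {"female"}:
                w += scenario.attraction_female_female
            statuses = {table.loc[a, "mating_status"], table.loc[b, "mating_status"]}
            if statuses == {"virgin"}:
                w += scenario.attraction_virgin_virgin
            if design.related(a, b):
                w += scenario.attraction_related + pop.loc[a, "latent_pref"]
            A[i, j] = w
    return A


def _mixed_sex_designs(scenario: Scenario, pop: pd.DataFrame) -> list[TrialDesign]:
    """Pair consecutive families: 4 + 4 individuals per arena."""
    designs = []
    for a in range(scenario.n_arenas):
        fam_a, fam_b = f"fam{2 * a:02d}", f"fam{2 * a + 1:02d}"
        members = pop[pop["family"].isin([fam_a, fam_b])].drop(columns="latent_pref")
        designs.append(TrialDesign(individuals=members, arena_id=f"mixed{a:02d}"))
    return designs


def _same_sex_designs(scenario: Scenario, pop: pd.DataFrame) -> list[TrialDesign]:
    """Per sex: groups of 4 families, 2 same-sex individuals each."""
    designs = []
    k = 0
    for sex in ("female", "male"):
        sub = pop[pop["sex"] == sex]
        fams = sorted(sub["family"].unique())
        for g in range(len(fams) // 4):
            group = fams[4 * g : 4 * g + 4]
            members = sub[sub["family"].isin(group)].drop(columns="latent_pref")
            designs.append(TrialDesign(individuals=members, arena_id=f"same{k:02d}"))
            k += 1
    return designs


def _simulate_arena_associations(
    scenario: Scenario,
    designs: Sequence[TrialDesign],
    pop: pd.DataFrame,
    seeds: Sequence[int],
) -> pd.DataFrame:
    thr = derive_threshold(scenario.mean_body_length_cm, scenario.threshold_multiplier)
    tables = []
    for design, seed in zip(designs, seeds):
        params = sd.ArenaSimParams(
            n_individuals=len(design.ids),
            arena_radius=scenario.arena_radius_cm,
            speed_mean=scenario.speed_mean_cms,
            speed_sd=scenario.speed_sd_cms,
            heading_persistence=scenario.heading_persistence,
            attraction=_attraction_matrix(scenario, design, pop),
            attraction_gain=scenario.attraction_gain,
            frame_rate=scenario.arena_frame_rate,
            duration=scenario.arena_duration_s,
            seed=seed,
        )
        traj = sd.simulate_arena(params, individual_ids=design.ids)
        tables.append(detect_associations(traj, thr, design))
    return pd.concat(tables, ignore_index=True)


@dataclass
class Exp2Result:
    designs: list[TrialDesign]
    associations: pd.DataFrame
    behavior_counts: dict[str, pd.DataFrame]  # per sex, long cell table
    behavior_models: dict[str, MixedModelResult]  # keys like 'female:gliding', 'male:all'
    association_models: dict[str, MixedModelResult]  # 'female-male', 'all'
    anova: dict[str, pd.DataFrame]
    tukey: dict[str, pd.DataFrame]
    term_table: pd.DataFrame  # tidy per-term table with FDR families
    arena_sops: pd.DataFrame
    log: list[str]


_STATUS_LEVELS = ("virgin-virgin", "virgin-experienced", "experienced-experienced")
_SEX_LEVELS = ("female-female", "female-male", "male-male")
_CELL_LEVELS = {
    "relatedness": ("related", "unrelated"),
    "mating_status": ("experienced", "virgin"),
}


def _behavior_events(
    scenario: Scenario, designs: Sequence[TrialDesign], seed: int
) -> pd.DataFrame:
    parts = []
    seeds = sd.spawn_seeds(seed, len(BEHAVIORS))
    for s, name in zip(seeds, BEHAVIORS):
        actor_sex = "female" if name in bhv.FEMALE_BEHAVIORS else "male"
        params = sd.BehaviorSimParams(
            base_rate=scenario.behavior_base_rates[name],
            effect_relatedness=scenario.behavior_relatedness_effects[name],
            effect_status=scenario.behavior_status_effects[name],
            dispersion=scenario.behavior_dispersion,
            arena_sd=scenario.behavior_arena_sd,
            n_arenas=scenario.n_arenas,
            seed=s,
        )
        parts.append(
            sd.simulate_behavior_events(
                params, name, designs, actor_sex, scenario.arena_duration_s
            )
        )
    return pd.concat(parts, ignore_index=True)


def run_experiment2(cfg: RunConfig) -> Exp2Result:
    scenario = cfg.scenario
    seeds = sd.spawn_seeds(cfg.master_seed, 3)
    pop = build_population(scenario, seeds[0])
    designs = _mixed_sex_designs(scenario, pop)
    log = [f"experiment 2: {len(designs)} mixed-sex arenas"]

    assoc = _simulate_arena_associations(
        scenario, designs, pop, sd.spawn_seeds(seeds[1], len(designs))
    )
    events = _behavior_events(scenario, designs, seeds[2])
    design_map = {d.arena_id: d for d in designs}
    counts = {
        sex: bhv.aggregate_counts(events, design_map, sex, validate=False)
        for sex in ("female", "male")
    }
    log.append(
        f"behaviour cells: female {len(counts['female'])}, male {len(counts['male'])}"
    )

    # assemble every NB fit for this experiment into one R worker call
    specs: list[ModelSpec] = []
    datasets: list[pd.DataFrame] = []
    lr: list[list[str]] = []
    names: list[str] = []

    cell_spec = ModelSpec(
        response="count",
        family="negative-binomial",
        fixed_effects=("relatedness", "mating_status"),
        random_effects=("arena_id",),
        alpha=cfg.alpha,
        factor_levels=_CELL_LEVELS,
    )
    for sex in ("female", "male"):
        for name in bhv.MODELED_BEHAVIORS[sex]:
            specs.append(cell_spec)
            datasets.append(counts[sex][counts[sex]["behavior"] == name])
            lr.append([])
            names.append(f"{sex}:{name}")
        specs.append(
            dataclasses.replace(cell_spec, random_effects=("arena_id", "behavior"))
        )
        datasets.append(bhv.pool_behaviors(counts[sex]))
        lr.append([])
        names.append(f"{sex}:all")

    fm = assoc[assoc["sex_class"] == "female-male"].copy()
    assoc_spec_fm = ModelSpec(
        response="associated_frames",
        family="negative-binomial",
        fixed_effects=("relatedness_class", "status_class"),
        random_effects=("arena_id",),
        alpha=cfg.alpha,
        factor_levels={
            "relatedness_class": ("related", "unrelated"),
            "status_class": _STATUS_LEVELS,
        },
    )
    specs.append(assoc_spec_fm)
    datasets.append(fm)
    lr.append(["relatedness_class", "status_class"])
    names.append("assoc:female-male")

    assoc_spec_all = dataclasses.replace(
        assoc_spec_fm,
        fixed_effects=("relatedness_class", "status_class", "sex_class"),
        factor_levels={
            "relatedness_class": ("related", "unrelated"),
            "status_class": _STATUS_LEVELS,
            "sex_class": _SEX_LEVELS,
        },
    )
    specs.append(assoc_spec_all)
    datasets.append(assoc)
    lr.append(["relatedness_class", "status_class", "sex_class"])
    names.append("assoc:all")

    fitted = fit_nb_glmm_batch(specs, datasets, lr)
    by_name = dict(zip(names, fitted))
    behavior_models = {n: by_name[n] for n in names if not n.startswith("assoc:")}
    association_models = {
        "female-male": by_name["assoc:female-male"],
        "all": by_name["assoc:all"],
    }

    anova: dict[str, pd.DataFrame] = {}
    tukey: dict[str, pd.DataFrame] = {}
    for key, res in association_models.items():
        preds = [t for t in res.spec.fixed_effects]
        anova[key] = likelihood_ratio_anova(res, preds)
        for factor, levels in (("status_class", _STATUS_LEVELS), ("sex_class", _SEX_LEVELS)):
            if factor not in res.spec.fixed_effects:
                continue
            lr_p = float(
                anova[key].set_index("predictor").loc[factor, "p"]
            )
            if lr_p < cfg.alpha:
                tukey[f"{key}:{factor}"] = tukey_pairwise(res, factor, levels)

    term_table = _exp2_term_table(behavior_models, association_models, anova)
    term_table = fdr_adjust_families(term_table)

    sop_rows = []
    for design in designs:
        for focal in design.ids:
            score = arena_sop(
                assoc[assoc["arena_id"] == design.arena_id],
                focal,
                design,
                "mixed-sex",
                per_capita=cfg.per_capita_arena_sop,
            )
            sop_rows.append(
                {
                    "focal_id": focal,
                    "sex": design.individuals.loc[focal, "sex"],
                    "sop_exp2": score.value if score.defined else np.nan,
                }
            )
    arena_sops = pd.DataFrame(sop_rows)

    cfg.write_table("exp2_associations", assoc)
    cfg.write_table("exp2_terms", term_table)
    cfg.write_table("exp2_arena_sops", arena_sops)
    for sex in ("female", "male"):
        cfg.write_table(f"exp2_behavior_counts_{sex}", counts[sex])
    return Exp2Result(
        designs=designs,
        associations=assoc,
        behavior_counts=counts,
        behavior_models=behavior_models,
        association_models=association_models,
        anova=anova,
        tukey=tukey,
        term_table=term_table,
        arena_sops=arena_sops,
        log=log,
    )


def _exp2_term_table(
    behavior_models: Mapping[str, MixedModelResult],
    association_models: Mapping[str, MixedModelResult],
    anova: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Tidy per-term table mirroring the mixed-sex results layout.

    FDR families are per predictor within each section: the four behaviour
    models of each sex form one family per predictor; the association models
    form families per predictor (completed by the same-sex arena model when
    the full analysis runs).
    """
    rows = []
    for name, res in behavior_models.items():
        sex, behavior = name.split(":")
        for pred, coef_prefix in (
            ("relatedness", "relatednessunrelated"),
            ("mating_status", "mating_statusvirgin"),
        ):
            sub = res.terms[res.terms["term"] == coef_prefix]
            if not len(sub):
                continue
            r = sub.iloc[0]
            rows.append(
                {
                    "section": f"{sex} behaviors",
                    "model": behavior,
                    "n": res.nobs,
                    "predictor": pred,
                    "estimate": r["estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "se": r["se"],
                    "stat": r["stat"],
                    "stat_name": "z",
                    "p": r["p"],
                    "converged": res.converged,
                    "fdr_family": f"{sex}-behaviors:{pred}",
                }
            )
    for key, res in association_models.items():
        an = anova[key].set_index("predictor")
        for pred in res.spec.fixed_effects:
            short = pred.replace("_class", "")
            rows.append(
                {
                    "section": "association duration",
                    "model": key,
                    "n": res.nobs,
                    "predictor": short,
                    "estimate": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "se": np.nan,
                    "stat": float(an.loc[pred, "chisq"]),
                    "stat_name": "chisq",
                    "p": float(an.loc[pred, "p"]),
                    "converged": res.converged,
                    "fdr_family": f"association:{short}",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Exp3Result:
    designs: list[TrialDesign]
    associations: pd.DataFrame
    model: MixedModelResult
    term_table: pd.DataFrame
    arena_sops: pd.DataFrame
    log: list[str]


def run_experiment3(cfg: RunConfig) -> Exp3Result:
    scenario = cfg.scenario
    seeds = sd.spawn_seeds(cfg.master_seed, 2)
    pop = build_population(scenario, seeds[0])
    designs = _same_sex_designs(scenario, pop)
    log = [f"experiment 3: {len(designs)} same-sex arenas"]
    assoc = _simulate_arena_associations(
        scenario, designs, pop, sd.spawn_seeds(seeds[1], len(designs))
    )
    # dyad sex is constant within a same-sex arena
    assoc = assoc.copy()
    assoc["sex"] = assoc["sex_class"].map(
        {"female-female": "female", "male-male": "male"}
    )
    spec = ModelSpec(
        response="associated_frames",
        family="negative-binomial",
        fixed_effects=("relatedness_class", "sex"),
        random_effects=("arena_id",),
        alpha=cfg.alpha,
        factor_levels={
            "relatedness_class": ("related", "unrelated"),
            "sex": ("female", "male"),
        },
    )
    model = fit_mixed_model(spec, assoc)
    rows = []
    for pred, coef in (
        ("relatedness", "relatedness_classunrelated"),
        ("sex", "sexmale"),
    ):
        sub = model.terms[model.terms["term"] == coef]
        if not len(sub):
            continue
        r = sub.iloc[0]
        rows.append(
            {
                "section": "same-sex association",
                "model": "association duration",
                "n": model.nobs,
                "predictor": pred,
                "estimate": r["estimate"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "se": r["se"],
                "stat": r["stat"],
                "stat_name": "z",
                "p": r["p"],
                "converged": model.converged,
                "fdr_family": f"association:{pred}",
            }
        )
    term_table = fdr_adjust_families(pd.DataFrame(rows))

    sop_rows = []
    for design in designs:
        for focal in design.ids:
            score = arena_sop(
                assoc[assoc["arena_id"] == design.arena_id],
                focal,
                design,
                "same-sex",
                per_capita=cfg.per_capita_arena_sop,
            )
            sop_rows.append(
                {
                    "focal_id": focal,
                    "sex": design.individuals.loc[focal, "sex"],
                    "sop_exp3": score.value if score.defined else np.nan,
                }
            )
    arena_sops = pd.DataFrame(sop_rows)
    cfg.write_table("exp3_associations", assoc)
    cfg.write_table("exp3_terms", term_table)
    cfg.write_table("exp3_arena_sops", arena_sops)
    return Exp3Result(
        designs=designs,
        associations=assoc,
        model=model,
        term_table=term_table,
        arena_sops=arena_sops,
        log=log,
    )


@dataclass
class CrossResult:
    sop_table: pd.DataFrame
    correlations: pd.DataFrame  # per sex x pair


def run_cross_experiment(
    cfg: RunConfig,
    exp1: Exp1Result,
    exp2: Exp2Result,
    exp3: Exp3Result,
) -> CrossResult:
    """Spearman consistency of per-individual kin preference across designs."""
    t1 = exp1.trials[~exp1.trials["breach"]][["focal_id", "sex", "sop_total"]].rename(
        columns={"sop_total": "sop_exp1"}
    )
    merged = t1.merge(
        exp2.arena_sops[["focal_id", "sop_exp2"]], on="focal_id", how="outer"
    ).merge(exp3.arena_sops[["focal_id", "sop_exp3"]], on="focal_id", how="outer")
    missing_sex = merged["sex"].isna()
    if missing_sex.any():
        # breach-excluded focals still appear in arenas; recover sex labels
        all_sops = pd.concat([exp2.arena_sops, exp3.arena_sops])
        sex_map = all_sops.drop_duplicates("focal_id").set_index("focal_id")["sex"]
        merged.loc[missing_sex, "sex"] = merged.loc[missing_sex, "focal_id"].map(sex_map)

    rows = []
    pairs = (("sop_exp2", "sop_exp1"), ("sop_exp3", "sop_exp1"), ("sop_exp2", "sop_exp3"))
    for sex in ("female", "male"):
        sub = merged[merged["sex"] == sex]
        for a, b in pairs:
            res: SpearmanResult = spearman_consistency(sub[a], sub[b])
            rows.append(
                {
                    "sex": sex,
                    "pair": f"{a.replace('sop_', '')}-vs-{b.replace('sop_', '')}",
                    "rho": res.rho,
                    "n": res.n,
                    "p": res.p,
                }
            )
    correlations = pd.DataFrame(rows)
    cfg.write_table("cross_experiment_correlations", correlations)
    return CrossResult(sop_table=merged, correlations=correlations)


@dataclass
class FullRun:
    exp1: Exp1Result
    exp2: Exp2Result
    exp3: Exp3Result
    cross: CrossResult
    combined_terms: pd.DataFrame


def run_all(cfg: RunConfig) -> FullRun:
    """All three experiments plus the cross-experiment consistency stage.

    The association-duration FDR families span the mixed-sex (female-male
    and all-pairs) and same-sex models, so the combined term table re-adjusts
    them jointly.
    """
    exp1 = run_experiment1(cfg)
    exp2 = run_experiment2(cfg)
    exp3 = run_experiment3(cfg)
    cross = run_cross_experiment(cfg, exp1, exp2, exp3)
    combined = pd.concat(
        [exp2.term_table.drop(columns="p_adj"), exp3.term_table.drop(columns="p_adj")],
        ignore_index=True,
    )
    combined = fdr_adjust_families(combined)
    cfg.write_table("combined_terms", combined)
    return FullRun(exp1=exp1, exp2=exp2, exp3=exp3, cross=cross, combined_terms=combined)
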