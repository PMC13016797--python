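"""Statistical layer: mixed models, post-hoc contrasts, FDR, rank tests.

The preference and count analyses share one modelling idiom: fixed effects
of interest (sex, mating status, relatedness, trait differences) with random
intercepts for nuisance grouping (family origin, arena, behaviour type).
Gaussian responses (SOP scores) are fitted as linear mixed models via
statsmodels ``MixedLM`` (maximum likelihood); overdispersed counts as
negative-binomial GLMMs via the R ``glmmTMB`` worker
(:mod:`kinpref._rbridge`).  Model construction, the stepwise
interaction-pruning loop, likelihood-ratio ANOVA, Tukey-adjusted pairwise
contrasts, and Benjamini–Hochberg FDR adjustment live here, independent of
which backend did the optimisation.

Interaction policy: all 2- and 3-way interactions among the fixed effects
enter initially and are pruned one per refit — the least significant
(highest Wald p >= alpha) droppable term first, never dropping a term that
is marginal to a retained higher-order interaction — until only significant
interactions or main effects remain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats as sps

from ._rbridge import NBJob, run_nb_glmm_jobs

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "fit_mixed_model",
    "fit_nb_glmm_batch",
    "likelihood_ratio_anova",
    "tukey_pairwise",
    "bh_fdr",
    "fdr_adjust_families",
    "one_sample_t",
    "rank_sum_test",
    "spearman_consistency",
    "TTestResult",
    "RankSumResult",
    "SpearmanResult",
    "LRTest",
]

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    response: str
    family: str  # 'gaussian' | 'negative-binomial'
    fixed_effects: tuple[str, ...]
    random_effects: tuple[str, ...]
    interactions: bool = True
    alpha: float = 0.05
    factor_levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "negative-binomial"}:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.random_effects:
            raise ValueError("mixed models need at least one random effect")
        if not self.fixed_effects:
            raise ValueError("no fixed effects specified")

    def initial_terms(self) -> list[str]:
        terms = list(self.fixed_effects)
        if self.interactions and len(self.fixed_effects) >= 2:
            for k in (2, 3):
                if len(self.fixed_effects) >= k:
                    terms += [
                        ":".join(c) for c in itertools.combinations(self.fixed_effects, k)
                    ]
        return terms

    def validate_data(self, data: pd.DataFrame) -> None:
        needed = {self.response, *self.fixed_effects, *self.random_effects}
        missing = needed - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns {sorted(missing)}")
        for re_col in self.random_effects:
            if data[re_col].nunique() < 2:
                raise ValueError(f"random effect {re_col!r} has fewer than 2 levels")


class LRTest(NamedTuple):
    chisq: float
    df: int
    p: float


@dataclass
class MixedModelResult:
    """Fitted-effect table plus enough state to refit reduced models.

    ``terms`` has one row per fixed-effect coefficient: estimate, SE, 95% CI,
    Wald statistic and raw p.  ``p_adj`` is attached later when the result
    joins an FDR family.  Convergence failures are carried in ``converged``,
    never silently dropped.
    """

    spec: ModelSpec
    data: pd.DataFrame = field(repr=False)
    terms: pd.DataFrame = field(repr=False)
    stat_name: str
    converged: bool
    loglik: float
    df_model: int
    nobs: int
    dispersion: float | None
    final_terms: list[str]
    dropped_terms: list[str]
    vcov: pd.DataFrame = field(repr=False)
    lr_tests: dict[str, LRTest] = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.terms.set_index("term").loc[name, "estimate"])

    def summary(self) -> str:
        lines = [
            "Mixed model results",
            "=" * 66,
            f"Response:   {self.spec.response:<24s} Family: {self.spec.family}",
            f"N obs:      {self.nobs:<24d} Log-likelihood: {self.loglik:.3f}",
            f"Random:     {', '.join(self.spec.random_effects):<24s} "
            f"Converged: {self.converged}",
        ]
        if self.dispersion is not None:
            lines.append(f"Dispersion: {self.dispersion:.4f}")
        lines.append("-" * 66)
        lines.append(
            f"{'term':<34s}{'est':>8s}{'se':>7s}{self.stat_name:>7s}{'p':>8s}"
        )
        for _, r in self.terms.iterrows():
            lines.append(
                f"{r['term']:<34s}{r['estimate']:>8.3f}{r['se']:>7.3f}"
                f"{r['stat']:>7.2f}{r['p']:>8.4f}"
            )
        if self.dropped_terms:
            lines.append(f"Dropped interactions: {', '.join(self.dropped_terms)}")
        for pred, lr in self.lr_tests.items():
            lines.append(
                f"LR test {pred}: chi2({lr.df}) = {lr.chisq:.3f}, p = {lr.p:.4g}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# term/coefficient bookkeeping

def _coef_components(coef_name: str) -> list[str]:
    """Variable names underlying a coefficient, e.g. 'sex[T.male]:x' -> ['sex','x']."""
    return [part.split("[")[0] for part in coef_name.split(":")]


def _coefs_of_term(coef_names: Iterable[str], term: str) -> list[str]:
    parts = term.split(":")
    out = []
    for name in coef_names:
        comps = _coef_components(name)
        if len(comps) == len(parts) and sorted(comps) == sorted(parts):
            out.append(name)
    return out


def _prepare_factors(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data.copy()
    for col, levels in spec.factor_levels.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=list(levels))
    return df


def _check_full_rank(formula_rhs: str, data: pd.DataFrame) -> None:
    from patsy import dmatrix

    X = np.asarray(dmatrix(formula_rhs, data, return_type="dataframe"))
    names = list(dmatrix(formula_rhs, data, return_type="dataframe").columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[k]] for k in range(len(diag)) if diag[k] < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


# ---------------------------------------------------------------------------
# Gaussian LMM via statsmodels

def _fit_lmm_once(
    response: str, terms: list[str], group_col: str, data: pd.DataFrame
):
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    rhs = " + ".join(terms) if terms else "1"
    _check_full_rank(rhs, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        md = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data[group_col])
        mdf = md.fit(reml=False)
    return mdf


def _fit_gaussian(
    spec: ModelSpec, data: pd.DataFrame, lr_tests: Sequence[str]
) -> MixedModelResult:
    if len(spec.random_effects) != 1:
        raise NotImplementedError(
            "gaussian mixed models support a single random intercept"
        )
    group = spec.random_effects[0]
    df = _prepare_factors(data, spec).dropna(subset=[spec.response, *spec.fixed_effects])
    terms = spec.initial_terms()
    dropped: list[str] = []
    mdf = _fit_lmm_once(spec.response, terms, group, df)

    while True:
        inter = [t for t in terms if ":" in t]
        if not inter:
            break
        droppable = [
            t
            for t in inter
            if not any(
                set(t.split(":")) < set(o.split(":")) for o in inter if o != t
            )
        ]
        fe_names = list(mdf.fe_params.index)
        pvals = {}
        for t in droppable:
            coefs = _coefs_of_term(fe_names, t)
            if coefs:
                pvals[t] = float(np.max([mdf.pvalues[c] for c in coefs]))
        if not pvals or max(pvals.values()) < spec.alpha:
            break
        worst = max(pvals, key=pvals.get)
        terms.remove(worst)
        dropped.append(worst)
        mdf = _fit_lmm_once(spec.response, terms, group, df)

    fe = mdf.fe_params
    se = mdf.bse_fe
    stat = fe / se
    p = 2 * sps.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.to_numpy(),
            "se": se.to_numpy(),
            "ci_low": fe.to_numpy() - _Z95 * se.to_numpy(),
            "ci_high": fe.to_numpy() + _Z95 * se.to_numpy(),
            "stat": stat.to_numpy(),
            "p": p,
        }
    ).reset_index(drop=True)
    vcov = mdf.cov_params().loc[fe.index, fe.index]

    result = MixedModelResult(
        spec=spec,
        data=df,
        terms=table,
        stat_name="z",
        converged=bool(mdf.converged),
        loglik=float(mdf.llf),
        df_model=len(fe),
        nobs=int(mdf.nobs),
        dispersion=None,
        final_terms=terms,
        dropped_terms=dropped,
        vcov=vcov,
    )
    for pred in lr_tests:
        result.lr_tests[pred] = _lr_test_gaussian(result, pred)
    return result


def _lr_test_gaussian(result: MixedModelResult, predictor: str) -> LRTest:
    spec = result.spec
    keep = [t for t in result.final_terms if predictor not in t.split(":")]
    mdf0 = _fit_lmm_once(spec.response, keep, spec.random_effects[0], result.data)
    mdf1 = _fit_lmm_once(
        spec.response, result.final_terms, spec.random_effects[0], result.data
    )
    df = len(mdf1.fe_params) - len(mdf0.fe_params)
    if df <= 0:
        raise ValueError(f"predictor {predictor!r} not in model")
    delta = 2.0 * (mdf1.llf - mdf0.llf)
    if not np.isfinite(delta):  # boundary-variance fit: surface as undefined
        return LRTest(chisq=float("nan"), df=int(df), p=float("nan"))
    chisq = max(0.0, float(delta))
    return LRTest(chisq=chisq, df=int(df), p=float(sps.chi2.sf(chisq, df)))


# ---------------------------------------------------------------------------
# Negative-binomial GLMM via glmmTMB

def _num(x) -> float:
    """R JSON scalars may arrive as 'NA'/'NaN'/None when a fit degenerates."""
    if x is None or (isinstance(x, str) and x in {"NA", "NaN", "NULL"}):
        return float("nan")
    return float(x)


def _numvec(xs) -> np.ndarray:
    return np.array([_num(x) for x in xs], dtype=float)


def _result_from_rfit(
    spec: ModelSpec, data: pd.DataFrame, res: dict
) -> MixedModelResult:
    est = _numvec(res["estimate"])
    se = _numvec(res["se"])
    table = pd.DataFrame(
        {
            "term": list(res["terms"]),
            "estimate": est,
            "se": se,
            "ci_low": est - _Z95 * se,
            "ci_high": est + _Z95 * se,
            "stat": _numvec(res["z"]),
            "p": _numvec(res["p"]),
        }
    )
    names = list(res["vcov_names"])
    vcov = pd.DataFrame(np.array([[_num(v) for v in row] for row in res["vcov"]]), index=names, columns=names)
    dropped = list(res.get("dropped", []))
    initial = spec.initial_terms()
    raw_lr = res.get("lr", {}) or {}  # jsonlite writes an empty named list as []
    lr = {
        pred: LRTest(chisq=_num(v["chisq"]), df=int(v["df"]), p=_num(v["p"]))
        for pred, v in (raw_lr.items() if isinstance(raw_lr, dict) else [])
    }
    return MixedModelResult(
        spec=spec,
        data=data,
        terms=table,
        stat_name="z",
        converged=bool(res["converged"]),
        loglik=_num(res["loglik"]),
        df_model=int(res["df_model"]),
        nobs=int(res["nobs"]),
        dispersion=_num(res["dispersion"]),
        final_terms=[t for t in initial if t not in dropped],
        dropped_terms=dropped,
        vcov=vcov,
        lr_tests=lr,
    )


def fit_nb_glmm_batch(
    specs: Sequence[ModelSpec],
    datasets: Sequence[pd.DataFrame],
    lr_tests: Sequence[Sequence[str]] | None = None,
) -> list[MixedModelResult]:
    """Fit many NB GLMMs in one R worker call (used by calibration sweeps)."""
    if len(specs) != len(datasets):
        raise ValueError("specs and datasets length mismatch")
    if lr_tests is None:
        lr_tests = [()] * len(specs)
    jobs = []
    for k, (spec, df) in enumerate(zip(specs, datasets)):
        spec.validate_data(df)
        jobs.append(
            NBJob(
                id=f"job{k:05d}",
                response=spec.response,
                fixed=list(spec.fixed_effects),
                random=list(spec.random_effects),
                data=df,
                interactions=spec.interactions,
                alpha=spec.alpha,
                lr_tests=list(lr_tests[k]),
                factor_levels={k2: list(v) for k2, v in spec.factor_levels.items()},
            )
        )
    raw = run_nb_glmm_jobs(jobs)
    return [
        _result_from_rfit(spec, df, raw[f"job{k:05d}"])
        for k, (spec, df) in enumerate(zip(specs, datasets))
    ]


def fit_mixed_model(
    spec: ModelSpec, data: pd.DataFrame, lr_tests: Sequence[str] = ()
) -> MixedModelResult:
    """Fit one LMM/GLMM per the spec, with stepwise interaction pruning.

    ``lr_tests`` lists predictors whose significance should additionally be
    assessed by likelihood-ratio model comparison (needed for factors with
    more than two levels, where single-coefficient Wald tests do not cover
    the whole predictor).
    """
    spec.validate_data(data)
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data, lr_tests)
    return fit_nb_glmm_batch([spec], [data], [list(lr_tests)])[0]


def likelihood_ratio_anova(
    result: MixedModelResult, predictors: Sequence[str]
) -> pd.DataFrame:
    """Per-predictor chi-square tests by model comparison (drop and refit)."""
    rows = []
    missing = [p for p in predictors if p not in result.lr_tests]
    if missing:
        if result.spec.family == "gaussian":
            for pred in missing:
                result.lr_tests[pred] = _lr_test_gaussian(result, pred)
        else:
            spec2 = ModelSpec(
                response=result.spec.response,
                family=result.spec.family,
                fixed_effects=tuple(result.final_terms),
                random_effects=result.spec.random_effects,
                interactions=False,
                alpha=result.spec.alpha,
                factor_levels=result.spec.factor_levels,
            )
            refit = fit_nb_glmm_batch([spec2], [result.data], [list(missing)])[0]
            result.lr_tests.update(refit.lr_tests)
    for pred in predictors:
        lr = result.lr_tests[pred]
        rows.append({"predictor": pred, "chisq": lr.chisq, "df": lr.df, "p": lr.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-hoc contrasts

def _coef_name_for_level(vcov_names: Sequence[str], factor: str, level: str) -> str | None:
    for cand in (f"{factor}{level}", f"{factor}[T.{level}]"):
        if cand in vcov_names:
            return cand
    return None


def tukey_pairwise(
    result: MixedModelResult, factor: str, levels: Sequence[str] | None = None
) -> pd.DataFrame:
    """All pairwise level contrasts with single-step (Tukey) adjustment.

    Contrasts are on the model's link scale.  The familywise adjustment uses
    the studentized-range distribution on the Wald z statistics (asymptotic
    degrees of freedom), the standard large-sample Tukey correction for
    mixed models.
    """
    if levels is None:
        levels = list(result.spec.factor_levels.get(factor, ()))
        if not levels:
            levels = sorted(result.data[factor].dropna().unique())
    k = len(levels)
    if k < 3:
        raise ValueError(
            f"factor {factor!r} has {k} levels; Tukey adjustment needs >= 3"
        )
    names = list(result.vcov.index)
    coef_of = {}
    for lv in levels:
        cn = _coef_name_for_level(names, factor, lv)
        coef_of[lv] = cn
    missing = [lv for lv, cn in coef_of.items() if cn is None]
    if len(missing) != 1:
        raise ValueError(
            f"could not map factor levels onto coefficients (non-reference levels "
            f"without a coefficient: {missing})"
        )
    baseline = missing[0]
    est = {lv: (0.0 if lv == baseline else result.coef(coef_of[lv])) for lv in levels}

    def var_of(a: str, b: str) -> float:
        ca, cb = coef_of[a], coef_of[b]
        v = 0.0
        if ca is not None:
            v += float(result.vcov.loc[ca, ca])
        if cb is not None:
            v += float(result.vcov.loc[cb, cb])
        if ca is not None and cb is not None:
            v -= 2.0 * float(result.vcov.loc[ca, cb])
        return v

    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = est[b] - est[a]
        se = float(np.sqrt(var_of(a, b)))
        z = diff / se if se > 0 else np.nan
        p_tukey = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(z), k, 1e7))
        rows.append(
            {
                "contrast": f"{b} - {a}",
                "estimate": diff,
                "se": se,
                "z": z,
                "p_unadj": float(2 * sps.norm.sf(abs(z))),
                "p_tukey": p_tukey,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple tests and multiplicity

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    Sort ascending; ``adj_i = min_{j >= i} m * p_(j) / j`` capped at 1; ties
    share a value by construction; original order is restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def fdr_adjust_families(
    table: pd.DataFrame, p_col: str = "p", family_col: str = "fdr_family"
) -> pd.DataFrame:
    """Attach ``p_adj`` per declared FDR family; rows without a family keep NaN."""
    out = table.copy()
    out["p_adj"] = np.nan
    for fam, idx in out.groupby(family_col, dropna=True).groups.items():
        if fam is None or (isinstance(fam, float) and np.isnan(fam)):
            continue
        out.loc[idx, "p_adj"] = bh_fdr(out.loc[idx, p_col].to_numpy())
    return out


class TTestResult(NamedTuple):
    mean: float
    t: float
    df: int
    p: float


def one_sample_t(values: Sequence[float], popmean: float = 0.0) -> TTestResult:
    """One-sample t test of the mean against ``popmean`` (two-sided)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 defined values")
    res = sps.ttest_1samp(x, popmean)
    t = float(res.statistic)
    if not np.isfinite(t):  # all values identical and equal to the null
        t, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    return TTestResult(mean=float(x.mean()), t=t, df=len(x) - 1, p=p)


class RankSumResult(NamedTuple):
    W: float
    p: float


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum (Mann–Whitney) test, two-sided.

    ``W`` is the Mann–Whitney U statistic of the first sample (mid-ranks for
    ties), matching the W reported by R's ``wilcox.test``.  Small tie-free
    samples use the exact null distribution; otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankSumResult(W=float(res.statistic), p=float(res.pvalue))


class SpearmanResult(NamedTuple):
    rho: float
    n: int
    p: float


def spearman_consistency(a: Sequence[float], b: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation of paired scores, mid-ranks for ties.

    Pairs with an undefined score on either side are dropped pairwise; fewer
    than 3 complete pairs is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, p = sps.spearmanr(a, b)
    return SpearmanResult(rho=float(rho), n=len(a), p=float(p))
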