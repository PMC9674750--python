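"""Analysis pipeline for 2AFC mapping-performance experiments.

Covers participant exclusions by catch-trial performance, covariate
shifting, construction of the fixed-effect designs for the categorical
(five-condition) and continuous (concreteness x mean training similarity)
experiments, mixed-logit fitting via :mod:`crossmap.glmm`, likelihood-ratio
model comparison, backward elimination of fixed effects, marginal and
conditional R-squared, and per-condition performance summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import MixedLogit, MixedLogitResults

__all__ = [
    "LrtResult",
    "EliminationStep",
    "EliminationResult",
    "apply_exclusions",
    "zero_min_transform",
    "build_design",
    "fit_glmm",
    "likelihood_ratio_test",
    "r2_nakagawa",
    "condition_summary",
    "backward_eliminate",
]

LOGISTIC_RESIDUAL_VARIANCE = np.pi**2 / 3.0


@dataclass
class LrtResult:
    """Likelihood-ratio comparison of two nested fits."""

    statistic: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        self.statistic = max(0.0, float(self.statistic))


def apply_exclusions(
    trials: pd.DataFrame,
    min_catch_correct: int = 8,
    native_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants failing the catch-trial criterion; strip catch rows.

    A participant is excluded when their number of correct catch trials is
    below ``min_catch_correct`` (default 8 of 10).  With ``native_only``,
    participants with ``is_native == False`` are excluded as well (the
    column must then exist).  Returns the cleaned analysis table (catch
    rows removed) and an exclusion log with one row per participant.
    """
    trials = trials.copy()
    if "is_catch" not in trials.columns:
        raise ValueError("trials table lacks an is_catch column")
    catch = trials[trials["is_catch"].astype(bool)]
    participants = trials["participant_id"].unique()
    missing = set(participants) - set(catch["participant_id"].unique())
    if missing:
        raise ValueError(f"participants without catch trials: {sorted(missing)[:10]}")

    n_correct = catch.groupby("participant_id")["catch_correct"].sum()
    log_rows = []
    excluded: set = set()
    for pid in participants:
        reasons = []
        if n_correct[pid] < min_catch_correct:
            reasons.append(f"catch {int(n_correct[pid])}<{min_catch_correct}")
        if native_only:
            if "is_native" not in trials.columns:
                raise ValueError("native_only requires an is_native column")
            if not trials.loc[trials["participant_id"] == pid, "is_native"].all():
                reasons.append("non-native")
        if reasons:
            excluded.add(pid)
        log_rows.append(
            {
                "participant_id": pid,
                "catch_correct": int(n_correct[pid]),
                "excluded": bool(reasons),
                "reason": "; ".join(reasons),
            }
        )
    clean = trials[
        ~trials["participant_id"].isin(excluded) & ~trials["is_catch"].astype(bool)
    ].reset_index(drop=True)
    return clean, pd.DataFrame(log_rows)


def zero_min_transform(
    trials: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Shift each covariate so its minimum is zero; return shifted table
    and the logged minima.  Slopes of any GLM(M) are unaffected; only the
    intercept is reparameterised."""
    out = trials.copy()
    minima = {}
    for col in covariates:
        m = float(out[col].min())
        out[col] = out[col] - m
        minima[col] = m
    return out, minima


# ---------------------------------------------------------------------------
# fixed-effect designs
# ---------------------------------------------------------------------------

EXP12_TERMS = ("concreteness", "neighbors", "concreteness:neighbors")
EXP3_TERMS = ("concreteness", "similarity", "concreteness:similarity")


def _exp12_columns(trials: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cond = trials["condition"].astype(str)
    concrete = cond.str.startswith("concrete").to_numpy(dtype=float)
    level = cond.str.split("/").str[-1]
    near = (level == "near").to_numpy(dtype=float)
    maximum = (level == "maximum").to_numpy(dtype=float)
    cols = [np.ones(len(trials))]
    names = ["Intercept"]
    if "concreteness" in terms:
        cols.append(concrete)
        names.append("concrete")
    if "neighbors" in terms:
        cols += [near, maximum]
        names += ["near", "maximum"]
    if "concreteness:neighbors" in terms:
        # the maximum level exists only on the concrete side, so the
        # concrete x maximum product is aliased with the maximum dummy and
        # is dropped; the interaction contributes one parameter
        cols.append(concrete * near)
        names.append("concrete:near")
    return np.column_stack(cols), names


def _exp3_columns(trials: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    c = trials["concreteness"].to_numpy(dtype=float)
    s = trials["mean_training_similarity"].to_numpy(dtype=float)
    cols = [np.ones(len(trials))]
    names = ["Intercept"]
    if "concreteness" in terms:
        cols.append(c)
        names.append("concreteness")
    if "similarity" in terms:
        cols.append(s)
        names.append("mean_training_similarity")
    if "concreteness:similarity" in terms:
        cols.append(c * s)
        names.append("concreteness:similarity")
    return np.column_stack(cols), names


def build_design(
    trials: pd.DataFrame, design: str, terms=None
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix (treatment coding, intercept = reference
    level abstract/far for the categorical design)."""
    if design == "exp12":
        return _exp12_columns(trials, terms if terms is not None else EXP12_TERMS)
    if design == "exp3":
        return _exp3_columns(trials, terms if terms is not None else EXP3_TERMS)
    raise ValueError(f"unknown design {design!r}")


def fit_glmm(
    trials: pd.DataFrame,
    design: str = "exp12",
    terms=None,
    response: str = "chose_model_image",
    groups: tuple[str, str] = ("participant_id", "word"),
) -> MixedLogitResults:
    """Fit the mixed logistic model with random intercepts for participants
    and items to a trial table."""
    X, names = build_design(trials, design, terms)
    y = trials[response].to_numpy(dtype=float)
    model = MixedLogit(
        y,
        X,
        {"participant": trials[groups[0]].to_numpy(), "item": trials[groups[1]].to_numpy()},
        exog_names=names,
    )
    return model.fit()


def likelihood_ratio_test(full: MixedLogitResults, reduced: MixedLogitResults) -> LrtResult:
    """Chi-squared likelihood-ratio test of nested fits on the same data."""
    if full.nobs != reduced.nobs:
        raise ValueError("fits are on different numbers of observations")
    full_names = set(full.params.index)
    red_names = set(reduced.params.index)
    if not red_names <= full_names:
        raise ValueError("models are not nested (coefficient names differ)")
    diff = full.k_params - reduced.k_params
    if diff < 0:
        raise ValueError("full model must have at least as many parameters as reduced")
    df = max(diff, 1)  # identical models degenerate to df=1, stat 0, p=1
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return LrtResult(stat, df, float(stats.chi2.sf(stat, df)))


def r2_nakagawa(fit, exog: np.ndarray | None = None) -> tuple[float, float]:
    """Marginal and conditional R-squared for a logistic mixed model.

    Marginal: variance of the fixed-effect linear predictor over the total
    (fixed + random-intercept + pi^2/3 residual) variance; conditional adds
    the random-intercept variance to the numerator.  ``fit`` may be a
    :class:`MixedLogitResults` (``exog`` defaults to its design matrix) or
    any object with ``params`` and ``random_variances``.
    """
    if exog is None:
        exog = fit.model.exog
    beta = np.asarray(fit.params, dtype=float)
    eta_fixed = np.asarray(exog, dtype=float) @ beta
    var_fixed = float(np.var(eta_fixed))
    var_random = float(sum(fit.random_variances.values()))
    denom = var_fixed + var_random + LOGISTIC_RESIDUAL_VARIANCE
    return var_fixed / denom, (var_fixed + var_random) / denom


def condition_summary(
    trials: pd.DataFrame,
    by: str = "condition",
    response: str = "chose_model_image",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition mapping performance: proportion of trials choosing the
    model image, with a normal-approximation confidence interval.  Chance
    level is 0.5."""
    if by not in trials.columns:
        raise ValueError(f"no {by!r} column")
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for cond, grp in trials.groupby(by, sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty condition {cond!r}")
        p = float(grp[response].mean())
        se = np.sqrt(p * (1.0 - p) / n)
        rows.append(
            {
                by: cond,
                "n": n,
                "performance": p,
                "ci_lower": p - crit * se,
                "ci_upper": p + crit * se,
                "chance": 0.5,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


@dataclass
class EliminationStep:
    term: str
    statistic: float
    df: int
    pvalue: float
    removed: bool


@dataclass
class EliminationResult:
    """Outcome of LRT-based backward elimination of fixed effects."""

    final_terms: tuple[str, ...]
    final_fit: MixedLogitResults
    steps: list[EliminationStep] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Backward elimination (likelihood-ratio tests)", "-" * 48]
        for s in self.steps:
            verdict = "removed" if s.removed else "kept"
            lines.append(
                f"drop {s.term:<28} X2({s.df}) = {s.statistic:6.2f}, "
                f"p = {s.pvalue:.4f} -> {verdict}"
            )
        lines.append(f"final terms: {list(self.final_terms) or '[intercept only]'}")
        lines.append("")
        lines.append(self.final_fit.summary())
        return "\n".join(lines)


def backward_eliminate(
    trials: pd.DataFrame,
    design: str = "exp12",
    alpha: float = 0.05,
    response: str = "chose_model_image",
    groups: tuple[str, str] = ("participant_id", "word"),
) -> EliminationResult:
    """Simplify the full fixed-effect model by backward elimination.

    The interaction is tested first; if removable (LRT p >= alpha) the
    remaining main effects are tested one at a time, at each round removing
    the least informative removable term, until every remaining term is
    significant.  Respects marginality: main effects are only tested after
    the interaction is gone.
    """
    all_terms = EXP12_TERMS if design == "exp12" else EXP3_TERMS
    interaction = all_terms[-1]
    terms = list(all_terms)
    fits: dict[tuple[str, ...], MixedLogitResults] = {}

    def _fit(tms) -> MixedLogitResults:
        key = tuple(tms)
        if key not in fits:
            fits[key] = fit_glmm(trials, design, terms=list(tms),
                                 response=response, groups=groups)
        return fits[key]

    steps: list[EliminationStep] = []
    current = _fit(terms)

    # stage 1: the interaction
    reduced_terms = [t for t in terms if t != interaction]
    reduced = _fit(reduced_terms)
    lrt = likelihood_ratio_test(current, reduced)
    removed = lrt.pvalue >= alpha
    steps.append(EliminationStep(interaction, lrt.statistic, lrt.df, lrt.pvalue, removed))
    if removed:
        terms, current = reduced_terms, reduced

        # stage 2: main effects, least informative first
        while terms:
            candidates = []
            for t in terms:
                red = _fit([u for u in terms if u != t])
                l = likelihood_ratio_test(current, red)
                candidates.append((t, l, red))
            t, l, red = max(candidates, key=lambda c: c[1].pvalue)
            if l.pvalue >= alpha:
                steps.append(EliminationStep(t, l.statistic, l.df, l.pvalue, True))
                terms = [u for u in terms if u != t]
                current = red
            else:
                for t2, l2, _ in candidates:
                    steps.append(
                        EliminationStep(t2, l2.statistic, l2.df, l2.pvalue, False)
                    )
                break
    return EliminationResult(tuple(terms), current, steps)
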