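"""Trait-moderated decision analyses.

Three analyses relate the trial-level exploration drives to behaviour:

1. **Leave-stay** — mixed-effects logistic regression of the per-trial
   decision to abandon the current animal on a set of three drives,
   each in full-factorial interaction with engagement time and a
   continuous trait score, with random intercepts for participant,
   setting, pattern type and animal.  Four candidate variable sets are
   compared by AIC; current and expected versions of the same quantity
   never co-occur in one model.
2. **Exploratory choice** — a conditional logit over the three animals
   available after each free leave, with option attributes novelty,
   expected learning progress and expected prediction error, fitted
   separately for low/high trait groups from a mean split.
3. **Learning performance** — a likelihood-ratio test for whether the
   decline of prediction error over engagement time differs by pattern
   type as a function of the trait (3 df: one contrast per non-reference
   pattern), using linear mixed models with a participant intercept.

All predictors are z-standardized globally over the analysed dataset;
engagement time is the consecutive-trial count within the current
engagement.  Trials on which a setting ended by a cap are excluded from
leave-stay observations (forced transitions are not decisions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.discrete.conditional_models import ConditionalLogit

from .glmm import BinomialMixedModel
from .lmm import GaussianMixedModel

__all__ = [
    "VARIABLE_SETS",
    "LeaveStayModel",
    "FitResult",
    "LrtResult",
    "compare_variable_sets",
    "mean_split",
    "ChoiceModel",
    "fit_choice_by_split",
    "LearningPerformanceModel",
]

#: The four candidate leave-stay variable sets (display label -> trace columns).
VARIABLE_SETS: dict[str, tuple[str, str, str]] = {
    "ExpPE+LP+Nov": ("epe_next", "lp", "novelty"),
    "PE+LP+Nov": ("pe", "lp", "novelty"),
    "ExpPE+ExpLP+Nov": ("epe_next", "elp_next", "novelty"),
    "PE+ExpLP+Nov": ("pe", "elp_next", "novelty"),
}

_RANDOM_FACTORS = ("participant", "setting", "pattern", "animal")


@dataclass
class FitResult:
    """Coefficient table plus fit statistics for one decision model."""

    table: pd.DataFrame  # index: term; columns: estimate, se, z, p
    aic: float
    bic: float
    loglik: float
    deviance: float
    n_obs: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.loglik):
            assert abs(self.deviance + 2.0 * self.loglik) < 1e-6


@dataclass
class LrtResult:
    """Likelihood-ratio test between nested models."""

    chi_square: float
    df: int
    p_value: float
    loglik_full: float
    loglik_null: float


def _zscore(x: np.ndarray) -> np.ndarray:
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=0)
    if not np.isfinite(s) or s == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (x - m) / s


class LeaveStayModel:
    """Mixed logistic model of leave-stay decisions for one variable set.

    Parameters
    ----------
    data : DataFrame
        Trial-level trace merged with participant traits; must carry the
        variable-set columns, ``trial_in_engagement``, the trait column,
        ``leave``, ``forced_end`` and the random-factor columns.
    variable_set : str
        Key of :data:`VARIABLE_SETS`.
    trait_col : str
        Continuous trait score column (standardized internally).
    include_forced : bool
        Keep cap-forced transitions as observations (off by default).
    """

    def __init__(self, data: pd.DataFrame, variable_set: str, trait_col: str,
                 include_forced: bool = False):
        if variable_set not in VARIABLE_SETS:
            raise ValueError(f"unknown variable set {variable_set!r}; "
                             f"choose from {sorted(VARIABLE_SETS)}")
        self.variable_set = variable_set
        self.trait_col = trait_col
        vars3 = VARIABLE_SETS[variable_set]
        df = data if include_forced else data[data["forced_end"] == 0]
        df = df.copy()
        y = df["leave"].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("leave flag must be binary")
        cols = {}
        for v in vars3:
            # standardize over defined values; progress is undefined on the
            # first trial of an engagement and enters at the mean (z = 0)
            z = _zscore(df[v].to_numpy(dtype=float))
            cols[v] = np.where(np.isnan(z), 0.0, z)
        time_z = _zscore(df["trial_in_engagement"].to_numpy(dtype=float))
        trait_z = _zscore(df[trait_col].to_numpy(dtype=float))
        names = ["const"]
        design = [np.ones(len(df))]
        for v in vars3:
            names.append(v)
            design.append(cols[v])
        names += ["time", "trait", "time:trait"]
        design += [time_z, trait_z, time_z * trait_z]
        for v in vars3:
            names += [f"{v}:time", f"{v}:trait", f"{v}:time:trait"]
            design += [cols[v] * time_z, cols[v] * trait_z, cols[v] * time_z * trait_z]
        self.endog = y
        self.exog = np.column_stack(design)
        self.exog_names = names
        self.groups = {g: df[g].to_numpy() for g in _RANDOM_FACTORS}
        self.n_obs = len(df)

    def fit(self) -> FitResult:
        model = BinomialMixedModel(self.endog, self.exog, self.groups, self.exog_names)
        res = model.fit()
        flags = [] if res.converged else ["non-convergence or separation flagged"]
        table = res.summary_frame()
        out = FitResult(
            table=table, aic=res.aic, bic=res.bic, loglik=res.llf,
            deviance=res.deviance, n_obs=self.n_obs, converged=res.converged, flags=flags,
        )
        out.random_effect_sd = res.random_effect_sd()
        return out


def compare_variable_sets(data: pd.DataFrame, trait_col: str,
                          specs=None) -> pd.DataFrame:
    """Fit every candidate variable set and rank by AIC (ascending).

    Returns a table with AIC, BIC, log-likelihood, deviance and a
    convergence flag per variable set; failed members are retained with
    NaN statistics and a flag rather than aborting the comparison.
    """
    specs = list(VARIABLE_SETS) if specs is None else list(specs)
    rows = []
    for vs in specs:
        try:
            fr = LeaveStayModel(data, vs, trait_col).fit()
            rows.append(
                {"variable_set": vs, "aic": fr.aic, "bic": fr.bic,
                 "loglik": fr.loglik, "deviance": fr.deviance,
                 "converged": fr.converged, "flag": "; ".join(fr.flags)}
            )
        except Exception as exc:  # partial table with flags per contract
            rows.append(
                {"variable_set": vs, "aic": np.nan, "bic": np.nan,
                 "loglik": np.nan, "deviance": np.nan,
                 "converged": False, "flag": f"fit failed: {exc}"}
            )
    out = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return out


def mean_split(scores) -> pd.Series:
    """Dichotomize a trait at its sample mean.

    Scores strictly below the mean are "low", scores at or above it are
    "high" (ties at the mean go high).
    """
    s = pd.Series(scores).astype(float)
    if s.nunique() < 2:
        raise ValueError("mean split requires at least two distinct scores")
    return pd.Series(np.where(s < s.mean(), "low", "high"), index=s.index)


class ChoiceModel:
    """Conditional logit over the three options at each free leave event.

    ``choices`` must have one row per (event, option) with columns
    ``event_id, novelty, elp, epe, chosen``; each event has exactly
    three options, exactly one of them chosen.  Attributes are
    z-standardized over option rows before fitting.
    """

    ATTRS = ("novelty", "elp", "epe")

    def __init__(self, choices: pd.DataFrame):
        counts = choices.groupby("event_id")["chosen"].agg(["size", "sum"])
        if not ((counts["size"] == 3).all() and (counts["sum"] == 1).all()):
            raise ValueError("each event needs exactly 3 options with exactly one chosen")
        df = choices.copy()
        for a in self.ATTRS:
            df[a + "_z"] = _zscore(df[a].to_numpy(dtype=float))
        self.data = df
        self.n_events = counts.shape[0]

    def fit(self) -> FitResult:
        df = self.data
        exog = df[[a + "_z" for a in self.ATTRS]].to_numpy()
        model = ConditionalLogit(df["chosen"].to_numpy(), exog, groups=df["event_id"].to_numpy())
        res = model.fit(disp=False)
        flags = []
        if self.n_events < 50:
            flags.append(f"low power: only {self.n_events} choice events")
        table = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues},
            index=list(self.ATTRS),
        )
        k = len(self.ATTRS)
        llf = float(res.llf)
        try:
            converged = bool(res.mle_retvals.get("converged", True))
        except AttributeError:
            converged = True
        out = FitResult(
            table=table, aic=2.0 * k - 2.0 * llf,
            bic=k * math.log(self.n_events) - 2.0 * llf, loglik=llf,
            deviance=-2.0 * llf, n_obs=int(len(df)),
            converged=converged, flags=flags,
        )
        out.n_events = self.n_events
        return out

    def predicted_probabilities(self, params=None) -> pd.Series:
        """Per-row choice probabilities (softmax of utilities within event)."""
        df = self.data
        if params is None:
            params = self.fit().table["estimate"].to_numpy()
        util = df[[a + "_z" for a in self.ATTRS]].to_numpy() @ np.asarray(params, float)
        out = np.empty(len(df))
        for _, idx in df.groupby("event_id").indices.items():
            u = util[idx]
            e = np.exp(u - u.max())
            out[idx] = e / e.sum()
        return pd.Series(out, index=df.index, name="p_choice")


def fit_choice_by_split(choices: pd.DataFrame, participants: pd.DataFrame,
                        trait_col: str) -> dict[str, FitResult]:
    """Mean-split the trait and fit one conditional logit per group."""
    traits = participants.set_index("participant")[trait_col]
    groups = mean_split(traits)
    out = {}
    for label in ("low", "high"):
        pids = groups[groups == label].index
        sub = choices[choices["participant"].isin(pids)]
        if not len(sub):
            raise ValueError(f"no choice events in the {label} group")
        out[label] = ChoiceModel(sub).fit()
    return out


class LearningPerformanceModel:
    """LRT for trait-dependent learning curves across pattern types.

    Compares linear mixed models (fitted by ML) of standardized
    prediction error on ``time * pattern * trait`` with and without the
    three-way interaction; the 3 degrees of freedom are the trait x time
    contrasts of the non-reference (high-noise) patterns.

    Both models carry a participant random intercept and a separate
    random time slope per pattern within participant.  The slope terms
    matter for calibration: prediction errors are autocorrelated within
    an engagement, so per-participant learning-curve slopes are
    overdispersed relative to an independence model, and testing a
    between-participant moderator against that overdispersion without
    the random slopes inflates the LRT well above its nominal chi-square
    reference.
    """

    def __init__(self, trace: pd.DataFrame, trait_col: str, reference: str = "HIGH_NOISE"):
        df = trace.reset_index(drop=True)
        pe_z = _zscore(df["pe"].to_numpy(dtype=float))
        time_z = _zscore(df["trial_in_engagement"].to_numpy(dtype=float))
        trait_z = _zscore(df[trait_col].to_numpy(dtype=float))
        patterns = sorted(df["pattern"].unique())
        if reference in patterns:
            patterns = [reference] + [p for p in patterns if p != reference]
        self.reference = patterns[0]
        self.patterns = patterns
        self.endog = pe_z
        cols = {"const": np.ones(len(df)), "time": time_z, "trait": trait_z}
        for p in patterns[1:]:
            cols[f"pat[{p}]"] = (df["pattern"] == p).to_numpy(dtype=float)
        for p in patterns[1:]:
            cols[f"pat[{p}]:time"] = cols[f"pat[{p}]"] * time_z
            cols[f"pat[{p}]:trait"] = cols[f"pat[{p}]"] * trait_z
        cols["time:trait"] = time_z * trait_z
        self.null_names = list(cols)
        self.X_null = np.column_stack(list(cols.values()))
        three_way = {
            f"pat[{p}]:time:trait": cols[f"pat[{p}]"] * time_z * trait_z
            for p in patterns[1:]
        }
        self.full_names = self.null_names + list(three_way)
        self.X_full = np.column_stack([self.X_null] + [v[:, None] for v in three_way.values()])
        self.n_drop = len(three_way)
        pid = df["participant"].to_numpy()
        terms = {"participant": (pid, None)}
        for p in patterns:
            terms[f"slope[{p}]"] = (pid, (df["pattern"] == p).to_numpy(dtype=float) * time_z)
        self.random_terms = terms

    def fit(self) -> LrtResult:
        res_null = GaussianMixedModel(
            self.endog, self.X_null, self.random_terms, self.null_names
        ).fit()
        res_full = GaussianMixedModel(
            self.endog, self.X_full, self.random_terms, self.full_names
        ).fit()
        stat = max(0.0, 2.0 * (res_full.llf - res_null.llf))
        df_ = self.n_drop
        return LrtResult(
            chi_square=stat, df=df_, p_value=float(chi2.sf(stat, df_)),
            loglik_full=res_full.llf, loglik_null=res_null.llf,
        )
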