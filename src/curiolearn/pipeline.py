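"""Data contracts, preprocessing and the end-to-end pipeline.

Trial logs are comma-separated text with a fixed header (see
:data:`TRIAL_SCHEMA`): locations are decimal fractions of the hiding
strip in [0, 1], trial indices within an engagement are 1-based, and
both the engagement index and the cumulative per-animal exposure are
stored.  Preprocessing removes participants who did not understand the
task and, per the boredom report, every setting after the one in which
a participant reported becoming bored — before any model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .cohort import PolicyLink, simulate_cohort
from .curiosity import build_choice_table, build_trace
from .decisions import (
    LearningPerformanceModel,
    compare_variable_sets,
    fit_choice_by_split,
)
from .hdr import HierarchicalDeltaModel, McmcConfig

__all__ = [
    "TRIAL_SCHEMA",
    "AnalysisConfig",
    "PreprocessReport",
    "apply_exclusions",
    "read_trial_log",
    "write_trial_log",
    "run_pipeline",
]

#: Required columns of a trial-log file and their dtypes.
TRIAL_SCHEMA: dict[str, type] = {
    "participant": int,
    "setting": int,
    "animal": int,
    "pattern": str,
    "setting_trial": int,
    "engagement_id": int,
    "trial_in_engagement": int,
    "exposure": int,
    "outcome": float,
    "prediction": float,
    "leave": int,
    "forced_end": int,
}


@dataclass
class PreprocessReport:
    """Bookkeeping of the exclusion and boredom filters."""

    n_participants_before: int
    n_participants_excluded: int
    excluded_participants: list
    settings_discarded: dict
    n_trials_before: int
    n_trials_discarded: int

    @property
    def n_trials_after(self) -> int:
        return self.n_trials_before - self.n_trials_discarded

    def reconciles(self, filtered: pd.DataFrame) -> bool:
        return len(filtered) == self.n_trials_after


def apply_exclusions(trials: pd.DataFrame, participants: pd.DataFrame):
    """Drop did-not-understand participants and post-boredom settings.

    ``participants`` must carry ``understood_task`` (0/1) and
    ``boredom_after_setting`` (1-3, or 0 meaning never).  Settings
    strictly after the reported boredom setting are discarded.  Returns
    ``(filtered_trials, filtered_participants, PreprocessReport)``.
    """
    for col in ("understood_task", "boredom_after_setting"):
        if col not in participants:
            raise ValueError(f"participants table lacks required column {col!r}")
    n_before = len(trials)
    bad = participants.loc[participants["understood_task"] == 0, "participant"].tolist()
    kept_p = participants[~participants["participant"].isin(bad)].copy()
    kept = trials[~trials["participant"].isin(bad)].copy()
    bored = kept_p.set_index("participant")["boredom_after_setting"]
    cutoffs = kept["participant"].map(bored)
    keep_mask = (cutoffs == 0) | (kept["setting"] <= cutoffs)
    discarded_settings = {}
    for pid, cut in bored.items():
        if cut != 0:
            lost = sorted(
                kept.loc[(kept["participant"] == pid) & (kept["setting"] > cut), "setting"].unique()
            )
            if lost:
                discarded_settings[pid] = [int(s) for s in lost]
    filtered = kept[keep_mask].reset_index(drop=True)
    report = PreprocessReport(
        n_participants_before=len(participants),
        n_participants_excluded=len(bad),
        excluded_participants=[int(p) for p in bad],
        settings_discarded=discarded_settings,
        n_trials_before=n_before,
        n_trials_discarded=n_before - len(filtered),
    )
    return filtered, kept_p.reset_index(drop=True), report


def write_trial_log(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_SCHEMA if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log lacks required columns: {missing}")
    trials.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; schema errors name the column/rows."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} lacks required columns: {missing}")
    for col, typ in TRIAL_SCHEMA.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad_rows or coerced.isna().any():
                rows = bad_rows or df.index[coerced.isna()].tolist()
                raise ValueError(
                    f"column {col!r} has invalid values at rows {rows[:10]} (0-based)"
                )
            df[col] = coerced.astype(typ)
    for col in ("outcome", "prediction"):
        out_of_range = df.index[(df[col] < 0) | (df[col] > 1)].tolist()
        if out_of_range:
            raise ValueError(f"column {col!r} outside [0, 1] at rows {out_of_range[:10]}")
    return df


@dataclass
class AnalysisConfig:
    """Everything a full run needs, round-trippable to YAML/JSON.

    ``trace_source`` selects where per-trial beliefs come from:
    ``"mcmc"`` refits the learner per (setting, animal); ``"generative"``
    uses the simulator's own beliefs (exact, instant — for method
    validation runs).
    """

    seed: int = 0
    n_participants: int = 70
    trait_col: str = "other_insistence_on_sameness"
    trace_source: str = "mcmc"
    mcmc: dict = field(default_factory=lambda: {"n_chains": 3, "n_samples": 2000, "burn_in": 0.5})
    null_link: bool = False
    standardization: str = "global"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trace_source not in ("mcmc", "generative"):
            raise ValueError("trace_source must be 'mcmc' or 'generative'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: AnalysisConfig, log=print) -> dict:
    """Simulate, preprocess, fit, derive drives, and run all analyses.

    Returns a results bundle (dict) with the preprocess report, learner
    posterior summaries, the leave-stay comparison table, per-group
    choice fits and the learning-performance LRT.  Deterministic under
    ``config.seed``.
    """
    log(f"[simulate] n={config.n_participants} seed={config.seed}")
    link = PolicyLink.null() if config.null_link else PolicyLink()
    cohort = simulate_cohort(config.n_participants, policy_link=link, rng_seed=config.seed)
    log(f"[simulate] {len(cohort.trials)} trials")

    trials, participants, report = apply_exclusions(cohort.trials, cohort.participants)
    log(f"[preprocess] excluded {report.n_participants_excluded} participants, "
        f"discarded {report.n_trials_discarded} trials")
    if not report.reconciles(trials):
        raise RuntimeError("stage=preprocess: trial counts do not reconcile")

    if config.trace_source == "mcmc":
        posts = []
        summaries = {}
        mc = McmcConfig(rng_seed=config.seed, **config.mcmc)
        for (setting, animal), _ in trials.groupby(["setting", "animal"]):
            try:
                res = HierarchicalDeltaModel.from_trials(trials, setting, animal).fit(mc)
            except ValueError as exc:  # too few trials on this animal
                log(f"[fit] setting={setting} animal={animal} skipped: {exc}")
                continue
            summaries[f"setting{setting}_animal{animal}"] = {
                "params": res.summary_frame["mean"].to_dict(),
                "rhat_max": float(res.rhat.max()),
                "converged": res.converged,
            }
            posts.append(res.trial_posterior)
            log(f"[fit] setting={setting} animal={animal} "
                f"rhat_max={res.rhat.max():.3f} converged={res.converged}")
        if not posts:
            raise RuntimeError("stage=fit: no animal model could be fitted")
        posterior = pd.concat(posts, ignore_index=True)
        keys = ["participant", "setting", "animal", "exposure"]
        covered = trials.merge(posterior[keys], on=keys, how="inner")
        if len(covered) < len(trials):
            log(f"[fit] {len(trials) - len(covered)} trials lack a posterior "
                "trace (single-trial animals) and are dropped from analysis")
        trace = build_trace(covered, posterior)
    else:
        summaries = {"note": "generative beliefs used; no learner refit"}
        trace = build_trace(trials)
        log("[fit] using generative beliefs")

    trace = trace.merge(participants, on="participant", how="left")
    choices = build_choice_table(trace)
    choices = choices.merge(participants, on="participant", how="left")
    log(f"[derive-vars] trace rows={len(trace)} choice options={len(choices)}")

    comparison = compare_variable_sets(trace, config.trait_col)
    log("[analyze] leave-stay comparison:\n" + comparison.to_string(index=False))
    choice_fits = fit_choice_by_split(choices, participants, config.trait_col)
    lrt = LearningPerformanceModel(trace, config.trait_col).fit()
    log(f"[analyze] learning LRT chi2({lrt.df})={lrt.chi_square:.2f} p={lrt.p_value:.4f}")

    bundle = {
        "config": asdict(config),
        "preprocess": {
            "n_participants_before": report.n_participants_before,
            "n_participants_excluded": report.n_participants_excluded,
            "n_trials_before": report.n_trials_before,
            "n_trials_discarded": report.n_trials_discarded,
            "n_trials_after": report.n_trials_after,
        },
        "learner_fits": summaries,
        "leave_stay_comparison": comparison.to_dict(orient="records"),
        "choice": {
            g: {
                "coefficients": fr.table["estimate"].to_dict(),
                "p_values": fr.table["p"].to_dict(),
                "n_events": getattr(fr, "n_events", None),
                "flags": fr.flags,
            }
            for g, fr in choice_fits.items()
        },
        "learning_lrt": {
            "chi_square": lrt.chi_square, "df": lrt.df, "p_value": lrt.p_value,
        },
    }
    if config.output_dir is not None:
        import pathlib

        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trial_log(cohort.trials, out / "trials.csv")
        cohort.participants.to_csv(out / "participants.csv", index=False)
        trace.to_csv(out / "trace.csv", index=False)
        choices.to_csv(out / "choices.csv", index=False)
        comparison.to_csv(out / "leave_stay_comparison.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=float)
        log(f"[report] written to {out}")
    return bundle
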