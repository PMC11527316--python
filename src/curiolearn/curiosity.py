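"""Trial-level exploration drives derived from a learner trace.

Five quantities are computed per trial from the learner's beliefs:

* ``pe``        — unsigned prediction error ``|r_t - V_t|``
* ``lp``        — learning progress ``pe_{t-1} - pe_t`` (positive =
  improving); defined from the second trial of an engagement onward
* ``novelty``   — negative cumulative exposure to the animal
* ``epe_next``  — expected prediction error for the next trial, a
  delta-rule forecast updated with the same realised learning rate
  ``alpha*_t`` as the belief itself:
  ``epe_{t+1} = epe_t + alpha*_t (pe_t - epe_t)``
* ``elp_next``  — expected learning progress for the next trial,
  ``pe_t - epe_{t+1}``

The forecast for an animal is initialised at that animal's first
realised prediction error (no anticipatory information).  While an
animal is not being played its novelty and forecasts are frozen.
Options never played carry novelty 0, an expected error of 1/3 (the
mean absolute error of a uniformly random guess against a uniformly
placed target on the unit strip) and zero expected progress.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "prediction_error",
    "learning_progress",
    "novelty",
    "expected_pe_update",
    "expected_lp",
    "EPE_UNSEEN",
    "build_trace",
    "build_choice_table",
    "standardize",
]

#: Expected unsigned error attributed to a never-played option.
EPE_UNSEEN = 1.0 / 3.0

_KEY = ["participant", "setting", "animal"]


def prediction_error(r, V):
    """Unsigned prediction error |r - V|."""
    return np.abs(np.asarray(r, dtype=float) - np.asarray(V, dtype=float))


def learning_progress(pe_prev, pe_now):
    """Signed progress pe_prev - pe_now; positive values mean improvement."""
    pe_prev = np.asarray(pe_prev, dtype=float)
    pe_now = np.asarray(pe_now, dtype=float)
    if (pe_prev < 0).any() or (pe_now < 0).any():
        raise ValueError("prediction errors must be unsigned (>= 0)")
    return pe_prev - pe_now

def novelty(exposure_count):
    """Novelty as negative exposure: less-played options are more novel."""
    exposure = np.asarray(exposure_count)
    if (exposure < 0).any():
        raise ValueError("exposure counts must be >= 0")
    return -exposure


def expected_pe_update(expected_pe, pe, alpha_star):
    """Delta-rule forecast update of the expected unsigned error."""
    alpha = np.asarray(alpha_star, dtype=float)
    if ((alpha < 0) | (alpha > 1)).any():
        raise ValueError("alpha_star must lie in [0, 1]")
    expected_pe = np.asarray(expected_pe, dtype=float)
    return expected_pe + alpha * (np.asarray(pe, dtype=float) - expected_pe)


def expected_lp(pe_now, expected_pe_next):
    """Expected progress: current error minus the forecast error for the next trial."""
    return np.asarray(pe_now, dtype=float) - np.asarray(expected_pe_next, dtype=float)


def _trace_one_animal(g: pd.DataFrame) -> pd.DataFrame:
    """Trace for one (participant, setting, animal), ordered by exposure."""
    g = g.sort_values("exposure")
    pe = prediction_error(g["outcome"].to_numpy(), g["V"].to_numpy())
    alpha = g["alpha_star"].to_numpy(dtype=float)
    n = len(g)
    lp = np.full(n, np.nan)
    eng = g["engagement_id"].to_numpy()
    same_eng = np.empty(n, dtype=bool)
    same_eng[0] = False
    same_eng[1:] = eng[1:] == eng[:-1]
    lp[same_eng] = learning_progress(pe[:-1][same_eng[1:]], pe[1:][same_eng[1:]])
    epe = np.empty(n)
    epe_next = np.empty(n)
    epe[0] = pe[0]
    for t in range(n):
        epe_next[t] = expected_pe_update(epe[t], pe[t], alpha[t])
        if t + 1 < n:
            epe[t + 1] = epe_next[t]
    out = g.copy()
    out["pe"] = pe
    out["lp"] = lp
    out["novelty"] = novelty(out["exposure"].to_numpy())
    out["epe"] = epe
    out["epe_next"] = epe_next
    out["elp_next"] = expected_lp(pe, epe_next)
    return out


def build_trace(trials: pd.DataFrame, posterior: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach the five exploration drives to every trial of a log.

    Parameters
    ----------
    trials : DataFrame
        One row per trial with at least ``participant, setting, animal,
        engagement_id, trial_in_engagement, exposure, outcome`` and —
        unless ``posterior`` supplies them — ``V`` and ``alpha_star``.
    posterior : DataFrame, optional
        Per-trial posterior means with columns ``participant, setting,
        animal, exposure, V, alpha_star`` (as produced by the learner
        fit); joined onto the log by those keys.  Every trial must be
        matched.

    Returns
    -------
    DataFrame in the input row order with added columns
    ``pe, lp, novelty, epe, epe_next, elp_next``.
    """
    df = trials.copy()
    keys = _KEY + ["exposure"]
    if posterior is not None:
        post = posterior[keys + ["V", "alpha_star"]]
        df = df.drop(columns=[c for c in ("V", "alpha_star") if c in df], errors="ignore")
        df = df.merge(post, on=keys, how="left", validate="one_to_one")
        if df["V"].isna().any():
            missing = df.loc[df["V"].isna(), keys].iloc[0].to_dict()
            raise ValueError(f"posterior trace does not cover all trials, e.g. {missing}")
    for col in ("V", "alpha_star"):
        if col not in df:
            raise ValueError(f"trace requires column {col!r} (supply a posterior)")
    order = df.index
    parts = [_trace_one_animal(g) for _, g in df.groupby(_KEY, sort=False)]
    return pd.concat(parts).loc[order]


def build_choice_table(trace: pd.DataFrame) -> pd.DataFrame:
    """Option attributes at every free leave event.

    For each leave that was a genuine decision (``forced_end == 0``) the
    three animals other than the one just abandoned are listed with
    their frozen novelty, expected error and expected progress (taken
    from each option's most recent played trial, or the unseen-option
    defaults), together with which option was chosen next.

    Requires the trace to carry ``leave``, ``forced_end`` and
    ``setting_trial`` columns (the within-setting play order).
    """
    rows = []
    for (pid, setting), g in trace.groupby(["participant", "setting"], sort=False):
        g = g.sort_values("setting_trial")
        animals = sorted(trace.loc[trace["setting"] == setting, "animal"].unique())
        state = {
            a: {"exposure": 0, "epe_next": EPE_UNSEEN, "elp_next": 0.0} for a in animals
        }
        arr = g[["animal", "exposure", "epe_next", "elp_next", "leave", "forced_end", "setting_trial"]].to_numpy()
        n = len(arr)
        for i in range(n):
            a, expo, epe_n, elp_n, leave, forced, st = arr[i]
            state[a] = {"exposure": expo, "epe_next": epe_n, "elp_next": elp_n}
            if leave == 1 and forced == 0:
                chosen = arr[i + 1][0] if i + 1 < n else None
                if chosen is None:
                    continue
                for opt in animals:
                    if opt == a:
                        continue
                    s = state[opt]
                    rows.append(
                        {
                            "participant": pid,
                            "setting": setting,
                            "event_trial": st,
                            "option": opt,
                            "novelty": -s["exposure"],
                            "epe": s["epe_next"],
                            "elp": s["elp_next"],
                            "chosen": int(opt == chosen),
                        }
                    )
    out = pd.DataFrame(rows)
    if len(out):
        out["event_id"] = out.groupby(["participant", "setting", "event_trial"]).ngroup()
    return out


def standardize(df: pd.DataFrame, cols, suffix: str = "_z") -> pd.DataFrame:
    """Z-score columns over the whole analysed dataset (global scope)."""
    out = df.copy()
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot standardize constant or empty column {c!r}")
        out[c + suffix] = (x - np.nanmean(x)) / sd
    return out
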