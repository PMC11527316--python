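"""Bayesian estimation of the hierarchical delta-rule learner.

One model is fitted per animal of each setting, pooling the trial
sequences of all participants who played that animal: the five learner
parameters (alpha_low, alpha_high, phi, beta_drift, eta) are shared
across participants, while the binary high-rate indicators ``z_t`` are
latent per participant-trial.  Sampling is Metropolis-within-Gibbs (see
``_mcmc``); priors are Uniform(0,1) on the learning rates (ordered
``alpha_low < alpha_high`` by rejection), Beta(1,1) on phi, and
Gamma(0.01, 0.01) on the precision ``1/eta``.

Usage follows the model/results convention::

    model = HierarchicalDeltaModel.from_trials(trials, setting=1, animal=0)
    res = model.fit(McmcConfig(n_samples=2000, rng_seed=7))
    res.summary_frame          # posterior mean/sd/CI/R-hat per parameter
    res.trial_posterior        # per-trial posterior means of V, z, alpha*
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from ._mcmc import run_chain, total_loglik
from .learner import LearnerParams

__all__ = ["McmcConfig", "HierarchicalDeltaModel", "HdrResults", "fit_mcmc", "split_rhat"]

PARAM_NAMES = ("alpha_low", "alpha_high", "phi", "beta_drift", "eta")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_samples`` is per chain; the first ``burn_in`` fraction is
    discarded (and used for proposal adaptation).  At least two chains
    are required for convergence diagnostics.
    """

    n_chains: int = 3
    n_samples: int = 20000
    burn_in: float = 0.5
    rhat_threshold: float = 1.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")
        if not (0.0 < self.burn_in < 1.0):
            raise ValueError("burn_in must be a fraction in (0, 1)")
        if self.n_samples < 10:
            raise ValueError("n_samples too small")


def split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor on split chains (delegates to arviz)."""
    return float(az.rhat(np.asarray(chains, dtype=float), method="split"))


class HierarchicalDeltaModel:
    """Delta-rule learner for one animal, pooled across participants.

    Parameters
    ----------
    B, r : (n_participants, T_max) float arrays
        Predictions and observed locations, padded past ``lengths``.
    lengths : (n_participants,) int array
    index : DataFrame, optional
        Row-aligned identifiers (participant, setting, animal, exposure)
        for the per-trial posterior output.
    """

    def __init__(self, B, r, lengths, index: pd.DataFrame | None = None):
        self.B = np.ascontiguousarray(B, dtype=float)
        self.r = np.ascontiguousarray(r, dtype=float)
        self.lengths = np.ascontiguousarray(lengths, dtype=np.int64)
        if self.B.shape != self.r.shape or len(self.lengths) != self.B.shape[0]:
            raise ValueError("B, r and lengths have inconsistent shapes")
        if (self.lengths < 2).any() or len(self.lengths) < 1:
            raise ValueError("every participant needs >= 2 trials on the animal")
        self.index = index

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, setting: int, animal) -> "HierarchicalDeltaModel":
        """Build the model from a cohort trial log for one (setting, animal)."""
        sub = trials[(trials["setting"] == setting) & (trials["animal"] == animal)]
        if not len(sub):
            raise ValueError(f"no trials for setting={setting}, animal={animal}")
        sub = sub.sort_values(["participant", "exposure"])
        counts = sub.groupby("participant", sort=True).size()
        counts = counts[counts >= 2]
        if not len(counts):
            raise ValueError("need at least one participant with >= 2 trials")
        pids = counts.index.to_numpy()
        Tmax = int(counts.max())
        n = len(pids)
        B = np.zeros((n, Tmax))
        r = np.zeros((n, Tmax))
        lengths = np.zeros(n, dtype=np.int64)
        idx_rows = []
        for i, pid in enumerate(pids):
            g = sub[sub["participant"] == pid]
            T = len(g)
            lengths[i] = T
            B[i, :T] = g["prediction"].to_numpy()
            r[i, :T] = g["outcome"].to_numpy()
            idx_rows.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "setting": setting,
                        "animal": animal,
                        "exposure": g["exposure"].to_numpy(),
                    }
                )
            )
        return cls(B, r, lengths, index=pd.concat(idx_rows, ignore_index=True))

    def loglik(self, params: LearnerParams, z: np.ndarray) -> float:
        """Response log-likelihood of the data under a fixed latent path."""
        return float(
            total_loglik(
                self.B, self.r, self.lengths, np.ascontiguousarray(z, dtype=np.int8),
                params.alpha_low, params.alpha_high, params.beta_drift, params.eta,
            )
        )

    def fit(self, config: McmcConfig | None = None) -> "HdrResults":
        config = config or McmcConfig()
        n_burn = int(config.n_samples * config.burn_in)
        draws = np.empty((config.n_chains, config.n_samples, 5))
        V_sum = np.zeros_like(self.B)
        z_sum = np.zeros_like(self.B)
        alpha_sum = np.zeros_like(self.B)
        n_kept_total = 0
        accepts = []
        valid = np.zeros(self.B.shape, dtype=bool)
        for i, T in enumerate(self.lengths):
            valid[i, :T] = True
        resid_var = max(float(np.var(self.B[valid])), 1e-4)
        for c in range(config.n_chains):
            ss = np.random.SeedSequence([config.rng_seed, c])
            rng = np.random.default_rng(ss)
            a_lo = rng.uniform(0.05, 0.4)
            a_hi = rng.uniform(0.5, 0.95)
            init = np.array(
                [
                    a_lo,
                    a_hi,
                    rng.uniform(0.05, 0.3),
                    rng.uniform(0.02, 0.2),
                    resid_var * rng.uniform(0.05, 0.5),
                ]
            )
            scales = np.array([0.3, 0.3, 0.3, 0.3])
            numba_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
            d, Vs, zs, als, n_kept, acc = run_chain(
                self.B, self.r, self.lengths, config.n_samples, n_burn,
                numba_seed, init, scales,
            )
            draws[c] = d
            V_sum += Vs
            z_sum += zs
            alpha_sum += als
            n_kept_total += n_kept
            accepts.append(acc)
        return HdrResults(self, config, draws, V_sum, z_sum, alpha_sum, n_kept_total, np.array(accepts))


class HdrResults:
    """Posterior summaries for one fitted animal model."""

    def __init__(self, model, config, draws, V_sum, z_sum, alpha_sum, n_kept, accept_rates):
        self.model = model
        self.config = config
        self.draws = draws  # (chains, samples, 5), burn-in included
        self.accept_rates = accept_rates
        n_burn = int(config.n_samples * config.burn_in)
        self.posterior = draws[:, n_burn:, :]  # post-burn-in
        means = self.posterior.reshape(-1, 5).mean(axis=0)
        sds = self.posterior.reshape(-1, 5).std(axis=0, ddof=1)
        lo, hi = np.percentile(self.posterior.reshape(-1, 5), [2.5, 97.5], axis=0)
        self.rhat = np.array([split_rhat(self.posterior[:, :, j]) for j in range(5)])
        self.summary_frame = pd.DataFrame(
            {
                "mean": means,
                "sd": sds,
                "ci_2.5": lo,
                "ci_97.5": hi,
                "rhat": self.rhat,
            },
            index=list(PARAM_NAMES),
        )
        self.converged = bool(np.all(self.rhat < config.rhat_threshold))
        self.params = LearnerParams(
            alpha_low=float(means[0]), alpha_high=float(means[1]), phi=float(means[2]),
            beta_drift=float(means[3]), eta=float(means[4]),
        )
        # per-trial posterior means, averaged over chains and kept draws
        rows = []
        for i in range(model.B.shape[0]):
            T = model.lengths[i]
            rows.append(
                pd.DataFrame(
                    {
                        "row": i,
                        "V": V_sum[i, :T] / n_kept,
                        "z": z_sum[i, :T] / n_kept,
                        "alpha_star": alpha_sum[i, :T] / n_kept,
                    }
                )
            )
        trial_post = pd.concat(rows, ignore_index=True)
        if model.index is not None:
            trial_post = pd.concat(
                [model.index.reset_index(drop=True), trial_post.drop(columns="row")], axis=1
            )
        self.trial_posterior = trial_post

    def summary(self) -> str:
        lines = [
            "Hierarchical delta-rule learner — posterior summary",
            f"chains={self.config.n_chains}  samples/chain={self.config.n_samples}  "
            f"burn-in={self.config.burn_in:.0%}  seed={self.config.rng_seed}",
            f"converged={self.converged} (all split-Rhat < {self.config.rhat_threshold})",
            "",
            self.summary_frame.to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, summary_path, trace_path) -> None:
        self.summary_frame.to_csv(summary_path)
        self.trial_posterior.to_csv(trace_path, index=False)


def fit_mcmc(trials: pd.DataFrame, setting: int, animal, config: McmcConfig | None = None) -> HdrResults:
    """Fit the learner for one animal of one setting across participants."""
    return HierarchicalDeltaModel.from_trials(trials, setting, animal).fit(config)
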