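"""Hierarchical delta-rule learner: forward belief updates and likelihood.

The learner tracks an animal's hiding location with two coupled
delta-rules.  A position rule updates the predicted location ``V`` with
the prediction error ``r - V``; a drift rule updates the predicted
per-trial displacement ``V'`` with the same error.  The position
learning rate switches between a low and a high value on every trial,
governed by a latent Bernoulli indicator ``z_t`` with rate ``phi``: the
high rate lets the learner re-anchor quickly after an abrupt change
point, the low rate filters noise in stable stretches.  Observed
predictions ``B_t`` are modelled as Gaussian around the current belief
``V_t`` with variance ``eta``.

Update order per trial (all using the pre-update state):

    V'_new = V' + beta * (r - V)
    V_new  = V  + V' + alpha_t * (r - V)

The belief about a new animal is initialised at that animal's first
observed location with zero drift, and the first trial contributes the
response likelihood evaluated at that initial belief.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearnerParams",
    "BeliefState",
    "LatentPath",
    "delta_update",
    "select_alpha",
    "response_loglik",
    "forward_filter",
    "simulate_learner",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LearnerParams:
    """Per-animal learner parameters, shared across participants.

    alpha_low, alpha_high : position learning rates, 0 < low < high < 1
    phi : Bernoulli rate of the high-rate indicator, in (0, 1)
    beta_drift : drift learning rate, in (0, 1)
    eta : response variance (strip units squared), > 0
    """

    alpha_low: float
    alpha_high: float
    phi: float
    beta_drift: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("alpha_low", "alpha_high", "phi", "beta_drift"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if not self.alpha_low < self.alpha_high:
            raise ValueError("identifiability requires alpha_low < alpha_high")
        if not self.eta > 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")


@dataclass
class BeliefState:
    """Current belief: predicted position V and predicted drift V'."""

    V: float
    V_drift: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V) and math.isfinite(self.V_drift)):
            raise ValueError("belief state must be finite")


@dataclass
class LatentPath:
    """Realised high/low-rate indicators for one trial sequence."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must be binary")

    def __len__(self) -> int:
        return len(self.z)

    def alpha_star(self, params: LearnerParams) -> np.ndarray:
        """Realised per-trial learning rate."""
        return np.where(self.z == 1, params.alpha_high, params.alpha_low)


def delta_update(state: BeliefState, r: float, alpha: float, beta: float) -> BeliefState:
    """One coupled delta-rule step; both updates use the pre-update state."""
    if not (math.isfinite(r) and math.isfinite(alpha) and math.isfinite(beta)):
        raise ValueError("inputs must be finite")
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("learning rates must lie in [0, 1]")
    pe = r - state.V
    return BeliefState(V=state.V + state.V_drift + alpha * pe, V_drift=state.V_drift + beta * pe)


def select_alpha(z: int, params: LearnerParams) -> float:
    """High rate when the indicator is 1, low rate when it is 0."""
    if z not in (0, 1):
        raise ValueError("z must be 0 or 1")
    return params.alpha_high if z == 1 else params.alpha_low


def response_loglik(B: float, V: float, eta: float) -> float:
    """Gaussian log-density of a prediction B around the belief V with variance eta."""
    if eta <= 0:
        raise ValueError("eta must be > 0")
    d = B - V
    return -0.5 * (_LOG_2PI + math.log(eta)) - 0.5 * d * d / eta


def forward_filter(
    B: np.ndarray,
    r: np.ndarray,
    params: LearnerParams,
    path: LatentPath,
    init: BeliefState | None = None,
) -> tuple[np.ndarray, float]:
    """Run the learner over one animal's trial sequence.

    Parameters
    ----------
    B, r : arrays of equal length T
        The participant's predictions and the observed locations.
    params : LearnerParams
    path : LatentPath of length T
        Realised indicators z_t.
    init : BeliefState, optional
        Starting belief; defaults to ``BeliefState(V=r[0], V_drift=0)``.

    Returns
    -------
    V : array of length T
        The pre-update belief used on each trial.
    loglik : float
        Sum over trials of the response log-likelihood of ``B_t`` at the
        pre-update ``V_t``.
    """
    B = np.asarray(B, dtype=float)
    r = np.asarray(r, dtype=float)
    if B.shape != r.shape or B.ndim != 1:
        raise ValueError("B and r must be 1-D arrays of equal length")
    if len(path) != len(B):
        raise ValueError(f"latent path length {len(path)} != sequence length {len(B)}")
    state = BeliefState(V=float(r[0])) if init is None else init
    V_seq = np.empty(len(B))
    ll = 0.0
    for t in range(len(B)):
        V_seq[t] = state.V
        ll += response_loglik(B[t], state.V, params.eta)
        state = delta_update(state, r[t], select_alpha(int(path.z[t]), params), params.beta_drift)
    return V_seq, ll


def simulate_learner(params: LearnerParams, sequence, rng_seed: int):
    """Generate synthetic predictions from the learner run generatively.

    ``z_t`` is sampled Bernoulli(phi), the belief is propagated with the
    forward updates, and ``B_t`` is drawn Gaussian(V_t, eta).  Returns a
    dict with arrays ``B``, ``V``, ``z``.
    """
    positions = np.asarray(getattr(sequence, "positions", sequence), dtype=float)
    rng = np.random.default_rng(rng_seed)
    T = len(positions)
    z = (rng.random(T) < params.phi).astype(np.int8)
    sd = math.sqrt(params.eta)
    V = np.empty(T)
    B = np.empty(T)
    state = BeliefState(V=float(positions[0]))
    for t in range(T):
        V[t] = state.V
        B[t] = state.V + rng.normal(0.0, sd)
        state = delta_update(
            state, positions[t], select_alpha(int(z[t]), params), params.beta_drift
        )
    return {"B": B, "V": V, "z": z}
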