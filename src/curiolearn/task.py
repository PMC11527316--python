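"""Hiding-pattern generation and session protocol for the exploration task.

Participants play a hide-and-seek game with four animal characters per
setting.  Each animal hides along a one-dimensional strip (normalised to
[0, 1]) following a Gaussian generative pattern whose latent mean can
drift gradually or be resampled abruptly (a change point).  A setting
ends once any animal has hidden ``per_animal_hide_cap`` times or the
participant has played ``per_setting_play_cap`` trials in total.

Four qualitative pattern types are used, three of them learnable:

* ``LOW_NOISE_DRIFT`` — low noise, small drift, rare change points
* ``HIGH_NOISE``      — high noise, stationary (unlearnable)
* ``HIGH_CPP``        — low noise, frequent change points
* ``DRIFT_CPP``       — low noise, strong drift and frequent change points

The numeric levels attached to each label are package defaults chosen to
realise those qualitative contrasts; they are configurable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PATTERN_LABELS",
    "DEFAULT_PATTERNS",
    "PatternSpec",
    "HidingSequence",
    "ExperimentConfig",
    "generate_hiding_sequence",
    "build_experiment",
    "setting_is_over",
]

PATTERN_LABELS = ("LOW_NOISE_DRIFT", "HIGH_NOISE", "HIGH_CPP", "DRIFT_CPP")


@dataclass(frozen=True)
class PatternSpec:
    """Generative parameters of one hiding pattern.

    Parameters
    ----------
    label : str
        One of :data:`PATTERN_LABELS`.
    mean0 : float
        Initial latent mean position, in [0, 1] strip units.
    noise_sd : float
        Standard deviation of the observed location around the latent
        mean (strip units, >= 0).
    drift_rate : float
        Per-trial displacement of the latent mean (strip units/trial).
        Reflected at the strip boundaries.
    cpp : float
        Change-point probability: per-trial probability that the latent
        mean is resampled uniformly on [0, 1].
    """

    label: str
    mean0: float = 0.5
    noise_sd: float = 0.0
    drift_rate: float = 0.0
    cpp: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {self.label!r}")
        if not (0.0 <= self.mean0 <= 1.0):
            raise ValueError(f"mean0 must lie in [0, 1], got {self.mean0}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.cpp <= 1.0):
            raise ValueError(f"cpp must lie in [0, 1], got {self.cpp}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSpec":
        return cls(**d)


#: Default numeric levels for each qualitative pattern label.
DEFAULT_PATTERNS: dict[str, PatternSpec] = {
    "LOW_NOISE_DRIFT": PatternSpec("LOW_NOISE_DRIFT", noise_sd=0.03, drift_rate=0.005, cpp=0.01),
    "HIGH_NOISE": PatternSpec("HIGH_NOISE", noise_sd=0.25, drift_rate=0.0, cpp=0.0),
    "HIGH_CPP": PatternSpec("HIGH_CPP", noise_sd=0.03, drift_rate=0.0, cpp=0.15),
    "DRIFT_CPP": PatternSpec("DRIFT_CPP", noise_sd=0.03, drift_rate=0.02, cpp=0.15),
}


@dataclass
class HidingSequence:
    """Latent means and observed hiding locations for one animal.

    ``means[t]`` is the latent mean on trial t (0-based), ``positions[t]``
    the observed location, and ``change_points`` the 0-based trial
    indices at which the mean was resampled.  With ``noise_sd == 0`` the
    positions equal the means.
    """

    means: np.ndarray
    positions: np.ndarray
    change_points: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.change_points = np.asarray(self.change_points, dtype=int)
        if len(self.means) != len(self.positions):
            raise ValueError("means and positions must have equal length")
        if len(self.change_points) and (
            self.change_points.min() < 0 or self.change_points.max() >= len(self.means)
        ):
            raise ValueError("change_points contain invalid trial indices")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with 1-based trial index."""
        is_cp = np.zeros(len(self), dtype=int)
        is_cp[self.change_points] = 1
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "mean": self.means,
                "position": self.positions,
                "is_change_point": is_cp,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HidingSequence":
        cp = np.flatnonzero(df["is_change_point"].to_numpy() == 1)
        return cls(df["mean"].to_numpy(), df["position"].to_numpy(), cp)


def _reflect_unit(x: float) -> float:
    """Reflect x into [0, 1] (mirror at the boundaries)."""
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


def generate_hiding_sequence(spec: PatternSpec, n_trials: int, rng_seed: int) -> HidingSequence:
    """Simulate one animal's hiding locations.

    Trial 1 starts at ``spec.mean0``.  On every later trial the latent
    mean is resampled uniformly on [0, 1] with probability ``spec.cpp``
    (recorded as a change point); otherwise it advances by
    ``spec.drift_rate`` with reflection at the boundaries.  The observed
    location is Gaussian around the mean with sd ``spec.noise_sd``,
    clipped to [0, 1].
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng_seed)
    means = np.empty(n_trials)
    cps: list[int] = []
    mean = float(spec.mean0)
    drift = float(spec.drift_rate)
    means[0] = mean
    for t in range(1, n_trials):
        if spec.cpp > 0 and rng.random() < spec.cpp:
            mean = rng.uniform(0.0, 1.0)
            cps.append(t)
        elif drift != 0.0:
            nxt = mean + drift
            if nxt < 0.0 or nxt > 1.0:
                drift = -drift
                nxt = _reflect_unit(nxt)
            mean = nxt
        means[t] = mean
    if spec.noise_sd > 0:
        positions = np.clip(means + rng.normal(0.0, spec.noise_sd, n_trials), 0.0, 1.0)
    else:
        positions = means.copy()
    return HidingSequence(means, positions, np.array(cps, dtype=int))


@dataclass
class ExperimentConfig:
    """Session protocol: settings, caps, and animal-to-pattern assignment.

    ``pattern_assignment[s][a]`` gives the :class:`PatternSpec` of animal
    ``a`` (0-based) in setting ``s`` (1-based).  Each setting contains
    exactly one pattern of each label.
    """

    n_settings: int = 3
    animals_per_setting: int = 4
    per_animal_hide_cap: int = 35
    per_setting_play_cap: int = 90
    pattern_assignment: dict[int, dict[int, PatternSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_settings", "animals_per_setting", "per_animal_hide_cap", "per_setting_play_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for s, amap in self.pattern_assignment.items():
            labels = sorted(spec.label for spec in amap.values())
            if labels != sorted(PATTERN_LABELS):
                raise ValueError(f"setting {s} must contain exactly one pattern of each label")

    def to_dict(self) -> dict:
        return {
            "n_settings": self.n_settings,
            "animals_per_setting": self.animals_per_setting,
            "per_animal_hide_cap": self.per_animal_hide_cap,
            "per_setting_play_cap": self.per_setting_play_cap,
            "pattern_assignment": {
                str(s): {str(a): spec.to_dict() for a, spec in amap.items()}
                for s, amap in self.pattern_assignment.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        pa = {
            int(s): {int(a): PatternSpec.from_dict(sd) for a, sd in amap.items()}
            for s, amap in d.get("pattern_assignment", {}).items()
        }
        return cls(
            n_settings=d.get("n_settings", 3),
            animals_per_setting=d.get("animals_per_setting", 4),
            per_animal_hide_cap=d.get("per_animal_hide_cap", 35),
            per_setting_play_cap=d.get("per_setting_play_cap", 90),
            pattern_assignment=pa,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_experiment(
    counterbalance_seed: int,
    patterns: dict[str, PatternSpec] | None = None,
    n_settings: int = 3,
) -> ExperimentConfig:
    """Build a session config with a counterbalanced pattern assignment.

    The animal-to-pattern assignment of each setting is one of the 4!
    permutations of the pattern labels, indexed deterministically by the
    seed: setting ``s`` uses permutation ``(seed + 7*(s-1)) mod 24``, so
    24 consecutive seeds enumerate every assignment for a given setting
    while settings within one session differ from each other.

    Each animal also gets a seed-determined home location (``mean0``
    uniform on [0.15, 0.85]) so that patterns start away from the strip
    centre and there is something to learn from the first trials on.
    """
    import dataclasses

    patterns = dict(DEFAULT_PATTERNS if patterns is None else patterns)
    perms = list(itertools.permutations(PATTERN_LABELS))
    rng = np.random.default_rng(counterbalance_seed)
    assignment: dict[int, dict[int, PatternSpec]] = {}
    for s in range(1, n_settings + 1):
        perm = perms[(counterbalance_seed + 7 * (s - 1)) % len(perms)]
        assignment[s] = {
            a: dataclasses.replace(patterns[perm[a]], mean0=float(rng.uniform(0.15, 0.85)))
            for a in range(4)
        }
    return ExperimentConfig(n_settings=n_settings, pattern_assignment=assignment)


def setting_is_over(per_animal_hide_counts, total_plays: int, config: ExperimentConfig) -> bool:
    """True once any animal reached the hide cap or total plays reached the play cap."""
    counts = np.asarray(per_animal_hide_counts)
    if (counts < 0).any() or total_plays < 0:
        raise ValueError("counts must be non-negative")
    return bool((counts >= config.per_animal_hide_cap).any() or total_plays >= config.per_setting_play_cap)
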