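"""Synthetic participants: trait questionnaires and simulated task play.

The cohort generator provides ground truth for every downstream stage.
Each participant has a latent trait (standard-normal across the cohort)
that drives

* their questionnaire responses — a 44-item instrument on a 3-point
  scale, partitioned into six domains (reduced contact, reduced
  empathy, reduced interpersonal insight, violations of social
  conventions, insistence on sameness, sensory stimulation and motor
  stereotypies), answered once as a self-report and once as an
  other-report;
* their task policy — how strongly learning progress, expected
  prediction error and novelty push them to abandon the current animal
  (with separate early- and late-engagement weights), which attributes
  attract their next choice, and how fast their internal delta-rule
  learner updates.

The trait-to-policy link is a documented linear map
(:class:`PolicyLink`), so the trait-by-time interactions targeted by
the downstream regressions exist in the generative process with known
signs: low-trait agents lean on learning progress early and on expected
error late, high-trait agents are more persistent and lean on learning
progress late.  Setting every slope to zero yields a null cohort for
type-I-error studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curiosity import EPE_UNSEEN
from .learner import BeliefState, LearnerParams, delta_update, select_alpha
from .task import ExperimentConfig, build_experiment, generate_hiding_sequence, setting_is_over

__all__ = [
    "SUBSCALE_ITEMS",
    "TraitProfile",
    "AgentPolicy",
    "PolicyLink",
    "CohortData",
    "simulate_questionnaire",
    "simulate_participant",
    "simulate_cohort",
]

#: Fixed partition of the 44 items into the six domains (0-based item slices).
SUBSCALE_ITEMS: dict[str, tuple[int, int]] = {
    "reduced_contact": (0, 8),
    "reduced_empathy": (8, 15),
    "reduced_interpersonal_insight": (15, 23),
    "violations_of_social_conventions": (23, 29),
    "insistence_on_sameness": (29, 36),
    "sensory_and_motor_stereotypies": (36, 44),
}

_N_ITEMS = 44
# Item thresholds of the ordered 3-category response model: fixed per
# item so the instrument is identical for every simulated respondent.
_CUT1 = np.linspace(-1.0, 1.0, _N_ITEMS)
_CUT2 = _CUT1 + 1.5
_ITEM_SCALE = 0.7
# Perceived-trait noise of each informant; other-reports are treated as
# the slightly more reliable source.
_REPORT_NOISE = {"self": 0.35, "other": 0.25}

# Nominal scales used to put policy weights on roughly per-SD units.
_LP_SCALE = 0.1
_EPE_SCALE = 0.1
_NOV_SCALE = 10.0
_T_MEAN = 6.0
_T_SD = 3.0


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class TraitProfile:
    """One questionnaire administration."""

    latent_trait: float
    report_type: str
    item_responses: np.ndarray
    subscale_scores: dict[str, int] = field(default_factory=dict)
    total_score: int = 0

    def __post_init__(self) -> None:
        self.item_responses = np.asarray(self.item_responses, dtype=int)
        if len(self.item_responses) != _N_ITEMS:
            raise ValueError(f"expected {_N_ITEMS} item responses")
        if not np.isin(self.item_responses, (1, 2, 3)).all():
            raise ValueError("item responses must be 1, 2 or 3")
        if not self.subscale_scores:
            self.subscale_scores = {
                name: int(self.item_responses[lo:hi].sum())
                for name, (lo, hi) in SUBSCALE_ITEMS.items()
            }
        self.total_score = int(sum(self.subscale_scores.values()))


def simulate_questionnaire(latent_trait: float, report_type: str, rng_seed: int) -> TraitProfile:
    """Draw one 44-item profile from an ordered 3-category response model.

    Each item has fixed thresholds; the probability of higher response
    categories increases monotonically with the latent trait.  The
    informant perceives the trait with Gaussian noise (self-reports
    noisier than other-reports).
    """
    if report_type not in _REPORT_NOISE:
        raise ValueError(f"report_type must be one of {sorted(_REPORT_NOISE)}")
    rng = np.random.default_rng(rng_seed)
    perceived = latent_trait + rng.normal(0.0, _REPORT_NOISE[report_type])
    p_le1 = 1.0 / (1.0 + np.exp(-(_CUT1 - perceived) / _ITEM_SCALE))
    p_le2 = 1.0 / (1.0 + np.exp(-(_CUT2 - perceived) / _ITEM_SCALE))
    u = rng.random(_N_ITEMS)
    responses = np.where(u < p_le1, 1, np.where(u < p_le2, 2, 3))
    return TraitProfile(latent_trait, report_type, responses)


@dataclass
class AgentPolicy:
    """Planted behavioural policy of one agent.

    Leave weights are log-odds per nominal-SD of the predictor; the
    effective weight of learning progress and expected error moves from
    its early to its late value along a logistic ramp in standardized
    engagement time.  Choice weights are conditional-logit utilities per
    nominal-SD of the option attribute.
    """

    leave_intercept: float = -1.8
    w_lp_early: float = 0.0
    w_lp_late: float = 0.0
    w_epe_early: float = 0.0
    w_epe_late: float = 0.0
    w_nov_leave: float = 0.0
    choice_w_nov: float = 0.0
    choice_w_elp: float = 0.0
    choice_w_epe: float = 0.0
    learner_params: LearnerParams = field(
        default_factory=lambda: LearnerParams(0.12, 0.75, 0.12, 0.08, 0.0064)
    )
    response_noise_sd: float = 0.08
    memory_retention: float = 1.0
    warmup_noise_sd: float = 0.0
    warmup_tau: float = 4.0
    switch_disruption_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")
        if not (0.0 <= self.memory_retention <= 1.0):
            raise ValueError("memory_retention must lie in [0, 1]")
        if self.warmup_noise_sd < 0 or self.warmup_tau <= 0:
            raise ValueError("warm-up parameters must be non-negative (tau > 0)")
        if self.switch_disruption_sd < 0:
            raise ValueError("switch_disruption_sd must be >= 0")

    def leave_weights_at(self, t_in_engagement: int) -> tuple[float, float]:
        """(w_lp, w_epe) at a given consecutive-trial count."""
        ramp = _sigmoid((t_in_engagement - _T_MEAN) / _T_SD)
        w_lp = self.w_lp_early + (self.w_lp_late - self.w_lp_early) * ramp
        w_epe = self.w_epe_early + (self.w_epe_late - self.w_epe_early) * ramp
        return w_lp, w_epe


@dataclass
class PolicyLink:
    """Deterministic map from the latent trait (in SD units) to a policy.

    Every ``*_slope`` is the change per trait-SD.  The defaults plant
    the qualitative structure the decision analyses look for:

    * leave weights — low-trait agents weight learning progress early
      (``lp_early``) and expected error late (``epe_late``); high-trait
      agents are more persistent (lower intercept) and weight learning
      progress late.  Both planted trait-by-time interactions are
      negative on the model's scale.
    * choice weights — everyone prefers novel options; expected-progress
      seeking rises with the trait, expected-error avoidance falls.
    * learning — the low learning rate rises with the trait
      (``alpha_low_slope``), so higher-trait agents improve faster on
      learnable patterns.
    """

    intercept_base: float = -1.8
    intercept_slope: float = -0.5
    intercept_noise_sd: float = 0.3
    lp_early_base: float = -0.4
    lp_early_slope: float = 0.4
    lp_late_base: float = -0.4
    lp_late_slope: float = -0.4
    epe_early_base: float = 0.0
    epe_early_slope: float = 0.0
    epe_late_base: float = 1.0
    epe_late_slope: float = -1.0
    nov_leave_base: float = 0.15
    nov_leave_slope: float = 0.0
    choice_nov_base: float = 0.8
    choice_nov_slope: float = 0.0
    choice_elp_base: float = 0.1
    choice_elp_slope: float = 0.2
    choice_epe_base: float = -0.15
    choice_epe_slope: float = 0.15
    alpha_low_base: float = 0.12
    alpha_low_slope: float = 0.06
    beta_drift_base: float = 0.03
    beta_drift_slope: float = 0.03
    retention_base: float = 1.0
    retention_slope: float = 0.0
    warmup_sd_base: float = 0.0
    warmup_sd_slope: float = 0.0
    disruption_base: float = 0.0
    disruption_slope: float = 0.0
    learner_base: LearnerParams = field(
        default_factory=lambda: LearnerParams(0.12, 0.75, 0.12, 0.03, 0.0064)
    )
    response_noise_sd: float = 0.08

    @classmethod
    def learning_speed_study(cls) -> "PolicyLink":
        """Link for the learning-performance power study.

        Trait-independent leave/choice policies with persistent agents,
        plus a strong trait gradient in learning: higher-trait agents
        are more disrupted by switching (larger belief kick) but repair
        much faster (higher low learning rate), producing steeper
        within-engagement error decline on the learnable patterns and
        little change on the unlearnable high-noise pattern.
        """
        link = cls.null()
        link.intercept_base = -2.8
        link.disruption_base = 0.15
        link.disruption_slope = 0.15
        link.alpha_low_base = 0.2
        link.alpha_low_slope = 0.13
        link.learner_base = LearnerParams(0.2, 0.5, 0.08, 0.02, 0.0064)
        return link

    @classmethod
    def null(cls) -> "PolicyLink":
        """Trait-independent policies: every slope zero (type-I studies)."""
        return cls(
            intercept_slope=0.0,
            lp_early_slope=0.0,
            lp_late_slope=0.0,
            epe_early_slope=0.0,
            epe_late_slope=0.0,
            nov_leave_slope=0.0,
            choice_elp_slope=0.0,
            choice_epe_slope=0.0,
            alpha_low_slope=0.0,
            beta_drift_slope=0.0,
            retention_slope=0.0,
            warmup_sd_slope=0.0,
            disruption_slope=0.0,
        )

    def policy_for(self, trait_z: float, intercept_noise: float = 0.0) -> AgentPolicy:
        alpha_low = float(np.clip(self.alpha_low_base + self.alpha_low_slope * trait_z, 0.01, 0.45))
        beta = float(np.clip(self.beta_drift_base + self.beta_drift_slope * trait_z, 0.001, 0.2))
        lp = replace(self.learner_base, alpha_low=alpha_low, beta_drift=beta)
        return AgentPolicy(
            leave_intercept=self.intercept_base + self.intercept_slope * trait_z + intercept_noise,
            w_lp_early=self.lp_early_base + self.lp_early_slope * trait_z,
            w_lp_late=self.lp_late_base + self.lp_late_slope * trait_z,
            w_epe_early=self.epe_early_base + self.epe_early_slope * trait_z,
            w_epe_late=self.epe_late_base + self.epe_late_slope * trait_z,
            w_nov_leave=self.nov_leave_base + self.nov_leave_slope * trait_z,
            choice_w_nov=self.choice_nov_base + self.choice_nov_slope * trait_z,
            choice_w_elp=self.choice_elp_base + self.choice_elp_slope * trait_z,
            choice_w_epe=self.choice_epe_base + self.choice_epe_slope * trait_z,
            learner_params=lp,
            response_noise_sd=self.response_noise_sd,
            memory_retention=float(
                np.clip(self.retention_base + self.retention_slope * trait_z, 0.0, 1.0)
            ),
            warmup_noise_sd=float(
                max(0.0, self.warmup_sd_base + self.warmup_sd_slope * trait_z)
            ),
            switch_disruption_sd=float(
                max(0.0, self.disruption_base + self.disruption_slope * trait_z)
            ),
        )


_TRIAL_COLUMNS = [
    "participant", "setting", "animal", "pattern", "setting_trial",
    "engagement_id", "trial_in_engagement", "exposure", "is_change_point",
    "outcome", "prediction", "V", "alpha_star", "z", "pe", "lp", "novelty",
    "epe", "epe_next", "elp_next", "leave", "forced_end",
]


def simulate_participant(
    policy: AgentPolicy,
    experiment: ExperimentConfig,
    rng_seed: int,
    participant_id: int = 0,
    sequence_seed: int | None = None,
) -> pd.DataFrame:
    """Play the full session under a planted policy.

    The agent runs the delta-rule learner internally (beliefs persist
    when an animal is revisited within a setting), computes its own
    trial-level drives, leaves with the policy's logistic probability,
    and on leaving picks among the other three animals by a
    conditional-logit over their frozen novelty, expected progress and
    expected error.  Session caps are enforced; a setting that ends by
    a cap marks its last trial as a forced transition.
    """
    rng = np.random.default_rng(rng_seed)
    lp_params = policy.learner_params
    rows: list[tuple] = []
    engagement_id = 0
    for setting in range(1, experiment.n_settings + 1):
        assign = experiment.pattern_assignment[setting]
        animals = sorted(assign)
        # per-participant sequences by default; a fixed sequence_seed yokes
        # the stimulus set across participants (shared realizations)
        seqs = {}
        for a in animals:
            if sequence_seed is None:
                sseed = int(rng.integers(2**31))
            else:
                sseed = int(
                    np.random.SeedSequence([sequence_seed, setting, a]).generate_state(1)[0]
                    % (2**31)
                )
                rng.integers(2**31)  # keep the participant rng stream aligned
            seqs[a] = generate_hiding_sequence(assign[a], experiment.per_animal_hide_cap, sseed)
        # per-animal frozen state within the setting
        exposure = {a: 0 for a in animals}
        belief: dict[int, BeliefState | None] = {a: None for a in animals}
        epe_held = {a: EPE_UNSEEN for a in animals}
        elp_held = {a: 0.0 for a in animals}
        total_plays = 0
        current = animals[int(rng.integers(len(animals)))]
        t_eng = 0
        pe_prev = np.nan
        engagement_id += 1
        while True:
            t_eng += 1
            expo = exposure[current] = exposure[current] + 1
            total_plays += 1
            seq = seqs[current]
            r = float(seq.positions[expo - 1])
            is_cp = int(expo - 1 in seq.change_points)
            state = belief[current]
            if state is None:
                # uninformed prior: the agent starts at the strip centre,
                # so its error declines over the first engagement as it learns
                state = BeliefState(V=0.5)
            V = state.V
            B = float(np.clip(V + rng.normal(0.0, policy.response_noise_sd), 0.0, 1.0))
            z = int(rng.random() < lp_params.phi)
            alpha = select_alpha(z, lp_params)
            pe = abs(r - V)
            lp = pe_prev - pe if t_eng >= 2 else np.nan
            epe = pe if expo == 1 else epe_held[current]
            epe_next = epe + alpha * (pe - epe)
            elp_next = pe - epe_next
            epe_held[current] = epe_next
            elp_held[current] = elp_next
            # attentional warm-up: right after a switch the perceived outcome
            # is noisy; perception stabilises over consecutive trials
            r_eff = r
            if policy.warmup_noise_sd > 0:
                w_t = policy.warmup_noise_sd * math.exp(-(t_eng - 1) / policy.warmup_tau)
                if w_t > 1e-4:
                    r_eff = float(np.clip(r + rng.normal(0.0, w_t), 0.0, 1.0))
            belief[current] = delta_update(state, r_eff, alpha, lp_params.beta_drift)
            # leave decision (after seeing the outcome)
            w_lp, w_epe = policy.leave_weights_at(t_eng)
            lp_term = 0.0 if not np.isfinite(lp) else lp
            logit = (
                policy.leave_intercept
                + w_lp * lp_term / _LP_SCALE
                + w_epe * epe_next / _EPE_SCALE
                + policy.w_nov_leave * (-expo) / _NOV_SCALE
            )
            leave = int(rng.random() < _sigmoid(logit))
            over = setting_is_over([exposure[a] for a in animals], total_plays, experiment)
            forced = int(over and not leave)
            rows.append(
                (participant_id, setting, current, assign[current].label, total_plays,
                 engagement_id, t_eng, expo, is_cp, r, B, V, alpha, z, pe, lp,
                 -expo, epe, epe_next, elp_next, leave, forced)
            )
            if over:
                break
            if leave:
                options = [a for a in animals if a != current]
                utils = np.array(
                    [
                        policy.choice_w_nov * (-exposure[a]) / _NOV_SCALE
                        + policy.choice_w_elp * elp_held[a] / _EPE_SCALE
                        + policy.choice_w_epe * epe_held[a] / _EPE_SCALE
                        for a in options
                    ]
                )
                p = np.exp(utils - utils.max())
                p /= p.sum()
                current = options[int(rng.choice(len(options), p=p))]
                # interference during disengagement: the remembered belief
                # decays toward the strip centre (full retention by default)
                rho = policy.memory_retention
                if rho < 1.0 and belief[current] is not None:
                    st = belief[current]
                    belief[current] = BeliefState(
                        V=0.5 + rho * (st.V - 0.5), V_drift=rho * st.V_drift
                    )
                    epe_held[current] = EPE_UNSEEN + rho * (epe_held[current] - EPE_UNSEEN)
                # switching disrupts the remembered location: a one-time
                # Gaussian kick to the belief, repaired by subsequent learning
                if policy.switch_disruption_sd > 0 and belief[current] is not None:
                    st = belief[current]
                    belief[current] = BeliefState(
                        V=float(np.clip(st.V + rng.normal(0.0, policy.switch_disruption_sd), 0.0, 1.0)),
                        V_drift=st.V_drift,
                    )
                engagement_id += 1
                t_eng = 0
                pe_prev = np.nan
            else:
                pe_prev = pe
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


@dataclass
class CohortData:
    """A simulated cohort: trial logs plus participant-level table."""

    trials: pd.DataFrame
    participants: pd.DataFrame

    def write(self, trials_path, participants_path) -> None:
        self.trials.to_csv(trials_path, index=False)
        self.participants.to_csv(participants_path, index=False)

    @classmethod
    def read(cls, trials_path, participants_path) -> "CohortData":
        return cls(pd.read_csv(trials_path), pd.read_csv(participants_path))


def simulate_cohort(
    n: int,
    policy_link: PolicyLink | None = None,
    rng_seed: int = 0,
    experiment: ExperimentConfig | None = None,
    p_understood: float = 0.9,
    yoke_sequences: bool = False,
) -> CohortData:
    """Simulate ``n`` participants with trait-linked policies.

    Latent traits are standard normal.  Each participant receives a
    counterbalanced experiment config (unless one is supplied), answers
    both questionnaire variants, plays the full session, and reports
    whether they understood the task and after which setting (1-3, or
    0 for never) they got bored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    link = policy_link if policy_link is not None else PolicyLink()
    master = np.random.default_rng(rng_seed)
    trial_frames = []
    part_rows = []
    for pid in range(1, n + 1):
        trait = float(master.normal())
        exp = experiment if experiment is not None else build_experiment(int(master.integers(2**31)))
        b_noise = float(master.normal(0.0, link.intercept_noise_sd))
        policy = link.policy_for(trait, intercept_noise=b_noise)
        trials = simulate_participant(
            policy, exp, int(master.integers(2**31)), participant_id=pid,
            sequence_seed=rng_seed if yoke_sequences else None,
        )
        trial_frames.append(trials)
        row = {
            "participant": pid,
            "latent_trait": trait,
            "understood_task": int(master.random() < p_understood),
            "boredom_after_setting": int(master.choice([1, 2, 3, 0])),
        }
        for report in ("self", "other"):
            prof = simulate_questionnaire(trait, report, int(master.integers(2**31)))
            row[f"{report}_total"] = prof.total_score
            for name, score in prof.subscale_scores.items():
                row[f"{report}_{name}"] = score
        part_rows.append(row)
    return CohortData(
        trials=pd.concat(trial_frames, ignore_index=True),
        participants=pd.DataFrame(part_rows),
    )
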