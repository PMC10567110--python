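"""Signal-detection observers and synthetic three-arm cohorts.

The study design this generator emulates: three arms (internet-based CBT,
antidepressant medication, no-treatment control), two timepoints (baseline
and 4-week follow-up), each participant contributing one 210-trial staircase
session per timepoint plus item-level questionnaire responses.

Observers are type-1/type-2 signal-detection agents.  On each trial the
internal evidence is drawn from N(s * d, sigma) where d is the log dot
difference and s = +/-1 encodes the side with more dots; the choice is the
evidence sign, so P(correct) = Phi(d / sigma) and the two-down one-up
staircase equilibrates where Phi(d/sigma) = sqrt(0.5), i.e. at
d* = sigma * Phi^-1(sqrt(0.5)).  Confidence compares normalised absolute
evidence |e|/sigma against five ordered criteria shifted by a per-person
bias (criterion units); larger bias means laxer criteria and higher ratings.

Latent symptom structure: three correlated transdiagnostic dimensions (AD,
CIT, SW) at baseline, with arm-specific mean changes at follow-up (clinical
arms improve, controls do not).  Confidence bias is coupled to the latent
state twice over: cross-sectionally (negative AD slope, positive CIT slope)
and longitudinally (bias change = coupling x AD change + arm time effect),
so the downstream pipeline has true effects to recover.  Item responses are
generated by inverting the weighted-sum scoring rule with ordinal rounding
and range clipping.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import (
    CATCH_ITEMS,
    DIMENSIONS,
    INSTRUMENTS,
    WSAS_ITEM_IDS,
    WSAS_SCALE,
    WeightsMatrix,
    clinical_item_ids,
)
from .staircase import SessionData, StaircaseConfig, run_session, sessions_to_frame

__all__ = [
    "ObserverModel",
    "LatentState",
    "CohortDesign",
    "Participant",
    "Cohort",
    "ARMS",
    "Z_EQUILIBRIUM",
    "calibrated_sigma",
    "simulate_choice",
    "simulate_confidence",
    "generate_participant",
    "generate_cohort",
    "generate_item_weights",
    "generate_questionnaire_responses",
]

ARMS = ("icbt", "antidepressant", "control")
TIMEPOINTS = ("baseline", "followup")

#: d/sigma at the two-down one-up operating point: Phi^-1(sqrt(0.5)).
Z_EQUILIBRIUM = 0.5449521356173604

#: Confidence criteria in normalised evidence units (|e|/sigma): the
#: (0.10, 0.28, 0.46, 0.64, 0.82) quantiles of |N(Z_EQUILIBRIUM, 1)|, so an
#: unbiased observer at the staircase operating point uses all six ratings
#: with mean ~3.7.
DEFAULT_CRITERIA = (0.1458, 0.4147, 0.7081, 1.0543, 1.5337)

#: Local slope of mean rating per unit of criterion shift at bias 0 with the
#: default criteria and jitter; converts couplings stated in rating points
#: into criterion units.
RATING_POINTS_PER_BIAS_UNIT = 2.08


def calibrated_sigma(equilibrium_log_diff: float) -> float:
    """Perceptual noise SD whose staircase equilibrium sits at a log difference."""
    return equilibrium_log_diff / Z_EQUILIBRIUM


@dataclass(frozen=True)
class ObserverModel:
    """A stationary signal-detection observer for the dot task.

    sigma: perceptual noise SD in log-dot units (larger = worse acuity).
    confidence_bias: shift of the confidence criteria in criterion units;
        +inf drives every rating to 6, -inf to 1.
    confidence_noise: SD of independent per-criterion jitter per trial.
    rt_location / rt_scale: log-normal response-time parameters (seconds).
    """

    sigma: float
    confidence_bias: float = 0.0
    confidence_noise: float = 0.5
    criteria: tuple[float, ...] = DEFAULT_CRITERIA
    rt_location: float = math.log(0.9)
    rt_scale: float = 0.4

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.confidence_noise < 0:
            raise ValueError("confidence_noise must be non-negative")
        if list(self.criteria) != sorted(self.criteria):
            raise ValueError("confidence criteria must be ordered")

    # Observer protocol for staircase.run_session
    def respond(
        self, log_diff: float, target_side: str, rng: np.random.Generator
    ) -> tuple[str, int, float]:
        chosen, _, evidence = simulate_choice(self, log_diff, rng, target_side)
        conf = simulate_confidence(self, evidence, rng)
        rt = float(rng.lognormal(self.rt_location, self.rt_scale))
        return chosen, conf, rt


def simulate_choice(
    observer: ObserverModel,
    log_diff: float,
    rng: np.random.Generator,
    target_side: str | None = None,
) -> tuple[str, bool, float]:
    """One type-1 decision: returns ``(chosen_side, correct, evidence)``.

    Evidence ~ N(s * log_diff, sigma) with s = +1 if the right patch has
    more dots; the choice is the evidence sign, so P(correct) =
    Phi(log_diff / sigma), strictly increasing in log_diff / sigma.
    """
    if not observer.sigma > 0:
        raise ValueError("sigma must be positive")
    if target_side is None:
        target_side = "right" if rng.random() < 0.5 else "left"
    if target_side not in ("left", "right"):
        raise ValueError(f"invalid target side {target_side!r}")
    s = 1.0 if target_side == "right" else -1.0
    evidence = float(rng.normal(s * log_diff, observer.sigma))
    chosen = "right" if evidence > 0 else "left"
    return chosen, chosen == target_side, evidence


def simulate_confidence(
    observer: ObserverModel, evidence: float, rng: np.random.Generator
) -> int:
    """Type-2 rating: normalised |evidence| against jittered shifted criteria."""
    if not math.isfinite(evidence):
        raise ValueError("evidence must be finite")
    u = abs(evidence) / observer.sigma
    crit = np.asarray(observer.criteria) - observer.confidence_bias
    if observer.confidence_noise > 0:
        crit = crit + rng.normal(0.0, observer.confidence_noise, len(crit))
    return int(1 + np.sum(u > crit))


@dataclass(frozen=True)
class LatentState:
    """Three transdiagnostic dimensions at two timepoints (population SD ~1)."""

    ad0: float
    cit0: float
    sw0: float
    ad1: float
    cit1: float
    sw1: float

    def at(self, timepoint: str) -> np.ndarray:
        if timepoint == "baseline":
            return np.array([self.ad0, self.cit0, self.sw0])
        if timepoint == "followup":
            return np.array([self.ad1, self.cit1, self.sw1])
        raise ValueError(f"unknown timepoint {timepoint!r}")

    @property
    def change(self) -> np.ndarray:
        return self.at("followup") - self.at("baseline")


def _arm_map(value) -> dict[str, float]:
    if isinstance(value, dict):
        return dict(value)
    return {arm: float(value) for arm in ARMS}


@dataclass
class CohortDesign:
    """Generative settings for a full three-arm, two-timepoint cohort.

    Couplings that feed confidence are stated in mean-rating points and
    converted internally to criterion units.  Defaults are the study
    conditions: completer arm sizes 649/82/88, anxious-depression improves
    in the clinical arms only, confidence bias is negatively coupled to AD
    cross-sectionally and to AD *change* longitudinally, and compulsivity
    carries a positive cross-sectional coupling.
    """

    seed: int = 0
    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"icbt": 649, "antidepressant": 82, "control": 88}
    )
    # latent structure
    dimension_correlations: tuple[tuple[float, ...], ...] = (
        (1.0, 0.4, 0.5),
        (0.4, 1.0, 0.3),
        (0.5, 0.3, 1.0),
    )
    change_sd: float = 0.8
    treatment_effect_ad: dict[str, float] = field(
        default_factory=lambda: {"icbt": -0.32, "antidepressant": -0.61, "control": 0.0}
    )
    treatment_effect_cit: dict[str, float] = field(
        default_factory=lambda: {"icbt": -0.20, "antidepressant": -0.25, "control": 0.0}
    )
    treatment_effect_sw: dict[str, float] = field(
        default_factory=lambda: {"icbt": -0.20, "antidepressant": -0.25, "control": 0.0}
    )
    # confidence couplings (rating points)
    cross_sectional_beta_ad: float = -0.10
    cross_sectional_beta_cit: float = 0.12
    baseline_bias_noise: float = 0.80
    confidence_time_effect: dict[str, float] = field(
        default_factory=lambda: {"icbt": 0.17, "antidepressant": 0.30, "control": 0.0}
    )
    coupling_bias_ad: float = -0.10
    change_bias_noise: float = 0.55
    # perception
    observer_sigma: float = 6.7
    sigma_log_sd: float = 0.08
    practice_sigma_factor: float = 0.95
    nonconverger_rate: float = 0.0
    nonconverger_sigma_factor: float = 4.0
    # questionnaires
    item_noise_sd: float = 0.35
    item_gain: float = 0.6
    catch_fail_rate: float = 0.083
    # demographics (shared across arms by default)
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {"Female": 0.774, "Male": 0.218, "Other": 0.008}
    )
    age_mean: float = 32.2
    age_sd: float = 11.0
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"UK": 0.843, "Ireland": 0.138, "Other": 0.019}
    )
    education_probs: dict[str, float] = field(
        default_factory=lambda: {
            "below_undergraduate": 0.227,
            "some_or_completed_undergraduate": 0.529,
            "above_undergraduate": 0.244,
        }
    )
    concurrent_treatment_probs: dict[str, float] = field(
        default_factory=lambda: {"icbt": 0.27, "antidepressant": 0.40, "control": 0.02}
    )
    program_type_probs: dict[str, float] = field(
        default_factory=lambda: {
            "space_from_depression": 0.247,
            "space_from_anxiety": 0.281,
            "life_skills": 0.139,
            "space_from_depression_and_anxiety": 0.120,
            "other": 0.213,
        }
    )
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        for arm, n in self.n_per_arm.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if n <= 0:
                raise ValueError(f"arm size for {arm!r} must be positive, got {n}")
        for probs in (
            self.gender_probs,
            self.country_probs,
            self.education_probs,
            self.program_type_probs,
        ):
            p = np.array(list(probs.values()), float)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("category probabilities must lie in [0, 1]")
        if not 0 <= self.catch_fail_rate <= 1:
            raise ValueError("catch_fail_rate must lie in [0, 1]")
        if not 0 <= self.nonconverger_rate <= 1:
            raise ValueError("nonconverger_rate must lie in [0, 1]")
        corr = np.asarray(self.dimension_correlations, float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("dimension_correlations must be a symmetric 3x3 matrix")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("dimension_correlations must be positive semi-definite")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_arm.values())


@dataclass
class Participant:
    participant_id: str
    arm: str
    age: float
    gender: str
    country: str
    education: str
    latent: LatentState
    observers: dict[str, ObserverModel]
    sessions: list[SessionData]
    items: pd.DataFrame  # long: timepoint, item_id, response
    concurrent_treatment: bool
    program_type: str | None = None
    minutes_in_program: float | None = None
    percent_viewed: float | None = None


@dataclass
class Cohort:
    design: CohortDesign
    participants: list[Participant]
    weights: WeightsMatrix

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "arm": p.arm,
                    "age": p.age,
                    "gender": p.gender,
                    "country": p.country,
                    "education": p.education,
                    "concurrent_treatment": p.concurrent_treatment,
                    "program_type": p.program_type,
                    "minutes_in_program": p.minutes_in_program,
                    "percent_viewed": p.percent_viewed,
                }
            )
        return pd.DataFrame(rows)

    def trials_frame(self) -> pd.DataFrame:
        return sessions_to_frame([s for p in self.participants for s in p.sessions])

    def items_frame(self) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            f = p.items.copy()
            f.insert(0, "participant_id", p.participant_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


# --- item weights -----------------------------------------------------------

#: Which dimension each instrument predominantly loads on in the stand-in
#: weights (simple structure with small cross-loadings).
_INSTRUMENT_DIMENSION = {
    "zung": "AD",
    "stai_t": "AD",
    "ssms": "CIT",
    "bis11": "CIT",
    "ocir": "CIT",
    "audit": "CIT",
    "lsas": "SW",
    "aes": "SW",
    "eat26": "SW",
}


def generate_item_weights(seed: int) -> WeightsMatrix:
    """Synthetic stand-in for the published 209x3 item-weight matrix.

    Each item loads mainly on its instrument's dominant dimension
    (uniform 0.3-0.8) with small Gaussian cross-loadings; roughly one item
    in ten also gets a moderate secondary loading.  Deterministic by seed.
    The real published weights, when available, are read from file instead
    (:func:`metacog.scoring.read_weights`).
    """
    rng = np.random.default_rng(seed)
    ids = clinical_item_ids()
    W = rng.normal(0.0, 0.05, size=(209, 3))
    dim_index = {d: j for j, d in enumerate(DIMENSIONS)}
    for i, item in enumerate(ids):
        instrument = item.rsplit("_", 1)[0]
        j = dim_index[_INSTRUMENT_DIMENSION[instrument]]
        W[i, j] = rng.uniform(0.3, 0.8)
        if rng.random() < 0.1:
            k = rng.choice([c for c in range(3) if c != j])
            W[i, k] = rng.uniform(0.1, 0.3)
    return WeightsMatrix(item_ids=tuple(ids), weights=W)


# --- questionnaire responses ------------------------------------------------


def generate_questionnaire_responses(
    latent: np.ndarray | Sequence[float],
    weights: WeightsMatrix,
    noise_sd: float,
    rng: np.random.Generator,
    item_gain: float = 0.6,
    wsas_severity: float = 0.0,
    careless: bool = False,
) -> pd.DataFrame:
    """Item responses consistent with a latent (AD, CIT, SW) state.

    Each clinical item's response is the scale midpoint plus
    ``span * (item_gain * (w_i . theta) + noise)`` rounded to the item's
    ordinal grid and clipped to its range — the approximate linear inverse of
    the weighted-sum scoring rule.  WSAS items are generated around a
    severity level on the 0-8 scale; the two catch items get their mandated
    response unless ``careless``, in which case one (occasionally both) is
    answered wrongly.

    Returns a long DataFrame with columns ``item_id, response``.
    """
    theta = np.asarray(latent, dtype=float)
    if theta.shape != (3,):
        raise ValueError("latent must have three components (AD, CIT, SW)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    signal = weights.weights @ theta  # (209,)
    ids = list(weights.item_ids)
    lo = np.empty(209)
    hi = np.empty(209)
    pos = 0
    for name, scale in INSTRUMENTS.items():
        lo[pos : pos + scale.n_items] = scale.lo
        hi[pos : pos + scale.n_items] = scale.hi
        pos += scale.n_items
    mid = (lo + hi) / 2.0
    span = (hi - lo) / 2.0
    raw = mid + span * (item_gain * signal + rng.normal(0.0, noise_sd, 209))
    responses = np.clip(np.floor(raw + 0.5), lo, hi).astype(int)

    wsas_raw = wsas_severity + rng.normal(0.0, 1.3, len(WSAS_ITEM_IDS))
    wsas = np.clip(np.floor(wsas_raw + 0.5), WSAS_SCALE.lo, WSAS_SCALE.hi).astype(int)

    catch_ids = list(CATCH_ITEMS)
    catch_resp = [CATCH_ITEMS[c].required for c in catch_ids]
    if careless:
        # most careless responders miss one check; a minority miss both
        fail_both = rng.random() < 1 / 6
        fail_idx = set(range(len(catch_ids))) if fail_both else {int(rng.integers(len(catch_ids)))}
        for k in fail_idx:
            item = CATCH_ITEMS[catch_ids[k]]
            wrong = [v for v in range(item.lo, item.hi + 1) if v != item.required]
            catch_resp[k] = int(rng.choice(wrong))

    return pd.DataFrame(
        {
            "item_id": ids + list(WSAS_ITEM_IDS) + catch_ids,
            "response": np.concatenate([responses, wsas, catch_resp]),
        }
    )


# --- participants and cohorts -----------------------------------------------


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], float)
    return str(keys[rng.choice(len(keys), p=p / p.sum())])


def generate_participant(
    arm: str,
    design: CohortDesign,
    rng: np.random.Generator | np.random.SeedSequence,
    weights: WeightsMatrix | None = None,
    participant_id: str | None = None,
) -> Participant:
    """Draw one participant: demographics, latent course, two sessions, items."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if isinstance(rng, np.random.SeedSequence):
        seedseq = rng
    else:
        seedseq = np.random.SeedSequence(int(rng.integers(2**31)))
    rng_local = np.random.default_rng(seedseq)
    session_seeds = seedseq.spawn(2)
    if weights is None:
        weights = generate_item_weights(design.seed)
    pid = participant_id or f"{arm}_{seedseq.entropy}"

    # demographics
    age = float(np.clip(rng_local.normal(design.age_mean, design.age_sd), 18, 80))
    gender = _choice(rng_local, design.gender_probs)
    country = _choice(rng_local, design.country_probs)
    education = _choice(rng_local, design.education_probs)

    # latent course
    corr = np.asarray(design.dimension_correlations, float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    theta0 = chol @ rng_local.standard_normal(3)
    arm_shift = np.array(
        [
            design.treatment_effect_ad[arm],
            design.treatment_effect_cit[arm],
            design.treatment_effect_sw[arm],
        ]
    )
    delta = arm_shift + design.change_sd * (chol @ rng_local.standard_normal(3))
    theta1 = theta0 + delta
    latent = LatentState(*theta0, *theta1)

    # confidence bias (rating points -> criterion units)
    pts = RATING_POINTS_PER_BIAS_UNIT
    bias0_points = (
        design.cross_sectional_beta_ad * theta0[0]
        + design.cross_sectional_beta_cit * theta0[1]
        + rng_local.normal(0.0, design.baseline_bias_noise)
    )
    dbias_points = (
        design.confidence_time_effect[arm]
        + design.coupling_bias_ad * delta[0]
        + rng_local.normal(0.0, design.change_bias_noise)
    )

    sigma0 = design.observer_sigma * math.exp(
        rng_local.normal(0.0, design.sigma_log_sd)
    )
    observers: dict[str, ObserverModel] = {}
    sessions: list[SessionData] = []
    items_frames = []
    for t_idx, timepoint in enumerate(TIMEPOINTS):
        sigma = sigma0 * (design.practice_sigma_factor if t_idx else 1.0)
        if rng_local.random() < design.nonconverger_rate:
            sigma = sigma * design.nonconverger_sigma_factor
        bias_points = bias0_points + (dbias_points if t_idx else 0.0)
        obs = ObserverModel(sigma=sigma, confidence_bias=bias_points / pts)
        observers[timepoint] = obs
        sessions.append(
            run_session(
                obs,
                design.staircase,
                seed=session_seeds[t_idx],
                participant_id=pid,
                timepoint=timepoint,
            )
        )
        careless = rng_local.random() < design.catch_fail_rate
        wsas_severity = 3.3 + 0.7 * latent.at(timepoint)[0] if arm != "control" else 0.9
        items = generate_questionnaire_responses(
            latent.at(timepoint),
            weights,
            design.item_noise_sd,
            rng_local,
            item_gain=design.item_gain,
            wsas_severity=wsas_severity,
            careless=careless,
        )
        items.insert(0, "timepoint", timepoint)
        items_frames.append(items)

    program_type = minutes = pct = None
    if arm == "icbt":
        program_type = _choice(rng_local, design.program_type_probs)
        minutes = float(rng_local.lognormal(math.log(120.0), 0.6))
        pct = float(100.0 * rng_local.beta(2.5, 1.2))
    concurrent = bool(rng_local.random() < design.concurrent_treatment_probs[arm])

    return Participant(
        participant_id=pid,
        arm=arm,
        age=age,
        gender=gender,
        country=country,
        education=education,
        latent=latent,
        observers=observers,
        sessions=sessions,
        items=pd.concat(items_frames, ignore_index=True),
        concurrent_treatment=concurrent,
        program_type=program_type,
        minutes_in_program=minutes,
        percent_viewed=pct,
    )


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate the full three-arm cohort, reproducibly by ``design.seed``.

    Each participant gets an independent seed substream keyed by
    ``(design.seed, arm, index)``, so changing one arm's size leaves every
    other participant's data unchanged.
    """
    weights = generate_item_weights(design.seed)
    participants: list[Participant] = []
    for arm_idx, arm in enumerate(ARMS):
        n = design.n_per_arm.get(arm, 0)
        for i in range(n):
            seedseq = np.random.SeedSequence(
                entropy=design.seed, spawn_key=(arm_idx, i)
            )
            participants.append(
                generate_participant(
                    arm,
                    design,
                    seedseq,
                    weights=weights,
                    participant_id=f"{arm}_{i:04d}",
                )
            )
    return Cohort(design=design, participants=participants, weights=weights)
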