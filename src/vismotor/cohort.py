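"""Synthetic study cohort generator.

Emulates a two-group (TV / NOTV) five-day intervention design: two daily
45-min touch-typing sessions of twelve 3-min lessons with a marker lesson
(L3) occurring 4+4 times on day 1 and 1+1 times on days 2-5; pre/post
TVA whole- and partial-report sessions; pre/post grating-orientation and
mechanical-detection-threshold measurements; and pre/post dictation blocks.

The generating models are chosen so that every learning score has a
closed-form expectation:

* lesson counts follow a multiplicative log-linear practice curve
  ``baseline * learning_rate^(day-1) * group_gain^(day-1) [TV only]
  * di_uplift^(session-1) * subject_effect`` with Poisson noise on entered
  characters and binomial errors, so Gain_L3 on day X has expectation
  ``(learning_rate * group_gain)^(X-1)`` and DI has expectation
  ``di_uplift``;
* TVA responses are drawn from the exponential race itself (per-item
  finishing times, first-k admission with the fractional-K mixture) — the
  simulator is therefore also the Monte-Carlo oracle for the analytic
  report probabilities in :mod:`vismotor.tva`;
* GOT responses are Bernoulli draws from a logistic psychometric function
  over log spacing with 0.5 chance level; MDT responses follow a logistic
  detection function over log force driving a method-of-limits staircase.

A single root seed governs everything; each subject consumes independent
substreams keyed by (seed, stream-id, subject-index), so enlarging the
cohort never perturbs existing subjects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError
from .somatosensory import DEFAULT_PASS_FRACTION, MDT_FORCE_LADDER
from .tva import Element, _capacity_mixture, _layout_rates

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueTVAParams:
    """Generating truth for one group x phase TVA condition."""

    t0: float = 15.0  # ms
    C: float = 20.0  # items/s
    K: float = 3.2  # items
    mu: float = 100.0  # ms
    alpha: float = 0.5
    w_lat: float = 0.5

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.C <= 0 or self.K <= 0 or self.mu < 0:
            raise ConfigurationError("tva_true: t0, mu >= 0 and C, K > 0 required")
        if not (0 < self.w_lat < 1) or self.alpha < 0:
            raise ConfigurationError("tva_true: need 0 < w_lat < 1 and alpha >= 0")


@dataclass(frozen=True)
class SensoryTruth:
    """Generating psychometric truth for GOT and MDT."""

    got_threshold_mm: float = 1.2  # spacing at 75% accuracy
    got_slope: float = 8.0  # per log-mm
    mdt_threshold_mN: float = 0.8  # force at 50% detection
    mdt_slope: float = 6.0  # per log-mN

    def __post_init__(self) -> None:
        if min(self.got_threshold_mm, self.got_slope, self.mdt_threshold_mN, self.mdt_slope) <= 0:
            raise ConfigurationError("sensory_true: all parameters must be > 0")


def default_tva_truth() -> dict:
    """Per (group, phase) generating TVA parameters.

    Baselines are equal across groups; post-test shifts reproduce the
    trial's reported between-group contrasts: C rises by 14.35 items/s in
    NOTV and 14.89 in TV, K rises by 0.048 in NOTV and by 0.302 in TV so
    that the between-group K_change difference is 0.254.
    """
    pre = TrueTVAParams()
    return {
        ("TV", "pre"): pre,
        ("NOTV", "pre"): pre,
        ("TV", "post"): dataclasses.replace(pre, C=pre.C + 14.89, K=pre.K + 0.302),
        ("NOTV", "post"): dataclasses.replace(pre, C=pre.C + 14.35, K=pre.K + 0.048),
    }


def group_gain_multiplier_for_mle_diff(
    delta: float, learning_rate: float, days: int = 5
) -> float:
    """TV-vs-NOTV daily gain ratio producing a true MLE difference ``delta``.

    Under the generating curve the expected MLE difference is
    ``sum_x ((lr*g)^(x-1) - lr^(x-1)) / (2*days)`` (DI terms cancel), so
    ``g`` solves that expression = delta in closed form via root finding.
    """

    def gap(g: float) -> float:
        return (
            sum((learning_rate * g) ** x - learning_rate**x for x in range(days))
            / (2 * days)
            - delta
        )

    return brentq(gap, 1.0, 2.0) if delta > 0 else 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Full generating configuration for one synthetic cohort."""

    n_per_group: int = 36
    seed: int = 0
    days: int = 5
    lessons_per_session: int = 12
    lesson_minutes: float = 3.0
    baseline_correct_rate: float = 180.0  # entered chars per 3-min lesson
    learning_rate: float = 1.12  # per-day multiplicative growth
    group_gain_multiplier: float = 1.0678303368482869  # true MLE diff 0.103
    di_uplift: float = 1.05  # session-2 within-day multiplier
    error_rate: float = 0.06
    subject_sd: float = 0.15  # lognormal scale of baseline speed
    learning_rate_sd: float = 0.0729  # lognormal scale of subject learning rate
    count_noise: bool = True
    tva_true: dict = field(default_factory=default_tva_truth)
    sensory_true: SensoryTruth = field(default_factory=SensoryTruth)
    display_size: int = 6
    tva_exposures: tuple = (10.0, 20.0, 50.0, 80.0, 140.0, 200.0)
    whole_trials_per_condition: int = 16  # x 6 exposures x masked/unmasked = 192
    partial_trials_per_layout: int = 28
    got_spacings: tuple = (3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.75, 0.5)
    mdt_forces: tuple = MDT_FORCE_LADDER
    got_pass_fraction: float = DEFAULT_PASS_FRACTION
    include_tva: bool = True
    include_sensory: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group: must be >= 2")
        positive = {
            "baseline_correct_rate": self.baseline_correct_rate,
            "learning_rate": self.learning_rate,
            "group_gain_multiplier": self.group_gain_multiplier,
            "di_uplift": self.di_uplift,
            "lesson_minutes": self.lesson_minutes,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name}: must be > 0, got {value}")
        if not (0 <= self.error_rate < 1):
            raise ConfigurationError(f"error_rate: must be in [0, 1), got {self.error_rate}")
        if any(not (10 <= e <= 200) for e in self.tva_exposures):
            raise ConfigurationError("tva_exposures: must lie within [10, 200] ms")
        if self.days < 1 or self.lessons_per_session < 1:
            raise ConfigurationError("days and lessons_per_session must be >= 1")


# ---------------------------------------------------------------------------
# partial-report layouts (generator design: four condition families,
# mirrored over hemifields, equal frequency)
# ---------------------------------------------------------------------------

PARTIAL_LAYOUTS: dict[str, tuple[Element, ...]] = {
    "T_L": (("left", "target"),),
    "T_R": (("right", "target"),),
    "T_L+D_R": (("left", "target"), ("right", "distractor")),
    "T_R+D_L": (("right", "target"), ("left", "distractor")),
    "T_L+D_L": (("left", "target"), ("left", "distractor")),
    "T_R+D_R": (("right", "target"), ("right", "distractor")),
    "T_L+T_R": (("left", "target"), ("right", "target")),
}


def whole_report_layout(n: int) -> tuple[Element, ...]:
    """n letters alternating over the hemifields, all targets."""
    return tuple(("left" if i % 2 == 0 else "right", "target") for i in range(n))


# ---------------------------------------------------------------------------
# exponential race simulator (also the Monte-Carlo oracle for vismotor.tva)
# ---------------------------------------------------------------------------


def race_target_counts(
    layout: tuple[Element, ...],
    true_params: TrueTVAParams,
    tau_eff_ms: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Simulate the race ``size`` times; count targets encoded per draw.

    Each element's finishing time is exponential with its layout rate; an
    element is encoded iff it finishes within ``tau_eff`` and ranks among
    the first k finishers, where k is drawn from the fractional-K integer
    mixture per trial.
    """
    m = len(layout)
    rates = (
        _layout_rates(layout, true_params.C, true_params.alpha, true_params.w_lat)
        / 1000.0
    )  # per ms
    times = np.full((size, m), np.inf)
    active = rates > 0
    if active.any():
        times[:, active] = rng.exponential(
            1.0 / rates[active], size=(size, int(active.sum()))
        )
    mixture = _capacity_mixture(true_params.K, m)
    if len(mixture) == 1:
        k = np.full(size, mixture[0][0])
    else:
        (lo, _), (hi, w_hi) = mixture
        k = lo + (rng.random(size) < w_hi).astype(int)
    ranks = np.argsort(np.argsort(times, axis=1), axis=1)
    encoded = (times <= tau_eff_ms) & (ranks < k[:, None])
    is_target = np.array([role == "target" for _, role in layout])
    return encoded[:, is_target].sum(axis=1)


def simulate_tva_trial(
    true_params: TrueTVAParams,
    layout: tuple[Element, ...],
    exposure_ms: float,
    masked: bool,
    rng: np.random.Generator,
) -> int:
    """One simulated trial: number of correctly reported targets."""
    tau = max(0.0, exposure_ms - true_params.t0)
    if not masked:
        tau += true_params.mu
    return int(race_target_counts(layout, true_params, tau, rng, size=1)[0])


# ---------------------------------------------------------------------------
# typing lessons
# ---------------------------------------------------------------------------


def _lesson_schedule(config: CohortConfig) -> dict[tuple[int, int], list[str]]:
    """lesson_id sequence per (day, session): L3 occupies 4 slots in each
    day-1 session and 1 slot per session thereafter."""
    schedule = {}
    for day in range(1, config.days + 1):
        n_marker = 4 if day == 1 else 1
        for session in (1, 2):
            ids: list[str] = []
            marker_done = 0
            filler = 0
            for slot in range(config.lessons_per_session):
                remaining = config.lessons_per_session - slot
                if marker_done < n_marker and (
                    slot % 3 == 2 or remaining <= n_marker - marker_done
                ):
                    ids.append("L3")
                    marker_done += 1
                else:
                    filler += 1
                    lesson_num = 1 + (filler % 17)
                    ids.append(f"L{lesson_num if lesson_num < 3 else lesson_num + 1}")
            schedule[(day, session)] = ids
    return schedule


def simulate_lesson_counts(
    subject_state: dict, day: int, session: int, lesson_id: str
) -> dict:
    """One lesson record drawn from the subject's practice curve.

    ``subject_state`` carries the resolved per-subject curve constants and
    the subject's RNG substream.
    """
    if not 1 <= day:
        raise ConfigurationError(f"day must be >= 1, got {day}")
    if session not in (1, 2):
        raise ConfigurationError(f"session must be 1 or 2, got {session}")
    mean = (
        subject_state["baseline"]
        * subject_state["learning_rate"] ** (day - 1)
        * subject_state["group_gain"] ** (day - 1)
        * subject_state["di_uplift"] ** (session - 1)
    )
    rng: np.random.Generator = subject_state["rng"]
    if subject_state["count_noise"]:
        entered = int(rng.poisson(mean))
        errors = int(rng.binomial(entered, subject_state["error_rate"]))
    else:
        entered = int(round(mean))
        errors = 0
    return {
        "subject_id": subject_state["subject_id"],
        "group": subject_state["group"],
        "day": day,
        "session": session,
        "lesson_id": lesson_id,
        "entered": entered,
        "errors": errors,
        "duration_min": subject_state["lesson_minutes"],
    }


# ---------------------------------------------------------------------------
# sensory tasks
# ---------------------------------------------------------------------------


def _got_accuracy(spacing_mm: float, truth: SensoryTruth) -> float:
    """Logistic psychometric function over log spacing, chance 0.5 and 75%
    accuracy at the generating threshold."""
    return 0.5 + 0.5 * expit(
        truth.got_slope * (math.log(spacing_mm) - math.log(truth.got_threshold_mm))
    )


def _mdt_detection_prob(force_mN: float, truth: SensoryTruth) -> float:
    return float(
        expit(truth.mdt_slope * (math.log(force_mN) - math.log(truth.mdt_threshold_mN)))
    )


def simulate_threshold_tasks(
    truth: SensoryTruth, config: CohortConfig, rng: np.random.Generator
) -> tuple[list[dict], list[dict]]:
    """Simulate one subject/phase: GOT blocks (descending, stop rule) and
    an MDT method-of-limits series (two determinations, 10 stimuli each)."""
    got_rows = []
    for idx, spacing in enumerate(config.got_spacings):
        p = _got_accuracy(spacing, truth)
        n_correct = int(rng.binomial(10, p))
        got_rows.append(
            {
                "block_index": idx,
                "spacing_mm": spacing,
                "n_trials": 10,
                "n_correct": n_correct,
            }
        )
        if n_correct / 10 < config.got_pass_fraction:
            break

    ladder = list(config.mdt_forces)
    mdt_rows = []
    for det in (1, 2):
        level = len(ladder) - 1  # start at the strongest stimulus
        descending = True
        for trial in range(10):
            force = ladder[level]
            detected = bool(rng.random() < _mdt_detection_prob(force, truth))
            mdt_rows.append(
                {
                    "determination": det,
                    "trial_index": trial,
                    "force_mN": force,
                    "detected": detected,
                }
            )
            if descending:
                if detected:
                    level = max(0, level - 1)
                else:
                    descending = False
                    level = min(len(ladder) - 1, level + 1)
            else:
                if detected:
                    descending = True
                    level = max(0, level - 1)
                else:
                    level = min(len(ladder) - 1, level + 1)
    return got_rows, mdt_rows


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """All synthetic measurements of one cohort, as tidy tables."""

    subjects: pd.DataFrame
    typing: pd.DataFrame
    tva_trials: pd.DataFrame
    got: pd.DataFrame
    mdt: pd.DataFrame
    dictation: pd.DataFrame
    config: CohortConfig


def _subject_rng(config: CohortConfig, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, index])


def _partial_exposure(truth: TrueTVAParams) -> float:
    """Per-subject partial-report exposure targeting ~70% single-target
    success (the pre-test individualization, emulated as one scalar)."""
    tau = -math.log(0.3) / truth.C * 1000.0
    return float(min(200.0, max(10.0, tau + truth.t0)))


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate the full synthetic dataset for one cohort."""
    n_total = 2 * config.n_per_group
    # randomize 1:1 within consecutive pairs so that growing the cohort
    # leaves earlier subjects' group assignment and data untouched
    groups = []
    for pair in range(config.n_per_group):
        first_tv = bool(_subject_rng(config, 999, pair).random() < 0.5)
        groups.extend(["TV", "NOTV"] if first_tv else ["NOTV", "TV"])

    subject_rows, typing_rows, tva_rows = [], [], []
    got_rows, mdt_rows, dict_rows = [], [], []
    schedule = _lesson_schedule(config)
    whole_layout = whole_report_layout(config.display_size)

    for idx in range(n_total):
        sid = f"S{idx + 1:03d}"
        group = groups[idx]
        rng_cov = _subject_rng(config, 0, idx)
        rng_typing = _subject_rng(config, 1, idx)
        rng_tva = _subject_rng(config, 2, idx)
        rng_sens = _subject_rng(config, 3, idx)

        age = int(np.clip(round(rng_cov.normal(23.0, 2.49)), 18, 35))
        gender = "f" if rng_cov.random() < 0.5 else "m"
        consumption = float(np.round(rng_cov.lognormal(math.log(18.0), 0.55), 1))
        content = (
            str(rng_cov.choice(["Relax", "Mixed", "Thrill"])) if group == "TV" else ""
        )
        subject_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "gender": gender,
                "consumption_h_week": consumption,
                "content_group": content,
            }
        )

        state = {
            "subject_id": sid,
            "group": group,
            "baseline": config.baseline_correct_rate
            * float(np.exp(rng_typing.normal(0.0, config.subject_sd))),
            "learning_rate": config.learning_rate
            * float(np.exp(rng_typing.normal(0.0, config.learning_rate_sd))),
            "group_gain": config.group_gain_multiplier if group == "TV" else 1.0,
            "di_uplift": config.di_uplift,
            "error_rate": config.error_rate,
            "count_noise": config.count_noise,
            "lesson_minutes": config.lesson_minutes,
            "rng": rng_typing,
        }
        for (day, session), lesson_ids in schedule.items():
            for lesson_id in lesson_ids:
                typing_rows.append(
                    simulate_lesson_counts(state, day, session, lesson_id)
                )

        # dictation: conventional typing at pre, touch-typing at post
        ccpm_pre = max(20.0, rng_typing.normal(140.0, 25.0))
        ccpm_post = max(10.0, ccpm_pre * rng_typing.normal(0.75, 0.08))
        for phase, ccpm in (("pre", ccpm_pre), ("post", ccpm_post)):
            dict_rows.append(
                {
                    "subject_id": sid,
                    "phase": phase,
                    "correct_chars": int(round(ccpm * 10.0)),
                    "minutes": 10.0,
                }
            )

        if config.include_tva:
            for phase in ("pre", "post"):
                truth = config.tva_true[(group, phase)]
                for exposure in config.tva_exposures:
                    for masked in (True, False):
                        tau = max(0.0, exposure - truth.t0) + (
                            0.0 if masked else truth.mu
                        )
                        counts = race_target_counts(
                            whole_layout,
                            truth,
                            tau,
                            rng_tva,
                            size=config.whole_trials_per_condition,
                        )
                        for c in counts:
                            tva_rows.append(
                                {
                                    "subject_id": sid,
                                    "phase": phase,
                                    "paradigm": "whole",
                                    "exposure_ms": exposure,
                                    "masked": masked,
                                    "n_displayed": config.display_size,
                                    "layout": "",
                                    "reported": int(c),
                                }
                            )
                exposure_p = _partial_exposure(truth)
                tau_p = max(0.0, exposure_p - truth.t0)
                for code, layout in PARTIAL_LAYOUTS.items():
                    counts = race_target_counts(
                        layout,
                        truth,
                        tau_p,
                        rng_tva,
                        size=config.partial_trials_per_layout,
                    )
                    for c in counts:
                        tva_rows.append(
                            {
                                "subject_id": sid,
                                "phase": phase,
                                "paradigm": "partial",
                                "exposure_ms": exposure_p,
                                "masked": True,
                                "n_displayed": len(layout),
                                "layout": code,
                                "reported": int(c),
                            }
                        )

        if config.include_sensory:
            for phase in ("pre", "post"):
                got, mdt = simulate_threshold_tasks(
                    config.sensory_true, config, rng_sens
                )
                for row in got:
                    got_rows.append({"subject_id": sid, "phase": phase, **row})
                for row in mdt:
                    mdt_rows.append({"subject_id": sid, "phase": phase, **row})

    empty_tva = pd.DataFrame(
        columns=[
            "subject_id", "phase", "paradigm", "exposure_ms",
            "masked", "n_displayed", "layout", "reported",
        ]
    )
    empty_got = pd.DataFrame(
        columns=["subject_id", "phase", "block_index", "spacing_mm", "n_trials", "n_correct"]
    )
    empty_mdt = pd.DataFrame(
        columns=["subject_id", "phase", "determination", "trial_index", "force_mN", "detected"]
    )
    return CohortDataset(
        subjects=pd.DataFrame(subject_rows),
        typing=pd.DataFrame(typing_rows),
        tva_trials=pd.DataFrame(tva_rows) if tva_rows else empty_tva,
        got=pd.DataFrame(got_rows) if got_rows else empty_got,
        mdt=pd.DataFrame(mdt_rows) if mdt_rows else empty_mdt,
        dictation=pd.DataFrame(dict_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "subjects": "subjects.csv",
    "typing": "typing.csv",
    "tva_trials": "tva_trials.csv",
    "got": "got.csv",
    "mdt": "mdt.csv",
    "dictation": "dictation.csv",
}


def _config_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tva_true"] = {
        f"{g}_{p}": dataclasses.asdict(v) for (g, p), v in config.tva_true.items()
    }
    return d


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict:
    """Write all tables (UTF-8 CSV with headers) plus a cohort.json manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in TABLE_FILES.items():
        getattr(dataset, attr).to_csv(outdir / fname, index=False)
    manifest = {
        "seed": dataset.config.seed,
        "n_per_group": dataset.config.n_per_group,
        "groups": sorted(dataset.subjects["group"].unique().tolist()),
        "n_subjects": int(len(dataset.subjects)),
        "config": _config_dict(dataset.config),
    }
    (outdir / "cohort.json").write_text(json.dumps(manifest, indent=2))
    return manifest
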