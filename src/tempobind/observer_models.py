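"""Synthetic observers for the temporal bisection task.

An observer is parameterized by per-modality temporal noise (sigma_A,
sigma_V, in ms), per-modality bisection biases, a lapse rate and an
integration mode for bimodal trials.  The decision variable is the signed
offset of the (combined) perceived probe from the perceived midpoint of
the anchors; this makes the psychometric function in nominal probe time a
cumulative Gaussian whose mean and SD map one-to-one onto the generating
parameters, so fitted PSEs and thresholds can be checked against ground
truth.

Integration modes for bimodal trials:

* ``MLE`` -- reliability-weighted average of the two unisensory estimates
  (weights inversely proportional to variance), the optimal-integration
  benchmark.
* ``AUDIO_DOMINANT`` / ``VISUAL_DOMINANT`` -- the bimodal judgement is
  driven by a single modality, with no precision benefit from the other.

Cohort generators draw per-subject parameters from log-normal (noise) and
normal (bias) distributions, emulating a group of child observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus_design import (
    Condition,
    StimulusTriplet,
    TrialSlot,
    build_trial,
)


class IntegrationMode(str, Enum):
    MLE = "MLE"
    AUDIO_DOMINANT = "AUDIO_DOMINANT"
    VISUAL_DOMINANT = "VISUAL_DOMINANT"


@dataclass(frozen=True)
class ObserverParams:
    """A synthetic participant.

    ``sigma_a``/``sigma_v``: temporal noise SD per modality, ms.
    ``bias_a``/``bias_v``: shift of the perceived midpoint, ms (the
    unisensory PSE is ``500 + bias``).  ``lapse``: probability of a
    stimulus-independent random response.  ``mode``: bimodal integration
    rule.
    """

    sigma_a: float
    sigma_v: float
    bias_a: float = 0.0
    bias_v: float = 0.0
    lapse: float = 0.02
    mode: IntegrationMode = IntegrationMode.MLE

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_a and sigma_v must be positive")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must be in [0, 0.5]")


@dataclass(frozen=True)
class TrialRecord:
    """One presented trial plus the binary bisection response.

    ``response`` is 1 if the probe was judged closer to the third stimulus,
    0 if closer to the first.
    """

    subject_id: str
    condition: Condition
    delta: float
    probe_nominal: float
    response: int
    is_easy: bool = False

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic group of observers.

    Noise SDs are log-normal (``log_*`` give the location and scale of the
    underlying normal, ms on the median scale via exp(loc)); biases are
    normal.  Defaults are supplied by :func:`typical_cohort_spec` and
    :func:`dyslexic_cohort_spec`.
    """

    group: str
    log_sigma_a_loc: float
    log_sigma_a_scale: float
    log_sigma_v_loc: float
    log_sigma_v_scale: float
    bias_a_mean: float = 0.0
    bias_a_sd: float = 0.0
    bias_v_mean: float = 0.0
    bias_v_sd: float = 0.0
    lapse: float = 0.02
    mode: IntegrationMode = IntegrationMode.MLE
    n_subjects: int = 32

    def __post_init__(self) -> None:
        if self.log_sigma_a_scale < 0 or self.log_sigma_v_scale < 0:
            raise ValueError("log-normal scale parameters must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def typical_cohort_spec(n_subjects: int = 32) -> CohortSpec:
    """Default typical-child group: precise audition (median sigma_A 100 ms),
    coarser vision (median sigma_V 200 ms), no bias, auditory dominance in
    bimodal trials."""
    return CohortSpec(
        group="typical",
        log_sigma_a_loc=float(np.log(100.0)),
        log_sigma_a_scale=0.3,
        log_sigma_v_loc=float(np.log(200.0)),
        log_sigma_v_scale=0.3,
        bias_a_sd=30.0,
        bias_v_sd=30.0,
        mode=IntegrationMode.AUDIO_DOMINANT,
        n_subjects=n_subjects,
    )


def dyslexic_cohort_spec(n_subjects: int = 32) -> CohortSpec:
    """Default dyslexic-child group: equally noisy audition and vision
    (median sigma 300 ms), a late bias of +250 ms in both modalities
    (unisensory PSE near 750 ms), and optimal (MLE) bimodal integration."""
    return CohortSpec(
        group="dyslexic",
        log_sigma_a_loc=float(np.log(300.0)),
        log_sigma_a_scale=0.3,
        log_sigma_v_loc=float(np.log(300.0)),
        log_sigma_v_scale=0.3,
        bias_a_mean=250.0,
        bias_a_sd=50.0,
        bias_v_mean=250.0,
        bias_v_sd=50.0,
        mode=IntegrationMode.MLE,
        n_subjects=n_subjects,
    )


def _modality_evidence(
    times: tuple[float, float, float], bias: float
) -> float:
    """Signed offset of the probe from the midpoint of the anchors, as seen
    by one modality before noise, shifted by that modality's bias."""
    anchor1, probe, anchor3 = times
    return probe - 0.5 * (anchor1 + anchor3) - bias


def mle_weights_from_observer(observer: ObserverParams) -> tuple[float, float]:
    """(w_V, w_A) reliability weights implied by the observer's noise."""
    va, aa = observer.sigma_v**2, observer.sigma_a**2
    return aa / (aa + va), va / (aa + va)


def simulate_response(
    observer: ObserverParams,
    trial: StimulusTriplet,
    rng: np.random.Generator,
) -> int:
    """Draw one binary bisection response.

    With probability ``lapse`` the response is a fair coin flip.  Otherwise
    each presented modality contributes a noisy internal estimate of the
    probe's offset from the perceived midpoint; estimates are combined
    according to the observer's integration mode, and the response is 1
    ("closer to third") iff the combined estimate is positive.  Exact ties
    are broken by a fair coin.
    """
    if observer.lapse > 0 and rng.random() < observer.lapse:
        return int(rng.random() < 0.5)

    x_a = x_v = None
    if trial.audio_times is not None:
        mean = _modality_evidence(trial.audio_times, observer.bias_a)
        x_a = rng.normal(mean, observer.sigma_a)
    if trial.visual_times is not None:
        mean = _modality_evidence(trial.visual_times, observer.bias_v)
        x_v = rng.normal(mean, observer.sigma_v)

    if x_a is not None and x_v is not None:
        if observer.mode is IntegrationMode.MLE:
            w_v, w_a = mle_weights_from_observer(observer)
            combined = w_a * x_a + w_v * x_v
        elif observer.mode is IntegrationMode.AUDIO_DOMINANT:
            combined = x_a
        else:
            combined = x_v
    elif x_a is not None:
        combined = x_a
    elif x_v is not None:
        combined = x_v
    else:
        raise ValueError("trial presents no modality")

    if combined == 0.0:
        return int(rng.random() < 0.5)
    return int(combined > 0.0)


def _draw_probe(slot: TrialSlot, easy_margin: float, rng: np.random.Generator) -> float:
    """Probe placement for non-adaptive sessions: easy slots land within
    easy_margin of a random anchor, regular slots are uniform in (0, 1000)."""
    if slot.is_easy:
        if rng.random() < 0.5:
            return float(rng.uniform(1.0, easy_margin))
        return float(rng.uniform(1000.0 - easy_margin, 999.0))
    return float(rng.uniform(1.0, 999.0))


def simulate_dataset(
    observer: ObserverParams,
    slots: Sequence[TrialSlot],
    rng: np.random.Generator,
    subject_id: str = "S00",
    easy_margin: float = 100.0,
) -> list[TrialRecord]:
    """Simulate one response per session slot.

    Slots with a preset ``probe_nominal`` keep it; open slots are placed
    uniformly (easy slots near an anchor).  For adaptive placement use
    :func:`tempobind.quest_adaptive.run_session` instead.
    """
    records = []
    for slot in slots:
        probe = slot.probe_nominal
        if probe is None:
            probe = _draw_probe(slot, easy_margin, rng)
        trial = build_trial(slot.condition, slot.delta, probe)
        response = simulate_response(observer, trial, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                condition=slot.condition,
                delta=slot.delta,
                probe_nominal=probe,
                response=response,
                is_easy=slot.is_easy,
            )
        )
    return records


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[ObserverParams]:
    """Draw ``spec.n_subjects`` independent observers from the cohort
    distributions."""
    observers = []
    for _ in range(spec.n_subjects):
        observers.append(
            ObserverParams(
                sigma_a=float(np.exp(rng.normal(spec.log_sigma_a_loc, spec.log_sigma_a_scale))),
                sigma_v=float(np.exp(rng.normal(spec.log_sigma_v_loc, spec.log_sigma_v_scale))),
                bias_a=float(rng.normal(spec.bias_a_mean, spec.bias_a_sd)),
                bias_v=float(rng.normal(spec.bias_v_mean, spec.bias_v_sd)),
                lapse=spec.lapse,
                mode=spec.mode,
            )
        )
    return observers


def records_to_frame(records: Sequence[TrialRecord], group: str = "") -> pd.DataFrame:
    """Tidy trial-log table: subject_id, group, condition, delta_ms,
    probe_nominal_ms, is_easy, response."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": group,
            "condition": [r.condition.value for r in records],
            "delta_ms": [r.delta for r in records],
            "probe_nominal_ms": [r.probe_nominal for r in records],
            "is_easy": [r.is_easy for r in records],
            "response": [r.response for r in records],
        }
    )
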