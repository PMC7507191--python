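"""Construction of temporal-bisection trials and sessions.

A trial presents three brief events on a nominal 0--1000 ms timeline
(anchors at 0 and 1000 ms, probe in between).  The observer judges whether
the probe is closer in time to the first or the third event.  Bimodal
trials may carry an audio-visual conflict: the probe is offset by +delta
between the two modalities and the anchors by -delta, so the net relative
conflict between probe and anchors is 2*delta.  The offset is split
symmetrically (+/- delta/2 to each modality) so that an observer weighting
the two senses equally predicts no shift of the bisection point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ANCHOR_EARLY = 0.0
ANCHOR_LATE = 1000.0
MIDPOINT = 500.0

VALID_DELTAS = (-50.0, 0.0, 50.0)


class Condition(str, Enum):
    """Experimental condition: unisensory or one of three bimodal conflicts."""

    V = "V"
    A = "A"
    AV_NEG = "AV_neg"
    AV_ZERO = "AV_zero"
    AV_POS = "AV_pos"

    @property
    def is_bimodal(self) -> bool:
        return self in (Condition.AV_NEG, Condition.AV_ZERO, Condition.AV_POS)

    @property
    def delta(self) -> float:
        """The conflict level implied by the condition label (ms)."""
        return {
            Condition.V: 0.0,
            Condition.A: 0.0,
            Condition.AV_NEG: -50.0,
            Condition.AV_ZERO: 0.0,
            Condition.AV_POS: 50.0,
        }[self]


BIMODAL_CONDITIONS = (Condition.AV_NEG, Condition.AV_ZERO, Condition.AV_POS)


class InvalidConfigurationError(ValueError):
    """Raised when a trial or session specification is inconsistent."""


@dataclass(frozen=True)
class StimulusTriplet:
    """Per-modality event times of the three stimuli in one trial.

    ``audio_times`` / ``visual_times`` are (anchor1, probe, anchor3) onset
    times in ms, or ``None`` for the absent modality of a unisensory trial.
    ``delta`` is the conflict parameter (audio minus visual offset at the
    probe); ``probe_nominal`` the nominal probe time on the shared timeline.
    """

    condition: Condition
    delta: float
    probe_nominal: float
    audio_times: Optional[tuple[float, float, float]]
    visual_times: Optional[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not (ANCHOR_EARLY < self.probe_nominal < ANCHOR_LATE):
            raise InvalidConfigurationError(
                f"probe_nominal must lie strictly inside "
                f"({ANCHOR_EARLY}, {ANCHOR_LATE}) ms, got {self.probe_nominal}"
            )


@dataclass(frozen=True)
class SessionConfig:
    """Layout of one experimental session.

    Defaults reproduce the standard design: 30 trials in each of five
    conditions (visual-only, audio-only, three bimodal conflict levels),
    about 20% of slots flagged as encouraging "easy" trials with the probe
    within ``easy_margin`` ms of an anchor.
    """

    trials_per_condition: int = 30
    condition_order: tuple[Condition, ...] = (
        Condition.V,
        Condition.A,
        Condition.AV_NEG,
        Condition.AV_ZERO,
        Condition.AV_POS,
    )
    easy_trial_rate: float = 0.20
    easy_margin: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise InvalidConfigurationError("trials_per_condition must be >= 1")
        if not 0.0 <= self.easy_trial_rate <= 1.0:
            raise InvalidConfigurationError("easy_trial_rate must be in [0, 1]")
        if not 0.0 < self.easy_margin <= MIDPOINT:
            raise InvalidConfigurationError("easy_margin must be in (0, 500] ms")


@dataclass(frozen=True)
class TrialSlot:
    """One slot of a session: condition, conflict level and easy flag.

    The probe time is left unset (``None``) for adaptive sessions, where
    the QUEST routine places it at run time.
    """

    trial_index: int
    condition: Condition
    delta: float
    is_easy: bool
    probe_nominal: Optional[float] = None


def build_trial(
    condition: Condition | str, delta: float, probe_nominal: float
) -> StimulusTriplet:
    """Construct the event times of one trial.

    The conflict ``delta`` is split symmetrically: the audio probe is at
    ``p + delta/2`` and the visual probe at ``p - delta/2``; anchors get the
    opposite split.  Unisensory conditions require ``delta == 0`` and carry
    times only for the presented modality.
    """
    condition = Condition(condition)
    if delta not in VALID_DELTAS:
        raise InvalidConfigurationError(
            f"delta must be one of {VALID_DELTAS} ms, got {delta}"
        )
    if not (ANCHOR_EARLY < probe_nominal < ANCHOR_LATE):
        raise InvalidConfigurationError(
            f"probe_nominal must be in ({ANCHOR_EARLY}, {ANCHOR_LATE}), "
            f"got {probe_nominal}"
        )
    if not condition.is_bimodal and delta != 0.0:
        raise InvalidConfigurationError(
            f"unisensory condition {condition.value} requires delta = 0"
        )

    half = delta / 2.0
    audio = (ANCHOR_EARLY - half, probe_nominal + half, ANCHOR_LATE - half)
    visual = (ANCHOR_EARLY + half, probe_nominal - half, ANCHOR_LATE + half)

    if condition is Condition.V:
        return StimulusTriplet(condition, delta, probe_nominal, None, visual)
    if condition is Condition.A:
        return StimulusTriplet(condition, delta, probe_nominal, audio, None)
    return StimulusTriplet(condition, delta, probe_nominal, audio, visual)


def modality_bisection_points(delta: float) -> tuple[float, float]:
    """Nominal probe times at which each modality exactly bisects its anchors.

    Under the symmetric conflict split the audio probe bisects the audio
    anchors at nominal probe ``500 - delta`` and the visual probe at
    ``500 + delta``; their mean is always the nominal midpoint.
    """
    if delta not in VALID_DELTAS:
        raise InvalidConfigurationError(
            f"delta must be one of {VALID_DELTAS} ms, got {delta}"
        )
    return MIDPOINT - delta, MIDPOINT + delta


def build_session(config: SessionConfig) -> list[TrialSlot]:
    """Emit the ordered trial slots of one session.

    Unisensory blocks come first in the configured order; the three bimodal
    conflict levels are randomly interleaved within the bimodal block.
    Each slot is independently flagged easy with probability
    ``easy_trial_rate``.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.trials_per_condition

    unisensory = [c for c in config.condition_order if not c.is_bimodal]
    bimodal = [c for c in config.condition_order if c.is_bimodal]

    ordered: list[Condition] = []
    for cond in unisensory:
        ordered.extend([cond] * n)
    interleaved = np.repeat(np.arange(len(bimodal)), n)
    rng.shuffle(interleaved)
    ordered.extend(bimodal[i] for i in interleaved)

    easy_flags = rng.random(len(ordered)) < config.easy_trial_rate
    return [
        TrialSlot(trial_index=i, condition=c, delta=c.delta, is_easy=bool(e))
        for i, (c, e) in enumerate(zip(ordered, easy_flags))
    ]


def session_to_frame(slots: Sequence[TrialSlot]) -> pd.DataFrame:
    """Serialize built trial slots as a tidy table.

    Columns: trial_index, condition, delta_ms, probe_nominal_ms, is_easy,
    audio_t1..t3, visual_t1..t3 (NaN for the absent modality or for slots
    whose probe is still unset).
    """
    rows = []
    for slot in slots:
        row: dict = {
            "trial_index": slot.trial_index,
            "condition": slot.condition.value,
            "delta_ms": slot.delta,
            "probe_nominal_ms": slot.probe_nominal,
            "is_easy": slot.is_easy,
        }
        if slot.probe_nominal is not None:
            trial = build_trial(slot.condition, slot.delta, slot.probe_nominal)
            for name, times in (("audio", trial.audio_times), ("visual", trial.visual_times)):
                for k in range(3):
                    row[f"{name}_t{k + 1}"] = times[k] if times is not None else np.nan
        else:
            for name in ("audio", "visual"):
                for k in range(3):
                    row[f"{name}_t{k + 1}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
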