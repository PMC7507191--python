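"""QUEST-style adaptive placement of the probe time.

A maximum-likelihood adaptive procedure: a posterior over candidate
bisection points (PSE values) is maintained on a discrete grid, updated
after every response with the Bernoulli likelihood of a fixed-slope
cumulative-Gaussian psychometric function, and the next probe is placed at
the current posterior mode.  The placement is perturbed with Gaussian
noise so the psychometric function is sampled over its whole range, and a
configurable fraction of trials are encouraging "easy" trials with the
probe close to one of the anchors.

The adaptive readout is used only to place trials; final PSE and
threshold estimates always come from refitting the full trial log (see
:mod:`tempobind.psychometric_fit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr, logsumexp, ndtr

from .observer_models import ObserverParams, TrialRecord, simulate_response
from .stimulus_design import (
    Condition,
    InvalidConfigurationError,
    SessionConfig,
    build_session,
    build_trial,
)


@dataclass(frozen=True)
class QuestConfig:
    """Adaptive-procedure settings (one independent track per condition)."""

    prior_mean: float = 500.0
    prior_sd: float = 300.0
    assumed_sigma: float = 150.0
    assumed_lapse: float = 0.02
    perturbation_sd: float = 100.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise InvalidConfigurationError("prior_sd must be positive")
        if self.assumed_sigma <= 0:
            raise InvalidConfigurationError("assumed_sigma must be positive")
        if not 0 <= self.assumed_lapse <= 0.5:
            raise InvalidConfigurationError("assumed_lapse must be in [0, 0.5]")
        if self.perturbation_sd < 0:
            raise InvalidConfigurationError("perturbation_sd must be >= 0")
        if self.grid_step <= 0:
            raise InvalidConfigurationError("grid_step must be positive")


@dataclass(frozen=True)
class QuestState:
    """Posterior over candidate PSE values on a discrete grid.

    ``log_posterior`` is unnormalized; all queries normalize on the fly so
    arithmetic stays in the log domain.
    """

    grid: np.ndarray
    log_posterior: np.ndarray
    assumed_sigma: float
    assumed_lapse: float
    perturbation_sd: float
    trial_count: int = 0

    def __post_init__(self) -> None:
        if self.grid.size == 0:
            raise InvalidConfigurationError("grid must be non-empty")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise InvalidConfigurationError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.log_posterior)):
            # -inf entries are fine (zero mass); NaN/+inf are not
            bad = ~np.isfinite(self.log_posterior) & ~np.isneginf(self.log_posterior)
            if np.any(bad):
                raise InvalidConfigurationError("log_posterior contains NaN/inf")
        if not np.isfinite(logsumexp(self.log_posterior)):
            raise InvalidConfigurationError("posterior is not normalizable")

    @property
    def posterior(self) -> np.ndarray:
        """Normalized posterior mass over the grid."""
        return np.exp(self.log_posterior - logsumexp(self.log_posterior))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.log_posterior))])

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.posterior))


def init_quest(
    prior_mean: float = 500.0,
    prior_sd: float = 300.0,
    assumed_sigma: float = 150.0,
    assumed_lapse: float = 0.02,
    perturbation_sd: float = 100.0,
    grid: np.ndarray | None = None,
    grid_step: float = 1.0,
) -> QuestState:
    """Initialize the posterior to a Gaussian prior over the PSE grid.

    The default grid covers (0, 1000) ms in 1-ms steps.
    """
    if grid is None:
        grid = np.arange(1.0, 1000.0, grid_step)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidConfigurationError("grid must be non-empty")
    log_prior = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    return QuestState(
        grid=grid,
        log_posterior=log_prior,
        assumed_sigma=assumed_sigma,
        assumed_lapse=assumed_lapse,
        perturbation_sd=perturbation_sd,
        trial_count=0,
    )


def quest_from_config(config: QuestConfig) -> QuestState:
    return init_quest(
        prior_mean=config.prior_mean,
        prior_sd=config.prior_sd,
        assumed_sigma=config.assumed_sigma,
        assumed_lapse=config.assumed_lapse,
        perturbation_sd=config.perturbation_sd,
        grid_step=config.grid_step,
    )


def next_probe(
    state: QuestState,
    easy_flag: bool,
    rng: np.random.Generator,
    easy_margin: float = 100.0,
) -> float:
    """Choose the next probe time.

    Regular trials: posterior mode plus Gaussian perturbation, clipped to
    (1, 999) ms.  Easy trials: uniform within ``easy_margin`` of a randomly
    chosen anchor.
    """
    if easy_flag:
        if rng.random() < 0.5:
            return float(rng.uniform(1.0, easy_margin))
        return float(rng.uniform(1000.0 - easy_margin, 999.0))
    probe = state.mode + rng.normal(0.0, state.perturbation_sd)
    return float(np.clip(probe, 1.0, 999.0))


def update(state: QuestState, probe: float, response: int) -> QuestState:
    """Fold one response into the posterior.

    The likelihood of responding "closer to third" given a candidate PSE is
    ``lapse/2 + (1 - lapse) * Phi((probe - PSE) / assumed_sigma)``.
    """
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    z = (probe - state.grid) / state.assumed_sigma
    lam = state.assumed_lapse
    if lam == 0.0:
        # log-domain tails avoid log(0) for extreme probes
        log_like = log_ndtr(z) if response == 1 else log_ndtr(-z)
    else:
        p_one = lam / 2.0 + (1.0 - lam) * ndtr(z)
        log_like = np.log(p_one if response == 1 else 1.0 - p_one)
    return replace(
        state,
        log_posterior=state.log_posterior + log_like,
        trial_count=state.trial_count + 1,
    )


def run_session(
    observer: ObserverParams,
    session_config: SessionConfig | None = None,
    quest_config: QuestConfig | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "S00",
) -> list[TrialRecord]:
    """Run one full adaptive session against a simulated observer.

    Each condition gets its own independent QUEST track.  For every slot
    the probe is placed by :func:`next_probe`, the observer answers, and
    the matching track is updated.  Returns the complete trial log.
    """
    session_config = session_config or SessionConfig()
    quest_config = quest_config or QuestConfig()
    rng = rng if rng is not None else np.random.default_rng(session_config.seed)

    states: dict[Condition, QuestState] = {
        cond: quest_from_config(quest_config)
        for cond in session_config.condition_order
    }
    records: list[TrialRecord] = []
    for slot in build_session(session_config):
        state = states[slot.condition]
        probe = next_probe(state, slot.is_easy, rng, session_config.easy_margin)
        trial = build_trial(slot.condition, slot.delta, probe)
        response = simulate_response(observer, trial, rng)
        states[slot.condition] = update(state, probe, response)
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
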