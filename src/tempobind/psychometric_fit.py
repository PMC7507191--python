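"""Maximum-likelihood cumulative-Gaussian fits of binary bisection responses.

The probability of judging the probe "closer to the third stimulus" is
modelled as

    P(1 | p) = lapse/2 + (1 - lapse) * Phi((p - PSE) / sigma)

with the lapse rate fixed (not estimated: 30-trial conditions cannot
identify it).  The fit maximizes the Bernoulli likelihood with a two-stage
optimizer -- a coarse grid seed followed by Nelder-Mead refinement in
(PSE, log sigma) -- with sigma bounded to [1, 1000] ms.  Standard errors
come from a case-resampling bootstrap (default 100 iterations; the SE is
the SD of the bootstrap distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

SIGMA_MIN = 1.0
SIGMA_MAX = 1000.0
MIN_TRIALS = 10


class InsufficientDataError(ValueError):
    """Fewer trials than the minimum needed to attempt a fit."""


class NonIdentifiableError(ValueError):
    """All responses in one class: PSE and sigma are not identifiable."""


class UnreliableSEError(RuntimeError):
    """More than half of the bootstrap resamples failed to fit."""


@dataclass(frozen=True)
class PsychometricEstimate:
    """Fitted PSE and discrimination threshold for one condition."""

    pse: float
    sigma: float
    n_trials: int
    neg_log_likelihood: float
    converged: bool
    condition: str = ""
    se_pse: float = float("nan")
    se_sigma: float = float("nan")
    n_boot_failed: int = 0


TrialsLike = Union[Sequence, pd.DataFrame]


def _extract(trials: TrialsLike) -> tuple[np.ndarray, np.ndarray]:
    """Pull (probe, response) arrays out of TrialRecords, a DataFrame, or a
    (probes, responses) pair."""
    if isinstance(trials, pd.DataFrame):
        return (
            trials["probe_nominal_ms"].to_numpy(dtype=float),
            trials["response"].to_numpy(dtype=int),
        )
    if (
        isinstance(trials, tuple)
        and len(trials) == 2
        and not hasattr(trials[0], "probe_nominal")
    ):
        return (
            np.asarray(trials[0], dtype=float),
            np.asarray(trials[1], dtype=int),
        )
    probes = np.array([t.probe_nominal for t in trials], dtype=float)
    responses = np.array([t.response for t in trials], dtype=int)
    return probes, responses


def negative_log_likelihood(
    probes: np.ndarray,
    responses: np.ndarray,
    pse: float,
    sigma: float,
    lapse: float,
) -> float:
    """Bernoulli negative log-likelihood of the responses under the model."""
    z = (probes - pse) / sigma
    if lapse == 0.0:
        ll = np.where(responses == 1, log_ndtr(z), log_ndtr(-z))
        return float(-np.sum(ll))
    p1 = lapse / 2.0 + (1.0 - lapse) * ndtr(z)
    p = np.where(responses == 1, p1, 1.0 - p1)
    return float(-np.sum(np.log(p)))


def _grid_seed(
    probes: np.ndarray, responses: np.ndarray, lapse: float
) -> tuple[float, float]:
    """Coarse grid search for a starting point."""
    pse_grid = np.linspace(probes.min() - 50.0, probes.max() + 50.0, 33)
    sigma_grid = np.geomspace(SIGMA_MIN, SIGMA_MAX, 17)
    best = (np.inf, pse_grid[0], sigma_grid[0])
    r1 = responses == 1
    for sigma in sigma_grid:
        z = (probes[None, :] - pse_grid[:, None]) / sigma
        if lapse == 0.0:
            ll = np.where(r1[None, :], log_ndtr(z), log_ndtr(-z))
        else:
            p1 = lapse / 2.0 + (1.0 - lapse) * ndtr(z)
            ll = np.log(np.where(r1[None, :], p1, 1.0 - p1))
        nll = -ll.sum(axis=1)
        i = int(np.argmin(nll))
        if nll[i] < best[0]:
            best = (float(nll[i]), float(pse_grid[i]), float(sigma))
    return best[1], best[2]


def fit_cumulative_gaussian(
    trials: TrialsLike,
    lapse: float = 0.02,
    condition: str = "",
) -> PsychometricEstimate:
    """Fit PSE and threshold sigma by maximum likelihood.

    Requires at least 10 trials and both response classes present.
    Deterministic for a fixed input.
    """
    probes, responses = _extract(trials)
    n = probes.size
    if n < MIN_TRIALS:
        raise InsufficientDataError(
            f"need at least {MIN_TRIALS} trials to fit, got {n}"
        )
    if responses.min() == responses.max():
        raise NonIdentifiableError(
            "all responses are in one class; PSE/sigma not identifiable"
        )

    pse0, sigma0 = _grid_seed(probes, responses, lapse)

    def objective(theta: np.ndarray) -> float:
        pse, log_sigma = theta
        sigma = float(np.exp(np.clip(log_sigma, np.log(SIGMA_MIN), np.log(SIGMA_MAX))))
        return negative_log_likelihood(probes, responses, pse, sigma, lapse)

    result = minimize(
        objective,
        x0=np.array([pse0, np.log(sigma0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 2000},
    )
    pse = float(result.x[0])
    sigma = float(np.exp(np.clip(result.x[1], np.log(SIGMA_MIN), np.log(SIGMA_MAX))))
    return PsychometricEstimate(
        pse=pse,
        sigma=sigma,
        n_trials=int(n),
        neg_log_likelihood=float(result.fun),
        converged=bool(result.success),
        condition=condition,
    )


def bootstrap_se(
    trials: TrialsLike,
    n_boot: int = 100,
    lapse: float = 0.02,
    rng: Optional[np.random.Generator] = None,
    resampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
) -> tuple[float, float, int]:
    """Case-resampling bootstrap SEs for (PSE, sigma).

    Returns ``(se_pse, se_sigma, n_failed)``.  Resamples whose refit raises
    (e.g. single-class resamples) are dropped and counted; more than 50%
    failures raises :class:`UnreliableSEError`.  ``resampler`` overrides the
    index draw (testing hook).
    """
    probes, responses = _extract(trials)
    n = probes.size
    rng = rng if rng is not None else np.random.default_rng(0)
    # fit once up front so pathological inputs fail fast
    fit_cumulative_gaussian((probes, responses), lapse=lapse)

    pses, sigmas, n_failed = [], [], 0
    for _ in range(n_boot):
        idx = resampler(rng, n) if resampler is not None else rng.integers(0, n, n)
        try:
            est = fit_cumulative_gaussian((probes[idx], responses[idx]), lapse=lapse)
        except (NonIdentifiableError, InsufficientDataError):
            n_failed += 1
            continue
        pses.append(est.pse)
        sigmas.append(est.sigma)
    if n_failed > n_boot / 2:
        raise UnreliableSEError(
            f"{n_failed}/{n_boot} bootstrap resamples failed to fit"
        )
    se_pse = float(np.std(pses, ddof=1)) if len(pses) > 1 else 0.0
    se_sigma = float(np.std(sigmas, ddof=1)) if len(sigmas) > 1 else 0.0
    return se_pse, se_sigma, n_failed


def fit_with_bootstrap(
    trials: TrialsLike,
    lapse: float = 0.02,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
    condition: str = "",
) -> PsychometricEstimate:
    """Fit plus bootstrap SEs in one call."""
    est = fit_cumulative_gaussian(trials, lapse=lapse, condition=condition)
    if n_boot == 0:
        return est
    se_pse, se_sigma, n_failed = bootstrap_se(
        trials, n_boot=n_boot, lapse=lapse, rng=rng
    )
    return replace(est, se_pse=se_pse, se_sigma=se_sigma, n_boot_failed=n_failed)


def binned_proportions(trials: TrialsLike, n_bins: int = 8) -> pd.DataFrame:
    """Equal-count binning of responses by probe time.

    Returns a table with columns ``bin_center`` (mean probe time in the
    bin), ``proportion`` (fraction responding "closer to third") and
    ``count``; counts sum to the number of trials.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    probes, responses = _extract(trials)
    order = np.argsort(probes, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        if chunk.size == 0:
            continue
        rows.append(
            {
                "bin_center": float(probes[chunk].mean()),
                "proportion": float(responses[chunk].mean()),
                "count": int(chunk.size),
            }
        )
    return pd.DataFrame(rows)


def estimates_to_frame(estimates: Sequence[PsychometricEstimate], subject_ids=None) -> pd.DataFrame:
    """Serialize estimates: subject_id, condition, pse_ms, sigma_ms,
    se_pse_ms, se_sigma_ms, n_trials, converged."""
    return pd.DataFrame(
        {
            "subject_id": subject_ids if subject_ids is not None else [""] * len(estimates),
            "condition": [e.condition for e in estimates],
            "pse_ms": [e.pse for e in estimates],
            "sigma_ms": [e.sigma for e in estimates],
            "se_pse_ms": [e.se_pse for e in estimates],
            "se_sigma_ms": [e.se_sigma for e in estimates],
            "n_trials": [e.n_trials for e in estimates],
            "converged": [e.converged for e in estimates],
        }
    )
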