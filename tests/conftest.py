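import numpy as np
import pytest
from scipy.special import log_ndtr, ndtr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bernoulli_responses(probes, pse, sigma, lapse, rng):
    """Independent response generator: draw directly from the analytic
    psychometric function (bypasses the observer simulator)."""
    p1 = lapse / 2.0 + (1.0 - lapse) * ndtr((np.asarray(probes) - pse) / sigma)
    return (rng.random(len(probes)) < p1).astype(int)


def grid_search_nll(probes, responses, lapse, pse_grid, sigma_grid):
    """Brute-force oracle: exhaustive NLL minimization over a discrete
    (PSE, sigma) grid.  Returns (min_nll, pse_argmin, sigma_argmin)."""
    probes = np.asarray(probes, float)
    r1 = np.asarray(responses) == 1
    best = (np.inf, None, None)
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
    return best
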