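import numpy as np
import pandas as pd
import pytest

from evotox import grafen_branch_lengths, parse_newick
from evotox.simulate import MortalitySimConfig, simulate_mortality


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with Grafen branch lengths (root height 1)."""
    return grafen_branch_lengths(parse_newick("((A,B),(C,D));"))


@pytest.fixture
def star_tree():
    """8-tip star phylogeny with unit branches."""
    return parse_newick("(" + ",".join(f"t{i}:1" for i in range(8)) + ");")


@pytest.fixture
def toy_symmetric_mortality():
    """Three doses with mortality symmetric around dose 4 (MLE LC50 = 4)."""
    return pd.DataFrame(
        {
            "pond_id": ["p1", "p1", "p1"],
            "type": ["woodland"] * 3,
            "conc_mg_l": [2.0, 4.0, 6.0],
            "replicate": [1, 2, 3],
            "n_exposed": [10, 10, 10],
            "n_dead": [1, 5, 9],
        }
    )


@pytest.fixture
def glm_design_mortality():
    """One population type under the study design, no random heterogeneity."""
    cfg = MortalitySimConfig(seed=11, sigma_pond=0.0, sigma_unit=0.0)
    tab = simulate_mortality(cfg)
    return tab[tab["type"] == "woodland"].reset_index(drop=True)


def gauss_hermite_marginal_loglik(y, n, eta_fixed, sigma, npts=50):
    """Oracle: adaptive Gauss-Hermite marginal log-likelihood, single group.

    Integrates the binomial likelihood over one normal random intercept by
    recentring 50 Hermite nodes on the posterior mode.  Independent of the
    package's Laplace code path.
    """
    from scipy.special import expit, gammaln, logsumexp

    y = np.asarray(y, float)
    n = np.asarray(n, float)
    eta_fixed = np.asarray(eta_fixed, float)
    mode = 0.0
    for _ in range(200):
        p = expit(eta_fixed + sigma * mode)
        grad = sigma * np.sum(y - n * p) - mode
        hess = -(sigma**2) * np.sum(n * p * (1 - p)) - 1.0
        step = grad / hess
        mode -= step
        if abs(step) < 1e-13:
            break
    p = expit(eta_fixed + sigma * mode)
    sd = 1.0 / np.sqrt(sigma**2 * np.sum(n * p * (1 - p)) + 1.0)
    nodes, weights = np.polynomial.hermite.hermgauss(npts)
    pts = mode + np.sqrt(2.0) * sd * nodes
    const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    vals = np.array(
        [
            const
            + float(np.sum(y * (eta_fixed + sigma * u) - n * np.logaddexp(0, eta_fixed + sigma * u)))
            - 0.5 * u * u
            for u in pts
        ]
    )
    return float(
        logsumexp(np.log(weights) + nodes**2 + vals)
        + np.log(np.sqrt(2.0) * sd)
        - 0.5 * np.log(2.0 * np.pi)
    )
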