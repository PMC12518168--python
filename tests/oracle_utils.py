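"""Independent oracles shared by the unit and acceptance tests."""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def convex_oracle_lambdas(fp: np.ndarray, fb: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Solve the L1-regularised maximum-entropy objective with a generic
    convex optimiser (L-BFGS-B on the positive/negative split), independent
    of the package's coordinate-descent path."""
    pbar = fp.mean(axis=0)
    d = fb.shape[1]

    def neg_gain(z):
        lam = z[:d] - z[d:]
        eta = fb @ lam
        val = logsumexp(eta) - np.log(fb.shape[0]) - pbar @ lam + beta @ (z[:d] + z[d:])
        w = np.exp(eta - logsumexp(eta))
        grad_lam = fb.T @ w - pbar
        return val, np.concatenate([grad_lam + beta, -grad_lam + beta])

    res = minimize(neg_gain, np.zeros(2 * d), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * d),
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
    return res.x[:d] - res.x[d:]


def gibbs_instance(n_cells: int, n_presences: int, true_lam, seed: int):
    """Tiny presence/background feature matrices drawn from a known Gibbs law
    over uniform [0,1] linear features."""
    rng = np.random.default_rng(seed)
    true_lam = np.asarray(true_lam, dtype=float)
    fb = rng.uniform(0, 1, size=(n_cells, true_lam.size))
    p = np.exp(fb @ true_lam)
    p /= p.sum()
    idx = rng.choice(n_cells, size=n_presences, p=p)
    return fb[idx], fb
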