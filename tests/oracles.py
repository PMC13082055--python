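"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's solver paths: roots are found with
generic root-finders on the defining equations, and reference quantities
come from closed forms or plain Monte Carlo.
"""

import numpy as np
from scipy import optimize


def firth_intercept_root(y, depths):
    """Intercept-only Firth quasi-Poisson root by bisection.

    Solves sum(Y) - e^b sum(N) + 1/2 = 0 directly (the leverage sum of an
    intercept-only design is identically 1).
    """
    y = np.asarray(y, dtype=float)
    depths = np.asarray(depths, dtype=float)

    def g(b):
        return y.sum() - np.exp(b) * depths.sum() + 0.5

    lo, hi = -60.0, 20.0
    return optimize.brentq(g, lo, hi, xtol=1e-14)


def hat_from_projection(mu, design):
    """Leverages via the explicit projection matrix W^{1/2}X(X'WX)^{-1}X'W^{1/2}."""
    w_half = np.sqrt(mu)
    a = design * w_half[:, None]
    h = a @ np.linalg.solve(a.T @ a, a.T)
    return np.diag(h)


def quasi_score_root(y, depths, design, firth_adjust=None):
    """Root of the quasi-score over an arbitrary design by a generic solver.

    ``firth_adjust`` is an optional fixed per-sample adjustment added to the
    counts (``h/2`` evaluated at the null model); None gives the ordinary
    quasi-Poisson root.
    """
    y = np.asarray(y, dtype=float)
    if firth_adjust is not None:
        y = y + 0.5 * np.asarray(firth_adjust)
    off = np.log(np.asarray(depths, dtype=float))
    design = np.asarray(design, dtype=float)

    def score(theta):
        mu = np.exp(np.clip(off + design @ theta, -700, 700))
        return design.T @ (y - mu)

    q = design.shape[1]
    th0 = np.zeros(q)
    # put the crude rate estimate on the first column that is an intercept
    th0[np.argmax((design == 1).all(axis=0))] = np.log(max(y.sum(), 0.5) / np.exp(off).sum())
    sol = optimize.root(score, th0, method="hybr", tol=1e-13)
    if not sol.success:
        raise RuntimeError(f"oracle root finder failed: {sol.message}")
    return sol.x


def bh_reference(p):
    """Step-up BH by direct definition q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q
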