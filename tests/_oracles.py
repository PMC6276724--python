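"""Independent reference implementations used only to check the package."""

import itertools

import numpy as np
from scipy.optimize import minimize


def dual_qp_oracle(K, y, C):
    """Dense solve of the soft-margin SVM dual with SLSQP.

    Returns (alpha, dual objective value).  Independent of the SMO path.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    res = minimize(
        fun,
        np.zeros(n),
        jac=jac,
        bounds=[(0.0, c) for c in C],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.x, -fun(res.x)


def bh_stepup_bruteforce(p, alpha):
    """Benjamini-Hochberg by direct threshold enumeration.

    Find the largest k with p_(k) <= k alpha / m; reject the k smallest.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def all_pairs_geodesic_bruteforce(mesh):
    """Floyd-Warshall shortest paths over mesh edges (small meshes only)."""
    n = mesh.n_vertices
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for tri in mesh.faces:
        for i, j in itertools.combinations(tri, 2):
            w = float(np.linalg.norm(mesh.vertices[i] - mesh.vertices[j]))
            d[i, j] = min(d[i, j], w)
            d[j, i] = d[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def anova_ss_bruteforce(values, groups):
    """One-way ANOVA F from the explicit sum-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    cells = list(dict.fromkeys(groups))
    grand = values.mean()
    ssb = ssw = 0.0
    for c in cells:
        s = values[np.asarray(groups) == c]
        ssb += len(s) * (s.mean() - grand) ** 2
        ssw += float(((s - s.mean()) ** 2).sum())
    df1, df2 = len(cells) - 1, len(values) - len(cells)
    return (ssb / df1) / (ssw / df2), (df1, df2)
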