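"""Independent oracles used by the test suite.

These deliberately avoid the coordinate-descent code path: the group-Lasso
oracle is an accelerated proximal-gradient (FISTA) run on the explicitly
materialised stacked design with the exact Lipschitz step, and the metric
oracle enumerates (SNP, trait) pairs one by one.
"""

import numpy as np

from mtglasso.solver import objective


def explicit_design(stacked, basis) -> np.ndarray:
    """Materialise the N x (p*q) orthonormalized stacked design."""
    return np.hstack(
        [stacked.block(j) @ basis.Rinv[j] for j in range(stacked.p)]
    )


def fista_group_lasso(stacked, basis, lam, weights, n_iter=20000):
    """High-accuracy FISTA solution; returns (coefs (p, q), objective)."""
    p, q, c = stacked.p, stacked.q, stacked.c
    Xt = explicit_design(stacked, basis)
    y = stacked.y
    H = Xt.T @ Xt / c
    g0 = Xt.T @ y / c
    L = float(np.linalg.eigvalsh(H).max())
    b = np.zeros(p * q)
    v = b.copy()
    tk = 1.0
    for _ in range(n_iter):
        u = (v - (H @ v - g0) / L).reshape(p, q)
        norms = np.sqrt((u**2).sum(axis=1))
        shrink = np.maximum(
            0.0, 1.0 - (lam * weights / L) / np.maximum(norms, 1e-300)
        )
        b_new = (shrink[:, None] * u).ravel()
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        v = b_new + ((tk - 1.0) / t_new) * (b_new - b)
        b, tk = b_new, t_new
    bm = b.reshape(p, q)
    return bm, objective(stacked, basis, bm, lam, weights)


def pairwise_metrics(estimate, truth):
    """Brute-force (SNP, trait)-pair enumeration of selection metrics."""
    est = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    tp = fp = fn = 0
    size = 0
    sse = 0.0
    for j in range(est.shape[0]):
        for k in range(est.shape[1]):
            selected = est[j, k] != 0
            real = truth[j, k] != 0
            if selected:
                size += 1
                if real:
                    tp += 1
                else:
                    fp += 1
            elif real:
                fn += 1
            sse += (est[j, k] - truth[j, k]) ** 2
    total_true = tp + fn
    fdr = fp / size if size else 0.0
    fnr = fn / total_true if total_true else 0.0
    return dict(tp=tp, size=size, fp=fp, fn=fn, fdr=fdr, fnr=fnr, sse=sse)


def random_instance(rng, n_max=50, p_max=10, q_max=3):
    """A random small dataset with non-constant SNP columns."""
    from mtglasso.stacking import MultiResponseData

    n = int(rng.integers(20, n_max + 1))
    p = int(rng.integers(3, p_max + 1))
    q = int(rng.integers(1, q_max + 1))
    while True:
        G = rng.integers(0, 3, size=(n, p))
        if np.all(G.std(axis=0) > 0):
            break
    beta = np.zeros((p, q))
    k_causal = int(rng.integers(0, p // 2 + 1))
    if k_causal:
        idx = rng.choice(p, size=k_causal, replace=False)
        beta[idx] = rng.normal(scale=0.5, size=(k_causal, q))
    Y = (G - G.mean(axis=0)) @ beta + rng.normal(size=(n, q))
    return MultiResponseData(G, Y)
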