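"""Group cyclical coordinate descent (GCD) for the stacked group Lasso.

The criterion, on block-orthonormalized covariates with scale convention
``X̃_j'X̃_j = c·I`` (c = n), is

    (1/(2c)) ||y - Σ_j X̃_j b_j||²  +  λ Σ_j w_j ||b_j||₂

with default group weights ``w_j = sqrt(d_j) = sqrt(q)``.  One group at a
time has the closed-form minimizer ``b_j = S(z_j, λ w_j)`` where ``z_j`` is
the group least-squares update from the current residual and ``S`` the
multivariate soft-threshold; cycling these updates never increases the
objective and converges to a global minimizer of the convex criterion.

Everything is carried on an ``n x q`` residual matrix rather than the
``n·q``-long stacked vector: for group ``j``,

    X̃_j' r = M_j' (R' x_j)   with   M_j = W R_j⁻¹,

so one update costs O(n q) and a full-gradient KKT scan is a single GEMM.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .stacking import OrthonormalBasis, StackedData

__all__ = [
    "GroupCoefficients",
    "SolverConfig",
    "LambdaPath",
    "group_soft_threshold",
    "lambda_max",
    "gcd_fit",
    "solve_path",
    "objective",
    "kkt_residual",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass(frozen=True)
class GroupCoefficients:
    """p coefficient blocks of length q, on a declared scale."""

    values: np.ndarray  # (p, q)
    scale: str = "orthonormalized"  # or "original"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("coefficients must be a (p, q) matrix")
        if not np.isfinite(v).all():
            raise ValueError("non-finite coefficients")
        object.__setattr__(self, "values", v)

    @property
    def active_groups(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.values != 0, axis=1))


@dataclasses.dataclass
class SolverConfig:
    """Tolerances, iteration caps and the λ grid for pathwise GCD."""

    tol: float = 1e-4
    max_iter: int = 10_000
    lambda_grid: np.ndarray | None = None
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    group_weights: np.ndarray | None = None
    strategy: str = "active_set"  # or "cyclic"
    track_objective: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or len(g) == 0 or np.any(g <= 0):
                raise ValueError("lambda_grid must be positive")
            if len(g) > 1 and np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")
            self.lambda_grid = g

    def weights(self, p: int, q: int) -> np.ndarray:
        if self.group_weights is None:
            return np.full(p, np.sqrt(q))
        w = np.asarray(self.group_weights, dtype=float)
        if w.shape != (p,) or np.any(w < 0):
            raise ValueError("group_weights must be p nonnegative reals")
        return w


@dataclasses.dataclass
class LambdaPath:
    """Solutions along a decreasing λ grid (orthonormalized scale)."""

    lambdas: np.ndarray  # (L,)
    coefs: np.ndarray  # (L, p, q)
    objectives: np.ndarray  # (L,)
    rss: np.ndarray  # (L,) stacked residual sum of squares
    n_sweeps: np.ndarray  # (L,)
    kkt: np.ndarray  # (L,) KKT residual at each solution
    converged: np.ndarray  # (L,) bool
    df: np.ndarray | None = None  # filled by model selection
    ebic: np.ndarray | None = None

    @property
    def n_active(self) -> np.ndarray:
        return np.count_nonzero(np.any(self.coefs != 0, axis=2), axis=1)


def group_soft_threshold(z: np.ndarray, threshold: float) -> np.ndarray:
    """Multivariate soft-threshold: (1 - threshold/||z||)₊ · z.

    Returns the exact zero vector when ``||z|| <= threshold`` (including
    z = 0), the argmin of ½||z - b||² + threshold·||b||₂.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    z = np.asarray(z, dtype=float)
    nrm = np.linalg.norm(z)
    if nrm <= threshold or nrm == 0.0:
        return np.zeros_like(z)
    return (1.0 - threshold / nrm) * z


def _correlations(stacked: StackedData, basis: OrthonormalBasis) -> np.ndarray:
    """z0 with z0_j = X̃_j' y / c, the per-group correlations at b = 0."""
    G0 = stacked.Yw.T @ stacked.Xs  # (q, p)
    return np.einsum("pki,kp->pi", basis.M, G0) / basis.c


def lambda_max(
    stacked: StackedData,
    basis: OrthonormalBasis,
    weights: np.ndarray | None = None,
) -> float:
    """Smallest λ whose solution is identically zero: max_j ||X̃_j'y|| / (c w_j)."""
    p, q = stacked.p, stacked.q
    w = np.full(p, np.sqrt(q)) if weights is None else np.asarray(weights, float)
    norms = np.linalg.norm(_correlations(stacked, basis), axis=1)
    with np.errstate(divide="ignore"):
        vals = np.where(w > 0, norms / np.where(w > 0, w, 1.0), np.inf)
    return float(np.max(vals)) if np.any(norms > 0) else 0.0


def _fitted_contribution(Xs: np.ndarray, M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fitted-value matrix (n, q): Σ_j outer(x_j, M_j b_j)."""
    Mb = np.einsum("pab,pb->pa", M, b)  # (p, q)
    return Xs @ Mb


def _sweep_py(Xs, M, c, lam_w, b, Rm, indices):
    """One cyclic pass over ``indices``; returns max coefficient change."""
    maxd = 0.0
    for j in indices:
        xj = Xs[:, j]
        g = Rm.T @ xj  # (q,)
        z = b[j] + (M[j].T @ g) / c
        nrm = np.sqrt(z @ z)
        t = lam_w[j]
        if nrm <= t or nrm == 0.0:
            new = np.zeros_like(z)
        else:
            new = (1.0 - t / nrm) * z
        d = new - b[j]
        if np.any(d != 0.0):
            Rm -= np.outer(xj, M[j] @ d)
            b[j] = new
            step = np.abs(d).max()
            if step > maxd:
                maxd = step
    return maxd


def _sweep_jit_impl(Xs, M, c, lam_w, b, Rm, indices):  # pragma: no cover
    # loop-level version of _sweep_py for numba; Xs should be Fortran-ordered
    n, q = Rm.shape
    maxd = 0.0
    g = np.empty(q)
    z = np.empty(q)
    d = np.empty(q)
    md = np.empty(q)
    for t_idx in range(indices.shape[0]):
        j = indices[t_idx]
        for k in range(q):
            g[k] = 0.0
        for i in range(n):
            x = Xs[i, j]
            if x != 0.0:
                for k in range(q):
                    g[k] += x * Rm[i, k]
        nrm2 = 0.0
        for k in range(q):
            acc = 0.0
            for l in range(q):
                acc += M[j, l, k] * g[l]
            zk = b[j, k] + acc / c
            z[k] = zk
            nrm2 += zk * zk
        nrm = np.sqrt(nrm2)
        t = lam_w[j]
        shrink = 0.0 if (nrm <= t or nrm == 0.0) else 1.0 - t / nrm
        changed = False
        for k in range(q):
            d[k] = shrink * z[k] - b[j, k]
            if d[k] != 0.0:
                changed = True
        if changed:
            for k in range(q):
                acc = 0.0
                for l in range(q):
                    acc += M[j, k, l] * d[l]
                md[k] = acc
            for i in range(n):
                x = Xs[i, j]
                if x != 0.0:
                    for k in range(q):
                        Rm[i, k] -= x * md[k]
            for k in range(q):
                b[j, k] += d[k]
                ad = abs(d[k])
                if ad > maxd:
                    maxd = ad
    return maxd


try:  # optional numba acceleration of the inner sweep
    from numba import njit as _njit

    _sweep_jit = _njit(cache=False)(_sweep_jit_impl)
except ImportError:  # pragma: no cover
    _sweep_jit = None


def _sweep(Xs, M, c, lam_w, b, Rm, indices):
    if _sweep_jit is not None:
        return _sweep_jit(Xs, M, c, lam_w, b, Rm,
                          np.asarray(indices, dtype=np.int64))
    return _sweep_py(Xs, M, c, lam_w, b, Rm, indices)


def _objective_from_residual(Rm, c, lam, w, b):
    pen = float(w @ np.linalg.norm(b, axis=1))
    return 0.5 * float((Rm**2).sum()) / c + lam * pen


def _fit_inplace(Xs, M, c, lam, w, b, Rm, config: SolverConfig, objs=None):
    """Run GCD at one λ, mutating ``b`` and ``Rm``.  Returns (sweeps, converged)."""
    p = Xs.shape[1]
    lam_w = lam * w
    sweeps = 0
    if config.strategy == "cyclic":
        order = np.arange(p)
        for _ in range(config.max_iter):
            maxd = _sweep(Xs, M, c, lam_w, b, Rm, order)
            sweeps += 1
            if objs is not None:
                objs.append(_objective_from_residual(Rm, c, lam, w, b))
            if maxd < config.tol:
                return sweeps, True
        return sweeps, False
    if config.strategy != "active_set":
        raise ValueError(f"unknown strategy {config.strategy!r}")
    for _ in range(config.max_iter):
        active = np.flatnonzero(np.any(b != 0.0, axis=1))
        inner_ok = True
        if active.size:
            inner_ok = False
            for _ in range(config.max_iter):
                maxd = _sweep(Xs, M, c, lam_w, b, Rm, active)
                sweeps += 1
                if objs is not None:
                    objs.append(_objective_from_residual(Rm, c, lam, w, b))
                if maxd < config.tol:
                    inner_ok = True
                    break
        # full-gradient scan: z_j for every group in one GEMM
        G = Rm.T @ Xs  # (q, p)
        Z = b + np.einsum("pki,kp->pi", M, G) / c
        norms = np.linalg.norm(Z, axis=1)
        inactive = np.all(b == 0.0, axis=1)
        violators = np.flatnonzero(inactive & (norms > lam_w * (1.0 + 1e-12)))
        if violators.size == 0:
            if inner_ok:
                return sweeps, True
        else:
            _sweep(Xs, M, c, lam_w, b, Rm, violators)
            sweeps += 1
            if objs is not None:
                objs.append(_objective_from_residual(Rm, c, lam, w, b))
    return sweeps, False


def gcd_fit(
    stacked: StackedData,
    basis: OrthonormalBasis,
    lam: float,
    init: np.ndarray | GroupCoefficients | None = None,
    config: SolverConfig | None = None,
    return_info: bool = False,
):
    """Fit the group Lasso at one λ by group cyclical coordinate descent.

    Starts from ``init`` (zero by default), cycles the closed-form group
    updates until the largest coefficient change in a sweep drops below
    ``config.tol``.  The returned solution is on the orthonormalized scale.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    config = config or SolverConfig()
    p, q, c = stacked.p, stacked.q, stacked.c
    w = config.weights(p, q)
    if init is None:
        b = np.zeros((p, q))
    else:
        vals = init.values if isinstance(init, GroupCoefficients) else init
        b = np.array(vals, dtype=float)
        if b.shape != (p, q):
            raise ValueError(f"init has shape {b.shape}, expected {(p, q)}")
    Xs = np.asfortranarray(stacked.Xs)
    Rm = stacked.Yw - _fitted_contribution(Xs, basis.M, b)
    objs = [] if config.track_objective else None
    sweeps, converged = _fit_inplace(Xs, basis.M, c, lam, w, b, Rm, config, objs)
    if not np.isfinite(Rm).all():
        raise FloatingPointError("non-finite residual during coordinate descent")
    if not converged:
        warnings.warn(
            f"GCD did not converge in {config.max_iter} sweeps at lambda={lam:g}",
            ConvergenceWarning,
        )
    coef = GroupCoefficients(b, scale="orthonormalized")
    if return_info:
        info = {
            "n_sweeps": sweeps,
            "converged": converged,
            "objective": _objective_from_residual(Rm, c, lam, w, b),
            "objective_per_sweep": objs,
            "rss": float((Rm**2).sum()),
            "kkt": _kkt_from_residual(Xs, basis.M, c, lam, w, b, Rm),
        }
        return coef, info
    return coef


def default_lambda_grid(lmax: float, config: SolverConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return config.lambda_grid
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, config.lambda_min_ratio * lmax, config.n_lambdas)


def solve_path(
    stacked: StackedData,
    basis: OrthonormalBasis,
    config: SolverConfig | None = None,
) -> LambdaPath:
    """Pathwise GCD over a decreasing λ grid with warm starts."""
    config = config or SolverConfig()
    p, q, c = stacked.p, stacked.q, stacked.c
    w = config.weights(p, q)
    lmax = lambda_max(stacked, basis, w)
    grid = default_lambda_grid(lmax, config)
    L = len(grid)
    coefs = np.zeros((L, p, q))
    objectives = np.empty(L)
    rss = np.empty(L)
    n_sweeps = np.zeros(L, dtype=int)
    kkt = np.empty(L)
    conv = np.zeros(L, dtype=bool)
    b = np.zeros((p, q))
    Xs = np.asfortranarray(stacked.Xs)
    Rm = stacked.Yw.copy()
    for i, lam in enumerate(grid):
        sweeps, ok = _fit_inplace(Xs, basis.M, c, lam, w, b, Rm, config)
        if not ok:
            warnings.warn(
                f"GCD did not converge at lambda={lam:g} (path index {i})",
                ConvergenceWarning,
            )
        coefs[i] = b
        rss[i] = float((Rm**2).sum())
        objectives[i] = _objective_from_residual(Rm, c, lam, w, b)
        n_sweeps[i] = sweeps
        kkt[i] = _kkt_from_residual(Xs, basis.M, c, lam, w, b, Rm)
        conv[i] = ok
    return LambdaPath(
        lambdas=np.asarray(grid, dtype=float),
        coefs=coefs,
        objectives=objectives,
        rss=rss,
        n_sweeps=n_sweeps,
        kkt=kkt,
        converged=conv,
    )


def objective(
    stacked: StackedData,
    basis: OrthonormalBasis,
    b: np.ndarray | GroupCoefficients,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    """(1/(2c))||y - X̃ b||² + λ Σ_j w_j ||b_j||₂ (orthonormalized scale)."""
    vals = b.values if isinstance(b, GroupCoefficients) else np.asarray(b, float)
    p, q, c = stacked.p, stacked.q, stacked.c
    if vals.shape != (p, q):
        raise ValueError(f"coefficients have shape {vals.shape}, expected {(p, q)}")
    w = np.full(p, np.sqrt(q)) if weights is None else np.asarray(weights, float)
    Rm = stacked.Yw - _fitted_contribution(stacked.Xs, basis.M, vals)
    return _objective_from_residual(Rm, c, lam, w, vals)


def _kkt_from_residual(Xs, M, c, lam, w, b, Rm) -> float:
    G = Rm.T @ Xs
    grad = np.einsum("pki,kp->pi", M, G) / c  # X̃_j' r / c
    norms_b = np.linalg.norm(b, axis=1)
    active = norms_b > 0
    res = 0.0
    if np.any(active):
        direc = b[active] / norms_b[active, None]
        r_act = grad[active] - (lam * w[active])[:, None] * direc
        res = max(res, float(np.abs(r_act).max()))
    if np.any(~active):
        g_in = np.linalg.norm(grad[~active], axis=1) - lam * w[~active]
        res = max(res, float(max(0.0, g_in.max())))
    return res


def kkt_residual(
    stacked: StackedData,
    basis: OrthonormalBasis,
    b: np.ndarray | GroupCoefficients,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    """Max violation of the group-Lasso stationarity conditions.

    Active groups must satisfy X̃_j'r/c = λ w_j b_j/||b_j||; inactive groups
    must satisfy ||X̃_j'r/c|| <= λ w_j.
    """
    vals = b.values if isinstance(b, GroupCoefficients) else np.asarray(b, float)
    p, q, c = stacked.p, stacked.q, stacked.c
    w = np.full(p, np.sqrt(q)) if weights is None else np.asarray(weights, float)
    Rm = stacked.Yw - _fitted_contribution(stacked.Xs, basis.M, vals)
    return _kkt_from_residual(stacked.Xs, basis.M, c, lam, w, vals, Rm)
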