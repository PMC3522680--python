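"""Tuning-parameter choice: group degrees of freedom and the extended BIC.

With p groups and N = n·q stacked observations, the criterion minimised over
the λ path is

    EBIC(λ) = N·log(RSS_λ / N) + df_λ·log(N) + 2·γ·df_λ·log(G),

with G = p (selection happens at the group level) and γ in [0, 1]; γ = 0 is
ordinary BIC, larger γ penalises large model spaces more and counters the
overly liberal selection BIC shows when p >> n.  df_λ is the group-Lasso
degrees-of-freedom approximation

    df = Σ_{j active} [ 1 + (d_j − 1)·||b_j|| / ||b_j^LS|| ],

where b_j^LS = X̃_j'y / c is the least-squares estimate from fitting group j
alone; when all d_j = 1 (the Lasso special case) this is the number of
nonzero coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .solver import GroupCoefficients, LambdaPath, _correlations
from .stacking import OrthonormalBasis, StackedData

__all__ = ["SelectionConfig", "group_df", "ebic", "select_lambda"]


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    gamma: float = 1.0
    df_mode: str = "yuan_lin"  # or "active_params"

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.df_mode not in ("yuan_lin", "active_params"):
            raise ValueError(f"unknown df_mode {self.df_mode!r}")


def group_df(
    b: np.ndarray | GroupCoefficients,
    stacked: StackedData,
    basis: OrthonormalBasis,
    df_mode: str = "yuan_lin",
    _ls_norms: np.ndarray | None = None,
) -> float:
    """Approximate degrees of freedom of a group-Lasso fit.

    Per-group contributions are clipped to [0, d_j] (the shrinkage ratio is
    capped at 1, which can otherwise be exceeded through correlation between
    groups).
    """
    vals = b.values if isinstance(b, GroupCoefficients) else np.asarray(b, float)
    q = stacked.q
    norms = np.linalg.norm(vals, axis=1)
    active = norms > 0
    if not np.any(active):
        return 0.0
    if df_mode == "active_params":
        return float(np.count_nonzero(vals))
    if _ls_norms is None:
        _ls_norms = np.linalg.norm(_correlations(stacked, basis), axis=1)
    ls = _ls_norms[active]
    if np.any(ls == 0):
        raise ValueError(
            "a group with zero single-group least-squares estimate has a "
            "nonzero penalized estimate; inconsistent state"
        )
    ratio = np.minimum(norms[active] / ls, 1.0)
    return float(np.sum(1.0 + (q - 1) * ratio))


def ebic(rss: float, df: float, N: int, G: int, gamma: float) -> float:
    """Extended BIC value; γ = 0 recovers ordinary BIC."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if N <= 0 or G < 1:
        raise ValueError("N must be positive and G >= 1")
    if df < 0:
        raise ValueError("df must be nonnegative")
    return float(N * np.log(rss / N) + df * np.log(N) + 2.0 * gamma * df * np.log(G))


def select_lambda(
    path: LambdaPath,
    stacked: StackedData,
    basis: OrthonormalBasis,
    config: SelectionConfig | None = None,
):
    """Pick the λ minimising EBIC along a fitted path.

    Fills ``path.df`` and ``path.ebic`` in place and returns
    ``(lambda_star, GroupCoefficients)``.  The grid is decreasing, so exact
    ties resolve toward the larger λ (the sparser model).
    """
    config = config or SelectionConfig()
    L = len(path.lambdas)
    if L == 0:
        raise ValueError("empty lambda path")
    N, G = stacked.N, stacked.p
    ls_norms = np.linalg.norm(_correlations(stacked, basis), axis=1)
    df = np.empty(L)
    crit = np.empty(L)
    # an exactly-interpolating fit has rss 0; floor it so the log stays finite
    rss = np.maximum(path.rss, np.finfo(float).tiny)
    for i in range(L):
        df[i] = group_df(
            path.coefs[i], stacked, basis, df_mode=config.df_mode, _ls_norms=ls_norms
        )
        crit[i] = ebic(rss[i], df[i], N, G, config.gamma)
    path.df = df
    path.ebic = crit
    idx = int(np.argmin(crit))  # first occurrence = largest λ on a decreasing grid
    return float(path.lambdas[idx]), GroupCoefficients(
        path.coefs[idx].copy(), scale="orthonormalized"
    )
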