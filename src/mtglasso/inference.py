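"""Multi-split adjusted p-values for selected SNP groups.

Repeat B times: split the subjects into two disjoint halves, run the full
selection pipeline (stack → group-Lasso path → EBIC) on the first half, and
on the second half compute, for every selected group j, the F-test p-value
from the regular linear regression in which group j is the only group.
Within a split, p-values are Bonferroni-adjusted by the selected-set size
and capped at 1; unselected groups get p = 1.  Across splits the adjusted
p-values are aggregated through empirical quantiles,

    Q_j(γ) = min{1, γ-quantile of {P_j^(b)/γ}},
    P_j    = min{1, (1 − log γ_min) · inf_γ Q_j(γ)},   γ_min = 0.05,

which is an asymptotically valid p-value adjusted for multiplicity and can
be used for both FWER and FDR control.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .stacking import MultiResponseData

__all__ = [
    "MultiSplitConfig",
    "MultiSplitResults",
    "group_f_test",
    "single_split",
    "aggregate",
    "adaptive_pvalue",
    "multisplit",
]


@dataclasses.dataclass(frozen=True)
class MultiSplitConfig:
    B: int = 50
    gamma_min: float = 0.05
    gamma_grid: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0.0 < self.gamma_min < 1.0:
            raise ValueError("gamma_min must lie in (0, 1)")
        grid = self.gamma_grid
        if grid is None:
            # 0.05, 0.10, ..., 1.00
            grid = np.round(np.arange(1, 21) * 0.05, 10)
        grid = np.asarray(grid, dtype=float)
        if np.any(grid < self.gamma_min) or np.any(grid > 1.0):
            raise ValueError("gamma_grid must lie within [gamma_min, 1]")
        object.__setattr__(self, "gamma_grid", grid)


@dataclasses.dataclass
class MultiSplitResults:
    """B×p adjusted per-split p-values plus the aggregated final p-values."""

    values: np.ndarray  # (B, p)
    selected_sets: list
    pvalues: np.ndarray  # (p,)
    snp_ids: tuple
    config: MultiSplitConfig


def group_f_test(data_half: MultiResponseData, group_index: int) -> float:
    """F-test p-value for 'group j is the only group' on one data half.

    The half's traits are stacked (N₂ = n₂·q rows) with per-trait intercepts;
    the null is that all q coefficients of SNP ``group_index`` are zero.
    Because the per-trait sub-designs occupy disjoint rows the fit decouples
    into q simple regressions, pooled into one F statistic on
    (q, N₂ − 2q) degrees of freedom.  For q = 1 this is the squared-t test
    of simple linear regression.
    """
    n, q = data_half.n, data_half.q
    if n < q + 2:
        raise ValueError("too few subjects in the half to run the F-test")
    x = data_half.genotypes[:, group_index].astype(float)
    x = x - x.mean()
    sxx = float(x @ x)
    Yc = data_half.phenotypes - data_half.phenotypes.mean(axis=0)
    df_resid = n * q - 2 * q
    if sxx <= 0 or df_resid <= 0:
        warnings.warn(
            f"degenerate design for SNP index {group_index}; returning p = 1"
        )
        return 1.0
    slopes = (x @ Yc) / sxx  # per-trait LS slopes
    rss0 = float((Yc**2).sum())
    rss1 = rss0 - sxx * float((slopes**2).sum())
    if rss1 <= 0:
        return 0.0
    F = ((rss0 - rss1) / q) / (rss1 / df_resid)
    return float(stats.f.sf(F, q, df_resid))


def single_split(
    data: MultiResponseData,
    rng: np.random.Generator,
    fit_kwargs: dict | None = None,
    model_kwargs: dict | None = None,
):
    """One split: select on half D1, test on half D2.

    Returns ``(selected_indices, adjusted_pvalues)`` with adjusted p-value
    min(p·|S|, 1) for groups in the selected set S and 1 elsewhere.
    """
    from .model import MultiTraitGroupLasso

    n, p = data.n, data.p
    if n < 4:
        raise ValueError("need at least four subjects to split and test")
    perm = rng.permutation(n)
    half = n // 2
    d1 = data.subset(np.sort(perm[:half]))
    d2 = data.subset(np.sort(perm[half:]))
    model = MultiTraitGroupLasso(d1, None, **(model_kwargs or {}))
    res = model.fit(**(fit_kwargs or {}))
    selected = np.flatnonzero(res.selected)
    pvals = np.ones(p)
    m = len(selected)
    for j in selected:
        pvals[j] = min(group_f_test(d2, int(j)) * m, 1.0)
    return selected, pvals


def aggregate(values: np.ndarray, gamma: float) -> np.ndarray:
    """Q_j(γ): empirical γ-quantile of {P_j^(b)/γ} per group, capped at 1."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    qtl = np.quantile(values / gamma, gamma, axis=0, method="inverted_cdf")
    return np.minimum(qtl, 1.0)


def adaptive_pvalue(
    values: np.ndarray, config: MultiSplitConfig | None = None
) -> np.ndarray:
    """Final p-values: min{1, (1 − log γ_min)·inf_γ Q_j(γ)} over the γ grid."""
    config = config or MultiSplitConfig()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    best = np.full(values.shape[1], np.inf)
    for gamma in config.gamma_grid:
        best = np.minimum(best, aggregate(values, float(gamma)))
    mult = 1.0 - np.log(config.gamma_min)
    return np.minimum(mult * best, 1.0)


def multisplit(
    data: MultiResponseData,
    config: MultiSplitConfig | None = None,
    fit_kwargs: dict | None = None,
    model_kwargs: dict | None = None,
) -> MultiSplitResults:
    """Run the full B-split procedure and aggregate to final p-values."""
    config = config or MultiSplitConfig()
    rng = np.random.default_rng(config.seed)
    values = np.ones((config.B, data.p))
    selected_sets = []
    for b in range(config.B):
        sel, pv = single_split(data, rng, fit_kwargs, model_kwargs)
        values[b] = pv
        selected_sets.append(sel)
    pvalues = adaptive_pvalue(values, config)
    return MultiSplitResults(
        values=values,
        selected_sets=selected_sets,
        pvalues=pvalues,
        snp_ids=data.snp_ids,
        config=config,
    )
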