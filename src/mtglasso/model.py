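"""Model/results interface for joint multi-trait group-Lasso marker selection.

`MultiTraitGroupLasso` is built from an (n, q) trait matrix and an (n, p)
additive-coded genotype matrix.  `fit()` runs the full pipeline — stack the
traits into one uni-response regression, orthonormalize the per-SNP
coefficient blocks, trace the group-Lasso path by group cyclical coordinate
descent, and pick λ by EBIC — returning a results object with the selected
SNPs, coefficient estimates, diagnostics, a `summary()` table, multi-split
p-values and prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import selection, solver, stacking

__all__ = ["MultiTraitGroupLasso", "MultiTraitGroupLassoResults"]


class MultiTraitGroupLasso:
    """Joint marker-selection model for q correlated quantitative traits.

    Parameters
    ----------
    phenotypes : (n, q) array of trait values.
    genotypes : (n, p) array with additive coding 0/1/2, no missing entries.
    whitening : 'identity' (default; traits are standardized, the criterion
        is a plain least-squares group Lasso), 'plugin' (one refit after
        estimating the residual covariance from an identity-whitened fit) or
        'user_supplied' (pass ``sigma`` on the original trait scale).
    standardize_traits : scale each centered trait to unit variance.
    group_weights : per-SNP penalty multipliers, default sqrt(q).
    """

    def __init__(
        self,
        phenotypes,
        genotypes,
        *,
        snp_ids=None,
        trait_names=None,
        subject_ids=None,
        whitening: str = "identity",
        sigma=None,
        standardize_traits: bool = True,
        group_weights=None,
    ):
        if isinstance(phenotypes, stacking.MultiResponseData):
            self.data = phenotypes
        else:
            self.data = stacking.MultiResponseData(
                np.asarray(genotypes),
                np.asarray(phenotypes, dtype=float),
                subject_ids=subject_ids,
                snp_ids=snp_ids,
                trait_names=trait_names,
            )
        if whitening not in ("identity", "plugin", "user_supplied"):
            raise ValueError(f"unknown whitening method {whitening!r}")
        self.whitening = whitening
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        self.standardize_traits = standardize_traits
        self.group_weights = group_weights

    @classmethod
    def from_data(cls, data: stacking.MultiResponseData, **kwargs):
        return cls(data, None, **kwargs)

    @classmethod
    def from_dataframes(
        cls, phenotypes: pd.DataFrame, genotypes: pd.DataFrame, **kwargs
    ):
        """Build from indexed DataFrames; subjects are inner-joined on index."""
        common = phenotypes.index.intersection(genotypes.index)
        if len(common) < 2:
            raise ValueError("fewer than two subjects shared between the tables")
        ph = phenotypes.loc[common]
        gt = genotypes.loc[common]
        return cls(
            ph.to_numpy(dtype=float),
            gt.to_numpy(),
            subject_ids=list(map(str, common)),
            snp_ids=list(map(str, gt.columns)),
            trait_names=list(map(str, ph.columns)),
            **kwargs,
        )

    def _init_kwargs(self) -> dict:
        return dict(
            whitening=self.whitening,
            sigma=self.sigma,
            standardize_traits=self.standardize_traits,
            group_weights=self.group_weights,
        )

    def _whitening_spec(self, preliminary_results=None) -> stacking.WhiteningSpec:
        q = self.data.q
        if self.whitening == "identity":
            return stacking.WhiteningSpec.identity(q)
        if self.whitening == "user_supplied":
            if self.sigma is None:
                raise ValueError("user_supplied whitening requires sigma")
            sigma = np.asarray(self.sigma, dtype=float)
            if self.standardize_traits:
                s = (
                    self.data.phenotypes - self.data.phenotypes.mean(axis=0)
                ).std(axis=0)
                sigma = sigma / np.outer(s, s)
            return stacking.WhiteningSpec(sigma, method="user_supplied")
        # plugin: residual covariance on the (centered, scaled) trait scale
        stk = stacking.stack(
            self.data, None, standardize_traits=self.standardize_traits
        )
        if preliminary_results is None:
            resid = stk.Yw
        else:
            B = preliminary_results._coef_scaled_traits
            resid = stk.Yw - stk.Xs @ B
        S = np.atleast_2d(np.cov(resid, rowvar=False, ddof=1))
        S = (S + S.T) / 2.0
        w, V = np.linalg.eigh(S)
        w = np.maximum(w, 1e-8 * max(w.max(), 1.0))
        return stacking.WhiteningSpec((V * w) @ V.T, method="plugin")

    def fit(
        self,
        *,
        gamma: float = 1.0,
        df_mode: str = "yuan_lin",
        lambda_grid=None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        tol: float = 1e-4,
        max_iter: int = 10_000,
        strategy: str = "active_set",
    ) -> "MultiTraitGroupLassoResults":
        """Fit the path and return the EBIC-selected solution."""
        fit_kwargs = dict(
            gamma=gamma,
            df_mode=df_mode,
            lambda_grid=lambda_grid,
            n_lambdas=n_lambdas,
            lambda_min_ratio=lambda_min_ratio,
            tol=tol,
            max_iter=max_iter,
            strategy=strategy,
        )
        results = self._fit_once(stacking.WhiteningSpec.identity(self.data.q)
                                 if self.whitening == "plugin"
                                 else self._whitening_spec(),
                                 fit_kwargs)
        if self.whitening == "plugin":
            spec = self._whitening_spec(preliminary_results=results)
            results = self._fit_once(spec, fit_kwargs)
        return results

    def _fit_once(self, spec, fit_kwargs) -> "MultiTraitGroupLassoResults":
        stacked = stacking.stack(
            self.data, spec, standardize_traits=self.standardize_traits
        )
        basis = stacking.orthonormalize(stacked)
        config = solver.SolverConfig(
            tol=fit_kwargs["tol"],
            max_iter=fit_kwargs["max_iter"],
            lambda_grid=fit_kwargs["lambda_grid"],
            n_lambdas=fit_kwargs["n_lambdas"],
            lambda_min_ratio=fit_kwargs["lambda_min_ratio"],
            group_weights=self.group_weights,
            strategy=fit_kwargs["strategy"],
        )
        path = solver.solve_path(stacked, basis, config)
        sel_config = selection.SelectionConfig(
            gamma=fit_kwargs["gamma"], df_mode=fit_kwargs["df_mode"]
        )
        lam_star, coef = selection.select_lambda(path, stacked, basis, sel_config)
        return MultiTraitGroupLassoResults(
            model=self,
            stacked=stacked,
            basis=basis,
            path=path,
            whitening_spec=spec,
            lambda_=lam_star,
            coef_orth=coef,
            fit_kwargs=fit_kwargs,
        )


class MultiTraitGroupLassoResults:
    """Fitted joint group-Lasso model: estimates, diagnostics, inference."""

    def __init__(
        self, model, stacked, basis, path, whitening_spec, lambda_, coef_orth,
        fit_kwargs,
    ):
        self.model = model
        self.stacked = stacked
        self.basis = basis
        self.path = path
        self.whitening_spec = whitening_spec
        self.lambda_ = lambda_
        self.coef_orth = coef_orth
        self.fit_kwargs = fit_kwargs
        idx = int(np.argmin(np.abs(path.lambdas - lambda_)))
        self.df_ = float(path.df[idx])
        self.ebic_ = float(path.ebic[idx])
        self.rss_ = float(path.rss[idx])
        self.converged_ = bool(path.converged[idx])

    # ---- coefficient scales -------------------------------------------------
    @property
    def _coef_scaled_traits(self) -> np.ndarray:
        """(p, q) on standardized-genotype / standardized-trait scale."""
        return stacking.backtransform(self.coef_orth.values, self.basis)

    @property
    def params(self) -> np.ndarray:
        """(p, q) coefficients: standardized genotypes, original trait units."""
        return self._coef_scaled_traits * self.stacked.trait_scale[None, :]

    @property
    def params_raw(self) -> np.ndarray:
        """(p, q) coefficients on the raw genotype (0/1/2) and trait scale."""
        return self.params / self.stacked.genotype_scale[:, None]

    @property
    def selected(self) -> np.ndarray:
        """Boolean length-p mask of SNPs with a nonzero coefficient group."""
        return np.any(self.coef_orth.values != 0, axis=1)

    @property
    def selected_snps(self) -> tuple:
        ids = np.asarray(self.stacked.snp_ids, dtype=object)
        return tuple(ids[self.selected])

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))

    # ---- prediction ---------------------------------------------------------
    def predict(self, genotypes) -> np.ndarray:
        """Predict all traits for new subjects (raw 0/1/2 genotypes)."""
        G = np.asarray(genotypes, dtype=float)
        if G.ndim != 2 or G.shape[1] != self.stacked.p:
            raise ValueError(f"genotypes must be (m, {self.stacked.p})")
        Xs = (G - self.stacked.genotype_center) / self.stacked.genotype_scale
        return Xs @ self.params + self.stacked.trait_center

    # ---- inference ----------------------------------------------------------
    def multisplit(self, B: int = 50, seed=None, gamma_min: float = 0.05,
                   gamma_grid=None):
        """Multi-split adjusted p-values for every SNP group (see inference)."""
        from . import inference

        config = inference.MultiSplitConfig(
            B=B, gamma_min=gamma_min, gamma_grid=gamma_grid, seed=seed
        )
        return inference.multisplit(
            self.model.data, config,
            fit_kwargs=self.fit_kwargs,
            model_kwargs=self.model._init_kwargs(),
        )

    # ---- reporting ----------------------------------------------------------
    def summary(self, max_rows: int = 40) -> str:
        stk = self.stacked
        lines = [
            "Joint multi-trait group Lasso",
            "=" * 64,
            f"subjects: {stk.n}    SNPs: {stk.p}    traits: {stk.q}"
            f"    stacked N: {stk.N}",
            f"whitening: {self.whitening_spec.method}"
            f"    EBIC gamma: {self.fit_kwargs['gamma']:g}",
            f"selected lambda: {self.lambda_:.6g}    df: {self.df_:.2f}"
            f"    EBIC: {self.ebic_:.2f}",
            f"selected SNPs (groups): {self.n_selected}",
            "-" * 64,
        ]
        sel = np.flatnonzero(self.selected)
        header = f"{'SNP':<16}" + "".join(
            f"{name:>12}" for name in stk.trait_names
        )
        lines.append(header)
        params = self.params
        for j in sel[:max_rows]:
            row = f"{stk.snp_ids[j]:<16}" + "".join(
                f"{params[j, k]:>12.4f}" for k in range(stk.q)
            )
            lines.append(row)
        if len(sel) > max_rows:
            lines.append(f"... ({len(sel) - max_rows} more)")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<MultiTraitGroupLassoResults: n={self.stacked.n}, p={self.stacked.p},"
            f" q={self.stacked.q}, selected={self.n_selected},"
            f" lambda={self.lambda_:.4g}>"
        )
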