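"""Selection metrics, baseline methods and the k-fold prediction comparison.

Counting is at the (SNP, trait)-pair level: the joint group method selects
pairs in blocks of q (a selected SNP contributes q pairs), while the
combined-individual baseline (one Lasso per trait, results pooled) selects
pairs trait by trait.  Reported per fit: true positives, model size, FDR
(0 when nothing is selected), FNR and the coefficient SSE against the truth.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SimulationDesign, simulate_dataset
from .stacking import MultiResponseData

__all__ = [
    "SelectionMetrics",
    "score_selection",
    "fit_individual_lasso",
    "IndividualLassoFit",
    "single_snp_scan",
    "SingleSnpScan",
    "prediction_cv",
    "replicate_metrics",
]


@dataclasses.dataclass(frozen=True)
class SelectionMetrics:
    true_positive: int
    model_size: int
    fdr: float
    fnr: float
    sse: float

    @property
    def false_positive(self) -> int:
        return self.model_size - self.true_positive


def score_selection(estimate, truth: np.ndarray) -> SelectionMetrics:
    """Score a (p, q) coefficient estimate against the true (p, q) matrix."""
    est = np.asarray(getattr(estimate, "params", estimate), dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape}, truth {truth.shape}")
    sel = est != 0
    true_pairs = truth != 0
    tp = int(np.count_nonzero(sel & true_pairs))
    size = int(np.count_nonzero(sel))
    fn = int(np.count_nonzero(true_pairs & ~sel))
    total_true = int(np.count_nonzero(true_pairs))
    fdr = (size - tp) / size if size > 0 else 0.0
    fnr = fn / total_true if total_true > 0 else 0.0
    sse = float(((est - truth) ** 2).sum())
    return SelectionMetrics(tp, size, fdr, fnr, sse)


@dataclasses.dataclass
class IndividualLassoFit:
    """Per-trait Lasso fits (q = 1 runs of the same pipeline) plus overlap."""

    results: list  # per-trait MultiTraitGroupLassoResults
    params: np.ndarray  # (p, q), standardized-genotype / raw-trait scale
    overlap: np.ndarray  # SNPs selected for every trait

    @property
    def selected_pairs(self) -> np.ndarray:
        return self.params != 0


def fit_individual_lasso(
    data: MultiResponseData, model_kwargs: dict | None = None, **fit_kwargs
) -> IndividualLassoFit:
    """Analyze each trait separately with the Lasso (group size 1).

    Uses the exact same path/EBIC machinery with q = 1, where the group
    Lasso is the Lasso and the DF is the nonzero-coefficient count; the
    combined result pools pairs across traits and reports the overlap set.
    """
    from .model import MultiTraitGroupLasso

    model_kwargs = dict(model_kwargs or {})
    model_kwargs.setdefault("whitening", "identity")
    results = []
    params = np.zeros((data.p, data.q))
    masks = []
    for k in range(data.q):
        model = MultiTraitGroupLasso(data.trait(k), None, **model_kwargs)
        res = model.fit(**fit_kwargs)
        results.append(res)
        params[:, k] = res.params[:, 0]
        masks.append(res.selected)
    overlap = np.flatnonzero(np.logical_and.reduce(masks))
    return IndividualLassoFit(results=results, params=params, overlap=overlap)


@dataclasses.dataclass
class SingleSnpScan:
    """One-SNP-at-a-time regression scan with Bonferroni correction."""

    coef: np.ndarray  # (p, q) per-SNP simple-regression slopes
    pvalues: np.ndarray  # (p, q)
    significant: np.ndarray  # (p, q) bool, p <= alpha / p_tested per trait
    alpha: float
    threshold: float
    tested: np.ndarray  # bool mask of non-constant SNPs


def single_snp_scan(data: MultiResponseData, alpha: float = 0.05) -> SingleSnpScan:
    """Simple linear regression of each trait on each SNP, Bonferroni at ``alpha``.

    Constant SNPs are excluded (with a warning) from testing and from the
    Bonferroni denominator.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    X = data.genotypes.astype(float)
    n, p, q = data.n, data.p, data.q
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    tested = sxx > 0
    if not tested.all():
        warnings.warn(
            f"{np.count_nonzero(~tested)} constant SNP(s) excluded from the scan"
        )
    Yc = data.phenotypes - data.phenotypes.mean(axis=0)
    syy = (Yc**2).sum(axis=0)
    sxy = Xc.T @ Yc  # (p, q)
    coef = np.zeros((p, q))
    pvals = np.ones((p, q))
    with np.errstate(divide="ignore", invalid="ignore"):
        coef[tested] = sxy[tested] / sxx[tested, None]
        r2 = sxy[tested] ** 2 / (sxx[tested, None] * syy[None, :])
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        tstat2 = r2 * (n - 2) / (1.0 - r2)
    pvals[tested] = stats.f.sf(tstat2, 1, n - 2)
    n_tested = int(np.count_nonzero(tested))
    threshold = alpha / max(n_tested, 1)
    significant = (pvals <= threshold) & tested[:, None]
    return SingleSnpScan(
        coef=coef, pvalues=pvals, significant=significant, alpha=alpha,
        threshold=threshold, tested=tested,
    )


def _folds(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def prediction_cv(
    data: MultiResponseData,
    k: int = 5,
    methods=("joint", "individual"),
    seed=None,
    model_kwargs: dict | None = None,
    **fit_kwargs,
) -> dict:
    """k-fold prediction mean squared error per method.

    Each fold: fit on the remaining k−1 parts (full pipeline with EBIC),
    predict every trait on the held-out part, pool squared errors across
    folds and traits.  Degenerate folds (e.g. a SNP constant in the training
    part) are skipped with a warning.
    """
    from .model import MultiTraitGroupLasso

    if data.n < k:
        raise ValueError("need at least k subjects for k folds")
    rng = np.random.default_rng(seed)
    folds = _folds(data.n, k, rng)
    errors = {m: [] for m in methods}
    for i, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        try:
            if "joint" in methods:
                res = MultiTraitGroupLasso(train, None, **(model_kwargs or {})).fit(
                    **fit_kwargs
                )
                pred = res.predict(test.genotypes)
                errors["joint"].append((pred - test.phenotypes) ** 2)
            if "individual" in methods:
                fit = fit_individual_lasso(train, model_kwargs, **fit_kwargs)
                pred = np.column_stack(
                    [
                        fit.results[t].predict(test.genotypes)[:, 0]
                        for t in range(data.q)
                    ]
                )
                errors["individual"].append((pred - test.phenotypes) ** 2)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"fold {i} skipped: {exc}")
            continue
    out = {}
    for m in methods:
        if not errors[m]:
            raise RuntimeError(f"all folds failed for method {m!r}")
        out[m] = float(np.concatenate([e.ravel() for e in errors[m]]).mean())
    return out


def replicate_metrics(
    design: SimulationDesign,
    n_replicates: int,
    seed=None,
    methods=("joint", "individual"),
    model_kwargs: dict | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Run a scenario repeatedly, one metrics row per replicate × method."""
    from .model import MultiTraitGroupLasso

    root = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        ds = simulate_dataset(design, rng)
        fits = {}
        if "joint" in methods:
            res = MultiTraitGroupLasso(ds.data, None, **(model_kwargs or {})).fit(
                **fit_kwargs
            )
            fits["joint"] = res.params
        if "individual" in methods:
            fits["individual"] = fit_individual_lasso(
                ds.data, model_kwargs, **fit_kwargs
            ).params
        for method, params in fits.items():
            m = score_selection(params, ds.true_beta)
            rows.append(
                {
                    "replicate": rep,
                    "method": method,
                    "n": design.n,
                    "p": design.p,
                    "q": design.q,
                    "rho": design.rho,
                    "effect_size": design.effect_size,
                    "unmatched_fraction": design.unmatched_fraction,
                    "true_positive": m.true_positive,
                    "model_size": m.model_size,
                    "fdr": m.fdr,
                    "fnr": m.fnr,
                    "sse": m.sse,
                }
            )
    return pd.DataFrame(rows)
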