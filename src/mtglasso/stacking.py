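"""Stacked (uni-response) representation of multi-trait genotype data.

A study with ``n`` subjects, ``q`` correlated quantitative traits and ``p``
SNPs is rewritten as one regression with ``N = n*q`` observations in which
each SNP contributes a *group* of ``q`` coefficients — one per trait.  A SNP
is then selected for all traits at once, which is the point of the joint
analysis: traits sharing a genetic basis lend each other power.

The stacked design is never materialised.  With subject-major / trait-minor
row order the covariate block of SNP ``j`` is ``kron(x_j, W)`` where ``x_j``
is the (standardized) genotype column and ``W`` the residual whitener, so
everything the solver needs reduces to small dense products with the
``n x p`` genotype matrix and an ``n x q`` residual matrix.

Blocks are orthonormalized group-wise through the Cholesky factor ``R_j`` of
their Gram matrix scaled so that ``X̃_j' X̃_j = c I`` with ``c = n``; the
group coordinate-descent update then has a closed form.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

__all__ = [
    "MultiResponseData",
    "WhiteningSpec",
    "StackedData",
    "OrthonormalBasis",
    "stack",
    "estimate_sigma",
    "orthonormalize",
    "backtransform",
    "to_orthonormal",
]

_VALID_GENOTYPES = (0, 1, 2)


@dataclasses.dataclass(frozen=True)
class MultiResponseData:
    """Genotypes (additive 0/1/2 coding) plus quantitative traits.

    Parameters
    ----------
    genotypes : (n, p) integer array with entries in {0, 1, 2}; no missing
        values are allowed — in joint modelling a SNP with missingness cannot
        be included, impute upstream instead.
    phenotypes : (n, q) float array of trait values.
    subject_ids, snp_ids, trait_names : optional identifier sequences.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    subject_ids: tuple = None
    snp_ids: tuple = None
    trait_names: tuple = None

    def __post_init__(self):
        G = np.asarray(self.genotypes)
        Y = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
        if Y.shape[0] == 1 and G.shape[0] != 1 and Y.shape[1] == G.shape[0]:
            Y = Y.T
        if G.ndim != 2:
            raise ValueError("genotypes must be a 2-D (subjects x SNPs) matrix")
        n, p = G.shape
        if Y.shape[0] != n:
            raise ValueError(
                f"phenotypes have {Y.shape[0]} rows but genotypes have {n} subjects"
            )
        if n < 2:
            raise ValueError("at least two subjects are required")
        if Y.shape[1] < 1:
            raise ValueError("at least one trait is required")
        if np.isnan(G.astype(float)).any():
            raise ValueError(
                "missing genotype entries: in joint modelling, SNPs with "
                "missingness cannot be included (impute or drop first)"
            )
        if not np.isin(G, _VALID_GENOTYPES).all():
            bad = np.argwhere(~np.isin(G, _VALID_GENOTYPES))[0]
            raise ValueError(
                f"genotype entry at subject {bad[0]}, SNP {bad[1]} is not in {{0,1,2}}"
            )
        if not np.isfinite(Y).all():
            raise ValueError("phenotypes contain non-finite values")
        object.__setattr__(self, "genotypes", np.ascontiguousarray(G, dtype=np.int8))
        object.__setattr__(self, "phenotypes", np.ascontiguousarray(Y, dtype=float))
        object.__setattr__(self, "subject_ids", _default_ids(self.subject_ids, n, "s"))
        object.__setattr__(self, "snp_ids", _default_ids(self.snp_ids, p, "snp"))
        object.__setattr__(
            self, "trait_names", _default_ids(self.trait_names, Y.shape[1], "trait")
        )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    @property
    def q(self) -> int:
        return self.phenotypes.shape[1]

    def subset(self, subject_index) -> "MultiResponseData":
        """Row-subset (e.g. one half of a sample split or a CV fold)."""
        idx = np.asarray(subject_index)
        return MultiResponseData(
            self.genotypes[idx],
            self.phenotypes[idx],
            subject_ids=tuple(np.asarray(self.subject_ids, dtype=object)[idx]),
            snp_ids=self.snp_ids,
            trait_names=self.trait_names,
        )

    def trait(self, k: int) -> "MultiResponseData":
        """Single-trait view (q = 1), used by the individual-Lasso baseline."""
        return MultiResponseData(
            self.genotypes,
            self.phenotypes[:, [k]],
            subject_ids=self.subject_ids,
            snp_ids=self.snp_ids,
            trait_names=(self.trait_names[k],),
        )


def _default_ids(ids, m, prefix):
    if ids is None:
        return tuple(f"{prefix}{i}" for i in range(m))
    ids = tuple(str(x) for x in ids)
    if len(ids) != m:
        raise ValueError(f"expected {m} identifiers, got {len(ids)}")
    return ids


@dataclasses.dataclass(frozen=True)
class WhiteningSpec:
    """Residual covariance Σ and the whitener W with W'W = Σ⁻¹.

    ``method='identity'`` keeps the criterion a plain least-squares group
    Lasso; ``'plugin'`` uses a sample covariance of per-trait residuals.
    """

    sigma: np.ndarray
    method: str = "identity"

    def __post_init__(self):
        S = np.asarray(self.sigma, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("sigma must be positive definite")
        object.__setattr__(self, "sigma", S)

    @property
    def q(self) -> int:
        return self.sigma.shape[0]

    @property
    def whitener(self) -> np.ndarray:
        """W = L⁻¹ for Σ = L L' (lower Cholesky), so that W'W = Σ⁻¹."""
        if self.method == "identity":
            return np.eye(self.q)
        L = np.linalg.cholesky(self.sigma)
        return scipy.linalg.solve_triangular(L, np.eye(self.q), lower=True)

    @classmethod
    def identity(cls, q: int) -> "WhiteningSpec":
        return cls(np.eye(q), method="identity")


def estimate_sigma(
    data: MultiResponseData,
    method: str = "identity",
    preliminary_beta: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> WhiteningSpec:
    """Residual covariance estimate used for whitening.

    ``plugin`` computes the sample covariance of per-trait residuals from a
    preliminary fit (coefficients on the standardized-genotype / raw-trait
    scale); with no fit supplied the centered phenotypes themselves are used.
    The estimate is ridge-floored to keep it positive definite.
    """
    q = data.q
    if method == "identity":
        return WhiteningSpec.identity(q)
    if method == "user_supplied":
        if sigma is None:
            raise ValueError("user_supplied whitening requires a sigma matrix")
        return WhiteningSpec(np.asarray(sigma, dtype=float), method="user_supplied")
    if method != "plugin":
        raise ValueError(f"unknown whitening method {method!r}")
    Yc = data.phenotypes - data.phenotypes.mean(axis=0)
    if preliminary_beta is not None:
        Xs = _standardize_columns(data.genotypes.astype(float))[0]
        Yc = Yc - Xs @ np.asarray(preliminary_beta, dtype=float)
    S = np.cov(Yc, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = max(ridge, ridge * w.max() if w.max() > 0 else ridge)
    w = np.maximum(w, floor)
    S = (V * w) @ V.T
    return WhiteningSpec((S + S.T) / 2.0, method="plugin")


def _standardize_columns(X: np.ndarray):
    """Center columns and scale to unit variance (ddof=0).

    Constant columns are centered but left unscaled (scale 1); the
    orthonormalization step rejects them, but degenerate all-zero designs are
    still representable (all blocks zero).
    """
    center = X.mean(axis=0)
    Xc = X - center
    scale = np.sqrt((Xc**2).mean(axis=0))
    scale = np.where(scale > 0, scale, 1.0)
    return Xc / scale, center, scale


@dataclasses.dataclass(frozen=True)
class StackedData:
    """Implicit stacked design: y is length N = n*q, block j is kron(x_j, W).

    Row order is subject-major, trait-minor: stacked row ``i*q + k`` is
    subject ``i``, trait ``k``.  Group ``j`` occupies stacked coefficient
    positions ``j*q .. (j+1)*q - 1``.
    """

    Xs: np.ndarray  # (n, p) standardized genotypes
    Yw: np.ndarray  # (n, q) centered, scaled, whitened responses
    W: np.ndarray  # (q, q) whitener
    genotype_center: np.ndarray
    genotype_scale: np.ndarray
    trait_center: np.ndarray
    trait_scale: np.ndarray
    snp_ids: tuple
    trait_names: tuple

    @property
    def n(self) -> int:
        return self.Xs.shape[0]

    @property
    def p(self) -> int:
        return self.Xs.shape[1]

    @property
    def q(self) -> int:
        return self.Yw.shape[1]

    @property
    def N(self) -> int:
        return self.n * self.q

    @property
    def c(self) -> float:
        """Scale convention in X̃_j'X̃_j = c·I (c = n)."""
        return float(self.n)

    @property
    def y(self) -> np.ndarray:
        """The stacked response vector (subject-major, trait-minor)."""
        return self.Yw.ravel()

    @property
    def group_sizes(self) -> np.ndarray:
        return np.full(self.p, self.q, dtype=int)

    def block(self, j: int) -> np.ndarray:
        """Materialise the N x q covariate block of SNP ``j`` (tests only)."""
        return np.kron(self.Xs[:, [j]], self.W)

    def group_gram(self, j: int) -> np.ndarray:
        xx = float(self.Xs[:, j] @ self.Xs[:, j])
        return xx * (self.W.T @ self.W)


def stack(
    data: MultiResponseData,
    whitening: WhiteningSpec | None = None,
    standardize_traits: bool = True,
) -> StackedData:
    """Transform multi-response data into the stacked uni-response design.

    Genotype columns are centered and scaled to unit variance; each trait is
    centered (and by default scaled to unit variance) so the grand mean of the
    stacked response is zero and no intercept is needed.  The whitener W is
    applied to every subject's q-vector of responses; the covariate blocks
    absorb W implicitly via :meth:`StackedData.block`.
    """
    q = data.q
    if whitening is None:
        whitening = WhiteningSpec.identity(q)
    if whitening.q != q:
        raise ValueError(f"whitening is {whitening.q}x{whitening.q} but q = {q}")
    Xs, g_center, g_scale = _standardize_columns(data.genotypes.astype(float))
    t_center = data.phenotypes.mean(axis=0)
    Yc = data.phenotypes - t_center
    if standardize_traits:
        t_scale = Yc.std(axis=0)
        if np.any(t_scale == 0):
            k = int(np.flatnonzero(t_scale == 0)[0])
            raise ValueError(f"trait {data.trait_names[k]!r} is constant")
    else:
        t_scale = np.ones(q)
    Yc = Yc / t_scale
    W = whitening.whitener
    Yw = Yc @ W.T
    return StackedData(
        Xs=Xs,
        Yw=Yw,
        W=W,
        genotype_center=g_center,
        genotype_scale=g_scale,
        trait_center=t_center,
        trait_scale=t_scale,
        snp_ids=data.snp_ids,
        trait_names=data.trait_names,
    )


@dataclasses.dataclass(frozen=True)
class OrthonormalBasis:
    """Per-group Cholesky factors R_j with X̃_j = X_j R_j⁻¹, X̃_j'X̃_j = c·I."""

    R: np.ndarray  # (p, q, q) upper triangular
    Rinv: np.ndarray  # (p, q, q)
    M: np.ndarray  # (p, q, q) = W @ Rinv_j, maps orthonormal coefs to trait scale
    c: float

    @property
    def scale_convention(self) -> float:
        return self.c


def orthonormalize(stacked: StackedData) -> OrthonormalBasis:
    """Block-wise orthonormalization via Cholesky of (1/c)·X_j'X_j.

    With identity whitening the block Gram is (x_j'x_j)·I_q, so R_j is a
    positive multiple of the identity; the general path covers an arbitrary
    whitener W through R_j = sqrt(x_j'x_j / c) · chol(W'W).
    """
    p, q, c = stacked.p, stacked.q, stacked.c
    ss = (stacked.Xs**2).sum(axis=0)
    if np.any(ss <= 1e-12 * stacked.n):
        j = int(np.flatnonzero(ss <= 1e-12 * stacked.n)[0])
        raise ValueError(
            f"SNP {stacked.snp_ids[j]!r} has zero variance: its covariate block "
            "is singular and cannot be orthonormalized"
        )
    A = stacked.W.T @ stacked.W
    U = scipy.linalg.cholesky(A, lower=False)  # A = U'U
    Uinv = scipy.linalg.solve_triangular(U, np.eye(q), lower=False)
    fac = np.sqrt(ss / c)
    R = fac[:, None, None] * U[None, :, :]
    Rinv = (1.0 / fac)[:, None, None] * Uinv[None, :, :]
    M = np.einsum("ab,pbc->pac", stacked.W, Rinv)
    return OrthonormalBasis(R=R, Rinv=Rinv, M=M, c=c)


def backtransform(b: np.ndarray, basis: OrthonormalBasis) -> np.ndarray:
    """Map orthonormal-scale coefficients back: β_j = R_j⁻¹ b_j.

    All-zero groups stay exactly zero.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != basis.R.shape[:2]:
        raise ValueError(
            f"coefficients have shape {b.shape}, basis expects {basis.R.shape[:2]}"
        )
    return np.einsum("pab,pb->pa", basis.Rinv, b)


def to_orthonormal(beta: np.ndarray, basis: OrthonormalBasis) -> np.ndarray:
    """Inverse of :func:`backtransform`: b_j = R_j β_j."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != basis.R.shape[:2]:
        raise ValueError(
            f"coefficients have shape {beta.shape}, basis expects {basis.R.shape[:2]}"
        )
    return np.einsum("pab,pb->pa", basis.R, beta)
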