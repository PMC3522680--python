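"""Synthetic multi-trait GWAS data with clustered SNP correlation.

The generator reproduces the simulation design the method is benchmarked
under: n subjects (default 500), p SNPs (default 5000), q = 2 quantitative
traits.  Genotypes arise from latent multivariate normals — pairwise
correlation 0.2 within each causal cluster, 0.2 among all noise SNPs, and
independence between causal and noise SNPs — discretised to {0, 1, 2} at the
quartiles Φ⁻¹(0.25) and Φ⁻¹(0.75), which mimics a SNP in Hardy–Weinberg
equilibrium at allele frequency ½ (genotype frequencies ¼, ½, ¼).

The twelve causal SNPs sit in three index clusters (25–28, 41–44, 57–60,
1-based) shared by both traits; with ``unmatched_fraction`` f > 0, the same
⌈12f⌉ shared indices are dropped and each trait receives its own
replacement indices adjacent to the clusters, so exactly a fraction f of
each trait's causal SNPs are trait-specific.  Responses are Y = Xs·β + E
with standardized genotypes Xs and bivariate-normal residual rows with unit
variances and correlation ρ (0.1 / 0.5 / 0.9 in the study design).

Exchangeable correlation blocks are generated from one shared factor per
block, so no p×p covariance matrix is ever materialised.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import stats

from .stacking import MultiResponseData, _standardize_columns

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "simulate_genotypes",
    "make_coefficients",
    "simulate_responses",
    "simulate_dataset",
    "write_dataset",
]

# default causal clusters, 0-based (SNPs 25-28, 41-44, 57-60 in 1-based indexing)
_DEFAULT_CLUSTERS = ((24, 25, 26, 27), (40, 41, 42, 43), (56, 57, 58, 59))


@dataclasses.dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation scenario."""

    n: int = 500
    p: int = 5000
    q: int = 2
    rho: float = 0.5
    causal_clusters: tuple = _DEFAULT_CLUSTERS
    within_cluster_corr: float = 0.2
    noise_corr: float = 0.2
    effect_size: float = 0.5
    unmatched_fraction: float = 0.0
    noise_scale: float = 1.0  # 0 is a testing hook: Y = Xs @ beta exactly
    seed: int | None = None

    def __post_init__(self):
        clusters = tuple(tuple(int(i) for i in c) for c in self.causal_clusters)
        flat = [i for c in clusters for i in c]
        if len(set(flat)) != len(flat):
            raise ValueError("causal clusters must be disjoint")
        if flat and (min(flat) < 0 or max(flat) >= self.p):
            raise ValueError("cluster indices must lie within 0..p-1")
        for r in (self.within_cluster_corr, self.noise_corr):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 <= self.unmatched_fraction <= 1.0:
            raise ValueError("unmatched_fraction must lie in [0, 1]")
        object.__setattr__(self, "causal_clusters", clusters)

    @property
    def causal_indices(self) -> np.ndarray:
        return np.array([i for c in self.causal_clusters for i in c], dtype=int)

    @property
    def residual_cov(self) -> np.ndarray:
        S = np.full((self.q, self.q), self.rho)
        np.fill_diagonal(S, 1.0)
        return self.noise_scale**2 * S


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    data: MultiResponseData
    true_beta: np.ndarray  # (p, q), standardized-genotype scale
    residual_cov: np.ndarray
    design: SimulationDesign


def _rng(design: SimulationDesign, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(design.seed)


def _exchangeable_block(rng, n, n_snps, corr):
    """Latent normals with exchangeable correlation via one shared factor."""
    eps = rng.standard_normal((n, n_snps))
    if corr == 0.0 or n_snps == 1:
        return eps
    f = rng.standard_normal((n, 1))
    return math.sqrt(corr) * f + math.sqrt(1.0 - corr) * eps


def simulate_genotypes(design: SimulationDesign, rng=None, return_latent=False):
    """Draw genotypes: clustered latent MVN, quartile-discretised to {0,1,2}."""
    rng = _rng(design, rng)
    n, p = design.n, design.p
    Z = np.empty((n, p))
    causal = design.causal_indices
    noise = np.setdiff1d(np.arange(p), causal)
    # one shared factor per causal cluster; causal independent of noise
    for cluster in design.causal_clusters:
        idx = np.array(cluster, dtype=int)
        Z[:, idx] = _exchangeable_block(rng, n, len(idx), design.within_cluster_corr)
    if noise.size:
        Z[:, noise] = _exchangeable_block(rng, n, noise.size, design.noise_corr)
    lo, hi = stats.norm.ppf(0.25), stats.norm.ppf(0.75)
    G = (Z >= lo).astype(np.int8) + (Z >= hi).astype(np.int8)
    if return_latent:
        return G, Z
    return G


def make_coefficients(design: SimulationDesign, rng=None) -> np.ndarray:
    """True (p, q) coefficient matrix with optionally unmatched supports.

    Fully matched (f = 0): every trait's support is the 12 cluster indices.
    With f > 0: the same m = ⌈12f⌉ shared indices are dropped from all
    traits, and each trait receives m trait-specific replacements drawn
    deterministically (from the seed) among non-causal SNPs adjacent to the
    clusters; each trait keeps exactly 12 causal SNPs, a fraction f of which
    are trait-specific.
    """
    rng = _rng(design, rng)
    p, q = design.p, design.q
    causal = design.causal_indices
    k = len(causal)
    beta = np.zeros((p, q))
    beta[causal, :] = design.effect_size
    m = math.ceil(k * design.unmatched_fraction)
    if m == 0:
        return beta
    dropped = np.sort(rng.choice(causal, size=m, replace=False))
    beta[dropped, :] = 0.0
    pool = _adjacent_pool(design, needed=m * q)
    replacements = rng.choice(pool, size=m * q, replace=False)
    for t in range(q):
        beta[replacements[t * m : (t + 1) * m], t] = design.effect_size
    return beta


def _adjacent_pool(design: SimulationDesign, needed: int) -> np.ndarray:
    """Non-causal SNPs near the causal clusters, widened until large enough."""
    causal = set(design.causal_indices.tolist())
    reach = 4
    while True:
        pool = set()
        for cluster in design.causal_clusters:
            lo, hi = min(cluster), max(cluster)
            for i in range(lo - reach, hi + reach + 1):
                if 0 <= i < design.p and i not in causal:
                    pool.add(i)
        if len(pool) >= needed or reach > design.p:
            break
        reach *= 2
    if len(pool) < needed:
        raise ValueError("not enough non-causal SNPs for unmatched supports")
    return np.array(sorted(pool), dtype=int)


def simulate_responses(
    X: np.ndarray, beta: np.ndarray, design: SimulationDesign, rng=None
) -> np.ndarray:
    """Y = Xs·β + E with Xs the standardized genotypes and correlated noise."""
    rng = _rng(design, rng)
    Xs, _, _ = _standardize_columns(np.asarray(X, dtype=float))
    signal = Xs @ beta
    if design.noise_scale == 0.0:
        return signal
    L = np.linalg.cholesky(design.residual_cov)
    E = rng.standard_normal((X.shape[0], design.q)) @ L.T
    return signal + E


def simulate_dataset(design: SimulationDesign, rng=None) -> SimulatedDataset:
    """Genotypes + coefficients + responses in one deterministic draw."""
    rng = _rng(design, rng)
    G = simulate_genotypes(design, rng)
    beta = make_coefficients(design, rng)
    Y = simulate_responses(G, beta, design, rng)
    data = MultiResponseData(
        G,
        Y,
        snp_ids=tuple(f"snp{j + 1}" for j in range(design.p)),
        trait_names=tuple(f"trait{k + 1}" for k in range(design.q)),
    )
    return SimulatedDataset(
        data=data, true_beta=beta, residual_cov=design.residual_cov, design=design
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict:
    """Write genotypes/phenotypes CSV and a truth TSV (snp_id, trait, beta)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = ds.data
    paths = {
        "genotypes": out / "genotypes.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.tsv",
    }
    gdf = pd.DataFrame(data.genotypes, index=list(data.subject_ids),
                       columns=list(data.snp_ids))
    gdf.index.name = "subject_id"
    gdf.to_csv(paths["genotypes"])
    pdf = pd.DataFrame(data.phenotypes, index=list(data.subject_ids),
                       columns=list(data.trait_names))
    pdf.index.name = "subject_id"
    pdf.to_csv(paths["phenotypes"], float_format="%.10g")
    rows = []
    nz = np.argwhere(ds.true_beta != 0)
    for j, k in nz:
        rows.append(
            {"snp_id": data.snp_ids[j], "trait": data.trait_names[k],
             "true_beta": ds.true_beta[j, k]}
        )
    pd.DataFrame(rows, columns=["snp_id", "trait", "true_beta"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
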