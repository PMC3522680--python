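"""Readers, writers and filters for genotype/phenotype tables.

Two genotype dialects are supported:

* ``csv_matrix`` — subjects × SNPs, header row of SNP ids, first column the
  subject id (comma- or tab-separated by extension);
* ``plink_raw`` — the PLINK ``.raw`` additive-coding dialect: whitespace
  delimited, six leading columns (FID IID PAT MAT SEX PHENOTYPE) followed by
  one {0,1,2,NA} column per SNP allele.

Missing genotypes are a hard error — in joint modelling, SNPs with
missingness cannot be included — unless mean imputation is requested, in
which case the column mean is rounded to the nearest of {0, 1, 2}.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .stacking import MultiResponseData

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "maf_filter",
    "minor_allele_frequency",
    "load_dataset",
    "result_table",
]

logger = logging.getLogger("mtglasso")

_MISSING_MSG = (
    "missing genotype values found: in joint modelling, SNPs with missingness "
    "cannot be included. Impute upstream or pass impute_mean=True."
)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_genotypes(path, dialect: str = "csv_matrix", impute_mean: bool = False):
    """Read a genotype matrix; returns ``(X, subject_ids, snp_ids)``.

    ``X`` is an integer (n, p) array with entries in {0, 1, 2}; identifiers
    keep file order.
    """
    path = Path(path)
    if dialect == "csv_matrix":
        df = _read_table(path)
        subject_ids = [str(i) for i in df.index]
        snp_ids = [str(c) for c in df.columns]
        vals = df.to_numpy(dtype=float)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in lead if c not in df.columns]
        if missing_cols:
            raise ValueError(
                f"{path} is not PLINK .raw: missing leading columns {missing_cols}"
            )
        subject_ids = [str(i) for i in df["IID"]]
        snp_cols = [c for c in df.columns if c not in lead]
        snp_ids = [str(c) for c in snp_cols]
        vals = df[snp_cols].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    mask = np.isnan(vals)
    if mask.any():
        if not impute_mean:
            raise ValueError(_MISSING_MSG)
        col_means = np.nanmean(vals, axis=0)
        fill = np.clip(np.rint(col_means), 0, 2)
        vals = np.where(mask, fill[None, :], vals)
        logger.info("mean-imputed %d missing genotype entries", int(mask.sum()))
    bad = ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype entry at row {subject_ids[r]!r}, SNP {snp_ids[c]!r} "
            f"is {vals[r, c]!r}, not one of 0/1/2"
        )
    return vals.astype(np.int8), subject_ids, snp_ids


def write_genotypes(path, X, subject_ids, snp_ids) -> None:
    df = pd.DataFrame(np.asarray(X), index=list(subject_ids), columns=list(snp_ids))
    df.index.name = "subject_id"
    df.to_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: subject-id column plus one column per trait."""
    df = _read_table(path)
    df.index = df.index.map(str)
    return df.astype(float)


def minor_allele_frequency(X) -> np.ndarray:
    """Per-SNP MAF under additive coding: min(f, 1−f), f = mean(x)/2."""
    f = np.asarray(X, dtype=float).mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(X, threshold: float = 0.05) -> np.ndarray:
    """Indices of SNPs with MAF >= threshold."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    return np.flatnonzero(minor_allele_frequency(X) >= threshold)


def load_dataset(
    genotype_path,
    phenotype_path,
    dialect: str = "csv_matrix",
    impute_mean: bool = False,
    maf_threshold: float | None = None,
) -> MultiResponseData:
    """Read, inner-join on subject id, optionally MAF-filter; log drops."""
    X, subj_g, snps = read_genotypes(genotype_path, dialect, impute_mean)
    pheno = read_phenotypes(phenotype_path)
    pheno = pheno.dropna()
    gdf = pd.DataFrame(X, index=subj_g, columns=snps)
    common = pheno.index.intersection(gdf.index)
    dropped = (len(subj_g) - len(common)) + (len(pheno) - len(common))
    if dropped:
        logger.info(
            "dropped %d subject records without complete genotype+phenotype",
            dropped,
        )
    gdf = gdf.loc[common]
    pheno = pheno.loc[common]
    X = gdf.to_numpy()
    if maf_threshold is not None:
        keep = maf_filter(X, maf_threshold)
        logger.info(
            "MAF filter at %.3g: kept %d of %d SNPs", maf_threshold, len(keep), X.shape[1]
        )
        X = X[:, keep]
        snps = [snps[i] for i in keep]
    else:
        snps = list(gdf.columns)
    return MultiResponseData(
        X,
        pheno.to_numpy(dtype=float),
        subject_ids=list(map(str, common)),
        snp_ids=snps,
        trait_names=list(map(str, pheno.columns)),
    )


def result_table(results, inference=None) -> pd.DataFrame:
    """Per-SNP result rows: id, MAF, selected flag, per-trait coefficients
    and (when available) the multi-split p-value."""
    stk = results.stacked
    maf = minor_allele_frequency(results.model.data.genotypes)
    tbl = {"snp_id": list(stk.snp_ids), "maf": np.round(maf, 6)}
    tbl["selected"] = results.selected.astype(int)
    params = results.params
    for k, name in enumerate(stk.trait_names):
        tbl[f"beta_{name}"] = params[:, k]
    if inference is not None:
        tbl["pvalue"] = inference.pvalues
    return pd.DataFrame(tbl)
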