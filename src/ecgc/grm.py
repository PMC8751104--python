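"""Genomic relationship matrix (VanRaden) and marker QC.

G = WW' / (2 * sum_i p_i (1 - p_i)) with W the column-centred dose matrix
and p_i allele frequencies estimated from the analysed sample. Mean
imputation of missing doses precedes the MAF filter; monomorphic columns
carry no information and are dropped before G is formed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_config import GenotypeMatrix

logger = logging.getLogger("ecgc")


def mean_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing doses by the per-SNP mean dose.

    All-missing SNPs are dropped (they cannot be imputed). Post-imputation
    doses may be non-integer.
    """
    doses = gm.doses.copy()
    all_missing = doses.columns[doses.isna().all(axis=0)]
    if len(all_missing):
        logger.warning("dropping %d all-missing SNPs", len(all_missing))
        doses = doses.drop(columns=all_missing)
    doses = doses.fillna(doses.mean(axis=0))
    return GenotypeMatrix(doses, gm.snp_map.loc[doses.columns])


def filter_maf(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly greater than maf_min."""
    if gm.doses.isna().any().any():
        raise ValueError("impute missing doses before MAF filtering")
    keep = gm.doses.columns[gm.maf > maf_min]
    if len(keep) == 0:
        raise ValueError(f"no SNPs left after MAF > {maf_min} filter")
    return GenotypeMatrix(gm.doses[keep], gm.snp_map.loc[keep])


def vanraden_grm(gm: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from imputed doses.

    Returns an n x n symmetric DataFrame indexed by variety id. Monomorphic
    columns are excluded from both numerator and denominator.
    """
    X = gm.doses.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing doses before building the GRM")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    ids = gm.doses.index
    return pd.DataFrame(G, index=ids, columns=ids)
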