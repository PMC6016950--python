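"""Parental expression quantification and evolved expression changes.

Counts are normalized with median-of-ratios size factors, converted to FPKM
(fragments per kilobase of transcript per million mapped reads), filtered at
a minimum mean expression, and summarized per population.  The evolved
expression change of a gene is the log2 ratio of its mean FPKM between the
derived and ancestral populations.  Differential expression is flagged with a
per-gene Welch t-test on log-normalized counts with Benjamini-Hochberg
control — a declared stand-in for a full count-model DE engine, recorded in
the output metadata so results are never mislabeled.  A genotype-matrix PCA
(multiallelic and missing-genotype variants removed) is included for
population-structure QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_METHOD = "welch-t on log2(normalized count + 0.5), BH FDR"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over genes positive in every sample,
    of the ratio of its count to the gene's geometric mean across samples.
    Rescaling all counts by a constant leaves normalized expression unchanged.

    Raises
    ------
    ValueError
        If fewer than two samples, or no gene is positive in all samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1, keepdims=True)
    log_sf = np.median(logx - log_geomean, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors == 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = normalized count / (length/10^3 * normalized library size/10^6).

    ``factors`` defaults to :func:`size_factors` of ``counts``.  After
    size-factor normalization every sample sits on one common library scale,
    so the per-million denominator is the mean normalized library size shared
    by all samples; dividing each sample by its own total instead would
    re-introduce the compositional bias the ratio-based factors removed (a
    population with a genuine global expression shift would see every gene's
    FPKM deflated).  The result is invariant to a global rescaling of all
    library sizes.

    Raises
    ------
    KeyError
        If a gene in ``counts`` has no transcript length, naming the gene.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no transcript length for gene {missing[0]!r}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive transcript length for gene {bad!r}")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    libsize = float(norm.sum(axis=0).mean())
    return (norm / (libsize / 1e6)).div(lengths / 1e3, axis=0)


def filter_low_expression(fpkm: pd.DataFrame, min_mean: float = 0.1) -> pd.DataFrame:
    """Drop genes whose mean FPKM across all samples is strictly below
    ``min_mean`` (a gene at exactly the threshold is retained)."""
    return fpkm.loc[fpkm.mean(axis=1) >= min_mean]


def _population_means(
    fpkm: pd.DataFrame, populations: pd.Series, pop: str
) -> pd.Series:
    cols = populations.index[populations == pop]
    if len(cols) == 0:
        raise ValueError(f"unknown population label {pop!r}")
    return fpkm[cols].mean(axis=1)


def parental_log_ratio(
    fpkm: pd.DataFrame, populations: pd.Series, pop_a: str, pop_b: str
) -> pd.Series:
    """Per-gene log2(mean FPKM in ``pop_a`` / mean FPKM in ``pop_b``).

    Genes with zero mean in either population are unquantifiable and
    returned as NaN rather than +/-inf.  Antisymmetric in its populations.
    """
    mean_a = _population_means(fpkm, populations, pop_a)
    mean_b = _population_means(fpkm, populations, pop_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(mean_a.to_numpy() / mean_b.to_numpy())
    ratio[(mean_a.to_numpy() <= 0) | (mean_b.to_numpy() <= 0)] = np.nan
    return pd.Series(ratio, index=fpkm.index, name=f"log2_{pop_a}_over_{pop_b}")


def pooled_normalized_counts(
    counts: pd.DataFrame,
    populations: pd.Series,
    pops: Sequence[str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Size-factor-normalized counts summed across each population's
    replicates and rounded to the nearest integer — the parental pseudo-counts
    the trans G-test consumes."""
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    out = {}
    for pop in pops:
        cols = populations.index[populations == pop]
        if len(cols) == 0:
            raise ValueError(f"unknown population label {pop!r}")
        out[pop] = norm[cols].sum(axis=1).round().astype(int)
    return pd.DataFrame(out, index=counts.index)


def call_differential_expression(
    counts: pd.DataFrame,
    populations: pd.Series,
    pop_a: str,
    pop_b: str,
    fdr: float = 0.10,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag genes differentially expressed between two populations.

    Welch's t-test per gene on log2(normalized count + 0.5), BH-adjusted at
    ``fdr``; direction from the sign of the mean difference (``pop_a`` minus
    ``pop_b``).  The pseudocount is internal to this stand-in test and is
    never used in cis/trans estimation.

    Returns a table with columns ``log2_fc, p, q, status`` where status is
    one of ``up`` (higher in ``pop_a``), ``down``, ``ns``.  The test identity
    is recorded in ``result.attrs['method']``.
    """
    cols_a = populations.index[populations == pop_a]
    cols_b = populations.index[populations == pop_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("differential expression needs >=2 replicates per group")
    if factors is None:
        factors = size_factors(counts)
    log_norm = np.log2(counts.div(factors, axis=1) + 0.5)
    a = log_norm[cols_a].to_numpy()
    b = log_norm[cols_b].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    status = np.where(q < fdr, np.where(diff > 0, "up", "down"), "ns")
    out = pd.DataFrame(
        {"log2_fc": diff, "p": p, "q": q, "status": status}, index=counts.index
    )
    out.attrs["method"] = DE_METHOD
    out.attrs["contrast"] = f"{pop_a} vs {pop_b}"
    out.attrs["fdr"] = fdr
    return out


@dataclass
class PCAResult:
    """Principal components of a genotype matrix."""

    coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    n_variants_used: int


def genotype_pca(
    genotypes: pd.DataFrame,
    multiallelic: Sequence[str] | None = None,
) -> PCAResult:
    """PCA of a variants x samples genotype matrix coded 0/1/2.

    Multiallelic variants (listed in ``multiallelic``) and variants with any
    missing genotype (NaN) are removed before centering.  Variance fractions
    beyond the matrix rank are reported as 0; a fully constant matrix yields
    all-zero coordinates and fractions.
    """
    if genotypes.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    keep = genotypes.dropna(axis=0)
    if multiallelic is not None:
        keep = keep.drop(index=[v for v in multiallelic if v in keep.index])
    x = keep.to_numpy(dtype=float).T  # samples x variants
    n_samples = x.shape[0]
    centered = x - x.mean(axis=0, keepdims=True)
    n_pcs = n_samples
    coords = np.zeros((n_samples, n_pcs))
    evr = np.zeros(n_pcs)
    if keep.shape[0] > 0:
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        var = s**2
        total = var.sum()
        k = min(len(s), n_pcs)
        coords[:, :k] = (u[:, :k] * s[:k])
        if total > 0:
            evr[:k] = var[:k] / total
    if keep.shape[0] == 0:
        warnings.warn("no variants left after filtering; PCA is degenerate")
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=genotypes.columns, columns=cols),
        explained_variance_ratio=evr,
        n_variants_used=int(keep.shape[0]),
    )
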