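"""Per-gene partitioning of evolved expression divergence into cis and trans.

For a gene with pooled hybrid allele counts (D derived-allele reads, A
ancestral-allele reads) and a parental expression change P (log2 of the mean
expression ratio, derived over ancestral):

* ``log2_cis  = log2(D / A)`` — the allelic imbalance in the F1 hybrid, which
  isolates cis-regulatory change because both alleles share one trans
  environment;
* ``log2_trans = P - log2_cis`` — the remainder of the parental change;
* ``percent_cis = |log2_cis| / (|log2_cis| + |log2_trans|)``.

Significance: the cis change is tested with an exact two-sided binomial test
of D against Binomial(D + A, 1/2); the trans change with a G-test comparing
the parental allele ratio with the hybrid ratio.  Both families are BH
adjusted at a 1% FDR and genes are classified as cis-only, trans-only,
concordant (both significant, same direction), discordant (both significant,
opposite directions) or conserved.

Replicates are pooled by summation before estimation and testing;
per-replicate values are for QC only.  Filters applied before any estimation:
pooled total <= ``min_reads`` (default 20) removed; zero reads on either
allele removed (infinite ratio); allelic fold change above ``max_fold``
(default 32, i.e. |log2_cis| > 5) removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("cis_only", "trans_only", "concordant", "discordant", "conserved")

#: How the trans G-test forms its expected counts.
#: ``independence``: 2x2 likelihood-ratio test of the hybrid allele counts
#: against the parental pooled counts, which propagates sampling noise in the
#: measured cis fraction.  ``fixed-cis``: the hybrid cis fraction is treated
#: as known and only the parental counts as random.
GTEST_MODES = ("independence", "fixed-cis")
DEFAULT_GTEST_MODE = "independence"


# ---------------------------------------------------------------------------
# pooling and filtering

def pool_allele_counts(allele_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-replicate hybrid allele counts per gene.

    Input is the long table (gene_id, replicate, derived_count,
    ancestral_count[, unassigned_count]); genes whose counts are missing
    (no informative variant) are dropped.  Returns a gene-indexed table with
    integer ``derived_reads`` and ``ancestral_reads``.
    """
    complete = allele_counts.dropna(subset=["derived_count", "ancestral_count"])
    pooled = (
        complete.groupby("gene_id")[["derived_count", "ancestral_count"]]
        .sum()
        .astype(int)
    )
    pooled.columns = ["derived_reads", "ancestral_reads"]
    return pooled


def pool_and_filter(
    allele_counts: pd.DataFrame,
    min_reads: int = 20,
    max_fold: float = 32.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pool replicates and apply the read-support and fold-change filters.

    Removes genes with pooled total <= ``min_reads``; genes with zero reads
    from either allele (infinite ratio); and genes whose allelic ratio
    exceeds ``max_fold`` in either direction.  Every filter that fires is
    recorded per removed gene.

    Returns
    -------
    (passed, filters): the surviving pooled table, and a Series mapping each
    removed gene to a comma-joined list of filter names
    (``low_reads``, ``zero_allele``, ``high_fold``).
    """
    pooled = pool_allele_counts(allele_counts)
    d = pooled["derived_reads"].to_numpy(dtype=float)
    a = pooled["ancestral_reads"].to_numpy(dtype=float)
    total = d + a
    low = total <= min_reads
    zero = (d == 0) | (a == 0)
    with np.errstate(divide="ignore"):
        fold = np.where(zero, np.inf, np.maximum(d, a) / np.minimum(np.maximum(d, 1e-300), np.maximum(a, 1e-300)))
    high = ~zero & (fold > max_fold)
    reasons = []
    for i in range(len(pooled)):
        fired = []
        if low[i]:
            fired.append("low_reads")
        if zero[i]:
            fired.append("zero_allele")
        if high[i]:
            fired.append("high_fold")
        reasons.append(",".join(fired))
    reasons = pd.Series(reasons, index=pooled.index, name="filters_failed")
    removed = reasons != ""
    return pooled.loc[~removed], reasons[removed]


# ---------------------------------------------------------------------------
# point estimates

def estimate_cis(pooled: pd.DataFrame) -> pd.Series:
    """log2 of pooled derived over ancestral reads.

    Genes must have passed :func:`pool_and_filter`; a zero count here is a
    contract violation, not data.
    """
    d = pooled["derived_reads"].to_numpy(dtype=float)
    a = pooled["ancestral_reads"].to_numpy(dtype=float)
    if (d <= 0).any() or (a <= 0).any():
        raise ValueError("zero allele count reached estimate_cis; filter contract violated")
    return pd.Series(np.log2(d / a), index=pooled.index, name="log2_cis")


def estimate_trans(log2_parental, log2_cis):
    """Trans change as the parental change minus the measured cis change."""
    return log2_parental - log2_cis


def percent_cis(log2_cis, log2_trans):
    """|cis| / (|cis| + |trans|); NaN when both changes are exactly zero."""
    c = np.abs(np.asarray(log2_cis, dtype=float))
    t = np.abs(np.asarray(log2_trans, dtype=float))
    denom = c + t
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, c / denom, np.nan)
    if np.isscalar(log2_cis) and np.isscalar(log2_trans):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# significance tests

def binom_pvalue_balanced(k, n):
    """Exact two-sided binomial p-value against p=1/2, vectorized.

    Two-sidedness by the minimum-likelihood rule: the p-value sums the
    probability of every outcome whose point mass does not exceed the
    observed one.  For the symmetric p=1/2 null this equals
    ``P(X <= min(k, n-k)) + P(X >= max(k, n-k))``, capped at 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    kmin = np.minimum(k, n - k)
    kmax = n - kmin
    p = stats.binom.cdf(kmin, n, 0.5) + stats.binom.sf(kmax - 1, n, 0.5)
    return np.minimum(p, 1.0)


def test_cis(pooled: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Binomial test of allelic balance per gene, BH-adjusted across genes.

    Returns columns ``p_cis`` and ``q_cis``; callers compare ``q_cis`` to the
    FDR threshold (default 1%).
    """
    d = pooled["derived_reads"].to_numpy()
    a = pooled["ancestral_reads"].to_numpy()
    p = binom_pvalue_balanced(d, d + a)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({"p_cis": p, "q_cis": q}, index=pooled.index)
    out.attrs["fdr"] = fdr
    return out


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Likelihood-ratio statistic G = 2 * sum O * ln(O / E) over the last axis.

    Zero observed cells contribute zero.  Always non-negative when row sums
    of O and E agree.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    return 2.0 * terms.sum(axis=-1)


def test_trans(
    parental_pooled: pd.DataFrame,
    cis_fraction: pd.Series | None = None,
    hybrid_pooled: pd.DataFrame | None = None,
    mode: str = DEFAULT_GTEST_MODE,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """G-test of the parental allele ratio against the hybrid cis ratio.

    A significant result means the parental expression ratio deviates from
    the ratio the measured cis change alone would produce — i.e. a trans
    change.  P-values come from the chi-square distribution with 1 df and are
    BH-adjusted across genes.

    Parameters
    ----------
    parental_pooled
        Gene-indexed table with normalized pooled parental counts in columns
        ``derived_reads`` and ``ancestral_reads``.
    cis_fraction
        Measured hybrid derived-allele fraction per gene (``fixed-cis`` mode).
    hybrid_pooled
        Pooled hybrid allele counts (``independence`` mode).
    mode
        ``independence`` (default): 2x2 likelihood-ratio test of hybrid
        against parental counts, which accounts for sampling noise in the
        measured cis fraction.  ``fixed-cis``: the cis fraction is treated as
        known and only the two parental cells as random; anti-conservative
        when hybrid depth is finite, provided for comparability.

    Returns columns ``g_trans``, ``p_trans``, ``q_trans``.
    """
    if mode not in GTEST_MODES:
        raise ValueError(f"unknown G-test mode {mode!r}")
    pd_ = parental_pooled["derived_reads"].to_numpy(dtype=float)
    pa = parental_pooled["ancestral_reads"].to_numpy(dtype=float)
    if mode == "fixed-cis":
        if cis_fraction is None:
            raise ValueError("fixed-cis mode needs the measured cis fraction")
        f = cis_fraction.reindex(parental_pooled.index).to_numpy(dtype=float)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("cis fraction outside (0, 1); filter contract violated")
        n = pd_ + pa
        observed = np.stack([pd_, pa], axis=-1)
        expected = np.stack([n * f, n * (1 - f)], axis=-1)
        g = g_statistic(observed, expected)
    else:
        if hybrid_pooled is None:
            raise ValueError("independence mode needs the pooled hybrid counts")
        hyb = hybrid_pooled.reindex(parental_pooled.index)
        hd = hyb["derived_reads"].to_numpy(dtype=float)
        ha = hyb["ancestral_reads"].to_numpy(dtype=float)
        observed = np.stack([hd, ha, pd_, pa], axis=-1)
        row_h = hd + ha
        row_p = pd_ + pa
        total = row_h + row_p
        col_d = hd + pd_
        col_a = ha + pa
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.stack(
                [
                    row_h * col_d / total,
                    row_h * col_a / total,
                    row_p * col_d / total,
                    row_p * col_a / total,
                ],
                axis=-1,
            )
        g = g_statistic(observed, expected)
        g = np.where(total > 0, g, np.nan)
    p = stats.chi2.sf(g, df=1)
    testable = np.isfinite(p)
    q = np.full_like(g, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    out = pd.DataFrame(
        {"g_trans": g, "p_trans": p, "q_trans": q}, index=parental_pooled.index
    )
    out.attrs["mode"] = mode
    out.attrs["fdr"] = fdr
    return out


def test_allelic_bias(log2_cis: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of median-zero allelic balance.

    Zeros are dropped before ranking.  Returns ``(statistic, p)``; if every
    value is zero the test is undefined and ``(nan, nan)`` is returned with a
    warning.
    """
    x = np.asarray(log2_cis, dtype=float)
    x = x[np.isfinite(x) & (x != 0.0)]
    if x.size == 0:
        warnings.warn("allelic bias test undefined: no nonzero cis estimates")
        return (float("nan"), float("nan"))
    res = stats.wilcoxon(x, zero_method="wilcox", alternative="two-sided", method="auto")
    return (float(res.statistic), float(res.pvalue))


def classify_genes(
    q_cis: pd.Series,
    q_trans: pd.Series,
    log2_cis: pd.Series,
    log2_trans: pd.Series,
    alpha: float = 0.01,
) -> pd.Series:
    """Assign each tested gene to one of the five regulatory categories.

    cis_only / trans_only when exactly one test is significant at ``alpha``
    (BH q-value); concordant / discordant when both are, by the agreement of
    the signs of the cis and trans changes; conserved when neither is.
    """
    sig_c = (q_cis < alpha).to_numpy()
    sig_t = (q_trans < alpha).to_numpy()
    same_sign = (np.sign(log2_cis.to_numpy()) * np.sign(log2_trans.to_numpy())) > 0
    cat = np.select(
        [
            sig_c & ~sig_t,
            ~sig_c & sig_t,
            sig_c & sig_t & same_sign,
            sig_c & sig_t & ~same_sign,
        ],
        ["cis_only", "trans_only", "concordant", "discordant"],
        default="conserved",
    )
    return pd.Series(
        pd.Categorical(cat, categories=list(CATEGORIES)), index=q_cis.index, name="category"
    )


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class RegulatoryResult:
    """Per-gene regulatory divergence estimates plus genome-wide summaries."""

    table: pd.DataFrame
    bias_statistic: float
    bias_p: float
    n_tested: int
    settings: dict = field(default_factory=dict)

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["category"].notna()]

    def category_counts(self) -> pd.Series:
        return self.tested["category"].value_counts().reindex(list(CATEGORIES), fill_value=0)


def estimate_regulation(
    hybrid_counts: pd.DataFrame,
    parental_log2: pd.Series,
    parental_pooled: pd.DataFrame,
    fdr: float = 0.01,
    min_reads: int = 20,
    max_fold: float = 32.0,
    gtest_mode: str = DEFAULT_GTEST_MODE,
) -> RegulatoryResult:
    """Run the full per-gene cis/trans decomposition for one cross.

    Parameters
    ----------
    hybrid_counts
        Long per-replicate hybrid allele count table (missing counts mark
        genes without an informative variant).
    parental_log2
        Per-gene parental log2 expression change (derived over ancestral)
        from :func:`regdiv.expression.parental_log_ratio`; NaN marks
        unquantifiable genes.
    parental_pooled
        Normalized pooled parental counts with columns named after the two
        populations in (derived, ancestral) order, or already renamed to
        ``derived_reads`` / ``ancestral_reads``.
    gtest_mode
        See :func:`test_trans`.

    Returns
    -------
    RegulatoryResult whose ``table`` has one row per gene appearing in
    ``hybrid_counts``, with estimates, p/q-values, category and the filters
    that removed non-tested genes.  ``log2_cis + log2_trans`` equals
    ``log2_parental`` exactly for every tested gene.
    """
    if list(parental_pooled.columns[:2]) != ["derived_reads", "ancestral_reads"]:
        parental_pooled = parental_pooled.rename(
            columns=dict(zip(parental_pooled.columns[:2], ["derived_reads", "ancestral_reads"]))
        )
    all_genes = pd.Index(hybrid_counts["gene_id"].unique(), name="gene_id")
    pooled_all = pool_allele_counts(hybrid_counts)
    passed, filters = pool_and_filter(hybrid_counts, min_reads=min_reads, max_fold=max_fold)

    table = pd.DataFrame(index=all_genes)
    table["derived_reads"] = pooled_all["derived_reads"]
    table["ancestral_reads"] = pooled_all["ancestral_reads"]
    table["filters_failed"] = ""
    table.loc[table["derived_reads"].isna(), "filters_failed"] = "no_informative_variant"
    table.loc[filters.index, "filters_failed"] = filters

    # restrict to genes that also have a quantifiable parental change
    parental = parental_log2.reindex(passed.index)
    unquant = parental.index[parental.isna()]
    if len(unquant):
        extra = table.loc[unquant, "filters_failed"].map(
            lambda s: "parental_unquantifiable" if s == "" else s + ",parental_unquantifiable"
        )
        table.loc[unquant, "filters_failed"] = extra
    tested = passed.drop(index=unquant)

    log2_cis = estimate_cis(tested)
    log2_par = parental_log2.reindex(tested.index)
    log2_trans = estimate_trans(log2_par, log2_cis)
    pct = percent_cis(log2_cis.to_numpy(), log2_trans.to_numpy())

    cis_tests = test_cis(tested, fdr=fdr)
    f_cis = tested["derived_reads"] / (tested["derived_reads"] + tested["ancestral_reads"])
    trans_tests = test_trans(
        parental_pooled.reindex(tested.index),
        cis_fraction=f_cis,
        hybrid_pooled=tested,
        mode=gtest_mode,
        fdr=fdr,
    )
    category = classify_genes(
        cis_tests["q_cis"], trans_tests["q_trans"], log2_cis, log2_trans, alpha=fdr
    )

    for col, values in [
        ("log2_cis", log2_cis),
        ("log2_parental", log2_par),
        ("log2_trans", log2_trans),
        ("percent_cis", pd.Series(pct, index=tested.index)),
        ("p_cis", cis_tests["p_cis"]),
        ("q_cis", cis_tests["q_cis"]),
        ("g_trans", trans_tests["g_trans"]),
        ("p_trans", trans_tests["p_trans"]),
        ("q_trans", trans_tests["q_trans"]),
    ]:
        table[col] = values
    table["category"] = category.reindex(table.index)

    stat, bias_p = test_allelic_bias(log2_cis)
    return RegulatoryResult(
        table=table,
        bias_statistic=stat,
        bias_p=bias_p,
        n_tested=len(tested),
        settings={
            "fdr": fdr,
            "min_reads": min_reads,
            "max_fold": max_fold,
            "gtest_mode": gtest_mode,
        },
    )


# ---------------------------------------------------------------------------
# genome-wide contingency analysis

@dataclass
class ContingencyResult:
    """2x2 binning of genes by dominant effect and direction agreement."""

    table: pd.DataFrame  # rows cis_major/trans_major, cols concordant/discordant
    row_proportions: pd.DataFrame
    binomial_p: pd.Series  # per-row exact test of discordant fraction vs 0.5
    rows_comparison_p: float  # Fisher exact test comparing the two rows


def contingency_analysis(
    table: pd.DataFrame, de_mask: pd.Series | None = None
) -> ContingencyResult:
    """Bin genes by whether cis or trans controls the majority of the change
    and whether the two changes agree in direction.

    Uses genes with a defined ``percent_cis`` and nonzero changes of both
    kinds; optionally restricted to differentially expressed genes via
    ``de_mask``.  Rows with no genes are reported as untestable (NaN p).
    """
    sub = table[table["category"].notna() & table["percent_cis"].notna()]
    sub = sub[(sub["log2_cis"] != 0) & (sub["log2_trans"] != 0)]
    if de_mask is not None:
        sub = sub[de_mask.reindex(sub.index, fill_value=False)]
    cis_major = sub["percent_cis"] > 0.5
    concordant = np.sign(sub["log2_cis"]) == np.sign(sub["log2_trans"])
    counts = pd.DataFrame(
        {
            "concordant": [
                int((cis_major & concordant).sum()),
                int((~cis_major & concordant).sum()),
            ],
            "discordant": [
                int((cis_major & ~concordant).sum()),
                int((~cis_major & ~concordant).sum()),
            ],
        },
        index=pd.Index(["cis_major", "trans_major"], name="dominant_effect"),
    )
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        props = counts.div(totals, axis=0)
    pvals = {}
    for row in counts.index:
        n = int(totals[row])
        if n == 0:
            pvals[row] = float("nan")
        else:
            pvals[row] = stats.binomtest(int(counts.loc[row, "discordant"]), n, 0.5).pvalue
    _, fisher_p = stats.fisher_exact(counts.to_numpy())
    return ContingencyResult(
        table=counts,
        row_proportions=props,
        binomial_p=pd.Series(pvals, name="binomial_p"),
        rows_comparison_p=float(fisher_p),
    )
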