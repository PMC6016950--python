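"""Gene-set expression-shift statistics and cross-population sharing.

Two questions about convergence are addressed here.  First, does a candidate
gene set (e.g. orthologs of known tooth-development genes) shift its
expression between two groups of samples more than chance?  The statistic is
a t-of-t: a per-member two-sample t-value between the groups, then a
one-sample t-test of those t-values against mean zero.  Its null calibration
is checked by bootstrap: gene sets of the same size drawn with replacement
from the expression matrix's gene universe, with the exceedance p-value
estimated by the add-one rule p = (1 + #{null >= observed}) / (1 + B), so
"larger than anything observed" reports 1/(1+B), never zero.

Second, are the expression, cis, or trans changes of two independently
derived populations shared?  Sharing is summarized by the Spearman rank
correlation of per-gene changes and by counts of genes moving in the same or
opposite directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    """A named collection of member gene identifiers (duplicates removed)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))

    def present_in(self, universe: pd.Index) -> list[str]:
        return [g for g in self.members if g in universe]


@dataclass
class ShiftTestResult:
    statistic: float  # one-sample t of the member t-values
    pvalue: float
    mean_t: float
    direction: int  # +1 set shifted up in group A, -1 down, 0 degenerate
    n_members_used: int
    n_members_dropped: int


def _member_t_values(
    values: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    members: Sequence[str],
) -> tuple[np.ndarray, int]:
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("shift test needs >=2 samples per group")
    present = [g for g in members if g in values.index]
    if len(present) < 2:
        raise ValueError("fewer than two set members found in the matrix")
    a = values.loc[present, cols_a].to_numpy(dtype=float)
    b = values.loc[present, cols_b].to_numpy(dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    n_dropped = int(degenerate.sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} member(s) with zero variance in both groups dropped")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = t[~degenerate]
    return t[np.isfinite(t)], n_dropped


def geneset_shift_test(
    values: pd.DataFrame,
    groups: pd.Series,
    gene_set: GeneSet | Sequence[str],
    group_a: str,
    group_b: str,
) -> ShiftTestResult:
    """Test whether a gene set's expression shifts between two groups.

    Per member, Welch's two-sample t between ``group_a`` and ``group_b``
    samples of ``values`` (a genes x samples matrix, typically log
    expression); then a one-sample t-test of the member t-values against
    mean zero.  Positive direction means the set is higher in ``group_a``.

    Members absent from the matrix are ignored; members with zero variance
    in both groups are dropped with a warning.  If every retained t-value is
    zero the test is degenerate and reported as p = 1.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else tuple(gene_set)
    tvals, n_dropped = _member_t_values(values, groups, group_a, group_b, members)
    if len(tvals) < 2 or np.all(tvals == 0):
        return ShiftTestResult(0.0, 1.0, 0.0, 0, len(tvals), n_dropped)
    mean_t = float(np.mean(tvals))
    if np.std(tvals, ddof=1) == 0:
        # all member t-values identical and nonzero: maximal evidence
        return ShiftTestResult(
            float(np.inf) * np.sign(mean_t), 0.0, mean_t, int(np.sign(mean_t)), len(tvals), n_dropped
        )
    res = stats.ttest_1samp(tvals, 0.0)
    return ShiftTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_t=mean_t,
        direction=int(np.sign(mean_t)),
        n_members_used=len(tvals),
        n_members_dropped=n_dropped,
    )


@dataclass
class BootstrapResult:
    null: np.ndarray
    observed: float | None
    pvalue: float | None  # add-one exceedance estimate
    B: int

    @property
    def floor(self) -> float:
        return 1.0 / (1 + self.B)


def bootstrap_null(
    values: pd.DataFrame,
    set_size: int,
    B: int,
    statistic_fn: Callable[[Sequence[str]], float],
    rng: np.random.Generator,
    observed: float | None = None,
) -> BootstrapResult:
    """Null distribution of a gene-set statistic under random membership.

    Draws ``B`` gene sets of ``set_size`` with replacement from the matrix's
    gene universe and evaluates ``statistic_fn`` on each.  If ``observed`` is
    given, the one-sided exceedance p-value is estimated with the add-one
    rule ``(1 + #{null >= observed}) / (1 + B)``, which is bounded below by
    ``1/(1+B)`` and monotone non-increasing in the observed statistic.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    universe = values.index.to_numpy()
    null = np.empty(B)
    for i in range(B):
        members = rng.choice(universe, size=set_size, replace=True)
        null[i] = statistic_fn(list(members))
    p = None
    if observed is not None:
        p = (1 + int(np.sum(null >= observed))) / (1 + B)
    return BootstrapResult(null=null, observed=observed, pvalue=p, B=B)


def change_correlation(changes_a: pd.Series, changes_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of per-gene changes between two populations.

    Restricted to genes finite in both inputs (ties mid-ranked); raises if
    fewer than three genes remain.  Invariant to strictly monotone
    transforms of either input.
    """
    joined = pd.concat([changes_a, changes_b], axis=1, join="inner").dropna()
    joined = joined[np.isfinite(joined).all(axis=1)]
    if len(joined) < 3:
        raise ValueError("need at least three paired finite values")
    r, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r), float(p)


@dataclass
class SharingSummary:
    """Direction sharing of per-gene changes across two populations."""

    n_compared: int
    shared_up: int
    shared_down: int
    opposed: int

    @property
    def n_shared(self) -> int:
        return self.shared_up + self.shared_down

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_compared if self.n_compared else float("nan")


def direction_sharing(
    changes_a: pd.Series,
    changes_b: pd.Series,
    significant_a: pd.Series | None = None,
    significant_b: pd.Series | None = None,
) -> SharingSummary:
    """Count genes whose changes agree or oppose in sign across populations.

    When significance flags are supplied the comparison is restricted to
    genes flagged in *both* populations; otherwise all genes are compared.
    Genes with a zero or missing change in either population are excluded,
    so ``shared_up + shared_down + opposed == n_compared``.
    """
    joined = pd.concat(
        [changes_a.rename("a"), changes_b.rename("b")], axis=1, join="inner"
    ).dropna()
    if significant_a is not None:
        joined = joined[significant_a.reindex(joined.index, fill_value=False)]
    if significant_b is not None:
        joined = joined[significant_b.reindex(joined.index, fill_value=False)]
    joined = joined[(joined["a"] != 0) & (joined["b"] != 0)]
    sa = np.sign(joined["a"].to_numpy())
    sb = np.sign(joined["b"].to_numpy())
    shared_up = int(((sa > 0) & (sb > 0)).sum())
    shared_down = int(((sa < 0) & (sb < 0)).sum())
    opposed = int((sa * sb < 0).sum())
    return SharingSummary(
        n_compared=len(joined),
        shared_up=shared_up,
        shared_down=shared_down,
        opposed=opposed,
    )


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:50]!r}")
            sets.append(GeneSet(name=parts[0], description=parts[1], members=tuple(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")
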