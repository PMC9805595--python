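"""Pathway-level statistics on correlation tables.

Tests whether a target gene's significant correlates that belong to a
focal pathway have systematically stronger correlations than its
significant correlates annotated to other pathways.  Correlation
coefficients are Fisher z-transformed (arctanh) before comparison, which
approximately normalises their sampling distribution; the group contrast
is a Welch two-sample t-test, with Shapiro-Wilk normality and F-test
variance-homogeneity checks reported as diagnostics alongside (they do
not gate the test).  Also provides pathway coverage (fraction of a
pathway's dataset-present genes recovered as significant) and
significant-correlation counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from codep.io import GeneSetCollection

logger = logging.getLogger("codep.pathway")

DEFAULT_Q_THRESH = 0.05


def fisher_z(r):
    """Fisher z-transformation arctanh(r) = 0.5 * ln((1+r)/(1-r)).

    Defined for |r| < 1; scalar or array input.  Raises ``ValueError``
    when any |r| >= 1 (the transform diverges there).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[~np.isnan(arr)]) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def welch_t(a, b):
    """Welch two-sample unpaired t-test.

    Returns ``(t_stat, df, p)`` with the Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.  Groups must have at least two
    observations each and nonzero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"welch_t needs >= 2 observations per group, got {len(a)}, {len(b)}"
        )
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("welch_t undefined: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _shapiro_or_nan(x: np.ndarray):
    if len(x) < 3 or np.ptp(x) == 0.0:
        return (math.nan, math.nan)
    w, p = stats.shapiro(x)
    return (float(w), float(p))


def _f_var_test(a: np.ndarray, b: np.ndarray):
    """Two-sided F-test for the ratio of two sample variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 or vb == 0.0:
        return (math.nan, math.nan)
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return (float(f), float(min(p, 1.0)))


@dataclass(frozen=True)
class PathwayTestResult:
    """Within-pathway vs other-pathway contrast for one target gene.

    ``testable`` is False when either group has fewer than two members or
    both are constant, in which case the t-test fields are NaN.
    """

    target: str
    pathway_id: str
    n_in: int
    n_out: int
    mean_z_in: float
    mean_z_out: float
    t_stat: float
    df: float
    p: float
    shapiro_in: tuple
    shapiro_out: tuple
    f_var: tuple
    testable: bool


def _significant_records(table: pd.DataFrame, target: str,
                         q_thresh: float) -> pd.DataFrame:
    sub = table[table["target"] == target]
    if sub.empty:
        raise KeyError(f"target {target!r} not present in correlation table")
    sub = sub[(sub["gene"] != sub["target"]) & sub["q"].notna()
              & (sub["q"] < q_thresh) & sub["r"].notna()]
    return sub


def pathway_z_test(
    table: pd.DataFrame,
    target: str,
    pathways: GeneSetCollection,
    focal: str,
    q_thresh: float = DEFAULT_Q_THRESH,
) -> PathwayTestResult:
    """Welch t-test of Fisher-z values: focal-pathway vs other-pathway genes.

    From the target's significant correlates (``q < q_thresh``, self
    excluded), group IN holds the Fisher-z of genes annotated to the
    focal set and group OUT the Fisher-z of genes annotated to at least
    one other set but not the focal one — an exclusive partition; genes
    in no set are ignored.  Records with |r| = 1 (untransformable) are
    dropped with a warning.
    """
    if focal not in pathways:
        raise KeyError(f"focal set {focal!r} not in collection")
    sub = _significant_records(table, target, q_thresh)
    extreme = sub["r"].abs() >= 1.0
    if extreme.any():
        logger.warning(
            "dropping %d record(s) with |r| = 1 from z-test for %s",
            int(extreme.sum()), target,
        )
        sub = sub[~extreme]

    membership = pathways.membership()
    focal_members = pathways[focal].members
    z_in, z_out = [], []
    for gene, r in zip(sub["gene"], sub["r"]):
        annotated = membership.get(gene)
        if not annotated:
            continue
        if gene in focal_members:
            z_in.append(math.atanh(r))
        else:
            z_out.append(math.atanh(r))
    a = np.asarray(z_in)
    b = np.asarray(z_out)

    n_in, n_out = len(a), len(b)
    mean_in = float(a.mean()) if n_in else math.nan
    mean_out = float(b.mean()) if n_out else math.nan
    testable = (
        n_in >= 2 and n_out >= 2
        and not (np.ptp(a) == 0.0 and np.ptp(b) == 0.0)
    )
    if testable:
        t_stat, df, p = welch_t(a, b)
        sh_in, sh_out = _shapiro_or_nan(a), _shapiro_or_nan(b)
        f_var = _f_var_test(a, b)
    else:
        t_stat = df = p = math.nan
        sh_in = sh_out = f_var = (math.nan, math.nan)
    return PathwayTestResult(
        target=target,
        pathway_id=focal,
        n_in=n_in,
        n_out=n_out,
        mean_z_in=mean_in,
        mean_z_out=mean_out,
        t_stat=t_stat,
        df=df,
        p=p,
        shapiro_in=sh_in,
        shapiro_out=sh_out,
        f_var=f_var,
        testable=testable,
    )


@dataclass(frozen=True)
class CoverageResult:
    """How much of a pathway the screen recovered as significant."""

    pathway_id: str
    covered: int
    present: int

    @property
    def coverage(self) -> float:
        return self.covered / self.present


def pathway_coverage(
    table: pd.DataFrame,
    pathway_members,
    dataset_genes,
    q_thresh: float = DEFAULT_Q_THRESH,
    pathway_id: str = "",
) -> CoverageResult:
    """Fraction of a pathway's dataset-present genes significant for >= 1 target.

    ``present`` counts pathway members that occur in ``dataset_genes``;
    ``covered`` counts those significant (``q < q_thresh``) for at least
    one target, self-correlations excluded.
    """
    members = set(pathway_members)
    present_genes = members & set(dataset_genes)
    if not present_genes:
        raise ValueError(
            f"pathway {pathway_id or '<unnamed>'} has no genes in the dataset"
        )
    sig = table[
        (table["gene"] != table["target"]) & table["q"].notna()
        & (table["q"] < q_thresh)
    ]
    covered_genes = present_genes & set(sig["gene"])
    return CoverageResult(
        pathway_id=pathway_id,
        covered=len(covered_genes),
        present=len(present_genes),
    )


def count_significant(
    table: pd.DataFrame,
    group_by: str = "target",
    q_thresh: float = DEFAULT_Q_THRESH,
    pathways: GeneSetCollection | None = None,
) -> pd.Series:
    """Count significant non-self records per group, ranked descending.

    ``group_by`` may be ``"target"``, ``"pathway"`` (requires a gene-set
    collection; a record counts once for every set annotating its gene),
    or the name of any extra column carried by the table (e.g. a lineage
    tag attached to per-lineage runs).  Ties are broken by label so the
    ranking is deterministic.
    """
    sig = table[
        (table["gene"] != table["target"]) & table["q"].notna()
        & (table["q"] < q_thresh)
    ]
    if group_by == "pathway":
        if pathways is None:
            raise ValueError("group_by='pathway' requires a gene-set collection")
        membership = pathways.membership()
        counts: dict[str, int] = {}
        for gene in sig["gene"]:
            for sid in membership.get(gene, ()):
                counts[sid] = counts.get(sid, 0) + 1
        series = pd.Series(counts, dtype=int)
    elif group_by in table.columns:
        series = sig.groupby(group_by, sort=False).size()
    else:
        raise KeyError(
            f"unknown grouping key {group_by!r}; use 'target', 'pathway' or "
            "a table column"
        )
    series.index = series.index.astype(str)
    series = series.sort_index(kind="stable")
    series = series.sort_values(ascending=False, kind="stable")
    series.name = "n_significant"
    return series.astype(int)
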