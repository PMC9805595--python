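"""Pairwise-complete Pearson correlation of dependency profiles.

The central computation: correlate the dependency profile of one or more
target genes against every other gene across cell lines, using only the
cell lines where both profiles are observed, attach two-sided p-values
from the t distribution, and control the false discovery rate with a
Benjamini-Hochberg adjustment per target family.  Results are emitted as
long-format tables (columns ``target, gene, r, p, q, n``) that all
downstream stages consume.

Self-correlations are computed and kept in the table (identifiable by
``target == gene``) but are excluded from the multiple-testing family; the
downstream network and counting stages drop them.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from concurrent.futures import ThreadPoolExecutor

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from codep.io import CORR_COLUMNS

logger = logging.getLogger("codep.correlate")

#: minimum pairwise-complete observations for a defined correlation;
#: operationalises the "more than four cell lines without missing values"
#: floor used for lineage-restricted runs
DEFAULT_MIN_N = 5

_ADJUST_ALIASES = {
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "by": "fdr_by",
    "fdr_by": "fdr_by",
    "none": "none",
}


# ---------------------------------------------------------------------------
# row filtering
# ---------------------------------------------------------------------------

def filter_rows(
    data: pd.DataFrame,
    meta: pd.DataFrame,
    constraints: Mapping[str, Sequence] | None,
) -> pd.DataFrame:
    """Restrict a dependency matrix to samples matching metadata constraints.

    ``constraints`` maps metadata column names to the values allowed in
    that column.  A sample is kept when, for *every* constrained column,
    its value is in the allowed set (conjunction over columns, disjunction
    within a column).  Samples absent from the metadata cannot satisfy a
    constraint and are dropped.  An empty/None constraint set is the
    identity.

    Raises ``KeyError`` for a constraint on a column the metadata lacks.
    An empty result is returned as a valid 0-row matrix with a warning.
    """
    if not constraints:
        return data.copy()
    for col in constraints:
        if col not in meta.columns:
            raise KeyError(
                f"unknown metadata column {col!r}; available: "
                f"{list(meta.columns)}"
            )
    keep = pd.Series(True, index=data.index)
    in_meta = data.index.isin(meta.index)
    keep &= in_meta
    common = data.index[in_meta]
    for col, allowed in constraints.items():
        ok = meta.loc[common, col].isin(set(allowed))
        keep &= ok.reindex(data.index, fill_value=False)
    out = data.loc[keep]
    if out.shape[0] == 0:
        logger.warning(
            "row filter %s matched no samples (of %d)", dict(constraints),
            data.shape[0],
        )
    return out.copy()


# ---------------------------------------------------------------------------
# Pearson correlation with p-value, pairwise-complete
# ---------------------------------------------------------------------------

def pearson_with_p(x, y, min_n: int = DEFAULT_MIN_N):
    """Pearson r, two-sided p and pairwise-complete n for two profiles.

    Only indices where both ``x`` and ``y`` are observed enter the
    computation (``n`` counts them).  If ``n < min_n`` or either profile
    is constant on the complete pairs, ``r`` and ``p`` are returned as
    ``NaN``.  The p-value is the two-sided tail of
    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` degrees of
    freedom; a perfect correlation yields ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"profiles must be 1-D of equal length, got {x.shape} vs {y.shape}"
        )
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < min_n:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if xs.max() == xs.min() or ys.max() == ys.min():
        return np.nan, np.nan, n
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    r = float(dx @ dy / np.sqrt((dx @ dx) * (dy @ dy)))
    r = min(1.0, max(-1.0, r))
    return r, _p_from_r(np.array([r]), np.array([n]))[0], n


def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r on n-2 df; |r| = 1 maps to p = 0."""
    p = np.full(r.shape, np.nan)
    perfect = np.abs(r) >= 1.0
    p[perfect & (n >= 2)] = 0.0
    reg = ~perfect & ~np.isnan(r) & (n >= 3)
    if reg.any():
        rr = r[reg]
        df = n[reg] - 2
        t = rr * np.sqrt(df / (1.0 - rr * rr))
        p[reg] = 2.0 * stats.t.sf(np.abs(t), df)
    return p


def _target_block(values, valid, t_idx, sel_idx, min_n):
    """Vectorised pairwise-complete correlation of one column vs many.

    ``values`` is the matrix with NaNs replaced by 0; ``valid`` the
    observed-entry mask.  Returns (r, p, n) arrays over ``sel_idx``.
    """
    t = values[:, t_idx]
    tv = valid[:, t_idx]
    Y = values[:, sel_idx]
    V = valid[:, sel_idx] & tv[:, None]
    n = V.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(n > 0, (t[:, None] * V).sum(axis=0) / n, 0.0)
        my = np.where(n > 0, np.where(V, Y, 0.0).sum(axis=0) / n, 0.0)
        dx = np.where(V, t[:, None] - mx, 0.0)
        dy = np.where(V, Y - my, 0.0)
        sxy = (dx * dy).sum(axis=0)
        sxx = (dx * dx).sum(axis=0)
        syy = (dy * dy).sum(axis=0)
        r = sxy / np.sqrt(sxx * syy)
    # constant-on-complete-pairs detection is exact (max == min), not an
    # epsilon test on the centred sums
    neg_inf = np.float64(-np.inf)
    pos_inf = np.float64(np.inf)
    tmax = np.where(V, t[:, None], neg_inf).max(axis=0)
    tmin = np.where(V, t[:, None], pos_inf).min(axis=0)
    ymax = np.where(V, Y, neg_inf).max(axis=0)
    ymin = np.where(V, Y, pos_inf).min(axis=0)
    zero_var = (tmax == tmin) | (ymax == ymin)
    bad = (n < min_n) | zero_var
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    p = _p_from_r(r, n)
    return r, p, n


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing entries pass through.

    The family size ``m`` is the number of non-missing p-values.  Each
    q is ``min_{j>=i} p_(j) * m / j`` along the sorted order, capped at 1,
    mapped back to the input positions; ``NaN`` in gives ``NaN`` out.
    """
    return adjust_pvalues(p_values, method="BH")


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Adjust p-values for multiple testing (default Benjamini-Hochberg).

    ``method`` accepts BH (aliases fdr_bh, benjamini-hochberg), holm,
    bonferroni, BY or ``none``; missing entries are preserved and the
    family consists of the non-missing entries only.
    """
    key = method.strip().lower()
    if key not in _ADJUST_ALIASES:
        raise ValueError(
            f"unknown adjustment method {method!r}; "
            f"choose from {sorted(set(_ADJUST_ALIASES))}"
        )
    p = np.asarray(p_values, dtype=float).copy()
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.sum() == 0:
        return out
    if _ADJUST_ALIASES[key] == "none":
        out[valid] = p[valid]
        return out
    out[valid] = multipletests(p[valid], method=_ADJUST_ALIASES[key])[1]
    return out


# ---------------------------------------------------------------------------
# long-format correlation tables
# ---------------------------------------------------------------------------

def _sorted_records(df: pd.DataFrame, by_target: bool = False) -> pd.DataFrame:
    """Deterministic order: ascending q (missing last), descending |r|,
    then target/gene labels."""
    key = pd.DataFrame(
        {
            "_q": df["q"].fillna(np.inf),
            "_nar": (-df["r"].abs()).fillna(np.inf),
            "_t": df["target"],
            "_g": df["gene"],
        }
    )
    cols = ["_q", "_nar", "_t", "_g"] if by_target else ["_q", "_nar", "_g"]
    order = key.sort_values(cols, kind="stable").index
    return df.loc[order].reset_index(drop=True)


def _validate_columns(data: pd.DataFrame, names, what: str) -> list:
    names = list(names)
    missing = [g for g in names if g not in data.columns]
    if missing:
        preview = ", ".join(map(str, missing[:10]))
        raise KeyError(f"{what} not in dataset columns: {preview}")
    return names


def cor_targets(
    data: pd.DataFrame,
    target: str,
    select: Sequence | None = None,
    min_n: int = DEFAULT_MIN_N,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Correlate one target gene against a selection of genes.

    Emits one record per selected gene (self-correlation included with
    ``r = 1`` but excluded from the multiple-testing family, so its ``q``
    is missing).  q-values are adjusted over this target's non-missing
    p-values — one family per target.  Records are sorted by ascending q,
    ties broken by descending ``|r|`` then gene symbol.
    """
    _validate_columns(data, [target], "target")
    sel = (
        list(data.columns)
        if select is None
        else _validate_columns(data, select, "selected genes")
    )
    raw = data.to_numpy(dtype=float)
    valid = ~np.isnan(raw)
    values = np.where(valid, raw, 0.0)
    col_pos = {g: i for i, g in enumerate(data.columns)}
    sel_idx = np.array([col_pos[g] for g in sel], dtype=int)
    r, p, n = _target_block(values, valid, col_pos[target], sel_idx, min_n)

    is_self = np.array([g == target for g in sel])
    fam = ~is_self & ~np.isnan(p)
    q = np.full(len(sel), np.nan)
    q[fam] = adjust_pvalues(p[fam], method=adjust)

    table = pd.DataFrame(
        {
            "target": target,
            "gene": sel,
            "r": r,
            "p": p,
            "q": q,
            "n": n.astype(int),
        }
    )
    table = _sorted_records(table)
    table.attrs["family"] = (
        f"per-target {adjust} over m={int(fam.sum())} non-self tests"
    )
    return table


def run_chunked(
    data: pd.DataFrame,
    targets: Sequence,
    select: Sequence | None = None,
    min_n: int = DEFAULT_MIN_N,
    adjust: str = "BH",
    chunk_size: int | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Target-wise correlation over a task list, optionally in parallel.

    Targets are split into chunks that run on a thread pool; results are
    reduced in task order, so the output is record-identical to the
    sequential run regardless of ``chunk_size`` and ``workers``.  Any
    worker failure propagates and fails the whole run.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if chunk_size is not None and chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    targets = _validate_columns(data, targets, "targets")
    if not targets:
        empty = pd.DataFrame(
            {c: pd.Series(dtype=(str if c in ("target", "gene") else float))
             for c in CORR_COLUMNS}
        )
        empty["n"] = empty["n"].astype(int)
        empty.attrs["family"] = f"per-target {adjust}"
        return empty

    if chunk_size is None:
        chunk_size = max(1, -(-len(targets) // max(workers, 1)))
    chunks = [
        targets[i:i + chunk_size] for i in range(0, len(targets), chunk_size)
    ]

    def _run_chunk(chunk):
        return [cor_targets(data, t, select, min_n, adjust) for t in chunk]

    if workers == 1 or len(chunks) == 1:
        parts = [tab for chunk in chunks for tab in _run_chunk(chunk)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            done = list(pool.map(_run_chunk, chunks))
        parts = [tab for chunk_out in done for tab in chunk_out]

    out = pd.concat(parts, ignore_index=True)
    out.attrs["family"] = f"per-target {adjust}, {len(targets)} families"
    return out


def cor_target_map(
    data: pd.DataFrame,
    targets: Sequence,
    select: Sequence | None = None,
    min_n: int = DEFAULT_MIN_N,
    adjust: str = "BH",
    workers: int = 1,
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Non-symmetric correlation map: each target against the selection.

    Concatenates per-target tables (independent multiple-testing family
    per target) with targets in input order; every target must exist
    before any computation starts.
    """
    return run_chunked(
        data, targets, select, min_n, adjust,
        chunk_size=chunk_size, workers=workers,
    )


def cor_map(
    data: pd.DataFrame,
    select: Sequence | None = None,
    min_n: int = DEFAULT_MIN_N,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Symmetric all-vs-all correlation map over the selected genes.

    All ordered pairs (both directions plus self-pairs) are emitted; the
    multiple-testing family is the set of unique unordered non-self pairs
    with a defined p, and each pair's q is shared by both directions.
    """
    sel = (
        list(data.columns)
        if select is None
        else _validate_columns(data, select, "selected genes")
    )
    k = len(sel)
    raw = data[sel].to_numpy(dtype=float)
    valid = ~np.isnan(raw)
    values = np.where(valid, raw, 0.0)

    R = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    N = np.zeros((k, k), dtype=int)
    for i in range(k):
        idx = np.arange(i, k)
        r, p, n = _target_block(values, valid, i, idx, min_n)
        R[i, idx] = r
        P[i, idx] = p
        N[i, idx] = n
        R[idx, i] = r
        P[idx, i] = p
        N[idx, i] = n

    iu, ju = np.triu_indices(k, k=1)
    pairs_p = P[iu, ju]
    q_flat = adjust_pvalues(pairs_p, method=adjust)
    Q = np.full((k, k), np.nan)
    Q[iu, ju] = q_flat
    Q[ju, iu] = q_flat

    ti, gi = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    sel_arr = np.array(sel, dtype=object)
    table = pd.DataFrame(
        {
            "target": sel_arr[ti.ravel()],
            "gene": sel_arr[gi.ravel()],
            "r": R.ravel(),
            "p": P.ravel(),
            "q": Q.ravel(),
            "n": N.ravel(),
        }
    )
    table = _sorted_records(table, by_target=True)
    m = int((~np.isnan(pairs_p)).sum())
    table.attrs["family"] = (
        f"global {adjust} over m={m} unique unordered non-self pairs"
    )
    return table
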