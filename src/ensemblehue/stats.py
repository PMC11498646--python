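"""Condition-level comparisons and correlation analyses on fit tables.

Operates on a "fit table" — one row per observer x condition with the PMF
bias and threshold measures (and, when available, the two category
boundaries nearest the target).  Provides the paired t-tests between
conditions, Bonferroni correction, and within-condition Pearson
correlations across observers.  Linear mixed models are deliberately out
of scope; :func:`to_long_format` exports the table for external LMM
software.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool  # zero-variance differences: p collapses to 0 or 1


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired-sample t-test; pairs must be matched by observer.

    With zero-variance differences the statistic degenerates (t = 0, p = 1
    for identical columns; |t| = inf, p = 0 for a constant nonzero
    difference); such results are flagged rather than raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, degenerate=True)
        t = math.inf if mean > 0 else -math.inf
        return PairedTResult(t=t, df=df, p=0.0, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(_sstats.t.sf(abs(t), df))
    return PairedTResult(t=t, df=df, p=min(p, 1.0), degenerate=False)


def bonferroni(pvals, m: int | None = None):
    """Bonferroni adjustment: ``min(1, m * p)`` elementwise.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must cover all tests")
    out = np.minimum(1.0, m * p)
    if np.ndim(pvals) == 0:
        return float(out[0])
    return out


def pairwise_condition_tests(fit_table: pd.DataFrame, measure: str,
                             family_size: int | None = None) -> pd.DataFrame:
    """Paired t-tests between all condition pairs on one measure.

    Pairs are matched by ``observer_id``; observers missing either
    condition drop out of that comparison.  Raw and Bonferroni-corrected
    p-values are reported (family = all pairs tested here unless
    ``family_size`` is given).
    """
    wide = fit_table.pivot(index="observer_id", columns="condition",
                           values=measure)
    conditions = list(wide.columns)
    rows = []
    for ca, cb in itertools.combinations(conditions, 2):
        sub = wide[[ca, cb]].dropna()
        if len(sub) < 3:
            continue
        res = paired_t(sub[ca], sub[cb])
        rows.append({"measure": measure, "condition_a": ca,
                     "condition_b": cb, "n_pairs": len(sub), "t": res.t,
                     "df": res.df, "p": res.p, "degenerate": res.degenerate})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p"].to_numpy(),
                                         family_size or len(out))
    return out


def correlate(fit_table: pd.DataFrame,
              measures=("bias_deg", "sigma_deg", "boundary_low",
                        "boundary_high"),
              family_size: int | None = None) -> pd.DataFrame:
    """Pearson correlations across observers, within each condition, for
    every pair of measures.

    Zero-variance columns yield an undefined (nan) r with a flag instead
    of an error.  p-values come from the t transform of r and are
    Bonferroni-corrected over the whole family of correlations computed
    here (or ``family_size`` if given).
    """
    measures = [m for m in measures if m in fit_table.columns]
    rows = []
    for condition, sub in fit_table.groupby("condition"):
        for ma, mb in itertools.combinations(measures, 2):
            pair = sub[[ma, mb]].dropna()
            n = len(pair)
            if n < 3:
                continue
            x = pair[ma].to_numpy(float)
            y = pair[mb].to_numpy(float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                rows.append({"condition": condition, "measure_a": ma,
                             "measure_b": mb, "n": n, "r": math.nan,
                             "p": math.nan, "degenerate": True})
                continue
            r, p = _sstats.pearsonr(x, y)
            rows.append({"condition": condition, "measure_a": ma,
                         "measure_b": mb, "n": n, "r": float(r),
                         "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows)
    if len(out):
        ok = ~out["degenerate"]
        adj = np.full(len(out), math.nan)
        if ok.any():
            adj[ok.to_numpy()] = bonferroni(
                out.loc[ok, "p"].to_numpy(),
                family_size or int(ok.sum()))
        out["p_bonferroni"] = adj
    return out


def to_long_format(fit_table: pd.DataFrame,
                   measures=("bias_deg", "sigma_deg")) -> pd.DataFrame:
    """Long-format export (observer, group, condition, measure, value) for
    external mixed-model software."""
    measures = [m for m in measures if m in fit_table.columns]
    return fit_table.melt(
        id_vars=[c for c in ("observer_id", "group", "condition")
                 if c in fit_table.columns],
        value_vars=measures, var_name="measure", value_name="value")


def plot_measure(fit_table: pd.DataFrame, measure: str, ax=None,
                 condition_order=None):
    """Per-observer dots with connecting lines across conditions, plus the
    group mean +/- 1 SEM — the conventional condition-by-observer figure.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    wide = fit_table.pivot(index="observer_id", columns="condition",
                           values=measure)
    if condition_order is not None:
        wide = wide[[c for c in condition_order if c in wide.columns]]
    xs = np.arange(len(wide.columns))
    for _, row in wide.iterrows():
        ax.plot(xs, row.to_numpy(float), "o-", color="0.6", alpha=0.6,
                markersize=4)
    mean = wide.mean(axis=0).to_numpy(float)
    sem = wide.std(axis=0, ddof=1).to_numpy(float) / math.sqrt(len(wide))
    ax.errorbar(xs, mean, yerr=sem, fmt="ko-", capsize=4, linewidth=2)
    ax.set_xticks(xs, wide.columns)
    ax.set_ylabel(measure)
    return ax
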