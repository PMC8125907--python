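"""Synthetic-lethality screen: drugs preferentially killing high-score lines.

Cell lines are split by the upper quartile of their deficient-NER score and
each drug's response (AUC; lower = more sensitive) is compared between the
two groups. The per-drug statistic is a reconstruction: Welch's t-test with a
signed mean-difference effect and Benjamini-Hochberg FDR, with a negative
effect (lower AUC in the deficient-high group) marking a predicted
vulnerability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NersigError
from .cohorteval import _scores_array

__all__ = ["quartile_stratify", "differential_sensitivity", "bh_fdr"]


def quartile_stratify(scores, upper_frac: float = 0.25) -> pd.Series | np.ndarray:
    """Label lines in the upper quartile of scores as NER-deficient.

    The cut is the linear-interpolation (type-7) 75th percentile; lines at or
    above the cut are labeled deficient. With all scores identical the cut
    equals every score, so all lines are labeled and a degeneracy warning is
    raised.
    """
    s, idx = _scores_array(scores)
    if s.size < 4:
        raise NersigError("quartile stratification needs >= 4 lines")
    if not 0 < upper_frac < 1:
        raise NersigError("upper_frac must be in (0, 1)")
    cut = np.quantile(s, 1.0 - upper_frac)
    labels = s >= cut
    if labels.all():
        warnings.warn("all scores at or above the quartile cut; stratification degenerate", UserWarning)
    if idx is not None:
        return pd.Series(labels, index=idx, name="dner_high")
    return labels


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise NersigError("p-value vector must be one-dimensional and non-empty")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise NersigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_sensitivity(
    resp: pd.DataFrame,
    labels,
    min_n: int = 3,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Per-drug differential response between deficient-high and other lines.

    Parameters
    ----------
    resp
        Cell line x drug response matrix (AUC-like, lower = more sensitive);
        NaN marks missing measurements.
    labels
        Boolean per-line labels (True = deficient-high), aligned to the rows.
    min_n
        Minimum measured lines per group per drug; drugs below it are kept in
        the output with ``tested=False`` rather than silently dropped.

    Returns
    -------
    DataFrame indexed by drug with columns ``effect`` (mean AUC difference,
    deficient minus others; negative = preferential killing), ``p``, ``q``
    (BH across tested drugs), ``n_dner``, ``n_other``, ``tested``, ``hit``.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(resp.index)
        if labels.isna().any():
            missing = list(resp.index[labels.isna()])
            raise NersigError(f"labels missing for lines: {missing[:5]}")
    y = np.asarray(labels).astype(bool)
    if y.size != resp.shape[0]:
        raise NersigError("labels length does not match number of lines")

    rows = []
    for drug in resp.columns:
        col = resp[drug]
        a = col[y].dropna().to_numpy(dtype=float)
        b = col[~y].dropna().to_numpy(dtype=float)
        tested = a.size >= min_n and b.size >= min_n
        if tested:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            effect = float(a.mean() - b.mean())
        else:
            p, effect = np.nan, np.nan
        rows.append((drug, effect, p, a.size, b.size, tested))
    out = pd.DataFrame(
        rows, columns=["drug", "effect", "p", "n_dner", "n_other", "tested"]
    ).set_index("drug")

    if not out["tested"].any():
        warnings.warn("no drug has enough measured lines in both groups", UserWarning)
        out["q"] = np.nan
        out["hit"] = False
        return out
    q = pd.Series(np.nan, index=out.index)
    q[out["tested"]] = bh_fdr(out.loc[out["tested"], "p"].to_numpy())
    out["q"] = q
    out["hit"] = out["tested"] & (out["effect"] < 0) & (out["q"] < fdr_thresh)
    return out
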