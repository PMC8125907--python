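"""Per-line differential expression versus control.

Each knockdown line is compared with the control group by Welch's two-sample
t-test on log2 expression, and false discovery rates are assigned by the
Storey q-value procedure (pi0 estimated from the p-value distribution).
Genes are then filtered at an absolute linear fold change > 1.5 and q < 0.05,
the thresholds used to define the consensus deficient-NER signature.

Fold-change convention: ``fold_change`` is the signed linear fold change,
``2**log2fc`` for up-regulation and ``-2**(-log2fc)`` for down-regulation,
so -2 means halving. Thresholds apply to its absolute value with strict
inequality: |FC| > 1.5 is equivalent to |log2FC| > log2(1.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import ExpressionMatrix, GroupDesign, NersigError

__all__ = [
    "log_transform",
    "welch_de",
    "moderated_de",
    "de_table",
    "storey_qvalue",
    "de_pass_filter",
    "signed_linear_fc",
]


def log_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a log2(x + pseudocount) copy of a linear-scale matrix.

    A matrix already flagged log-scale is returned unchanged with a warning
    (idempotence). Negative values on the linear scale are an error.
    """
    if pseudocount <= 0:
        raise NersigError("pseudocount must be > 0")
    if mat.log_scale:
        warnings.warn("matrix already log-scale; log_transform is a no-op", UserWarning)
        return ExpressionMatrix(mat.data.copy(), log_scale=True, provenance=dict(mat.provenance))
    values = mat.data.to_numpy(dtype=float)
    if np.any(values < 0):
        raise NersigError("negative values in linear-scale matrix; cannot log-transform")
    out = pd.DataFrame(
        np.log2(values + pseudocount), index=mat.data.index, columns=mat.data.columns
    )
    prov = dict(mat.provenance)
    prov["log_transform"] = {"pseudocount": pseudocount}
    return ExpressionMatrix(out, log_scale=True, provenance=prov)


def signed_linear_fc(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2**lfc if lfc >= 0 else -2**(-lfc)."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, np.exp2(log2fc), -np.exp2(-log2fc))


def welch_de(
    mat: ExpressionMatrix, design: GroupDesign, case_group: str
) -> pd.DataFrame:
    """Welch two-sample t-test per gene: one case group versus control.

    Returns a DataFrame indexed by gene with columns ``comparison``,
    ``log2fc``, ``fold_change``, ``p_value``, ``q_value``, ``mean_ctrl``,
    ``mean_case``. log2FC = mean(case) - mean(control) on log2 values.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means are equal and p = 0 otherwise, the limit of the t statistic.
    """
    case, ctrl = _group_arrays(mat, design, case_group)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2fc = mean_case - mean_ctrl

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)

    # Zero within-group variance in both groups: flag and apply the limit rule.
    var_case = case.var(axis=1, ddof=1)
    var_ctrl = ctrl.var(axis=1, ddof=1)
    degenerate = (var_case == 0) & (var_ctrl == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both groups; "
            "p set by the zero-variance limit rule",
            UserWarning,
        )
        pvals[degenerate] = np.where(log2fc[degenerate] == 0.0, 1.0, 0.0)

    qvals, _pi0 = storey_qvalue(pvals)
    return pd.DataFrame(
        {
            "comparison": case_group,
            "log2fc": log2fc,
            "fold_change": signed_linear_fc(log2fc),
            "p_value": pvals,
            "q_value": qvals,
            "mean_ctrl": mean_ctrl,
            "mean_case": mean_case,
        },
        index=pd.Index(mat.data.index, name="gene"),
    )


def _group_arrays(
    mat: ExpressionMatrix, design: GroupDesign, case_group: str
) -> tuple[np.ndarray, np.ndarray]:
    if not mat.log_scale:
        raise NersigError("differential expression requires a log-scale matrix")
    case_ids = design.samples_in(case_group)
    ctrl_ids = design.samples_in(design.control)
    if len(case_ids) < 2:
        raise NersigError(f"case group {case_group!r} has fewer than 2 samples")
    if len(ctrl_ids) < 2:
        raise NersigError(f"control group {design.control!r} has fewer than 2 samples")
    missing = [s for s in case_ids + ctrl_ids if s not in mat.data.columns]
    if missing:
        raise NersigError(f"design samples absent from matrix: {missing[:5]}")
    return (
        mat.data[case_ids].to_numpy(dtype=float),
        mat.data[ctrl_ids].to_numpy(dtype=float),
    )


def _invert_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma

    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed sample
    variances by matching the moments of log(s^2), then returns the posterior
    variances (d0*s0^2 + df*s^2)/(d0 + df) and the prior df d0 (inf when the
    observed spread is no larger than chi-square sampling noise alone).
    """
    from scipy.special import digamma, polygamma

    positive = s2[s2 > 0]
    if positive.size < 2:
        return s2.copy(), 0.0
    floor = positive.min() * 1e-12
    z = np.log(np.maximum(s2, floor))
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = np.inf
        s0 = float(np.exp(e.mean()))
        return np.full_like(s2, s0), d0
    d0 = 2.0 * _invert_trigamma(evar)
    s0 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


def moderated_de(
    mat: ExpressionMatrix, design: GroupDesign, case_group: str
) -> pd.DataFrame:
    """Moderated t-test per gene: pooled variance shrunk across genes.

    With few replicates per group the per-gene variance estimate has very few
    degrees of freedom, so raw t-tests are badly underpowered. Here each
    gene's pooled two-sample variance is shrunk toward an empirical-Bayes
    prior fitted across all genes, and the t statistic uses the posterior
    variance with df = residual df + prior df. Output schema matches
    ``welch_de``.
    """
    case, ctrl = _group_arrays(mat, design, case_group)
    n1, n2 = case.shape[1], ctrl.shape[1]
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2fc = mean_case - mean_ctrl
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df_resid
    s2_post, d0 = _squeeze_var(s2, df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = log2fc / se
    df_total = df_resid + d0
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero posterior variance; "
            "p set by the zero-variance limit rule",
            UserWarning,
        )
        pvals[degenerate] = np.where(log2fc[degenerate] == 0.0, 1.0, 0.0)

    qvals, _pi0 = storey_qvalue(pvals)
    return pd.DataFrame(
        {
            "comparison": case_group,
            "log2fc": log2fc,
            "fold_change": signed_linear_fc(log2fc),
            "p_value": pvals,
            "q_value": qvals,
            "mean_ctrl": mean_ctrl,
            "mean_case": mean_case,
        },
        index=pd.Index(mat.data.index, name="gene"),
    )


def de_table(
    mat: ExpressionMatrix, design: GroupDesign, case_group: str, method: str = "moderated"
) -> pd.DataFrame:
    """Dispatch to the configured per-gene test (``moderated`` or ``welch``)."""
    if method == "moderated":
        return moderated_de(mat, design, case_group)
    if method == "welch":
        return welch_de(mat, design, case_group)
    raise NersigError(f"unknown DE method {method!r}")


_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def _estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray) -> float:
    """Storey's pi0: lambda-grid estimates smoothed by a cubic spline and
    read off at the largest lambda, clipped to (0, 1]."""
    m = pvals.size
    pi0_lambda = np.array([(pvals > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.all(pi0_lambda >= 1.0):
        return 1.0
    # Natural cubic smoothing spline with GCV-selected penalty, as in the
    # standard q-value implementation; extrapolate to the largest lambda.
    spline = interpolate.make_smoothing_spline(lambdas, pi0_lambda)
    pi0 = float(spline(lambdas.max()))
    positive = pi0_lambda[pi0_lambda > 0]
    floor = float(positive.min()) if positive.size else 1e-8
    return float(min(1.0, max(pi0, min(floor, 1.0), 1e-8)))


def storey_qvalue(
    pvals: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray = _LAMBDA_GRID,
) -> tuple[np.ndarray, float]:
    """Storey q-values for a vector of p-values.

    Parameters
    ----------
    pvals
        p-values in [0, 1], length >= 1.
    pi0
        Proportion of true nulls. Estimated from the p-value distribution
        when None; pass 1.0 to recover Benjamini-Hochberg adjusted p-values.

    Returns
    -------
    (qvals, pi0)
        q_i = pi0 * min_{p_j >= p_i} (m * p_j / rank(p_j)), clipped to [0, 1],
        monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise NersigError("p-value vector must be one-dimensional and non-empty")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise NersigError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = _estimate_pi0(p, np.asarray(lambdas, dtype=float))
    elif not (0 < pi0 <= 1):
        raise NersigError("pi0 must lie in (0, 1]")

    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # Step-up: q at rank i is the running minimum from the largest p downward.
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(pi0 * q_sorted, 0.0, 1.0)
    return q, float(pi0)


def de_pass_filter(
    res: pd.DataFrame, fc_thresh: float = 1.5, fdr_thresh: float = 0.05
) -> set[str]:
    """Genes with |signed linear fold change| > fc_thresh and q < fdr_thresh.

    Both inequalities are strict: a gene at exactly the threshold is excluded.
    """
    if fc_thresh <= 0 or fdr_thresh <= 0:
        raise NersigError("thresholds must be > 0")
    mask = (res["fold_change"].abs() > fc_thresh) & (res["q_value"] < fdr_thresh)
    return set(res.index[mask])
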