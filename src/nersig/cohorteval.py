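"""Cohort-level validation of the deficient-NER score.

Covers the classification and survival analyses run on tumor cohorts:
ROC / AUROC against a mutation-derived gold standard, the Youden-index
operating point with a stratified percentile-bootstrap confidence interval,
two-group log-rank testing and a binary-covariate Cox hazard ratio, and the
three-group mutational-signature concordance check (are predicted-deficient
tumors without NER mutations mutationally similar to gold-standard ones?).

Score orientation throughout: higher score = more NER-deficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .containers import NersigError
from .signature import ScoreVector

__all__ = [
    "ThresholdResult",
    "ConcordanceResult",
    "CoxResult",
    "roc_and_youden",
    "stratify",
    "logrank_test",
    "cox_hr_binary",
    "mutsig_concordance",
]


@dataclass
class ThresholdResult:
    """ROC summary with the Youden operating point and its bootstrap CI."""

    roc: pd.DataFrame  # columns: threshold, sensitivity, fpr
    auroc: float
    youden_threshold: float
    youden_j: float
    sensitivity_at_cut: float
    fpr_at_cut: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass
class CoxResult:
    hr: float
    ci95: tuple[float, float]
    p: float
    log_hr: float
    se: float


@dataclass
class ConcordanceResult:
    """Per-signature effect sizes of groups 1 and 2 vs group 3, and their
    Pearson correlation across signatures."""

    delta_group1: pd.Series
    delta_group2: pd.Series
    pearson_r: float


def _scores_array(scores) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(scores, ScoreVector):
        return scores.scores.to_numpy(dtype=float), scores.scores.index
    if isinstance(scores, pd.Series):
        return scores.to_numpy(dtype=float), scores.index
    return np.asarray(scores, dtype=float), None


def _auroc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank formulation; ties get average rank."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _youden_cut(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """Best cutpoint by Youden's J over candidate thresholds.

    Ties on J are broken toward higher sensitivity, then the lowest threshold.
    Returns (threshold, J, sensitivity, fpr) for the rule score > threshold.
    """
    thresholds = _candidate_thresholds(scores)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # predicted positive when score > t
    tp = np.array([(labels & (scores > t)).sum() for t in thresholds], dtype=float)
    fp = np.array([((~labels) & (scores > t)).sum() for t in thresholds], dtype=float)
    sens = tp / n_pos
    fpr = fp / n_neg
    j = sens - fpr
    best = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    best = best[np.argsort(-sens[best], kind="mergesort")]
    top_sens = sens[best[0]]
    best = [i for i in best if sens[i] == top_sens]
    idx = min(best, key=lambda i: thresholds[i])
    return float(thresholds[idx]), float(j[idx]), float(sens[idx]), float(fpr[idx])


def roc_and_youden(scores, labels, n_boot: int = 2000, seed: int = 0) -> ThresholdResult:
    """ROC curve, AUROC, and the Youden-index threshold with a bootstrap CI.

    Parameters
    ----------
    scores
        ScoreVector, Series or array of per-sample scores.
    labels
        Boolean array-like, True for the positive (NER-deficient) class,
        aligned with the scores.
    n_boot, seed
        Class-stratified bootstrap resamples for the percentile CI of the
        threshold.
    """
    s, idx = _scores_array(scores)
    if isinstance(labels, pd.Series) and idx is not None:
        labels = labels.reindex(idx)
    y = np.asarray(labels).astype(bool)
    if y.size != s.size:
        raise NersigError("scores and labels differ in length")
    if y.all() or not y.any():
        raise NersigError("both label classes must be present")
    if n_boot < 1:
        raise NersigError("n_boot must be >= 1")

    auroc = _auroc_rank(s, y)
    thresholds = _candidate_thresholds(s)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    roc = pd.DataFrame(
        {
            "threshold": thresholds,
            "sensitivity": [(y & (s > t)).sum() / n_pos for t in thresholds],
            "fpr": [((~y) & (s > t)).sum() / n_neg for t in thresholds],
        }
    )
    cut, j, sens, fpr = _youden_cut(s, y)

    rng = np.random.default_rng(seed)
    pos, neg = s[y], s[~y]
    boot_cuts = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=n_pos, replace=True)
        bn = rng.choice(neg, size=n_neg, replace=True)
        bs = np.concatenate([bp, bn])
        by = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        boot_cuts[b] = _youden_cut(bs, by)[0]
    finite = boot_cuts[np.isfinite(boot_cuts)]
    if finite.size:
        ci_low, ci_high = np.percentile(finite, [2.5, 97.5])
    else:  # pathological: every resample separated at +/-inf
        ci_low, ci_high = -np.inf, np.inf

    return ThresholdResult(
        roc=roc,
        auroc=float(auroc),
        youden_threshold=cut,
        youden_j=j,
        sensitivity_at_cut=sens,
        fpr_at_cut=fpr,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
    )


def stratify(scores, threshold: float) -> pd.Series | np.ndarray:
    """Predicted NER-deficient labels: score strictly greater than threshold."""
    if not np.isfinite(threshold):
        raise NersigError("stratification threshold must be finite")
    s, idx = _scores_array(scores)
    labels = s > threshold
    if idx is not None:
        return pd.Series(labels, index=idx, name="predicted_dner")
    return labels


def _check_survival(tbl: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event", "group"):
        if col not in tbl.columns:
            raise NersigError(f"survival table missing column {col!r}")
    if (tbl["time"] <= 0).any():
        raise NersigError("survival times must be > 0")
    if not tbl["event"].isin([0, 1]).all():
        raise NersigError("event flags must be 0 or 1")
    return tbl


def logrank_test(tbl: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    tbl = _check_survival(tbl)
    groups = sorted(tbl["group"].unique())
    if len(groups) != 2:
        raise NersigError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    if tbl["event"].sum() < 1:
        raise NersigError("log-rank test needs at least one event")
    a = tbl[tbl["group"] == groups[0]]
    b = tbl[tbl["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr_binary(tbl: pd.DataFrame, case_group: str | None = None) -> CoxResult:
    """Cox proportional-hazards estimate for a single binary covariate.

    Maximizes the Breslow partial likelihood by Newton iteration; the hazard
    ratio is for ``case_group`` relative to the other group (default: the
    lexicographically larger label). Wald 95% CI and p-value.
    """
    tbl = _check_survival(tbl)
    groups = sorted(tbl["group"].unique())
    if len(groups) != 2:
        raise NersigError(f"Cox binary model needs exactly 2 groups, got {len(groups)}")
    if case_group is None:
        case_group = groups[1]
    elif case_group not in groups:
        raise NersigError(f"case_group {case_group!r} not in survival table")
    x = (tbl["group"] == case_group).to_numpy(dtype=float)
    t = tbl["time"].to_numpy(dtype=float)
    e = tbl["event"].to_numpy(dtype=int)
    for g in groups:
        if tbl.loc[tbl["group"] == g, "event"].sum() == 0:
            raise NersigError(f"group {g!r} has no events; partial likelihood is monotone")

    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    # Risk-set composition just before each distinct event time.
    te, xe = t[e == 1], x[e == 1]
    event_times, first_idx, d = np.unique(te, return_index=True, return_counts=True)
    d = d.astype(float)
    s = np.add.reduceat(xe, first_idx)  # cases among events at each time
    n1_suffix = np.cumsum(x[::-1])[::-1]  # cases at risk from position i onward
    n_suffix = np.arange(t.size, 0, -1, dtype=float)
    at = np.searchsorted(t, event_times, side="left")
    n1_risk = n1_suffix[at]
    n0_risk = n_suffix[at] - n1_risk

    beta = 0.0
    for _ in range(50):
        eb = np.exp(beta)
        denom = n0_risk + n1_risk * eb
        expect = n1_risk * eb / denom
        u = float(np.sum(s - d * expect))
        info = float(np.sum(d * expect * (1 - expect)))
        if info <= 0:
            raise NersigError("singular information; cannot fit Cox model")
        step = u / info
        beta += step
        if abs(step) < 1e-12:
            break
    eb = np.exp(beta)
    denom = n0_risk + n1_risk * eb
    expect = n1_risk * eb / denom
    se = float(1.0 / np.sqrt(np.sum(d * expect * (1 - expect))))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    lo, hi = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
    return CoxResult(hr=float(np.exp(beta)), ci95=(float(lo), float(hi)), p=p, log_hr=float(beta), se=se)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.nan
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def mutsig_concordance(
    mat: pd.DataFrame,
    group1,
    group2,
    group3,
    standardized: bool = True,
) -> ConcordanceResult:
    """Concordance of mutational-process shifts in two groups vs a reference.

    ``mat`` is sample x signature activity. For each signature, the shift of
    group1 (gold-standard deficient) and group2 (predicted deficient) relative
    to group3 (proficient) is summarized as Cohen's d with pooled SD (or the
    raw mean difference when ``standardized=False``); the result's Pearson r
    measures how concordant the two shift profiles are across signatures.
    """
    g1, g2, g3 = (list(g) for g in (group1, group2, group3))
    sets = [set(g1), set(g2), set(g3)]
    if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
        raise NersigError("groups must be disjoint")
    for name, g in zip(("group1", "group2", "group3"), (g1, g2, g3)):
        if len(g) < 2:
            raise NersigError(f"{name} needs >= 2 samples")
        missing = [sid for sid in g if sid not in mat.index]
        if missing:
            raise NersigError(f"{name} samples absent from matrix: {missing[:5]}")
    vals = mat.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(~np.isfinite(vals)):
        raise NersigError("mutational-signature activities must be finite and non-negative")

    ref = mat.loc[g3]
    deltas = {}
    for name, g in (("delta_group1", g1), ("delta_group2", g2)):
        sub = mat.loc[g]
        if standardized:
            deltas[name] = pd.Series(
                [_cohens_d(sub[c].to_numpy(), ref[c].to_numpy()) for c in mat.columns],
                index=mat.columns,
            )
        else:
            deltas[name] = sub.mean() - ref.mean()
    d1, d2 = deltas["delta_group1"], deltas["delta_group2"]
    valid = d1.notna() & d2.notna()
    if valid.sum() < 2:
        raise NersigError("fewer than 2 signatures with defined effect sizes")
    r = float(stats.pearsonr(d1[valid], d2[valid]).statistic)
    return ConcordanceResult(delta_group1=d1, delta_group2=d2, pearson_r=r)
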