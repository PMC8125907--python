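"""Consensus deficient-NER signature: gene selection, coefficients, scoring.

The signature is the set of genes differentially expressed, in the same
direction, in every knockdown line of the isogenic panel (|FC| > 1.5 and
q < 0.05 per line). Each gene's coefficient c_i is the average of its signed
per-line log2 fold changes. A sample s is scored as

    S(s) = sum_i c_i * z_i(s) / sum_i |c_i|

where z_i is the gene's z-normalized log2 expression across the cohort being
scored. Higher scores indicate greater predicted NER deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, NersigError
from .diffexpr import de_pass_filter, signed_linear_fc

__all__ = [
    "GeneSignature",
    "ScoreVector",
    "WardClustering",
    "select_consensus_genes",
    "build_signature",
    "score_samples",
    "ward_cluster",
]


@dataclass
class GeneSignature:
    """Gene-to-coefficient map with derivation provenance."""

    coefficients: pd.Series  # index = gene, value = coefficient
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise NersigError("signature contains duplicate genes")
        if (self.coefficients == 0).any():
            zeros = list(self.coefficients.index[self.coefficients == 0])
            raise NersigError(f"zero coefficients not allowed: {zeros[:5]}")

    def __len__(self) -> int:
        return len(self.coefficients)

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass
class ScoreVector:
    """Per-sample signature scores for one cohort."""

    scores: pd.Series  # index = sample_id
    n_genes_used: int
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class WardClustering:
    """Ward-linkage dendrogram over samples plus the deterministic leaf order."""

    linkage: np.ndarray
    sample_ids: list[str]  # input order, matching linkage leaf indices
    sample_order: list[str]  # dendrogram leaf order, left to right


def select_consensus_genes(
    results: Mapping[str, pd.DataFrame],
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
    require_consistent_sign: bool = True,
) -> set[str]:
    """Genes passing the DE filter in *every* comparison, with consistent sign.

    Parameters
    ----------
    results
        Mapping from comparison label to a per-gene DE table (``welch_de``
        output). At least two comparisons are required.
    require_consistent_sign
        Exclude genes whose log2FC direction differs between lines; a single
        averaged coefficient would be meaningless for such genes.
    """
    if len(results) < 2:
        raise NersigError("consensus selection needs at least 2 comparisons")
    per_line = [de_pass_filter(res, fc_thresh, fdr_thresh) for res in results.values()]
    consensus = set.intersection(*per_line)
    if require_consistent_sign and consensus:
        signs = pd.DataFrame(
            {name: np.sign(res.loc[sorted(consensus), "log2fc"]) for name, res in results.items()}
        )
        concordant = signs.apply(lambda row: row.nunique() == 1, axis=1)
        consensus = set(signs.index[concordant])
    if not consensus:
        warnings.warn("consensus gene set is empty at these thresholds", UserWarning)
    return consensus


def build_signature(
    results: Mapping[str, pd.DataFrame],
    genes: set[str] | list[str],
    scale: str = "log2",
    fc_thresh: float | None = None,
    fdr_thresh: float | None = None,
) -> GeneSignature:
    """Assign each consensus gene the average fold change across comparisons.

    ``scale="log2"`` (default) averages the signed log2 fold changes;
    ``scale="linear"`` averages signed linear fold changes instead. Every gene
    must be present in every comparison table.
    """
    if scale not in ("log2", "linear"):
        raise NersigError(f"unknown coefficient scale {scale!r}")
    genes = sorted(genes)
    if not genes:
        raise NersigError("cannot build a signature from an empty gene set")
    for name, res in results.items():
        absent = [g for g in genes if g not in res.index]
        if absent:
            raise NersigError(f"gene {absent[0]!r} missing from comparison {name!r}")
    per_line = pd.DataFrame({name: res.loc[genes, "log2fc"] for name, res in results.items()})
    if scale == "log2":
        coef = per_line.mean(axis=1)
    else:
        coef = pd.DataFrame(
            {c: signed_linear_fc(per_line[c].to_numpy()) for c in per_line}, index=per_line.index
        ).mean(axis=1)
    provenance = {
        "comparisons": list(results.keys()),
        "coefficient_scale": scale,
        "fc_thresh": fc_thresh,
        "fdr_thresh": fdr_thresh,
    }
    return GeneSignature(coefficients=coef, provenance=provenance)


def score_samples(
    mat: ExpressionMatrix,
    sig: GeneSignature,
    max_dropped_frac: float = 0.2,
    reference: tuple[pd.Series, pd.Series] | None = None,
) -> ScoreVector:
    """Weighted z-score of each sample against the signature.

    z-normalization uses the mean and standard deviation of each gene across
    the cohort being scored (the signature is applied to cohorts it was never
    trained on, so no frozen reference exists by default). For single-sample
    scoring, pass ``reference=(means, sds)`` computed on a reference cohort.

    Genes absent from the matrix or with zero cohort variance are dropped and
    the denominator renormalized over retained genes; dropping more than
    ``max_dropped_frac`` of the signature is an error.
    """
    if mat.n_samples < 2 and reference is None:
        raise NersigError("scoring needs >= 2 samples for cohort z-normalization")
    if not mat.log_scale:
        raise NersigError("score_samples requires a log-scale matrix")

    present = [g for g in sig.genes if g in mat.data.index]
    dropped = [g for g in sig.genes if g not in mat.data.index]
    sub = mat.data.loc[present]
    if reference is None:
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
    else:
        ref_mean, ref_sd = reference
        absent = [g for g in present if g not in ref_mean.index or g not in ref_sd.index]
        if absent:
            raise NersigError(f"reference lacks mean/sd for genes: {absent[:5]}")
        means = ref_mean.loc[present]
        sds = ref_sd.loc[present]

    zero_var = list(sds.index[sds == 0])
    if zero_var:
        dropped = dropped + zero_var
        keep = sds.index[sds != 0]
        sub, means, sds = sub.loc[keep], means.loc[keep], sds.loc[keep]

    if len(sub) == 0:
        raise NersigError("no signature genes retained; cannot score")
    if len(dropped) / len(sig) > max_dropped_frac:
        raise NersigError(
            f"{len(dropped)}/{len(sig)} signature genes dropped, exceeding "
            f"max_dropped_frac={max_dropped_frac}"
        )

    z = sub.sub(means, axis=0).div(sds, axis=0)
    coef = sig.coefficients.loc[sub.index]
    scores = z.mul(coef, axis=0).sum(axis=0) / coef.abs().sum()
    scores.name = "dner_score"
    return ScoreVector(scores=scores, n_genes_used=len(sub), dropped_genes=dropped)


def ward_cluster(mat: ExpressionMatrix, genes: set[str] | list[str]) -> WardClustering:
    """Hierarchical clustering of samples with Ward linkage.

    Distances are Euclidean over the z-normalized rows of the signature genes,
    so each gene contributes on a common scale. Zero-variance genes are
    skipped (their z is undefined).
    """
    genes = [g for g in sorted(genes) if g in mat.data.index]
    if not genes:
        raise NersigError("empty gene set for clustering")
    sub = mat.data.loc[genes]
    sds = sub.std(axis=1, ddof=1)
    sub = sub.loc[sds.index[sds != 0]]
    if sub.empty:
        raise NersigError("all clustering genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    dist = pdist(z.to_numpy().T, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="ward")
    leaves = hierarchy.leaves_list(linkage)
    sample_ids = list(mat.data.columns)
    return WardClustering(
        linkage=linkage,
        sample_ids=sample_ids,
        sample_order=[sample_ids[i] for i in leaves],
    )
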