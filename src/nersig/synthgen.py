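"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the data the pipeline consumes:

* an isogenic knockdown panel (K lines + shared control, n replicates each)
  with a planted "core" gene set differentially expressed in every line,
  line-private DE genes, and additive Gaussian noise on the log2 scale;
* a tumor cohort in which a deficient-NER subset has its signature-gene
  expression shifted along the coefficient signs, distinct
  mutational-signature activities, and exponential survival with a planted
  hazard ratio;
* a cell-line drug screen in which designated lethal drugs have lower AUC in
  upper-quartile-score lines;
* single-drug dose-response curves obeying the median-effect equation, with
  Gaussian noise on the logit of the fraction affected so fa stays in (0, 1).

All configs require an explicit seed; identical config + seed reproduces the
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroupDesign, NersigError
from .drugcombo import DoseResponseCurve
from .signature import GeneSignature, ScoreVector

__all__ = [
    "PanelSimConfig",
    "CohortSimConfig",
    "ScreenSimConfig",
    "MedianEffectSimConfig",
    "PanelTruth",
    "CohortSim",
    "simulate_isogenic_panel",
    "simulate_tumor_cohort",
    "simulate_drug_screen",
    "simulate_dose_response",
]

# Default knockdown labels mirror the five NER genes silenced in the panel.
NER_PANEL_LINES = ("shXPA", "shXPC", "shERCC4", "shERCC5", "shERCC6")
CONTROL_LINE = "shCTRL"


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise NersigError(f"invalid config field {name!r}: {msg}")


@dataclass
class PanelSimConfig:
    """Isogenic-panel simulation: 5 knockdown lines x 3 replicates by default,
    matching the experimental design the signature was derived from."""

    seed: int
    n_genes: int = 1000
    n_lines: int = 5
    n_reps_per_group: int = 3
    n_core_de: int = 105
    n_private_de: int = 30
    core_log2fc_mean: float = 1.2
    core_log2fc_sd: float = 0.1
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_lines", "n_reps_per_group", "n_core_de"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.n_private_de >= 0, "n_private_de", "must be >= 0")
        _require(
            self.n_core_de + self.n_lines * self.n_private_de <= self.n_genes,
            "n_genes",
            "core + private DE genes exceed total genes",
        )
        _require(self.noise_sd > 0, "noise_sd", "must be > 0")
        _require(self.core_log2fc_sd >= 0, "core_log2fc_sd", "must be >= 0")
        _require(self.n_reps_per_group >= 2, "n_reps_per_group", "must be >= 2")


@dataclass
class CohortSimConfig:
    """Tumor-cohort simulation with a planted deficient-NER subset."""

    seed: int
    n_tumors: int = 300
    frac_dner: float = 0.25
    score_shift: float = 3.0
    n_mutsigs: int = 30
    mutsig_shift: float = 1.0
    survival_hr: float = 0.46
    censor_rate: float = 0.2
    frac_mutated: float = 0.5  # fraction of deficient tumors carrying an NER mutation
    baseline_hazard: float = 1.0 / 24.0  # events per month; median ~17 months

    def __post_init__(self) -> None:
        _require(self.n_tumors >= 4, "n_tumors", "must be >= 4")
        _require(0 < self.frac_dner < 1, "frac_dner", "must be in (0, 1)")
        _require(self.survival_hr > 0, "survival_hr", "must be > 0")
        _require(0 <= self.censor_rate < 1, "censor_rate", "must be in [0, 1)")
        _require(self.n_mutsigs >= 2, "n_mutsigs", "must be >= 2")
        _require(0 <= self.frac_mutated <= 1, "frac_mutated", "must be in [0, 1]")
        _require(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")


@dataclass
class ScreenSimConfig:
    """Cell-line drug-screen simulation with planted lethal drugs."""

    seed: int
    n_lines: int = 40
    n_drugs: int = 50
    n_lethal_drugs: int = 5
    auc_effect: float = 0.3
    auc_noise_sd: float = 0.05
    auc_baseline: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_drugs"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.n_lethal_drugs >= 0, "n_lethal_drugs", "must be >= 0")
        _require(self.n_lethal_drugs <= self.n_drugs, "n_lethal_drugs", "cannot exceed n_drugs")
        _require(self.auc_noise_sd > 0, "auc_noise_sd", "must be > 0")
        _require(0 <= self.auc_baseline <= 1, "auc_baseline", "must be in [0, 1]")
        _require(self.n_lines >= 4, "n_lines", "must be >= 4 for quartile stratification")


@dataclass
class MedianEffectSimConfig:
    """Dose-response simulation under the median-effect equation."""

    seed: int
    m_true: float = 2.0
    dm_true: float = 5.0
    doses: tuple[float, ...] = (0.5, 1.0, 2.5, 5.0, 10.0, 25.0)
    fa_noise_sd: float = 0.1  # on the logit of fa
    drug: str = "drugA"

    def __post_init__(self) -> None:
        _require(self.dm_true > 0, "dm_true", "must be > 0")
        _require(self.m_true != 0, "m_true", "must be nonzero")
        doses = np.asarray(self.doses, dtype=float)
        _require(doses.size >= 2, "doses", "need >= 2 doses")
        _require(bool(np.all(doses > 0)), "doses", "must be strictly positive")
        _require(np.unique(doses).size == doses.size, "doses", "must be distinct")
        _require(self.fa_noise_sd >= 0, "fa_noise_sd", "must be >= 0")


@dataclass
class PanelTruth:
    """Planted ground truth of the isogenic-panel simulation."""

    core_genes: list[str]
    private_genes: dict[str, list[str]]  # line -> genes DE only in that line
    planted_log2fc: pd.DataFrame  # gene x line; 0 where not DE


@dataclass
class CohortSim:
    """Simulated tumor cohort: expression, labels, mutsig activity, survival."""

    expression: ExpressionMatrix
    labels: pd.DataFrame  # sample, dner, ner_mutated
    mutsig: pd.DataFrame  # sample x signature activity
    survival: pd.DataFrame  # sample, time, event, group
    shifted_mutsigs: list[str]


def simulate_isogenic_panel(
    cfg: PanelSimConfig,
) -> tuple[ExpressionMatrix, GroupDesign, PanelTruth]:
    """Simulate the knockdown panel: control + n_lines groups, planted DE.

    Core genes carry the same signed log2 shift in every knockdown line;
    each line additionally has private DE genes shifted only in that line.
    Replicate noise is additive Gaussian on the log2 scale.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    if cfg.n_lines <= len(NER_PANEL_LINES):
        lines = list(NER_PANEL_LINES[: cfg.n_lines])
    else:
        lines = [f"shKD{i + 1}" for i in range(cfg.n_lines)]
    groups = [CONTROL_LINE] + lines

    de_pool = rng.permutation(cfg.n_genes)
    core_idx = de_pool[: cfg.n_core_de]
    private_idx = {
        line: de_pool[cfg.n_core_de + k * cfg.n_private_de : cfg.n_core_de + (k + 1) * cfg.n_private_de]
        for k, line in enumerate(lines)
    }

    core_signs = rng.choice([-1.0, 1.0], size=cfg.n_core_de)
    core_fc = core_signs * rng.normal(cfg.core_log2fc_mean, cfg.core_log2fc_sd, cfg.n_core_de)
    planted = pd.DataFrame(0.0, index=genes, columns=lines)
    for line in lines:
        planted.iloc[core_idx, planted.columns.get_loc(line)] = core_fc
        pidx = private_idx[line]
        signs = rng.choice([-1.0, 1.0], size=pidx.size)
        planted.iloc[pidx, planted.columns.get_loc(line)] = signs * rng.normal(
            cfg.core_log2fc_mean, cfg.core_log2fc_sd, pidx.size
        )

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    cols, data = [], []
    for group in groups:
        shift = np.zeros(cfg.n_genes) if group == CONTROL_LINE else planted[group].to_numpy()
        for rep in range(1, cfg.n_reps_per_group + 1):
            cols.append(f"{group}_rep{rep}")
            data.append(baseline + shift + rng.normal(0.0, cfg.noise_sd, cfg.n_genes))
    mat = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=genes, columns=cols),
        log_scale=True,
        provenance={"simulator": "isogenic_panel", "seed": cfg.seed},
    )
    design = GroupDesign(
        groups=pd.Series({c: c.rsplit("_rep", 1)[0] for c in cols}, name="group"),
        control=CONTROL_LINE,
    )
    truth = PanelTruth(
        core_genes=[genes[i] for i in core_idx],
        private_genes={line: [genes[i] for i in idx] for line, idx in private_idx.items()},
        planted_log2fc=planted,
    )
    return mat, design, truth


def simulate_tumor_cohort(cfg: CohortSimConfig, sig: GeneSignature) -> CohortSim:
    """Simulate a tumor cohort whose deficient subset scores high on ``sig``.

    Deficient tumors have each signature gene shifted by
    ``score_shift * sign(coefficient)`` standard deviations, carry elevated
    activity (+``mutsig_shift``) on a designated half of the mutational
    signatures, and draw exponential survival with hazard
    ``baseline_hazard * survival_hr`` (HR < 1 means longer survival).
    Censoring is an independent exponential calibrated to ``censor_rate``.
    """
    if len(sig) == 0:
        raise NersigError("signature is empty")
    rng = np.random.default_rng(cfg.seed)
    samples = [f"tumor{i:04d}" for i in range(cfg.n_tumors)]
    n_dner = max(1, int(round(cfg.frac_dner * cfg.n_tumors)))
    dner = np.zeros(cfg.n_tumors, dtype=bool)
    dner[rng.choice(cfg.n_tumors, size=n_dner, replace=False)] = True

    genes = sig.genes
    coef_sign = np.sign(sig.coefficients.to_numpy())
    base = rng.normal(8.0, 1.0, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), cfg.n_tumors))
    expr[:, dner] += cfg.score_shift * coef_sign[:, None]
    mat = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=samples),
        log_scale=True,
        provenance={"simulator": "tumor_cohort", "seed": cfg.seed},
    )

    mutated = dner & (rng.random(cfg.n_tumors) < cfg.frac_mutated)
    labels = pd.DataFrame({"sample": samples, "dner": dner, "ner_mutated": mutated}).set_index(
        "sample"
    )

    sig_names = [f"SBS{i + 1}" for i in range(cfg.n_mutsigs)]
    n_shifted = max(1, cfg.n_mutsigs // 2)
    shifted = sig_names[:n_shifted]
    activity = rng.gamma(shape=2.0, scale=0.5, size=(cfg.n_tumors, cfg.n_mutsigs))
    activity[dner, :n_shifted] += cfg.mutsig_shift
    mutsig = pd.DataFrame(activity, index=samples, columns=sig_names)

    hazard = np.where(dner, cfg.baseline_hazard * cfg.survival_hr, cfg.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        cens_rate = cfg.baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=cfg.n_tumors)
    else:
        cens_time = np.full(cfg.n_tumors, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    survival = pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "group": np.where(dner, "dNER", "NERproficient"),
        }
    ).set_index("sample")

    return CohortSim(
        expression=mat, labels=labels, mutsig=mutsig, survival=survival, shifted_mutsigs=shifted
    )


def simulate_drug_screen(
    cfg: ScreenSimConfig, scores: ScoreVector
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate an AUC screen where lethal drugs hit upper-quartile lines.

    ``scores`` must cover exactly the configured number of lines; its index
    provides the line IDs. AUC values are the configured baseline plus
    Gaussian noise, with ``auc_effect`` subtracted for lethal drugs in lines
    whose score falls in the upper quartile, then clipped to [0, 1].
    """
    from .drugscreen import quartile_stratify  # local import avoids a cycle

    line_ids = list(scores.scores.index)
    if len(line_ids) != cfg.n_lines:
        raise NersigError(
            f"score vector covers {len(line_ids)} lines but config expects {cfg.n_lines}"
        )
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"drug{j:03d}" for j in range(cfg.n_drugs)]
    lethal = drugs[: cfg.n_lethal_drugs]
    high = quartile_stratify(scores).to_numpy()

    auc = cfg.auc_baseline + rng.normal(0.0, cfg.auc_noise_sd, size=(cfg.n_lines, cfg.n_drugs))
    auc[np.ix_(high, [drugs.index(d) for d in lethal])] -= cfg.auc_effect
    auc = np.clip(auc, 0.0, 1.0)
    return pd.DataFrame(auc, index=line_ids, columns=drugs), lethal


def simulate_dose_response(cfg: MedianEffectSimConfig) -> DoseResponseCurve:
    """Simulate fa(D) = (D/Dm)^m / (1 + (D/Dm)^m) with logit-Gaussian noise."""
    rng = np.random.default_rng(cfg.seed)
    doses = np.asarray(cfg.doses, dtype=float)
    ratio = (doses / cfg.dm_true) ** cfg.m_true
    fa = ratio / (1.0 + ratio)
    if cfg.fa_noise_sd > 0:
        logit = np.log(fa / (1.0 - fa)) + rng.normal(0.0, cfg.fa_noise_sd, doses.size)
        fa = 1.0 / (1.0 + np.exp(-logit))
    return DoseResponseCurve(drug=cfg.drug, doses=doses, fa=fa)
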