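"""Tabular readers/writers and run configuration.

Tab-separated files are canonical; comma-separated input is accepted on read
via delimiter sniffing. Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GroupDesign, NersigError
from .signature import GeneSignature, ScoreVector

__all__ = [
    "PipelineConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_signature_tsv",
    "write_signature_tsv",
    "read_maf_lite",
    "read_clinical_tsv",
    "read_matrix_tsv",
    "write_scores_tsv",
    "write_de_tsv",
    "stage_seed",
]

# Variant classes kept as functionally relevant (non-silent) by default.
NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonstop_Mutation",
)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_tsv(path: str | Path, log_scale: bool = False) -> ExpressionMatrix:
    """Read a gene-by-sample matrix: header row of sample IDs, first column
    gene IDs. Rejects ragged rows, duplicate genes and non-numeric cells with
    the offending line number."""
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    if raw.isna().any().any():
        line = int(raw.isna().any(axis=1).to_numpy().argmax()) + 2
        raise NersigError(f"{path.name}: ragged or empty cell at line {line}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise NersigError(f"{path.name}: duplicated gene ID {dup!r}")
    try:
        values = raw.astype(float)
    except ValueError:
        for i, (_, row) in enumerate(raw.iterrows()):
            try:
                row.astype(float)
            except ValueError as exc:
                raise NersigError(f"{path.name}: non-numeric cell at line {i + 2}") from exc
        raise
    return ExpressionMatrix(values, log_scale=log_scale, provenance={"source": str(path)})


def write_expression_tsv(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="gene")


def read_design_tsv(path: str | Path, control: str) -> GroupDesign:
    """Two-column TSV: sample, group."""
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise NersigError(f"{path}: design needs columns sample, group")
    df.columns = ["sample", "group"] + list(df.columns[2:])
    return GroupDesign(groups=pd.Series(df["group"].values, index=df["sample"].values), control=control)


def write_design_tsv(design: GroupDesign, path: str | Path) -> None:
    pd.DataFrame({"sample": design.groups.index, "group": design.groups.values}).to_csv(
        path, sep="\t", index=False
    )


def write_signature_tsv(sig: GeneSignature, path: str | Path) -> None:
    """Two-column TSV (gene, coefficient) plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"gene": sig.coefficients.index, "coefficient": sig.coefficients.values}
    ).to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sig.provenance, fh, indent=2, default=str)


def read_signature_tsv(path: str | Path) -> GeneSignature:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if not {"gene", "coefficient"} <= set(df.columns):
        raise NersigError(f"{path}: signature needs columns gene, coefficient")
    provenance: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh)
    return GeneSignature(
        coefficients=pd.Series(df["coefficient"].values, index=df["gene"].values),
        provenance=provenance,
    )


def read_maf_lite(
    path: str | Path, nonsilent: tuple[str, ...] = NONSILENT_CLASSES
) -> dict[str, set[str]]:
    """Parse a MAF-lite table into per-sample sets of non-silently mutated genes.

    Requires columns sample, gene, variant_classification (case-insensitive).
    Samples with only silent variants map to empty sets; samples absent from
    the file are simply absent (wild-type downstream).
    """
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    needed = ["sample", "gene", "variant_classification"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise NersigError(f"{path}: MAF-lite missing columns {missing}")
    out: dict[str, set[str]] = {}
    keep = set(nonsilent)
    for _, row in df.iterrows():
        sid = str(row[cols["sample"]])
        out.setdefault(sid, set())
        if str(row[cols["variant_classification"]]) in keep:
            out[sid].add(str(row[cols["gene"]]))
    return out


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with columns sample, time, event (and optionally group)."""
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("sample", "time", "event") if c not in df.columns]
    if missing:
        raise NersigError(f"{path}: clinical table missing columns {missing}")
    return df.set_index("sample")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Generic sample-by-feature numeric matrix (mutsig activities, drug AUCs)."""
    sep = _sniff_sep(Path(path))
    return pd.read_csv(path, sep=sep, index_col=0)


def write_scores_tsv(scores: ScoreVector, path: str | Path) -> None:
    scores.scores.rename_axis("sample").to_csv(path, sep="\t", header=["score"])


def write_de_tsv(res: pd.DataFrame, path: str | Path) -> None:
    res.rename_axis("gene").to_csv(path, sep="\t")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed and the stage name,
    so stages are independently reproducible."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the literal pipeline thresholds."""

    seed: int = 0
    outdir: str = "nersig_out"
    fc_thresh: float = 1.5
    fdr_thresh: float = 0.05
    upper_quartile_frac: float = 0.25
    coefficient_scale: str = "log2"
    de_method: str = "moderated"
    ci_exclusive: bool = True
    pseudocount: float = 1.0
    expression_log_scale: bool = True
    inputs: dict = field(default_factory=dict)  # optional stage -> path map
    sim: dict = field(default_factory=dict)  # overrides for simulator configs

    def __post_init__(self) -> None:
        if self.fc_thresh <= 0 or self.fdr_thresh <= 0 or not 0 < self.upper_quartile_frac < 1:
            raise NersigError("pipeline thresholds must be positive (quartile fraction in (0,1))")
        if self.coefficient_scale not in ("log2", "linear"):
            raise NersigError(f"unknown coefficient_scale {self.coefficient_scale!r}")
        if self.de_method not in ("moderated", "welch"):
            raise NersigError(f"unknown de_method {self.de_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise NersigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
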