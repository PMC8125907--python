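"""Core in-memory containers shared across the pipeline.

Expression data lives in a pandas DataFrame (genes in rows, samples in
columns) wrapped with a scale flag, because every downstream statistic
(fold changes, z-scores) assumes log2 expression and silent scale mix-ups
are the classic failure mode of signature pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GroupDesign", "NersigError"]


class NersigError(ValueError):
    """User-facing error: bad input data or configuration."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    data
        DataFrame with unique gene IDs as index and unique sample IDs as
        columns. Values must be finite.
    log_scale
        True if values are log2 abundance; False for linear scale (TPM-like).
    provenance
        Free-form metadata (source file, simulation config, ...).
    """

    data: pd.DataFrame
    log_scale: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise NersigError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise NersigError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values.astype(float))):
            raise NersigError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GroupDesign:
    """Sample-to-group assignment with a designated control group."""

    groups: pd.Series  # index = sample_id, value = group label
    control: str

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            raise NersigError("design assigns a sample to more than one group")
        if self.control not in set(self.groups.values):
            raise NersigError(f"control group {self.control!r} absent from design")
        if (self.groups == self.control).sum() < 2:
            raise NersigError(f"control group {self.control!r} has fewer than 2 samples")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def case_groups(self) -> list[str]:
        """All non-control group labels, in order of first appearance."""
        seen: list[str] = []
        for g in self.groups.values:
            if g != self.control and g not in seen:
                seen.append(g)
        return seen


def degenerate_warning(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=3)
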