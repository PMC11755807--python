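"""Shared light-weight containers for count data."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class PiwiflowError(Exception):
    """Base class for all piwiflow errors."""


class ConfigError(PiwiflowError):
    """Invalid configuration value; the message names the offending field."""


class IntegrityError(PiwiflowError):
    """Inconsistent inputs (e.g. unknown feature references, mixed UMI lengths)."""


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.
    annotations
        Per-feature annotation indexed like ``counts`` with at least a
        ``kind`` column (``TE``, ``piRNA`` or ``PCG``); TE features carry
        ``class`` (SINE/LINE/ERV/...) and ``clade`` columns.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise IntegrityError("duplicate feature identifiers in count matrix")
        if self.counts.columns.duplicated().any():
            raise IntegrityError("duplicate sample identifiers in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise IntegrityError("negative counts in count matrix")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.counts.index)
        elif not self.annotations.index.equals(self.counts.index):
            self.annotations = self.annotations.reindex(self.counts.index)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, counts_path: str | Path, annotations_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        if annotations_path is not None:
            self.annotations.to_csv(annotations_path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, annotations_path: str | Path | None = None
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        ann = None
        if annotations_path is not None:
            ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        return cls(counts=counts, annotations=ann)
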