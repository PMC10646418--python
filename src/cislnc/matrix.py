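"""Expression containers: transcripts-by-samples matrix and tissue panel."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .errors import DataError

SAMPLE_SHEET_COLUMNS = ["sample", "group", "replicate"]


class ExpressionMatrix:
    """Transcripts x samples abundance table with group labels.

    ``values`` is a DataFrame indexed by transcript id with one column per
    sample; ``samples`` is a sample sheet with columns (sample, group,
    replicate). Values are nonnegative abundances (FPKM or 2^-dCt).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if values.shape[0] < 1:
            raise DataError("expression matrix must contain at least one transcript")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
        if missing:
            raise DataError(f"sample sheet missing column(s): {', '.join(missing)}")
        samples = samples.reset_index(drop=True)
        unknown = set(values.columns) - set(samples["sample"])
        if unknown:
            raise DataError(f"samples without group labels: {sorted(unknown)}")
        if (values.values < 0).any():
            raise DataError("expression values must be nonnegative")
        self.values = values
        self.samples = samples

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> List[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def group_samples(self, group: str) -> List[str]:
        out = [
            s
            for s in self.values.columns
            if s in set(self.samples.loc[self.samples["group"] == group, "sample"])
        ]
        if not out:
            raise DataError(f"group {group!r} has no samples in the matrix")
        return out

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_samples(group)]

    def group_mean(self, group: str) -> pd.Series:
        return self.group_values(group).mean(axis=1)

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="transcript_id")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="transcript_id")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(values, samples)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.values.shape[0]} transcripts x "
            f"{self.values.shape[1]} samples, groups={self.groups})"
        )


@dataclass
class TissuePanel:
    """Transcripts x tissues expression with one designated focal tissue."""

    values: pd.DataFrame
    focal_tissue: str = "islet"

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise DataError("tissue panel needs the focal tissue plus >=1 other")
        if self.focal_tissue not in self.values.columns:
            raise DataError(f"focal tissue {self.focal_tissue!r} not in panel")
        if (self.values.values < 0).any():
            raise DataError("tissue panel values must be nonnegative")

    @property
    def other_tissues(self) -> List[str]:
        return [c for c in self.values.columns if c != self.focal_tissue]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path, focal_tissue: str = "islet") -> "TissuePanel":
        values = pd.read_csv(path, sep="\t", index_col="transcript_id")
        return cls(values, focal_tissue=focal_tissue)
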