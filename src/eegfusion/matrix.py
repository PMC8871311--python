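"""The FeatureMatrix container: rows = segments, columns = named features."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """Feature rows sharing one column-name schema, plus per-row class labels.

    ``case_tag`` ('dwt' | 'emd' | 'fused') and ``dialect``
    ('multi_channel' | 'single_channel') are in-memory provenance tags and
    are not persisted to CSV.
    """

    values: np.ndarray  # (n_rows, n_cols)
    names: list[str]
    labels: list[str]
    case_tag: str | None = None
    dialect: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            arr = arr.reshape(-1, len(self.names))
        if arr.shape[1] != len(self.names):
            raise SchemaError(f"{arr.shape[1]} columns for {len(self.names)} names")
        self.values = arr
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise SchemaError(f"duplicate column names: {dupes}")
        if len(self.labels) != self.values.shape[0]:
            raise AlignmentError(
                f"{len(self.labels)} labels for {self.values.shape[0]} rows"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df[LABEL_COLUMN] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        if LABEL_COLUMN in self.names:
            raise SchemaError(f"{LABEL_COLUMN!r} is reserved for the class column")
        # pandas writes shortest-repr floats, which round-trip exactly
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if LABEL_COLUMN not in df.columns:
            raise SchemaError(f"{path}: missing {LABEL_COLUMN!r} column")
        names = [c for c in df.columns if c != LABEL_COLUMN]
        values = df[names].to_numpy(dtype=float).reshape(len(df), len(names))
        return cls(values, names, [str(v) for v in df[LABEL_COLUMN]])

    def equals(self, other: "FeatureMatrix") -> bool:
        return (
            self.names == other.names
            and self.labels == other.labels
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )
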