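"""Feature-by-sample expression container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "lncRNA", "miRNA", "circRNA")
SCALES = ("counts", "FPKM", "TPM", "RPM")
CONDITIONS = ("GF_C", "GF_T")


@dataclass
class ExpressionMatrix:
    """One RNA layer's feature-by-sample values plus condition labels.

    Parameters
    ----------
    layer:
        One of ``mRNA``, ``lncRNA``, ``miRNA``, ``circRNA``.
    values:
        DataFrame of nonnegative values, features on rows, samples on
        columns.
    conditions:
        Mapping/Series sample id -> condition label (``GF_C`` large
        follicles / ``GF_T`` small follicles).
    scale:
        ``counts`` for raw data, otherwise the normalization applied.
    """

    layer: str
    values: pd.DataFrame
    conditions: pd.Series
    scale: str = "counts"
    feature_lengths: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.conditions, pd.Series):
            self.conditions = pd.Series(dict(self.conditions))
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        bad = set(self.conditions.loc[list(self.values.columns)]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.conditions = self.conditions.loc[list(self.values.columns)]

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def expression_lookup(self) -> dict[str, np.ndarray]:
        """feature id -> value vector, sample order fixed to the columns."""
        arr = self.values.to_numpy(dtype=float)
        return {fid: arr[i] for i, fid in enumerate(self.values.index)}

    # -- I/O -------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        layer: str,
        conditions: pd.Series | dict,
        scale: str = "counts",
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(layer=layer, values=values, conditions=pd.Series(dict(conditions)), scale=scale)


def read_condition_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["condition"].to_numpy(), index=df["sample"])


def write_condition_map(conditions: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": conditions.index, "condition": conditions.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
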