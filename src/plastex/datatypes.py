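"""Core tabular domain types shared by every analysis stage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("EH", "MA")
#: reference level of the two-level environment factor
REFERENCE_CONDITION = "MA"

CATEGORIES = (
    "non_DE",
    "maize_specific",
    "teosinte_specific",
    "shared_same",
    "shared_opposite",
)


class PlastexError(Exception):
    """Base class for package errors."""


class ConfigError(PlastexError):
    """Invalid configuration."""


class ParseError(PlastexError):
    """Malformed input table."""


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample.
        Values must be nonnegative integers (or within 1e-9 of one).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("count matrix contains non-numeric values")
        if np.isnan(values.astype(float)).any():
            raise ParseError("count matrix contains missing values")
        if (values < 0).any():
            gene = df.index[np.where(values < 0)[0][0]]
            raise ParseError(f"negative count at gene {gene!r}")
        rounded = np.rint(values.astype(float))
        if np.abs(values - rounded) .max(initial=0.0) > 1e-9:
            idx = np.unravel_index(
                np.argmax(np.abs(values - rounded)), values.shape
            )
            raise ParseError(
                f"non-integer count at gene {df.index[idx[0]]!r}, "
                f"sample {df.columns[idx[1]]!r}"
            )
        self.data = pd.DataFrame(
            rounded.astype(np.int64), index=df.index, columns=df.columns
        )
        self.data.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.data[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleDesign:
    """Per-sample design: taxon, group (population/inbred), condition."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "taxon", "group", "condition")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ParseError(f"design table missing columns: {missing}")
        df = df.astype({c: str for c in self.REQUIRED})
        if df["sample_id"].duplicated().any():
            raise ParseError("duplicate sample ids in design")
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise ParseError(
                f"unknown conditions {bad}; expected one of {CONDITIONS}"
            )
        if df[list(self.REQUIRED)].isna().any().any():
            raise ParseError("design table contains missing values")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def condition_indicator(self, sample_ids=None) -> np.ndarray:
        """1 for EH samples, 0 for MA (the reference)."""
        tbl = self.table.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return (
            tbl.loc[ids, "condition"].ne(REFERENCE_CONDITION)
        ).to_numpy(dtype=float)

    def groups(self, sample_ids=None) -> list[str]:
        tbl = self.table.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return tbl.loc[ids, "group"].tolist()

    def check_matches(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise ParseError(
                "design sample ids do not match count matrix sample ids"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets over a common background universe."""

    sets: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sets = {str(k): {str(g) for g in v} for k, v in self.sets.items()}
        self.background = {str(g) for g in self.background}

    def restricted(self, name: str) -> set[str]:
        """Set intersected with the background, warning on strays."""
        s = self.sets[name]
        if self.background and not s <= self.background:
            stray = len(s - self.background)
            warnings.warn(
                f"gene set {name!r}: {stray} ids outside background ignored",
                stacklevel=2,
            )
            return s & self.background
        return set(s)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)
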