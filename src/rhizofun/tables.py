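"""Core tabular containers: ASV count tables, soil-function matrices, sample metadata.

Conventions used throughout the package: ASV tables are taxa-in-rows,
samples-in-columns (the usual amplicon orientation); function matrices are
samples-in-rows. All containers wrap pandas objects and validate on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "FunctionMatrix",
    "SampleMetadata",
    "FormatError",
    "CANONICAL_FUNCTIONS",
    "KINGDOMS",
]


class FormatError(ValueError):
    """Raised when an input table violates the declared format."""


KINGDOMS = ("bacteria", "fungi")

#: The twelve soil ecosystem-function variables the pipeline expects by default:
#: alkaline phosphatase (ALP), available P (AP), total P (TP), microbial biomass
#: P (MBP), ammonium N (AN), nitrate N (NN), microbial biomass N (MBN), total N
#: (TN), urease (Ure), microbial biomass C (MBC), soil organic C (SOC) and
#: sucrase (SSC). Users may supply any other set; these are the canonical names.
CANONICAL_FUNCTIONS = (
    "ALP", "AP", "TP", "MBP", "AN", "NN", "MBN", "TN", "Ure", "MBC", "SOC", "SSC",
)


@dataclass
class AsvTable:
    """Counts of ASVs (rows) x samples (columns) for one kingdom.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = ASV ids, columns = sample ids.
    kingdom : str
        Either ``"bacteria"`` or ``"fungi"``.
    taxonomy : dict, optional
        Map from ASV id to an ordered lineage list (domain ... genus); lineages
        may be truncated. Every key must be an ASV id of the table.
    """

    counts: pd.DataFrame
    kingdom: str
    taxonomy: dict[str, list[str]] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise FormatError(f"unknown kingdom {self.kingdom!r}; expected one of {KINGDOMS}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate ASV ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if integral
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))[0]
                raise FormatError(
                    f"non-integer count at ASV {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at ASV {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.counts.index)
            if unknown:
                raise FormatError(f"taxonomy keys not in table: {sorted(unknown)[:5]}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; errors on a zero-total sample."""
        totals = self.sample_sums()
        zero = totals[totals == 0]
        if len(zero):
            raise FormatError(f"sample(s) with zero total count: {list(zero.index)}")
        return self.counts / totals


@dataclass
class FunctionMatrix:
    """Samples (rows) x measured soil functions (columns), in measurement units."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate function names")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"missing or non-finite value for sample "
                f"{self.values.index[bad[0]]!r}, function {self.values.columns[bad[1]]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def function_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Sample design table: treatment label and replicate number per sample."""

    table: pd.DataFrame  # index = sample id; columns: treatment, replicate

    def __post_init__(self) -> None:
        required = {"treatment", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing column(s): {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def treatments(self) -> pd.Series:
        return self.table["treatment"]

    def check_samples(self, sample_ids) -> None:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples missing from metadata: {sorted(missing)[:5]}")
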