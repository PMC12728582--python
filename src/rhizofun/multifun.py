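"""Soil multifunctionality indices.

Three indices summarise a samples x functions matrix of measured ecosystem
functions:

* the single-function indices: each function min–max standardised to [0, 1]
  across samples, ``STD = (X - X_min) / (X_max - X_min)``;
* the average multifunctionality index (AMI): the per-sample mean of the
  standardised functions, optionally restricted to element-cycling groups
  (carbon, nitrogen, phosphorus) to give AMI.C / AMI.N / AMI.P;
* the principal-coordinate multifunctionality index (PMI): the first five
  axes of a PCoA of Bray–Curtis distances between standardised function
  profiles, which spreads multifunctionality over several orthogonal
  dimensions so no single function dominates.

Bray–Curtis is computed on the standardised (unitless, non-negative) profiles;
raw measurements in heterogeneous units would make the dissimilarity
meaningless. PCoA axis signs are arbitrary, so each PMI axis is oriented to
correlate non-negatively with AMI (axis 1 then increases with overall
multifunctionality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import bray_curtis_matrix, pcoa
from .tables import FunctionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateRangeError",
    "MultifunResult",
    "standardize_minmax",
    "standardize_functions",
    "compute_ami",
    "compute_group_ami",
    "compute_pmi",
    "multifunctionality",
    "DEFAULT_GROUPS",
]


class DegenerateRangeError(ValueError):
    """Raised when min–max standardisation is requested for a constant vector."""


#: Default element-cycling membership of the twelve canonical functions.
#: C = carbon pools/enzymes, N = nitrogen, P = phosphorus. Overridable.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "C": ("SOC", "MBC", "SSC"),
    "N": ("TN", "AN", "NN", "MBN", "Ure"),
    "P": ("TP", "AP", "MBP", "ALP"),
}


def standardize_minmax(values) -> np.ndarray:
    """Min–max standardisation (X - X_min)/(X_max - X_min) onto [0, 1]."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError("all values identical; range is zero")
    return (x - lo) / (hi - lo)


def standardize_functions(fm: FunctionMatrix, on_degenerate: str = "error") -> pd.DataFrame:
    """Column-wise min–max standardisation of a function matrix.

    ``on_degenerate``: ``"error"`` aborts on a constant column (the default —
    silently dropping one would invisibly change AMI's denominator);
    ``"drop"`` removes it with a warning.
    """
    cols = {}
    for name in fm.function_names:
        try:
            cols[name] = standardize_minmax(fm.values[name].to_numpy())
        except DegenerateRangeError:
            if on_degenerate == "drop":
                logger.warning("dropping constant function column %r", name)
                continue
            raise DegenerateRangeError(f"function {name!r} is constant across samples")
    return pd.DataFrame(cols, index=fm.values.index)


@dataclass
class MultifunResult:
    std_matrix: pd.DataFrame
    ami: pd.Series
    group_ami: pd.DataFrame | None = None
    pmi: pd.DataFrame | None = None
    pmi_eigenvalues: np.ndarray | None = None
    group_map: dict | None = None


def compute_ami(fm: FunctionMatrix, on_degenerate: str = "error") -> MultifunResult:
    """Average multifunctionality index: row means of the standardised matrix."""
    std = standardize_functions(fm, on_degenerate=on_degenerate)
    ami = std.mean(axis=1)
    ami.name = "AMI"
    return MultifunResult(std_matrix=std, ami=ami)


def compute_group_ami(fm: FunctionMatrix, group_map: dict | None = None) -> pd.DataFrame:
    """Per-sample mean of standardised functions within each named group."""
    if group_map is None:
        group_map = {k: v for k, v in DEFAULT_GROUPS.items()}
    std = standardize_functions(fm)
    out = {}
    for group, members in group_map.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {group!r} is empty")
        unknown = [m for m in members if m not in std.columns]
        if unknown:
            raise KeyError(f"group {group!r} refers to unknown function(s) {unknown}")
        out[f"AMI.{group}"] = std[members].mean(axis=1)
    return pd.DataFrame(out, index=std.index)


def _orient_axis(axis: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip an ordination axis so it correlates non-negatively with the
    reference; if the correlation is ~0, orient the largest-magnitude
    coordinate positive."""
    a = axis - axis.mean()
    r = reference - reference.mean()
    denom = np.sqrt((a**2).sum() * (r**2).sum())
    corr = (a * r).sum() / denom if denom > 0 else 0.0
    if abs(corr) < 1e-12:
        pivot = np.argmax(np.abs(axis))
        return axis if axis[pivot] >= 0 else -axis
    return axis if corr >= 0 else -axis


def compute_pmi(fm: FunctionMatrix, n_axes: int = 5):
    """Principal-coordinate multifunctionality index.

    Returns ``(pmi, eigenvalues)``: per-sample scores on up to ``n_axes``
    leading PCoA axes of Bray–Curtis distances between standardised profiles.
    """
    std = standardize_functions(fm)
    zero_rows = std.index[(std.to_numpy() == 0).all(axis=1)]
    if len(zero_rows):
        raise ValueError(
            f"sample(s) {list(zero_rows)} have all-zero standardised profiles; "
            "Bray-Curtis is undefined for them"
        )
    d = bray_curtis_matrix(std.to_numpy())
    n = d.shape[0]
    if n - 1 < n_axes:
        logger.info("only %d axes available for %d samples", n - 1, n)
    coords, eigvals = pcoa(d, n_axes=n_axes)
    ami = std.mean(axis=1).to_numpy()
    for k in range(coords.shape[1]):
        coords[:, k] = _orient_axis(coords[:, k], ami)
    pmi = pd.DataFrame(
        coords,
        index=std.index,
        columns=[f"PMI.{k + 1}" for k in range(coords.shape[1])],
    )
    return pmi, eigvals


def multifunctionality(
    fm: FunctionMatrix,
    group_map: dict | None = None,
    n_axes: int = 5,
    on_degenerate: str = "error",
) -> MultifunResult:
    """All three multifunctionality indices in one result object."""
    res = compute_ami(fm, on_degenerate=on_degenerate)
    res.group_map = {k: tuple(v) for k, v in (group_map or DEFAULT_GROUPS).items()}
    res.group_ami = compute_group_ami(fm, group_map)
    res.pmi, res.pmi_eigenvalues = compute_pmi(fm, n_axes=n_axes)
    return res
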