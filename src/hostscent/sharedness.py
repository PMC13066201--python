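"""Degree-of-sharedness indices of volatile compounds among fruit species.

A compound's sharedness is the Shannon diversity (natural log) of the
per-species detection proportions: with proportions p_s renormalized to
q_s = p_s / sum(p_s), the index is -sum q_s ln q_s.  For 0/1 proportion
vectors this is exactly ln(k) for a compound present in k species, so it runs
from 0 (one species) to ln(S) (all S species).  Subset variants restrict the
proportion vectors to a species subset (e.g. the 13 heavily infested hosts)
before renormalizing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "detection_proportions",
    "sharedness_index",
    "sharedness_table",
    "subset_sharedness",
]


def detection_proportions(detection: pd.DataFrame,
                          species: pd.Series) -> pd.DataFrame:
    """Proportion of each species' samples in which each compound appears.

    ``detection`` is samples x compounds (binary), ``species`` maps each
    sample to its species label.  Returns compounds x species with values in
    [0, 1].
    """
    species = pd.Series(species)
    if species.isna().any() or len(species) != len(detection):
        raise ValueError("every sample must carry a species label")
    grouped = detection.groupby(species.to_numpy()).mean()
    return grouped.T  # compounds x species


def sharedness_index(proportions: Sequence[float] | np.ndarray) -> float:
    """Shannon sharedness of one compound's detection-proportion vector."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("compound emitted by no species: index undefined")
    q = p / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() + 0.0)  # avoid -0.0


def _index_rows(table: pd.DataFrame) -> pd.Series:
    p = table.to_numpy(float)
    total = p.sum(axis=1, keepdims=True)
    out = np.full(len(table), np.nan)
    present = total[:, 0] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        q = p[present] / total[present]
        contrib = np.where(q > 0, q * np.log(q), 0.0)
    out[present] = -contrib.sum(axis=1) + 0.0  # avoid -0.0
    return pd.Series(out, index=table.index)


def subset_sharedness(table: pd.DataFrame,
                      subset: Sequence[str]) -> pd.Series:
    """Sharedness over a species subset; NaN for compounds absent from it."""
    subset = list(subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    missing = set(subset) - set(table.columns)
    if missing:
        raise ValueError(f"unknown species in subset: {sorted(missing)}")
    return _index_rows(table[subset])


def sharedness_table(table: pd.DataFrame,
                     subsets: dict[str, Sequence[str]] | None = None,
                     ) -> pd.DataFrame:
    """Per-compound sharedness for the full species set and named subsets.

    ``table`` is a detection-proportion table (compounds x species).  The
    full-set column is named ``sharedness_<S>`` for S species; each entry of
    ``subsets`` adds a ``sharedness_<name>`` column (NaN where the compound
    is absent from every subset species).
    """
    out = {f"sharedness_{table.shape[1]}": _index_rows(table)}
    for name, sp in (subsets or {}).items():
        out[f"sharedness_{name}"] = subset_sharedness(table, sp)
    return pd.DataFrame(out)
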