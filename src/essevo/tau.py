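"""Tissue-specificity index tau from an FPKM expression matrix.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N tissues; 0 for uniform
expression, 1 for expression confined to a single tissue.  The index is
computed on raw FPKM by default; a log2(FPKM+1) option supports
alternative-definition comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: tissues removed by default before computing tau (male-cohort analysis)
FEMALE_SPECIFIC_TISSUES = frozenset({"ovary", "placenta", "uterus"})


def select_tissues(matrix: pd.DataFrame, mode: str = "exclude_female_specific",
                   female_specific=FEMALE_SPECIFIC_TISSUES) -> pd.DataFrame:
    """Return the tissue submatrix for the requested mode.

    ``exclude_female_specific`` drops the female-specific tissues (default
    ovary/placenta/uterus); ``all`` keeps every column.
    """
    if mode == "all":
        return matrix
    if mode != "exclude_female_specific":
        raise ValueError(f"unknown tissue mode {mode!r}")
    present = [t for t in matrix.columns if t in female_specific]
    missing = set(female_specific) - set(matrix.columns)
    if missing and not present:
        warnings.warn(
            f"none of the excluded tissues {sorted(female_specific)} are in "
            "the matrix; returning it unchanged"
        )
        return matrix
    if missing:
        raise ValueError(f"tissues not found in matrix: {sorted(missing)}")
    return matrix.drop(columns=present)


def compute_tau(profile, log_transform: bool = False) -> float | None:
    """tau for one expression profile; ``None`` when x_max == 0 (undefined)."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-d with at least two tissues")
    if np.any(x < 0) or not np.isfinite(x).all():
        raise ValueError("FPKM values must be finite and non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max()
    if xmax == 0.0:
        return None
    return float(np.sum(1.0 - x / xmax) / (len(x) - 1))


def tau_table(matrix: pd.DataFrame, mode: str = "exclude_female_specific",
              log_transform: bool = False):
    """Per-gene tau over the selected tissues.

    Returns ``(series, dropped)`` where ``dropped`` lists genes whose profile
    is all-zero (tau undefined; excluded rather than set to 0).
    """
    sub = select_tissues(matrix, mode=mode)
    values = {}
    dropped = []
    for gene, row in sub.iterrows():
        t = compute_tau(row.to_numpy(), log_transform=log_transform)
        if t is None:
            dropped.append(gene)
        else:
            values[gene] = t
    return pd.Series(values, name="tau"), dropped


def read_fpkm(path) -> pd.DataFrame:
    """Read a genes x tissues FPKM matrix from TSV (first column gene ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)
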