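"""Sample-wise and gene-wise normalization.

Two transforms are supported besides the identity:

* **z-score** — ``(x - mean) / sd`` with the (n-1) standard deviation used
  repo-wide; a constant vector maps to all zeros.
* **scaled robust sigmoid (SRS)** — an outlier-robust unit-interval transform:

  .. math:: y_i = \\frac{1}{1 + \\exp(-(x_i - \\mathrm{med}(x)) / (\\mathrm{IQR}(x)/1.35))}

  rescaled to ``(y - min) / (max - min)``.  The 1.35 constant converts the
  interquartile range to a normal-equivalent standard deviation.  When the
  IQR is zero the sd is used in the denominator; a fully constant vector maps
  to all 0.5.

Both transforms are invariant to positive affine transforms of their input.
Normalization is always applied per donor — its purpose is the removal of
donor-specific batch differences — and sample (row-wise) normalization
precedes gene (column-wise) normalization in the pipeline.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger("braintx")

METHODS = ("none", "zscore", "srs")

#: IQR -> normal-equivalent sd conversion used inside the robust sigmoid
SRS_IQR_CONSTANT = 1.35


def normalize_vector(x, method: str) -> np.ndarray:
    """Normalize a 1-D numeric vector with the given method."""
    if method not in METHODS:
        raise ParameterError(f"unknown normalization method {method!r}")
    x = np.asarray(x, float)
    if x.size == 0:
        raise ParameterError("cannot normalize an empty vector")
    if method == "none":
        return x.copy()
    if method == "zscore":
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    # srs
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    denom = (q75 - q25) / SRS_IQR_CONSTANT
    if denom == 0:
        denom = x.std(ddof=1) if x.size > 1 else 0.0
    if denom == 0 or not np.isfinite(denom):
        return np.full_like(x, 0.5)
    with np.errstate(over="ignore"):  # saturates cleanly at 0/1
        y = 1.0 / (1.0 + np.exp(-(x - med) / denom))
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (y - lo) / (hi - lo)


def normalize_samples(expression: pd.DataFrame, method: str) -> pd.DataFrame:
    """Row-wise normalization: each sample's gene vector is transformed.

    ``expression`` is one donor's sample x gene matrix.
    """
    if method == "none":
        return expression.copy()
    out = expression.copy()
    out.loc[:, :] = np.apply_along_axis(
        normalize_vector, 1, expression.to_numpy(float), method
    )
    return out


def normalize_genes(
    expression: pd.DataFrame,
    method: str,
    *,
    matched_only: bool = False,
    within_structures: bool = False,
    assigned: Optional[pd.Series] = None,
    structure_class: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Column-wise normalization: each gene is transformed across samples.

    Parameters
    ----------
    expression : one donor's sample x gene matrix (index = well_id).
    method : "none", "zscore" or "srs".
    matched_only : compute statistics on — and restrict the output to —
        samples assigned to an atlas region.  Requires ``assigned``.
    within_structures : apply the transform separately within each
        structure class present.  Requires ``structure_class``.  A class with
        fewer than 2 samples is passed through unchanged (logged).
    assigned : boolean Series over well_ids (True = matched to a region).
    structure_class : Series over well_ids giving each sample's class.
    """
    if method == "none":
        return expression.copy()
    if matched_only:
        if assigned is None:
            raise ParameterError("matched_only normalization requires assignments")
        keep = assigned.reindex(expression.index).fillna(False).astype(bool)
        expression = expression.loc[keep[keep].index]
    if within_structures:
        if structure_class is None:
            raise ParameterError(
                "within-structure normalization requires structure classes"
            )
        groups = structure_class.reindex(expression.index)
    else:
        groups = pd.Series("all", index=expression.index)

    out = expression.copy()
    for cls, idx in out.groupby(groups, sort=False).groups.items():
        block = out.loc[idx]
        if len(block) < 2:
            logger.warning(
                "structure class %r has %d sample(s); passed through unchanged",
                cls, len(block),
            )
            continue
        out.loc[idx, :] = np.apply_along_axis(
            normalize_vector, 0, block.to_numpy(float), method
        )
    return out
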