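"""Imputation, scaling and missing-data accounting for intensity matrices.

The processing chain mirrors how relative peak ion counts are prepared in a
seed metabolomics screen:

1. :func:`impute_minimum` — each below-detection cell receives the smallest
   intensity at which that metabolite was ever detected, on the assumption
   that the true value sits at or under the detection limit.
2. :func:`median_scale` — each metabolite is divided by the median of its
   *detected* values, so that the detected median equals 1.0 and compounds of
   wildly different ionisation efficiency become comparable.
3. :func:`log_transform` — elementwise log2 (or natural log) for display and
   for the multivariate analysis.

:func:`detection_frequency` and :func:`flag_high_missingness` account for how
often each compound fell below the detection limit; heavily null compounds are
carried through the univariate screen but flagged as unreliable, because
minimum imputation shrinks their apparent variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DetectionFrequencyTable:
    """Per (line, metabolite) detected fraction and per-metabolite null rate.

    ``per_line`` is a lines x metabolites frame of fractions in [0, 1];
    ``overall_null_fraction`` is the fraction of *all* samples in which the
    metabolite was missing.
    """

    per_line: pd.DataFrame
    overall_null_fraction: pd.Series
    line_sizes: pd.Series


def impute_minimum(matrix: IntensityMatrix) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Replace missing cells with the metabolite's observed minimum detected value.

    Metabolites never detected in any sample cannot be imputed; they are
    dropped from the panel with a logged warning.

    Returns the completed matrix and a boolean mask frame (``True`` where a
    cell was imputed), restricted to the retained metabolites.
    """
    values = matrix.values
    mask = values.isna()
    never_detected = mask.all(axis=0)
    if never_detected.any():
        dropped = list(values.columns[never_detected])
        logger.warning(
            "dropping %d metabolite(s) with no detected value: %s",
            len(dropped), dropped,
        )
        values = values.loc[:, ~never_detected]
        mask = mask.loc[:, ~never_detected]
    col_min = values.min(axis=0, skipna=True)
    filled = values.fillna(col_min)
    return matrix.with_values(filled), mask


def median_scale(
    matrix: IntensityMatrix, imputed_mask: pd.DataFrame | None = None
) -> IntensityMatrix:
    """Divide every metabolite column by the median of its detected values.

    ``imputed_mask`` (as returned by :func:`impute_minimum`) marks cells that
    were filled in; those are excluded from the median so imputation cannot
    move it.  After scaling, the median of detected values of every column is
    exactly 1.0.
    """
    if matrix.scale_state != "raw":
        raise ValueError(f"median_scale requires a raw matrix, got {matrix.scale_state!r}")
    values = matrix.values
    detected = values
    if imputed_mask is not None:
        detected = values.mask(imputed_mask.reindex_like(values).fillna(False).astype(bool))
    medians = detected.median(axis=0, skipna=True)
    zero = medians[medians == 0]
    if len(zero):
        raise ValueError(
            f"median of detected values is zero for metabolite(s): {list(zero.index)}"
        )
    return matrix.with_values(values / medians, scale_state="median_scaled")


def log_transform(matrix: IntensityMatrix, base: float = 2.0) -> IntensityMatrix:
    """Elementwise logarithm (base 2 or e) of a complete, positive matrix."""
    if matrix.scale_state != "median_scaled":
        raise ValueError(
            "log_transform applies to a median-scaled matrix "
            f"(scale chain raw -> median_scaled -> log), got {matrix.scale_state!r}"
        )
    values = matrix.values
    if values.isna().to_numpy().any():
        raise ValueError("log_transform requires a complete matrix (impute first)")
    nonpos = values <= 0
    if nonpos.to_numpy().any():
        cells = [
            (str(values.index[i]), str(values.columns[j]))
            for i, j in zip(*np.nonzero(nonpos.to_numpy()))
        ][:10]
        raise ValueError(f"non-positive value(s) at {cells}")
    if base in (2, 2.0):
        logged = np.log2(values)
    elif abs(base - np.e) < 1e-9:
        logged = np.log(values)
    else:
        raise ValueError("log base must be 2 or e")
    return matrix.with_values(logged, scale_state="log")


def detection_frequency(matrix: IntensityMatrix) -> DetectionFrequencyTable:
    """Fraction of each line's seeds in which each metabolite was detected."""
    if matrix.scale_state != "raw":
        raise ValueError("detection_frequency runs on the raw (pre-imputation) matrix")
    detected = matrix.values.notna()
    per_line = detected.groupby(matrix.design["line_id"]).mean()
    per_line.index.name = "line_id"
    overall_null = 1.0 - detected.mean(axis=0)
    overall_null.name = "overall_null_fraction"
    return DetectionFrequencyTable(
        per_line=per_line,
        overall_null_fraction=overall_null,
        line_sizes=matrix.line_sizes(),
    )


def flag_high_missingness(
    freqs: DetectionFrequencyTable, threshold: float = 0.5
) -> set[str]:
    """Metabolites whose overall null fraction strictly exceeds ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    null = freqs.overall_null_fraction
    return set(null.index[null > threshold])
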