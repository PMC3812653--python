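"""Dynamic range of each metabolite across the germplasm pool.

For every metabolite the natural dynamic range is the ratio of the highest
per-line mean to the lowest per-line mean across the pool of conventional
lines.  Ratios are taken on the median-scaled linear scale, where they are
invariant to the arbitrary per-compound ionisation efficiency.  Ranges are
then summarised by biochemical pathway class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

RATIO_BINS = (1.0, 2.0, 10.0, 100.0, np.inf)
RATIO_BIN_LABELS = ("[1,2)", "[2,10)", "[10,100)", "[100,inf)")


@dataclass
class LineMeans:
    """Per-line, per-metabolite means — the unit of inference.

    ``means`` is a lines x metabolites frame (lines sorted lexicographically);
    ``n_samples`` gives each line's replicate count; ``scale_state`` records
    the scale the means were taken on.
    """

    means: pd.DataFrame
    n_samples: pd.Series
    scale_state: str


def line_means(
    matrix: IntensityMatrix,
    lines=None,
    allow_missing: bool = False,
) -> LineMeans:
    """Arithmetic mean of each line's replicates, per metabolite.

    Requires a complete matrix (run :func:`~metabeq.preprocessing.impute_minimum`
    first) unless ``allow_missing`` is set, in which case means are taken over
    detected values only.
    """
    if lines is not None:
        matrix = matrix.subset_lines(lines)
    if not allow_missing and matrix.has_missing():
        raise ValueError("matrix has missing cells; impute first or pass allow_missing=True")
    grouped = matrix.values.groupby(matrix.design["line_id"])
    means = grouped.mean().sort_index()
    means.index.name = "line_id"
    return LineMeans(means=means, n_samples=grouped.size().sort_index(), scale_state=matrix.scale_state)


def dynamic_range(means: LineMeans) -> pd.DataFrame:
    """Highest/lowest line and their fold ratio, per metabolite.

    Ties in the extreme lines break toward the lexicographically smallest
    line id.  A metabolite whose minimum line mean is zero gets
    ``fold_ratio = inf`` and ``infinite_ratio = True``.

    Returns a frame indexed by metabolite with columns ``max_line``,
    ``min_line``, ``max_mean``, ``min_mean``, ``fold_ratio``, ``infinite_ratio``.
    """
    if means.scale_state == "log":
        raise ValueError("dynamic ranges are ratios of means on the linear scale, not log")
    m = means.means.sort_index()  # lexicographic line order fixes tie-breaks
    if (m.to_numpy() < 0).any():
        raise ValueError("negative line mean encountered; ranges need a non-negative scale")
    max_line = m.idxmax(axis=0)
    min_line = m.idxmin(axis=0)
    max_mean = m.max(axis=0)
    min_mean = m.min(axis=0)
    with np.errstate(divide="ignore"):
        ratio = max_mean / min_mean
    out = pd.DataFrame(
        {
            "max_line": max_line,
            "min_line": min_line,
            "max_mean": max_mean,
            "min_mean": min_mean,
            "fold_ratio": ratio,
            "infinite_ratio": ~np.isfinite(ratio),
        }
    )
    out.index.name = "metabolite_id"
    return out


def range_distribution_by_class(
    ranges: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Summarise fold ratios per pathway class.

    ``annotations`` maps metabolite_id -> pathway_class (see
    :func:`metabeq.io.read_annotations`); metabolites without a row are
    treated as "unannotated".

    Returns ``(per_class, fraction_below_10)`` where ``per_class`` has, for
    each class: metabolite count, median/min/max finite fold ratio, the count
    of infinite ratios, and counts in the bins [1,2), [2,10), [10,100),
    [100,inf) (infinite ratios land in the last bin).  ``fraction_below_10``
    is the overall fraction of metabolites with fold_ratio < 10.
    """
    ann = annotations.set_index("metabolite_id")["pathway_class"] if "metabolite_id" in annotations.columns else annotations["pathway_class"]
    classes = ranges.index.to_series().map(ann).fillna("unannotated")
    ratio = ranges["fold_ratio"]
    finite = ratio[np.isfinite(ratio)]

    rows = []
    for cls, idx in classes.groupby(classes).groups.items():
        r = ratio.loc[idx]
        fin = r[np.isfinite(r)]
        binned = np.histogram(np.clip(r, None, 1e18), bins=RATIO_BINS)[0]
        rows.append(
            {
                "pathway_class": cls,
                "n_metabolites": len(r),
                "median_fold_ratio": float(fin.median()) if len(fin) else np.nan,
                "min_fold_ratio": float(fin.min()) if len(fin) else np.nan,
                "max_fold_ratio": float(fin.max()) if len(fin) else np.nan,
                "n_infinite": int((~np.isfinite(r)).sum()),
                **{f"n_{lab}": int(c) for lab, c in zip(RATIO_BIN_LABELS, binned)},
            }
        )
    per_class = pd.DataFrame(rows).set_index("pathway_class").sort_index()
    fraction_below_10 = float((ratio < 10).mean())
    return per_class, fraction_below_10
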