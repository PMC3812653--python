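"""Tabular input/output and the end-to-end pipeline driver.

Input format: a wide CSV/TSV with the design columns (``sample_id``,
``line_id``, ``replicate``) followed by one column per metabolite holding
integrated peak ion counts.  Empty cells, ``NA`` and ``NaN``
(case-insensitive) mark below-detection values; a switch optionally treats
literal zero the same way, for upstream software that writes zeros for
undetected peaks.  The delimiter is inferred from the file extension
(``.csv`` comma, ``.tsv``/``.txt`` tab).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .matrix import InputError, IntensityMatrix
from .multivariate import assess_multivariate
from .natural_variation import dynamic_range, line_means, range_distribution_by_class
from .preprocessing import detection_frequency, impute_minimum, median_scale
from .univariate import pvalue_histogram, test_all_metabolites

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "na", "nan"}

DEFAULT_DESIGN_COLUMNS = {
    "sample_id": "sample_id",
    "line_id": "line_id",
    "replicate": "replicate",
}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_intensity_table(
    path,
    design_columns: dict | None = None,
    zero_as_missing: bool = False,
    transpose: bool = False,
) -> IntensityMatrix:
    """Read a wide intensity table into an :class:`IntensityMatrix`.

    ``design_columns`` maps the canonical names ``sample_id`` / ``line_id`` /
    ``replicate`` to the file's column names.  With ``transpose`` the file is
    oriented metabolites x samples and is flipped after reading (the design
    columns then appear as rows).
    """
    path = Path(path)
    cols = {**DEFAULT_DESIGN_COLUMNS, **(design_columns or {})}
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.set_index(raw.columns[0]).T.reset_index(names=cols["sample_id"])
    for canon in ("sample_id", "line_id", "replicate"):
        if cols[canon] not in raw.columns:
            raise InputError(f"missing design column {cols[canon]!r} in {path.name}")

    sample_ids = raw[cols["sample_id"]]
    dup = sample_ids[sample_ids.duplicated()]
    if len(dup):
        raise InputError(f"duplicate sample id(s): {sorted(dup.unique())}")

    design = pd.DataFrame(
        {
            "line_id": raw[cols["line_id"]].to_numpy(),
            "replicate": pd.to_numeric(raw[cols["replicate"]]).to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    met_cols = [c for c in raw.columns if c not in {cols[k] for k in cols}]
    parsed = {}
    for c in met_cols:
        col = raw[c].str.strip()
        is_missing = col.str.lower().isin(MISSING_TOKENS)
        numeric = pd.to_numeric(col.where(~is_missing), errors="coerce")
        bad = ~is_missing & numeric.isna()
        if bad.any():
            token = col[bad].iloc[0]
            raise InputError(
                f"unknown missing-value token {token!r} in column {c!r} of {path.name}"
            )
        if (numeric < 0).any():
            raise InputError(f"negative intensity in column {c!r} of {path.name}")
        if zero_as_missing:
            numeric = numeric.mask(numeric == 0)
        parsed[c] = numeric.to_numpy(dtype=float)
    values = pd.DataFrame(parsed, index=design.index, columns=met_cols)
    values.columns.name = "metabolite_id"
    logger.info("read %s: %d samples x %d metabolites", path.name, *values.shape)
    return IntensityMatrix(values=values, design=design, scale_state="raw")


def write_intensity_table(matrix: IntensityMatrix, path) -> None:
    """Write the matrix back out; missing cells become empty fields."""
    path = Path(path)
    out = pd.concat([matrix.design, matrix.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")


def read_annotations(path, metabolites=None) -> pd.DataFrame:
    """Read a metabolite annotation table (metabolite_id, pathway_class[, sub_pathway]).

    Metabolites listed in ``metabolites`` but absent from the file get
    pathway_class ``"unannotated"``.
    """
    path = Path(path)
    try:
        ann = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        ann = pd.DataFrame(columns=["metabolite_id", "pathway_class"])
    if len(ann) and not {"metabolite_id", "pathway_class"} <= set(ann.columns):
        raise InputError(f"{path.name} needs columns metabolite_id and pathway_class")
    dup = ann["metabolite_id"][ann["metabolite_id"].duplicated()] if len(ann) else []
    if len(dup):
        raise InputError(f"duplicate metabolite id(s) in annotations: {sorted(set(dup))}")
    if "sub_pathway" not in ann.columns:
        ann["sub_pathway"] = ""
    if metabolites is not None:
        known = set(ann["metabolite_id"]) if len(ann) else set()
        extra = [m for m in metabolites if m not in known]
        if extra:
            ann = pd.concat(
                [ann, pd.DataFrame({"metabolite_id": extra, "pathway_class": "unannotated",
                                    "sub_pathway": ""})],
                ignore_index=True,
            )
    return ann[["metabolite_id", "pathway_class", "sub_pathway"]]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _boxplot_stats(matrix: IntensityMatrix) -> pd.DataFrame:
    """Tukey five-number summary per line x metabolite on the current scale."""
    rows = []
    for line in matrix.lines:
        sub = matrix.values.loc[matrix.samples_of(line)]
        q1 = sub.quantile(0.25)
        q3 = sub.quantile(0.75)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for met in sub.columns:
            col = sub[met].dropna()
            out = col[(col < lo_fence[met]) | (col > hi_fence[met])]
            rows.append(
                {
                    "line_id": line,
                    "metabolite_id": met,
                    "n": len(col),
                    "mean": col.mean(),
                    "min": col.min(),
                    "q1": q1[met],
                    "median": col.median(),
                    "q3": q3[met],
                    "max": col.max(),
                    "outliers": ";".join(f"{v:.6g}" for v in out),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    matrix: IntensityMatrix,
    annotations: pd.DataFrame,
    outdir=None,
    n_components: int = 1,
) -> dict[str, pd.DataFrame]:
    """Profile the pool, screen the test line, and project it onto the PCA.

    Returns the result tables keyed by name; with ``outdir`` each is also
    written as a TSV.  Deterministic given inputs and config.
    """
    all_lines = matrix.lines
    baseline = config.resolve_baseline(all_lines)
    logger.info("pipeline: %d lines, %d baseline, test line %s",
                len(all_lines), len(baseline), config.test_line)

    ann = annotations.set_index("metabolite_id")["pathway_class"]

    freqs = detection_frequency(matrix)
    imputed, mask = impute_minimum(matrix)
    scaled = median_scale(imputed, mask)

    # natural variation over the conventional pool (baseline lines only)
    lm = line_means(scaled, lines=baseline)
    ranges = dynamic_range(lm)
    profile = ranges.copy()
    profile.insert(0, "pathway_class", profile.index.map(ann).fillna("unannotated"))
    class_summary, frac_lt10 = range_distribution_by_class(ranges, annotations)
    class_summary.attrs["fraction_below_10"] = frac_lt10
    logger.info("natural variation: %d metabolites, %.1f%% below 10-fold",
                len(profile), 100 * frac_lt10)

    equiv = test_all_metabolites(matrix, config)
    equiv = equiv.copy()
    equiv.insert(0, "pathway_class", equiv.index.map(ann).fillna("unannotated"))
    logger.info("univariate screen: %d results, %d outside the %.0f%% interval",
                len(equiv), int((~equiv["inside_interval"]).sum()),
                100 * (1 - config.alpha))

    counts, edges = pvalue_histogram(equiv["p_value"].to_numpy(), n_bins=20)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})

    model, pca_report = assess_multivariate(matrix, config, n_components=n_components)
    logger.info("PCA: PC1 explains %.1f%% of variance",
                100 * model.variance_explained[0])

    det = (100.0 * freqs.per_line).round(1)
    tables = {
        "natural_variation_profile": profile.reset_index(),
        "natural_variation_class_summary": class_summary.reset_index(),
        "equivalence_results": equiv.reset_index(),
        "pvalue_histogram": hist,
        "pca_report": pca_report,
        "pca_baseline_scores": model.baseline_scores.reset_index(names="line_id"),
        "detection_frequency": det.reset_index(),
        "boxplot_stats": _boxplot_stats(scaled),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            dest = outdir / f"{name}.tsv"
            table.to_csv(dest, sep="\t", index=False, na_rep="NA")
            logger.info("wrote %s (%d rows)", dest, len(table))
    return tables
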