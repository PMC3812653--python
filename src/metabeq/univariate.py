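"""Per-metabolite screen of a candidate line against the baseline pool.

Model
-----
For one metabolite, the intensity of seed *s* of line *i* is modelled with a
one-way random-effects decomposition

    y_is = mu + L_i + e_is,    L_i ~ N(0, sigma2_line),  e_is ~ N(0, sigma2_error),

with the line treated as the experimental unit.  Variance components are
estimated by the method of moments from the one-way ANOVA mean squares.  A
(1 - alpha) prediction interval for the mean of a *new* line of m seeds drawn
from the same pool is

    center +/- t_{1-alpha/2, k-1} * sqrt(s2_lm * (1 + 1/k)),

where ``center`` is the grand mean of the k baseline line means and ``s2_lm``
their sample variance.  For a balanced design, s2_lm equals
sigma2_line + sigma2_error/m by the method-of-moments identity, so the
interval combines both variance components automatically; when the candidate
line has a different number of seeds the component form is substituted.
Inverting the interval yields a two-sided p-value: the candidate's mean lies
inside the (1 - alpha) interval exactly when p > alpha.

Multiplicity over the metabolite panel is handled with Storey-Tibshirani
q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .config import RunConfig
from .matrix import ConfigError, IntensityMatrix
from .preprocessing import (
    detection_frequency,
    flag_high_missingness,
    impute_minimum,
    log_transform,
    median_scale,
)

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components for one metabolite.

    ``sigma2_line`` is truncated at zero for reporting;
    ``sigma2_line_untruncated`` keeps the raw moment estimate, which satisfies
    (balanced case) ``var(line means) = sigma2_line_untruncated + sigma2_error / m``.
    """

    sigma2_line: float
    sigma2_error: float
    ms_between: float
    ms_within: float
    df_between: int
    df_within: int
    n_per_line: float
    negative_truncated: bool
    sigma2_line_untruncated: float
    s2_line_means: float
    k: int


@dataclass
class PredictionInterval:
    center: float
    lower: float
    upper: float
    alpha: float
    df: int
    new_line_m: int
    degenerate: bool = False


def _mom_frame(values: pd.DataFrame, line_ids: pd.Series) -> pd.DataFrame:
    """Vectorised one-way ANOVA / method of moments, one column per metabolite.

    Unbalanced designs use the unweighted-means analysis: line means carry
    equal weight and the effective per-line size is the harmonic mean.
    """
    grouped = values.groupby(line_ids)
    n_i = grouped.size()
    k = len(n_i)
    if k < 2:
        raise ValueError("variance components need at least two lines")
    N = int(n_i.sum())
    lm = grouped.mean()
    s2_lm = lm.var(axis=0, ddof=1)
    within_var = grouped.var(ddof=1)
    ssw = within_var.mul(n_i - 1, axis=0).sum(axis=0)
    df_within = N - k
    ms_within = ssw / df_within if df_within > 0 else pd.Series(np.nan, index=values.columns)
    n_h = k / (1.0 / n_i).sum()  # harmonic mean; equals m when balanced
    ms_between = n_h * s2_lm
    sigma2_line_untrunc = s2_lm - ms_within / n_h
    out = pd.DataFrame(
        {
            "center": lm.mean(axis=0),
            "s2_line_means": s2_lm,
            "ms_within": ms_within,
            "ms_between": ms_between,
            "sigma2_error": ms_within,
            "sigma2_line_untruncated": sigma2_line_untrunc,
            "sigma2_line": sigma2_line_untrunc.clip(lower=0.0),
        }
    )
    out.attrs.update({"k": k, "df_between": k - 1, "df_within": df_within, "n_h": float(n_h)})
    return out


def variance_components_mom(groups) -> VarianceComponents:
    """Method-of-moments components from per-line replicate vectors.

    ``groups`` maps line_id -> sequence of replicate values.
    """
    if len(groups) < 2:
        raise ValueError("between-line variance is undefined with a single line")
    rows, labels = [], []
    for line, vals in groups.items():
        for v in np.asarray(vals, dtype=float):
            rows.append(v)
            labels.append(line)
    frame = pd.DataFrame({"y": rows})
    res = _mom_frame(frame, pd.Series(labels, index=frame.index))
    r = res.iloc[0]
    return VarianceComponents(
        sigma2_line=float(r["sigma2_line"]),
        sigma2_error=float(r["sigma2_error"]),
        ms_between=float(r["ms_between"]),
        ms_within=float(r["ms_within"]),
        df_between=res.attrs["df_between"],
        df_within=res.attrs["df_within"],
        n_per_line=res.attrs["n_h"],
        negative_truncated=bool(r["sigma2_line_untruncated"] < 0),
        sigma2_line_untruncated=float(r["sigma2_line_untruncated"]),
        s2_line_means=float(r["s2_line_means"]),
        k=res.attrs["k"],
    )


def _predictive_variance(
    line_means: np.ndarray,
    vc: VarianceComponents | None,
    new_line_m: int | None,
) -> float:
    """s2_lm, substituting components only when the new line's m differs."""
    if (
        vc is not None
        and new_line_m is not None
        and abs(new_line_m - vc.n_per_line) > 1e-12
    ):
        return vc.sigma2_line + vc.sigma2_error / new_line_m
    return float(np.var(line_means, ddof=1))


def new_line_prediction_interval(
    line_means,
    vc: VarianceComponents | None = None,
    new_line_m: int | None = None,
    alpha: float = 0.05,
) -> PredictionInterval:
    """(1 - alpha) prediction interval for the mean of a new line of m seeds."""
    line_means = np.asarray(line_means, dtype=float)
    k = line_means.size
    if k < 3:
        raise ValueError("need at least 3 baseline line means")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    center = float(line_means.mean())
    s2_lm = _predictive_variance(line_means, vc, new_line_m)
    df = k - 1
    if s2_lm <= 0.0:
        return PredictionInterval(center, center, center, alpha, df,
                                  new_line_m or 0, degenerate=True)
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * np.sqrt(s2_lm * (1.0 + 1.0 / k))
    return PredictionInterval(center, center - half, center + half, alpha, df,
                              new_line_m or 0)


def equivalence_p_value(
    line_means,
    new_line_mean: float,
    vc: VarianceComponents | None = None,
    new_line_m: int | None = None,
) -> float:
    """Two-sided p-value from inverting the new-line prediction interval.

    Equivalent to a t-test of the candidate mean against the baseline line
    means with predictive variance s2_lm * (1 + 1/k) and k - 1 df.
    """
    line_means = np.asarray(line_means, dtype=float)
    k = line_means.size
    if k < 3:
        raise ValueError("need at least 3 baseline line means")
    center = line_means.mean()
    s2_lm = _predictive_variance(line_means, vc, new_line_m)
    if s2_lm <= 0.0:
        return 1.0 if new_line_mean == center else 0.0
    t = (new_line_mean - center) / np.sqrt(s2_lm * (1.0 + 1.0 / k))
    return float(2.0 * stats.t.sf(abs(t), k - 1))


_LAMBDA_GRID = np.arange(0.0, 0.9001, 0.05)


def estimate_pi0(p_values) -> float:
    """Storey's null-proportion estimate via the natural-cubic-spline smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid 0, 0.05, ..., 0.90;
    a natural cubic spline through these points is evaluated at the largest
    grid value and clamped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in _LAMBDA_GRID])
    spline = CubicSpline(_LAMBDA_GRID, pi0_lambda, bc_type="natural")
    pi0 = float(spline(_LAMBDA_GRID[-1]))
    return min(max(pi0, np.finfo(float).eps), 1.0)


def storey_qvalues(p_values, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values.

    With fewer than 100 p-values the spline estimate of pi0 is unstable, so
    pi0 falls back to 1 (a logged notice); the procedure then reduces to
    Benjamini-Hochberg with the step-up minimum.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if m < 100:
            logger.info("fewer than 100 p-values: using pi0 = 1 (BH-equivalent)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def pvalue_histogram(p_values, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of p-values on [0, 1]; p = 1 lands in the last bin."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    p = np.asarray(p_values, dtype=float)
    counts, edges = np.histogram(p, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return counts, edges


def test_all_metabolites(
    matrix: IntensityMatrix, config: RunConfig
) -> pd.DataFrame:
    """Run the prediction-interval screen for every metabolite.

    The raw matrix is imputed and median-scaled; the screen runs on the
    scaled linear values unless ``config.test_on_log_scale`` is set.  One row
    per metabolite, with columns ``baseline_center``, ``pi_lower``,
    ``pi_upper``, ``new_line_mean``, ``p_value``, ``q_value``,
    ``inside_interval``, ``missingness_flagged``, ``all_null_in_test_line``,
    ``degenerate``; ``result.attrs`` carries ``pi0``, ``k`` and the baseline
    line ids.
    """
    if matrix.scale_state != "raw":
        raise ValueError("test_all_metabolites starts from the raw matrix")
    all_lines = matrix.lines
    baseline = config.resolve_baseline(all_lines)
    if config.test_line not in all_lines:
        raise ConfigError(f"test line {config.test_line!r} absent from the matrix")
    if len(baseline) < 3:
        raise ConfigError("need at least 3 baseline lines")

    freqs = detection_frequency(matrix)
    flagged = flag_high_missingness(freqs, config.missingness_flag_threshold)
    test_samples = matrix.samples_of(config.test_line)
    all_null_test = matrix.values.loc[test_samples].isna().all(axis=0)

    imputed, mask = impute_minimum(matrix)
    scaled = median_scale(imputed, mask)
    if config.test_on_log_scale:
        scaled = log_transform(scaled, config.log_base)
    working = scaled

    base = working.subset_lines(baseline)
    mom = _mom_frame(base.values, base.design["line_id"])
    k = mom.attrs["k"]
    df = k - 1
    n_h = mom.attrs["n_h"]

    balanced_match = abs(n_h - config.new_line_m) < 1e-12 and (
        base.line_sizes().nunique() == 1
    )
    if balanced_match:
        s2_lm = mom["s2_line_means"]
    else:
        s2_lm = mom["sigma2_line"] + mom["sigma2_error"] / config.new_line_m

    test_vals = working.values.loc[test_samples]
    new_mean = test_vals.mean(axis=0)

    center = mom["center"]
    pred_sd = np.sqrt(s2_lm.clip(lower=0.0) * (1.0 + 1.0 / k))
    degenerate = s2_lm <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = (new_mean - center) / pred_sd
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p = pd.Series(np.where(degenerate, np.where(new_mean == center, 1.0, 0.0), p),
                  index=center.index)

    t_crit = stats.t.ppf(1.0 - config.alpha / 2.0, df)
    half = np.where(degenerate, 0.0, t_crit * pred_sd)
    q, pi0 = storey_qvalues(p.to_numpy())

    result = pd.DataFrame(
        {
            "baseline_center": center,
            "pi_lower": center - half,
            "pi_upper": center + half,
            "new_line_mean": new_mean,
            "p_value": p,
            "q_value": q,
            "inside_interval": p > config.alpha,
            "missingness_flagged": center.index.isin(flagged),
            "all_null_in_test_line": all_null_test.reindex(center.index).fillna(False).astype(bool),
            "degenerate": degenerate,
        }
    )
    result.index.name = "metabolite_id"
    result.attrs.update(
        {"pi0": pi0, "k": k, "baseline_lines": baseline, "test_line": config.test_line,
         "alpha": config.alpha, "scale": working.scale_state}
    )
    logger.info(
        "tested %d metabolites: %s vs %d baseline lines (pi0=%.3f)",
        len(result), config.test_line, k, pi0,
    )
    return result
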