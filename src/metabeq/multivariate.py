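"""PCA of baseline line means with projection of held-out lines.

To avoid per-metabolite multiplicity altogether, the whole panel is reduced
to a handful of principal components: a PCA is fitted to the log-transformed,
per-metabolite standardised line means of the baseline pool, the held-out
candidate (and optionally parent) lines are projected onto the loadings, and
a t-based prediction interval on the baseline component scores says whether a
projected line looks like a new draw from the pool.

The PCA is computed by a thin SVD of the k x J standardised grid (J can far
exceed k); loadings are orientation-fixed so results are deterministic.

A subtlety with J >> k: the leading component partly chases sampling noise,
so the *in-sample* baseline scores have systematically larger spread than the
projection of a genuinely new line onto the same loadings.  A prediction
interval built from in-sample scores therefore over-covers badly.  The
default interval instead estimates the new-line score scale by leave-one-out
cross-validation: each baseline line is projected onto a PCA refitted
(including re-standardisation) without it, and the interval half-width is
t_{1-alpha/2, k-1} * rms(held-out scores) * sqrt(1 + 1/k).  The in-sample
("naive") construction remains available via ``method="naive"`` and is the
fallback when a model carries no cross-validated scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .matrix import ConfigError, IntensityMatrix
from .natural_variation import LineMeans, line_means
from .preprocessing import impute_minimum, log_transform, median_scale
from .univariate import PredictionInterval

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Centering/scaling vectors, loadings and baseline scores.

    ``loadings`` is an n_components x J array of orthonormal rows;
    ``variance_explained`` covers *all* computable components (so it sums
    to 1), ``baseline_scores`` the retained ones.
    """

    center: pd.Series
    scale: pd.Series
    loadings: np.ndarray
    variance_explained: np.ndarray
    baseline_scores: pd.DataFrame
    k: int
    n_components: int
    loo_scores: pd.DataFrame | None = None  # leave-one-out held-out scores

    @property
    def metabolites(self) -> pd.Index:
        return self.center.index


def standardize_line_means(
    means: LineMeans,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center and scale each metabolite column to mean 0, sample sd 1.

    Metabolites with zero variance across the baseline lines cannot be scaled
    and are dropped with a logged warning.  Returns ``(grid, center, scale)``.
    """
    m = means.means
    if m.shape[0] < 3:
        raise ValueError("need at least 3 baseline lines")
    center = m.mean(axis=0)
    scale = m.std(axis=0, ddof=1)
    zero = scale <= 0.0
    if zero.any():
        logger.warning(
            "dropping %d zero-variance metabolite(s) from the PCA: %s",
            int(zero.sum()), list(m.columns[zero])[:10],
        )
        m, center, scale = m.loc[:, ~zero], center[~zero], scale[~zero]
    grid = (m - center) / scale
    return grid, center, scale


def fit_pca(grid: pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """Thin-SVD principal components of a standardised lines x metabolites grid.

    Orientation convention: within each loading the entry of largest
    magnitude is positive (first such column on ties), making the
    decomposition deterministic.
    """
    k, j = grid.shape
    if k < 3:
        raise ValueError("need at least 3 lines")
    z = grid.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # orientation: largest-|entry| loading coordinate made positive
    for c in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    total = float((s**2).sum())
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    max_rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components is None:
        n_components = max_rank
    n_components = min(n_components, max_rank) if max_rank else 0
    scores = u[:, :n_components] * s[:n_components]
    model = PCAModel(
        center=pd.Series(0.0, index=grid.columns),  # grid already centered
        scale=pd.Series(1.0, index=grid.columns),
        loadings=vt[:n_components].copy(),
        variance_explained=var_explained,
        baseline_scores=pd.DataFrame(
            scores, index=grid.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        k=k,
        n_components=n_components,
    )
    return model


def _loo_held_out_scores(means: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Project each line onto a PCA refitted without it (re-standardised).

    Folds whose rank cannot support a component leave ``NaN`` there.
    """
    k = means.shape[0]
    m = means.to_numpy(dtype=float)
    out = np.full((k, n_components), np.nan)
    for i in range(k):
        rest = np.delete(m, i, axis=0)
        center = rest.mean(axis=0)
        scale = rest.std(axis=0, ddof=1)
        keep = scale > 0
        z = (rest[:, keep] - center[keep]) / scale[keep]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        x = (m[i, keep] - center[keep]) / scale[keep]
        nc = min(n_components, rank)
        out[i, :nc] = vt[:nc] @ x
    return pd.DataFrame(out, index=means.index,
                        columns=[f"PC{c + 1}" for c in range(n_components)])


def fit_standardized_pca(means: LineMeans, n_components: int | None = None) -> PCAModel:
    """Standardise baseline line means and fit the PCA in one step.

    The returned model's ``center``/``scale`` map *unstandardised* log-scale
    line-mean vectors into the model space, so held-out lines can be
    projected directly; cross-validated held-out scores are attached for the
    calibrated score interval.
    """
    grid, center, scale = standardize_line_means(means)
    model = fit_pca(grid, n_components)
    model.center = center
    model.scale = scale
    model.loo_scores = _loo_held_out_scores(means.means, model.n_components)
    return model


def project_line(model: PCAModel, line_mean_vector: pd.Series) -> np.ndarray:
    """Component scores of a new line's (log-scale) mean vector."""
    missing = model.metabolites.difference(line_mean_vector.index)
    if len(missing):
        raise KeyError(f"line mean vector lacks metabolite(s): {list(missing)[:10]}")
    x = line_mean_vector.reindex(model.metabolites).to_numpy(dtype=float)
    z = (x - model.center.to_numpy()) / model.scale.to_numpy()
    return model.loadings @ z


def pc_prediction_interval(
    model: PCAModel,
    component: int = 1,
    alpha: float = 0.05,
    method: str = "calibrated",
) -> PredictionInterval:
    """t prediction interval for a new line's score on one component.

    Baseline scores are centered by construction, so the interval is
    0 +/- t_{1-alpha/2, k-1} * s * sqrt(1 + 1/k), where ``s`` estimates the
    score scale of a *new* line: the rms of the leave-one-out held-out scores
    (``method="calibrated"``, the default) or the in-sample baseline score
    standard deviation (``method="naive"``, which over-covers when the
    metabolite count far exceeds the line count).  Models fitted without
    cross-validated scores fall back to the naive estimate.
    """
    if not 1 <= component <= model.n_components:
        raise ValueError(f"component {component} not retained (1..{model.n_components})")
    if method not in ("calibrated", "naive"):
        raise ValueError(f"unknown method {method!r}")
    k = model.k
    df = k - 1
    sd = None
    if method == "calibrated" and model.loo_scores is not None:
        held_out = model.loo_scores.iloc[:, component - 1].dropna().to_numpy()
        if held_out.size >= 3:
            sd = float(np.sqrt(np.mean(held_out**2)))
    if sd is None:
        sd = float(np.std(model.baseline_scores.iloc[:, component - 1], ddof=1))
    if sd <= 0.0:
        return PredictionInterval(0.0, 0.0, 0.0, alpha, df, 0, degenerate=True)
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * sd * np.sqrt(1.0 + 1.0 / k)
    return PredictionInterval(0.0, -half, half, alpha, df, 0)


def assess_multivariate(
    matrix: IntensityMatrix,
    config: RunConfig,
    n_components: int = 1,
) -> tuple[PCAModel, pd.DataFrame]:
    """Full multivariate path: preprocess, fit baseline PCA, project test lines.

    The raw matrix is imputed, median-scaled and log-transformed; line means
    are taken on the log scale; the PCA baseline excludes the test and parent
    lines.  Returns the fitted model and a report frame with one row per
    (component, projected line): columns ``component``,
    ``variance_explained``, ``pi_lower``, ``pi_upper``, ``line_id``,
    ``score``, ``inside``.
    """
    if matrix.scale_state != "raw":
        raise ValueError("assess_multivariate starts from the raw matrix")
    all_lines = matrix.lines
    baseline = config.resolve_baseline(all_lines)
    test_lines = [config.test_line]
    if config.parent_line is not None:
        if config.parent_line not in all_lines:
            raise ConfigError(f"parent line {config.parent_line!r} absent from the matrix")
        test_lines.append(config.parent_line)

    imputed, mask = impute_minimum(matrix)
    logged = log_transform(median_scale(imputed, mask), config.log_base)
    lm_all = line_means(logged)
    base_means = LineMeans(
        means=lm_all.means.loc[baseline],
        n_samples=lm_all.n_samples.loc[baseline],
        scale_state="log",
    )
    model = fit_standardized_pca(base_means, n_components)

    rows = []
    for comp in range(1, model.n_components + 1):
        pi = pc_prediction_interval(model, comp, config.alpha)
        for line in test_lines:
            score = float(project_line(model, lm_all.means.loc[line])[comp - 1])
            rows.append(
                {
                    "component": comp,
                    "variance_explained": float(model.variance_explained[comp - 1]),
                    "pi_lower": pi.lower,
                    "pi_upper": pi.upper,
                    "line_id": line,
                    "score": score,
                    "inside": bool(pi.lower <= score <= pi.upper),
                }
            )
    report = pd.DataFrame(rows)
    report.attrs.update({"alpha": config.alpha, "baseline_lines": baseline})
    return model, report
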