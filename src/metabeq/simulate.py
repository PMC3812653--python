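"""Synthetic seed-metabolome panels with known ground truth.

The generator realises the same model the analysis assumes: on the log2
scale, the intensity of seed *s* of line *i* for metabolite *j* is

    log2 y_isj = mu_j + L_ij + e_isj,
    L_ij ~ N(0, sigma_line_j^2),   e_isj ~ N(0, sigma_error_j^2),

exponentiated to raw ion-count-like intensities.  Per-metabolite parameters
(mu_j, sigma_line_j, sigma_error_j) are drawn uniformly from configured
ranges; targeted perturbations add a log-fold shift to specific
line x metabolite cells; an optional detection limit censors the lowest
fraction of each metabolite's values to missing.

All draws come from one ``numpy.random.default_rng`` stream in a fixed,
documented order (mu, sigma_line, sigma_error, line effects, seed errors),
so a panel is reproducible from its seed on any platform.

The module also hosts the simulation studies (calibration, coverage,
parameter recovery, spike detection) used to validate the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .matrix import IntensityMatrix
from .natural_variation import dynamic_range, line_means
from .preprocessing import impute_minimum, median_scale
from .univariate import _mom_frame, test_all_metabolites
from .multivariate import assess_multivariate

logger = logging.getLogger(__name__)

DEFAULT_PATHWAY_CLASSES = (
    "amino acid",
    "carbohydrate",
    "lipid",
    "cofactor",
    "nucleotide",
    "peptide",
    "secondary metabolite",
)


@dataclass
class SyntheticConfig:
    """Generating parameters for a germplasm panel.

    Defaults emulate the study design this package targets: 49 lines x 8
    seeds x 169 metabolites, between-line SDs spanning tightly regulated
    (~1.4-fold range) to highly variable (>200-fold) compounds on the log2
    scale, and moderate within-line replicate noise.
    """

    n_lines: int = 49
    n_seeds_per_line: int = 8
    n_metabolites: int = 169
    grand_mean_log_range: tuple[float, float] = (10.0, 20.0)  # log2 ion counts
    sigma_line_range: tuple[float, float] = (0.05, 1.4)       # log2
    sigma_error_range: tuple[float, float] = (0.1, 0.4)       # log2
    detection_quantile: float = 0.1
    perturbations: tuple[tuple[str, str, float], ...] = ()
    pathway_classes: tuple[str, ...] = DEFAULT_PATHWAY_CLASSES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.grand_mean_log_range, self.sigma_line_range, self.sigma_error_range):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) is not well-ordered")
        if not 0.0 <= self.detection_quantile < 1.0:
            raise ValueError("detection_quantile must lie in [0, 1)")
        if self.n_lines < 3:
            raise ValueError("need at least 3 lines")

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"M{j + 1:03d}" for j in range(self.n_metabolites)]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a generated panel."""

    mu: pd.Series                  # per-metabolite grand mean, log2
    sigma_line: pd.Series          # per-metabolite between-line SD, log2
    sigma_error: pd.Series         # per-metabolite within-line SD, log2
    line_effects: pd.DataFrame     # lines x metabolites realised L_ij, log2
    perturbations: tuple[tuple[str, str, float], ...]
    detection_limit: pd.Series     # per-metabolite limit on the raw scale (NaN = none)
    config: SyntheticConfig


def simulate_panel(config: SyntheticConfig) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Generate a complete (uncensored) raw-intensity panel plus its truth."""
    rng = np.random.default_rng(config.rng_seed)
    lines = config.line_ids
    mets = config.metabolite_ids
    n_l, n_s, n_m = config.n_lines, config.n_seeds_per_line, config.n_metabolites

    mu = rng.uniform(*config.grand_mean_log_range, size=n_m)
    sigma_line = rng.uniform(*config.sigma_line_range, size=n_m)
    sigma_error = rng.uniform(*config.sigma_error_range, size=n_m)
    line_eff = rng.standard_normal((n_l, n_m)) * sigma_line
    errors = rng.standard_normal((n_l * n_s, n_m)) * np.repeat(sigma_error[None, :], n_l * n_s, axis=0)

    log_vals = mu[None, :] + np.repeat(line_eff, n_s, axis=0) + errors

    sample_ids = [f"{line}_s{r + 1}" for line in lines for r in range(n_s)]
    design = pd.DataFrame(
        {
            "line_id": np.repeat(lines, n_s),
            "replicate": np.tile(np.arange(1, n_s + 1), n_l),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(
        np.exp2(log_vals), index=design.index, columns=pd.Index(mets, name="metabolite_id")
    )
    matrix = IntensityMatrix(values=values, design=design, scale_state="raw")
    truth = SyntheticTruth(
        mu=pd.Series(mu, index=mets),
        sigma_line=pd.Series(sigma_line, index=mets),
        sigma_error=pd.Series(sigma_error, index=mets),
        line_effects=pd.DataFrame(line_eff, index=pd.Index(lines, name="line_id"), columns=mets),
        perturbations=(),
        detection_limit=pd.Series(np.nan, index=mets),
        config=config,
    )
    if config.perturbations:
        matrix, truth = apply_perturbations(matrix, truth, config.perturbations)
    return matrix, truth


def apply_perturbations(
    matrix: IntensityMatrix,
    truth: SyntheticTruth,
    perturbations,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Multiply named line x metabolite cells by 2**delta (delta on log2 scale)."""
    values = matrix.values.copy()
    ledger = list(truth.perturbations)
    for line_id, met_id, delta in perturbations:
        if line_id not in set(matrix.design["line_id"]):
            raise KeyError(f"perturbation names unknown line {line_id!r}")
        if met_id not in values.columns:
            raise KeyError(f"perturbation names unknown metabolite {met_id!r}")
        samples = matrix.samples_of(line_id)
        values.loc[samples, met_id] *= 2.0 ** delta
        ledger.append((line_id, met_id, float(delta)))
    return matrix.with_values(values), replace(truth, perturbations=tuple(ledger))


def apply_censoring(
    matrix: IntensityMatrix,
    truth: SyntheticTruth,
    detection_quantile: float | None = None,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Censor each metabolite's lowest values below its detection limit.

    The limit is the per-metabolite ``detection_quantile`` quantile of the
    generated values; cells strictly below it become missing.
    """
    q = truth.config.detection_quantile if detection_quantile is None else detection_quantile
    if not 0.0 <= q < 1.0:
        raise ValueError("detection_quantile must lie in [0, 1)")
    if q == 0.0:
        return matrix, replace(truth, detection_limit=pd.Series(np.nan, index=matrix.metabolites))
    limits = matrix.values.quantile(q, axis=0)
    censored = matrix.values.mask(matrix.values.lt(limits, axis=1))
    return matrix.with_values(censored), replace(truth, detection_limit=limits)


def annotations_for(config: SyntheticConfig) -> pd.DataFrame:
    """Annotation table cycling the configured pathway classes over metabolites."""
    classes = [config.pathway_classes[j % len(config.pathway_classes)]
               for j in range(config.n_metabolites)]
    return pd.DataFrame(
        {
            "metabolite_id": config.metabolite_ids,
            "pathway_class": classes,
            "sub_pathway": "",
        }
    )


def recover_parameters(
    matrix: IntensityMatrix, truth: SyntheticTruth
) -> tuple[pd.DataFrame, dict]:
    """Compare method-of-moments components to the generating parameters.

    Components are estimated on the log2 scale of the (imputed, if censored)
    raw intensities.  Bias is assessed with the *untruncated* between-line
    estimate, since truncation at zero is positively biased by construction
    for near-zero components.

    Returns a per-metabolite frame and a summary dict with median relative
    biases and RMSEs.
    """
    if matrix.has_missing():
        matrix, _ = impute_minimum(matrix)
    logvals = np.log2(matrix.values)
    mom = _mom_frame(logvals, matrix.design["line_id"])
    s2_line_true = (truth.sigma_line.loc[mom.index] ** 2)
    s2_err_true = (truth.sigma_error.loc[mom.index] ** 2)
    report = pd.DataFrame(
        {
            "sigma2_line_true": s2_line_true,
            "sigma2_line_est": mom["sigma2_line_untruncated"],
            "sigma2_error_true": s2_err_true,
            "sigma2_error_est": mom["sigma2_error"],
        }
    )
    report["rel_bias_line"] = report["sigma2_line_est"] / report["sigma2_line_true"] - 1.0
    report["rel_bias_error"] = report["sigma2_error_est"] / report["sigma2_error_true"] - 1.0
    def _median(col: pd.Series) -> float:
        finite = col[np.isfinite(col)]
        return float(finite.median()) if len(finite) else float("nan")

    summary = {
        "median_rel_bias_sigma2_line": _median(report["rel_bias_line"]),
        "median_rel_bias_sigma2_error": _median(report["rel_bias_error"]),
        "rmse_sigma2_line": float(np.sqrt(((report["sigma2_line_est"] - report["sigma2_line_true"]) ** 2).mean())),
        "rmse_sigma2_error": float(np.sqrt(((report["sigma2_error_est"] - report["sigma2_error_true"]) ** 2).mean())),
    }
    return report, summary


# ---------------------------------------------------------------------------
# Simulation studies used by the validation suite and the acceptance script.
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def null_calibration_study(
    n_panels: int = 20,
    n_baseline: int = 48,
    n_seeds: int = 8,
    n_metabolites: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error and univariate PI coverage on null panels.

    Each panel has ``n_baseline + 1`` lines; the extra line is held out and
    screened against the baseline pool.  Under the null every line is a draw
    from the same pool, so the fraction of p < alpha estimates the size of
    the test and 1 - coverage of the (1 - alpha) interval.
    """
    seeds = _spawn_seeds(seed, n_panels)
    n_tested = 0
    n_reject = 0
    n_covered = 0
    for s in seeds:
        cfg = SyntheticConfig(
            n_lines=n_baseline + 1,
            n_seeds_per_line=n_seeds,
            n_metabolites=n_metabolites,
            detection_quantile=0.0,
            rng_seed=int(s),
        )
        matrix, _ = simulate_panel(cfg)
        test_line = cfg.line_ids[-1]
        run = RunConfig(test_line=test_line, alpha=alpha, new_line_m=n_seeds)
        res = test_all_metabolites(matrix, run)
        n_tested += len(res)
        n_reject += int((res["p_value"] < alpha).sum())
        n_covered += int(res["inside_interval"].sum())
    return {
        "fraction_p_below_alpha": n_reject / n_tested,
        "pi_coverage": n_covered / n_tested,
        "n_tests": n_tested,
        "n_panels": n_panels,
    }


def pc1_coverage_study(
    n_replicates: int = 200,
    n_baseline: int = 48,
    n_seeds: int = 8,
    n_metabolites: int = 169,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Coverage of the PC1 score prediction interval for a held-out null line."""
    seeds = _spawn_seeds(seed, n_replicates)
    covered = 0
    for s in seeds:
        cfg = SyntheticConfig(
            n_lines=n_baseline + 1,
            n_seeds_per_line=n_seeds,
            n_metabolites=n_metabolites,
            detection_quantile=0.0,
            rng_seed=int(s),
        )
        matrix, _ = simulate_panel(cfg)
        run = RunConfig(test_line=cfg.line_ids[-1], alpha=alpha, new_line_m=n_seeds)
        _, report = assess_multivariate(matrix, run, n_components=1)
        covered += int(report["inside"].iloc[0])
    return {"pc1_coverage": covered / n_replicates, "n_replicates": n_replicates}


def recovery_study(
    n_baseline: int = 48,
    n_seeds: int = 8,
    n_metabolites: int = 500,
    seed: int = 0,
) -> dict:
    """Parameter recovery on one uncensored panel of baseline lines."""
    cfg = SyntheticConfig(
        n_lines=n_baseline,
        n_seeds_per_line=n_seeds,
        n_metabolites=n_metabolites,
        detection_quantile=0.0,
        rng_seed=int(seed) % (2**31),
    )
    matrix, truth = simulate_panel(cfg)
    _, summary = recover_parameters(matrix, truth)
    summary["n_metabolites"] = n_metabolites
    return summary


def simulate_spiked_panel(
    config: SyntheticConfig,
    test_line: str | None = None,
    delta_log2: float = 2.0,
    target: str | None = None,
) -> tuple[IntensityMatrix, SyntheticTruth, str]:
    """Panel with one metabolite shifted in the test line.

    The scenario emulates an engineered-pathway compound: unless ``target``
    names a metabolite explicitly, the spike lands on the metabolite with the
    smallest between-line SD, i.e. a tightly regulated compound whose
    engineered shift dwarfs its natural variation — the situation in which a
    single-pathway perturbation stands out against germplasm-wide variation.
    """
    matrix, truth = simulate_panel(replace(config, perturbations=()))
    if test_line is None:
        test_line = config.line_ids[-1]
    if target is None:
        target = str(truth.sigma_line.idxmin())
    matrix, truth = apply_perturbations(matrix, truth, [(test_line, target, delta_log2)])
    return matrix, truth, target


def spike_detection_study(
    n_panels: int = 100,
    delta_log2: float = 2.0,
    q_threshold: float = 0.1,
    seed: int = 0,
) -> dict:
    """How often the spiked metabolite attains the minimum q and q < threshold."""
    seeds = _spawn_seeds(seed, n_panels)
    min_q_hits = 0
    q_below = 0
    for s in seeds:
        cfg = SyntheticConfig(rng_seed=int(s), detection_quantile=0.0)
        matrix, truth, target = simulate_spiked_panel(cfg, delta_log2=delta_log2)
        test_line = cfg.line_ids[-1]
        run = RunConfig(test_line=test_line, q_threshold=q_threshold)
        res = test_all_metabolites(matrix, run)
        min_q_hits += int(res["q_value"].idxmin() == target)
        q_below += int(res.loc[target, "q_value"] < q_threshold)
    return {
        "min_q_rate": min_q_hits / n_panels,
        "q_below_threshold_rate": q_below / n_panels,
        "n_panels": n_panels,
        "delta_log2": delta_log2,
    }


def realized_dynamic_range(config: SyntheticConfig | None = None) -> dict:
    """Realised fold-ratio endpoints of a default panel's conventional pool."""
    cfg = config or SyntheticConfig()
    matrix, _ = simulate_panel(cfg)
    imputed, mask = impute_minimum(matrix)
    scaled = median_scale(imputed, mask)
    ranges = dynamic_range(line_means(scaled))
    finite = ranges.loc[~ranges["infinite_ratio"], "fold_ratio"]
    return {
        "min_fold_ratio": float(finite.min()),
        "max_fold_ratio": float(finite.max()),
        "n_metabolites": len(ranges),
    }
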