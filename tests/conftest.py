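import numpy as np
import pandas as pd
import pytest

from metabeq import IntensityMatrix, SyntheticConfig, simulate_panel


def make_matrix(columns: dict, line_of_sample=None, scale_state="raw") -> IntensityMatrix:
    """Build a small IntensityMatrix from {metabolite: values} columns.

    Sample ids are s1..sn; by default each sample is its own line, or pass
    ``line_of_sample`` as a list of line ids (replicates numbered within line).
    """
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    n = len(values)
    values.index = pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id")
    lines = line_of_sample if line_of_sample is not None else [f"line{i + 1}" for i in range(n)]
    reps = []
    seen = {}
    for ln in lines:
        seen[ln] = seen.get(ln, 0) + 1
        reps.append(seen[ln])
    design = pd.DataFrame({"line_id": lines, "replicate": reps}, index=values.index)
    return IntensityMatrix(values=values, design=design, scale_state=scale_state)


@pytest.fixture(scope="session")
def default_panel():
    """One default-sized synthetic panel (49 lines x 8 seeds x 169 metabolites)."""
    return simulate_panel(SyntheticConfig(rng_seed=0))


@pytest.fixture
def small_panel():
    """A quick 10-line x 4-seed x 20-metabolite panel."""
    cfg = SyntheticConfig(n_lines=10, n_seeds_per_line=4, n_metabolites=20,
                          detection_quantile=0.0, rng_seed=7)
    return simulate_panel(cfg)
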