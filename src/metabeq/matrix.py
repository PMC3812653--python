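"""Sample-by-metabolite intensity container shared by every pipeline stage.

The matrix holds integrated peak ion counts (or values derived from them),
one row per individual seed, one column per metabolite, with ``NaN`` marking
intensities below the instrument detection limit.  A parallel design table
maps each sample to its line (genetic background) and replicate index.

The ``scale_state`` tag tracks where a matrix sits in the fixed processing
chain ``raw -> median_scaled -> log``; the preprocessing functions refuse to
apply a step out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALE_STATES = ("raw", "median_scaled", "log")

DESIGN_COLUMNS = ("line_id", "replicate")


class InputError(ValueError):
    """Malformed input table (duplicates, negative intensities, bad tokens)."""


class ConfigError(ValueError):
    """Inconsistent run configuration (e.g. test line in the baseline set)."""


@dataclass
class IntensityMatrix:
    """Seed-level intensities plus the sample design.

    Parameters
    ----------
    values
        ``samples x metabolites`` frame of non-negative floats; ``NaN`` is a
        below-detection (missing) cell.  Index holds unique sample ids.
    design
        Frame indexed identically to ``values`` with columns ``line_id`` and
        ``replicate``.
    scale_state
        One of ``"raw"``, ``"median_scaled"``, ``"log"``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if not self.values.index.equals(self.design.index):
            raise InputError("values and design must share the same sample index")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample id(s): {dups}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise InputError(f"design table lacks required column {col!r}")
        # replicate indices must be unique within a line
        dup_rep = self.design.duplicated(subset=["line_id", "replicate"])
        if dup_rep.any():
            bad = self.design.loc[dup_rep, ["line_id", "replicate"]].iloc[0]
            raise InputError(
                f"duplicate replicate {bad['replicate']!r} within line {bad['line_id']!r}"
            )
        vals = self.values.to_numpy(dtype=float, copy=False)
        if self.scale_state != "log":
            with np.errstate(invalid="ignore"):
                if np.any(vals < 0):
                    rows, cols = np.nonzero(vals < 0)
                    cell = (self.values.index[rows[0]], self.values.columns[cols[0]])
                    raise InputError(f"negative intensity at sample={cell[0]!r}, metabolite={cell[1]!r}")
        if not np.all(np.isfinite(vals) | np.isnan(vals)):
            raise InputError("non-finite intensity value present")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def lines(self) -> list[str]:
        return sorted(self.design["line_id"].unique())

    def samples_of(self, line_id: str) -> pd.Index:
        mask = self.design["line_id"] == line_id
        if not mask.any():
            raise KeyError(f"unknown line {line_id!r}")
        return self.design.index[mask]

    def line_sizes(self) -> pd.Series:
        """Number of seed replicates per line."""
        return self.design.groupby("line_id").size()

    def subset_lines(self, lines) -> "IntensityMatrix":
        lines = list(lines)
        unknown = set(lines) - set(self.design["line_id"])
        if unknown:
            raise KeyError(f"unknown line(s): {sorted(unknown)}")
        mask = self.design["line_id"].isin(lines)
        return replace(self, values=self.values.loc[mask], design=self.design.loc[mask])

    def with_values(self, values: pd.DataFrame, scale_state: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            values=values,
            design=self.design.loc[values.index],
            scale_state=self.scale_state if scale_state is None else scale_state,
        )

    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())
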