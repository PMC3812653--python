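"""Run configuration for an equivalence assessment."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .matrix import ConfigError


@dataclass
class RunConfig:
    """Which lines form the baseline pool, which line is on trial, and the
    statistical knobs of the screen.

    ``baseline_lines`` empty means "every line except the test and parent
    lines", resolved against the matrix at run time.
    """

    test_line: str
    baseline_lines: frozenset[str] = frozenset()
    parent_line: str | None = None
    alpha: float = 0.05
    new_line_m: int = 8
    missingness_flag_threshold: float = 0.5
    q_threshold: float = 0.1
    log_base: float = 2.0
    zero_as_missing: bool = False
    test_on_log_scale: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.baseline_lines = frozenset(self.baseline_lines)
        if self.test_line in self.baseline_lines:
            raise ConfigError(f"test line {self.test_line!r} is in the baseline set")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.missingness_flag_threshold <= 1.0:
            raise ConfigError("missingness_flag_threshold must be in (0, 1]")
        if self.new_line_m < 1:
            raise ConfigError("new_line_m must be a positive integer")
        if self.log_base not in (2, 2.0) and abs(self.log_base - 2.718281828459045) > 1e-9:
            raise ConfigError("log_base must be 2 or e")

    def resolve_baseline(self, all_lines) -> list[str]:
        """Baseline line ids, excluding test and parent, in sorted order."""
        all_lines = set(all_lines)
        if self.test_line not in all_lines:
            raise ConfigError(f"test line {self.test_line!r} not present in the data")
        if self.baseline_lines:
            missing = set(self.baseline_lines) - all_lines
            if missing:
                raise ConfigError(f"baseline line(s) absent from the data: {sorted(missing)}")
            return sorted(self.baseline_lines)
        excluded = {self.test_line}
        if self.parent_line is not None:
            excluded.add(self.parent_line)
        return sorted(all_lines - excluded)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        if "baseline_lines" in data and data["baseline_lines"] is not None:
            data["baseline_lines"] = frozenset(data["baseline_lines"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_lines"] = sorted(self.baseline_lines)
        return d
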