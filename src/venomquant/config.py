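"""Run configuration: a flat YAML file of paths and stage parameters."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

import yaml

from .records import InputError, ParameterError

_PATH_KEYS = ("trace", "lanes", "ms1", "peptides", "fasta", "annotations",
              "expression")


@dataclass
class RunConfig:
    """Validated configuration for a quantification run.

    Input paths may be omitted in fixture mode (they are then generated).
    Every numeric default is the pipeline-wide default documented on the
    corresponding stage function.
    """

    trace: str | None = None
    lanes: str | None = None
    ms1: str | None = None
    peptides: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    expression: str | None = None

    baseline_window: float = 6.0
    min_prominence: float | None = None
    min_area_fraction: float = 0.001
    rt_tolerance: float = 1.0
    exclude: list = field(default_factory=list)
    identity_threshold: float = 0.95
    max_internal_insertion: int = 50
    min_unique_peptides: int = 1
    il_equivalent: bool = True
    report_decimals: int = 1
    seed: int = 0
    fixture: dict | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.baseline_window <= 0:
            problems.append("baseline_window must be > 0")
        if self.min_prominence is not None and self.min_prominence < 0:
            problems.append("min_prominence must be >= 0")
        if not 0 <= self.min_area_fraction < 1:
            problems.append("min_area_fraction must be in [0, 1)")
        if self.rt_tolerance <= 0:
            problems.append("rt_tolerance must be > 0")
        if not 0 < self.identity_threshold <= 1:
            problems.append("identity_threshold must be in (0, 1]")
        if self.max_internal_insertion < 0:
            problems.append("max_internal_insertion must be >= 0")
        if self.min_unique_peptides < 1:
            problems.append("min_unique_peptides must be >= 1")
        if self.report_decimals < 0:
            problems.append("report_decimals must be >= 0")
        if self.fixture is None:
            for key in _PATH_KEYS:
                p = getattr(self, key)
                if key == "expression":
                    if p is not None and not os.path.exists(p):
                        problems.append(f"{key}: no such file {p!r}")
                    continue
                if p is None:
                    problems.append(f"{key}: path required (no fixture mode)")
                elif not os.path.exists(p):
                    problems.append(f"{key}: no such file {p!r}")
        elif self.fixture is not None and "seed" not in self.fixture:
            problems.append("fixture mode requires an explicit fixture.seed")
        if problems:
            raise ParameterError("invalid configuration:\n  " + "\n  ".join(problems))


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys and every out-of-range
    value are reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config {path!r} is not a key/value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParameterError(f"invalid configuration:\n  unknown keys: {unknown}")
    return RunConfig(**raw)
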