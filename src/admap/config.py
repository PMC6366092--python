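"""Run configuration: documented keys, defaults, YAML loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Every tunable the pipeline honours, with its default.

    C: calibration constant of the density law rho_av = C / N (matches the
       15-Å real-distance-map density);
    max_M: largest separation range with statistics (covers k <= 10 * max_M);
    min_count: observations needed for a table entry to be significant;
    band: separation band counted per residue for disorder prediction;
    theta_preset: 'accw' (0.62) or 'accp' (0.53);
    half_width: smoothing window half-width in residues;
    fit_degree: polynomial degree of the disorder-probability fit;
    min_height / min_span: peak criterion and minimum compact-region span;
    min_coverage: training-exclusion rule for calibration proteins;
    seed: seed for any seeded generation step.
    """

    C: float = 36.12
    max_M: int = 9
    min_count: int = 10
    band: tuple[int, int] = (9, 29)
    theta_preset: str = "accw"
    theta: float | None = None  # raw override; wins over the preset
    half_width: int = 5
    fit_degree: int = 3
    min_height: float = 0.01
    min_span: int = 20
    min_coverage: float = 0.10
    seed: int = 0

    def resolved_theta(self) -> float:
        from .disorder import THRESHOLD_PRESETS

        if self.theta is not None:
            return float(self.theta)
        if self.theta_preset not in THRESHOLD_PRESETS:
            raise ConfigError(
                f"unknown theta preset {self.theta_preset!r}; "
                f"use one of {sorted(THRESHOLD_PRESETS)}"
            )
        return THRESHOLD_PRESETS[self.theta_preset]

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML key-value config file, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    if "band" in raw:
        raw["band"] = tuple(raw["band"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
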