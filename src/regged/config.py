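"""Flat key-value configuration files for the CLI.

Format: one ``key = value`` pair per line, ``#`` comments, blank lines
ignored.  Keys are validated against the simulation configuration at
startup; unknown keys are an error, not a warning.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .calibration import LinearMap
from .simulate import SimulationConfig

__all__ = ["ConfigError", "parse_config_file", "simulation_config_from_file"]


class ConfigError(ValueError):
    """A configuration file is malformed or contains unknown/invalid keys."""


def parse_config_file(path: str | Path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}: line {lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in stripped.split("=", 1))
        if not key:
            raise ConfigError(f"{path}: line {lineno}: empty key")
        if key in pairs:
            raise ConfigError(f"{path}: line {lineno}: duplicate key {key!r}")
        pairs[key] = value
    return pairs


_INT_KEYS = {"n_probesets", "n_samples_per_compartment", "seed"}
_FLOAT_KEYS = {
    "baseline_mean",
    "baseline_sd",
    "noise_sd",
    "enriched_fraction",
    "enrichment_effect",
    "distortion_slope",
    "distortion_intercept",
}


def simulation_config_from_file(path: str | Path) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a flat config file.

    ``distortion_slope`` / ``distortion_intercept`` set the affine
    compartment distortion; all other keys map directly onto the config
    fields.
    """
    raw = parse_config_file(path)
    known = _INT_KEYS | _FLOAT_KEYS
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")

    kwargs: dict[str, object] = {}
    slope = intercept = None
    defaults = SimulationConfig()
    for key, value in raw.items():
        try:
            if key == "distortion_slope":
                slope = float(value)
            elif key == "distortion_intercept":
                intercept = float(value)
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        except ValueError:
            raise ConfigError(f"{path}: invalid value {value!r} for key {key!r}") from None
    if slope is not None or intercept is not None:
        kwargs["distortion"] = LinearMap(
            slope=slope if slope is not None else defaults.distortion.slope,
            intercept=intercept if intercept is not None else defaults.distortion.intercept,
        )
    try:
        return SimulationConfig(**kwargs)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
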