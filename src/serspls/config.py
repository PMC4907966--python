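"""Run configuration: YAML/JSON parsing into the package's domain objects."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocess import WindowSet
from .synth import (
    DEFAULT_AXIS_SPEC,
    AnalyteLibrary,
    Band,
    NoiseConfig,
    build_axis,
    default_libraries,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parsed run configuration shared by the CLI subcommands."""

    axis_spec: tuple[float, float, float] = DEFAULT_AXIS_SPEC
    libraries: dict[str, AnalyteLibrary] = field(default_factory=default_libraries)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    window_k: float = 3.0
    windows: dict[str, WindowSet] | None = None
    replicates: int = 5
    max_components: int = 10

    def __post_init__(self) -> None:
        if self.windows is not None:
            undefined = set(self.windows) - set(self.libraries)
            if undefined:
                raise ValueError(f"windows reference undefined analytes: {sorted(undefined)}")

    @property
    def axis(self) -> np.ndarray:
        return build_axis(*self.axis_spec)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "axis" in raw:
            ax = raw["axis"]
            kwargs["axis_spec"] = (float(ax["start"]), float(ax["stop"]), float(ax["step"]))
        if "libraries" in raw:
            kwargs["libraries"] = {
                name: AnalyteLibrary(name, tuple(Band(*map(float, b)) for b in bands))
                for name, bands in raw["libraries"].items()
            }
        if "noise" in raw:
            kwargs["noise"] = NoiseConfig(**raw["noise"])
        if "windows" in raw:
            win = dict(raw["windows"])
            if "k" in win:
                kwargs["window_k"] = float(win.pop("k"))
            if win:
                kwargs["windows"] = {
                    name: WindowSet(name, tuple((float(lo), float(hi)) for lo, hi in ivs))
                    for name, ivs in win.items()
                }
        for key in ("replicates", "max_components"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config; None gives defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(raw)
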