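"""Unified pipeline configuration.

Every threshold in the pipeline lives in one TOML file with sections
``[raster]``, ``[tree_mask]``, ``[delineation]``, ``[accuracy]`` and
``[synthetic]`` — there are no hidden defaults outside this module, because
the spectral thresholds are sensor- and season-specific and must be
re-tunable in one place.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .accuracy import DBH_MIN_CM
from .delineation import SpeciesThresholds, SplitConfig
from .mask import MaskConfig
from .synthetic import SceneSpec

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RasterOptions:
    nir_role: str = "nir1"
    red_role: str = "red"
    coarse_factor: int = 4


@dataclass
class AccuracyOptions:
    dbh_min_cm: float = DBH_MIN_CM
    plot_side_m: float = 50.0


_SECTION_TYPES = {
    "raster": RasterOptions,
    "tree_mask": MaskConfig,
    "delineation": SplitConfig,
    "accuracy": AccuracyOptions,
    "synthetic": SceneSpec,
}


@dataclass
class PipelineConfig:
    raster: RasterOptions = field(default_factory=RasterOptions)
    tree_mask: MaskConfig = field(default_factory=MaskConfig)
    delineation: SplitConfig = field(default_factory=SplitConfig)
    accuracy: AccuracyOptions = field(default_factory=AccuracyOptions)
    synthetic: SceneSpec = field(default_factory=SceneSpec)
    species_thresholds: SpeciesThresholds = field(
        default_factory=SpeciesThresholds)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        kwargs = {}
        species = None
        for section, content in data.items():
            if section == "species_thresholds":
                deltas = {}
                for key, pair in content.items():
                    if not key.startswith("type_"):
                        raise ConfigError(
                            f"species_thresholds keys are type_N, got {key!r}")
                    deltas[int(key.split("_")[1])] = (float(pair[0]),
                                                      float(pair[1]))
                species = SpeciesThresholds(deltas)
                continue
            if section not in _SECTION_TYPES:
                raise ConfigError(f"unknown config section [{section}]")
            typ = _SECTION_TYPES[section]
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(content) - valid
            if unknown:
                raise ConfigError(
                    f"unknown keys in [{section}]: {sorted(unknown)}")
            content = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in content.items()}
            kwargs[section] = typ(**content)
        cfg = cls(**kwargs)
        if species is not None:
            cfg.species_thresholds = species
        return cfg

    def to_toml(self) -> str:
        """Serialise; round-trips through :meth:`from_toml`."""
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, str):
                return f'"{v}"'
            if isinstance(v, tuple):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            return repr(v)

        lines = []
        for section in _SECTION_TYPES:
            obj = getattr(self, section)
            lines.append(f"[{section}]")
            for f in dataclasses.fields(obj):
                lines.append(f"{f.name} = {fmt(getattr(obj, f.name))}")
            lines.append("")
        lines.append("[species_thresholds]")
        for t in sorted(self.species_thresholds.deltas):
            nd, ni = self.species_thresholds.deltas[t]
            lines.append(f"type_{t} = [{nd!r}, {ni!r}]")
        return "\n".join(lines) + "\n"
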