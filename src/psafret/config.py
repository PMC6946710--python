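"""TOML run configuration with strict key validation."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .anisotropy import OpticsConfig
from .errors import ConfigError
from .simulate import CameraModel, OligomerModel, SceneGeometry, SwitchingParams

_ALLOWED: dict[str, set[str]] = {
    "paths": {"stack", "reference", "rois", "output"},
    "optics": {"na", "refractive_index", "g_factor", "apply_axelrod"},
    "fit": {"cutoff", "low_signal_frac"},
    "simulate": {
        "n_subunits",
        "r_mono",
        "r_et",
        "coupling",
        "d_over_r0",
        "p_off_per_frame",
        "n_frames",
        "photons_per_fluor",
        "read_noise_sd",
        "offset",
        "gain",
        "n_oligomers",
        "seed",
        "height",
        "half_width",
        "channel_offset",
    },
}


@dataclass
class RunConfig:
    """Validated configuration for the CLI workflows."""

    paths: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def optics_config(self, **overrides) -> OpticsConfig:
        kw = dict(self.optics)
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return OpticsConfig(
            numerical_aperture=kw.get("na", 1.4),
            refractive_index=kw.get("refractive_index", 1.515),
            g_factor=kw.get("g_factor", 1.0),
            apply_axelrod=bool(kw.get("apply_axelrod", False)),
        )

    def oligomer_model(self) -> OligomerModel:
        s = self.simulate
        return OligomerModel(
            n_subunits=int(s.get("n_subunits", 2)),
            r_mono=s.get("r_mono", 0.35),
            r_et=s.get("r_et", 0.0),
            coupling=s.get("coupling"),
            d_over_r0=s.get("d_over_r0"),
        )

    def switching_params(self) -> SwitchingParams:
        s = self.simulate
        return SwitchingParams(
            p_off_per_frame=s.get("p_off_per_frame", 0.08),
            n_frames=int(s.get("n_frames", 50)),
        )

    def camera_model(self) -> CameraModel:
        s = self.simulate
        return CameraModel(
            photons_per_fluor=s.get("photons_per_fluor", 200.0),
            read_noise_sd=s.get("read_noise_sd", 2.0),
            offset=s.get("offset", 100.0),
            gain=s.get("gain", 1.0),
        )

    def scene_geometry(self) -> SceneGeometry:
        s = self.simulate
        geo = SceneGeometry()
        if "height" in s:
            geo.height = int(s["height"])
        if "half_width" in s:
            geo.half_width = int(s["half_width"])
        if "channel_offset" in s:
            geo.channel_offset = tuple(int(v) for v in s["channel_offset"])
        return geo


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a TOML config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML in {path}: {exc}") from exc

    for section, content in raw.items():
        if section not in _ALLOWED:
            raise ConfigError(
                f"unknown config section [{section}]; expected one of {sorted(_ALLOWED)}"
            )
        if not isinstance(content, dict):
            raise ConfigError(f"section [{section}] must be a table")
        unknown = set(content) - _ALLOWED[section]
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in [{section}]; "
                f"allowed: {sorted(_ALLOWED[section])}"
            )
    return RunConfig(
        paths=raw.get("paths", {}),
        optics=raw.get("optics", {}),
        fit=raw.get("fit", {}),
        simulate=raw.get("simulate", {}),
    )
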