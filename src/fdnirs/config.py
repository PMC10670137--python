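"""Run configuration: a YAML document validated into typed stage objects.

Every tunable of the pipeline lives here with the protocol's printed
constants as defaults (10.4 Hz sampling, 110 MHz modulation, 690/830 nm,
2-3.5 cm separations, 0.02-0.7 Hz band, R^2 gate 0.97, 6 s analysis
window). Errors name the offending field by its dotted path so a bad config
fails loudly before anything runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .extinction import ExtinctionTable
from .preprocess import FilterSpec
from .simulate import (
    DEFAULT_BASELINE_UM,
    DEFAULT_FS_HZ,
    DEFAULT_MUSP_CM,
    HemodynamicResponseModel,
    NoiseModel,
    default_amplitudes,
)
from .types import EPOCHS, MODALITIES, PARADIGMS, Geometry


class ConfigError(ValueError):
    """Invalid configuration; message carries the dotted field path."""


@dataclass
class RunConfig:
    subjects: dict[str, list[str]] = field(
        default_factory=lambda: {"s01": ["cTBS", "iTBS"]}
    )
    seed: int = 0
    geometry: Geometry = field(default_factory=Geometry)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    hrf: HemodynamicResponseModel = field(default_factory=HemodynamicResponseModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    extinction: ExtinctionTable = field(default_factory=ExtinctionTable)
    baseline_uM: tuple[float, float] = DEFAULT_BASELINE_UM
    musp_cm: tuple[float, ...] = DEFAULT_MUSP_CM
    fs_hz: float = DEFAULT_FS_HZ
    r2_threshold: float = 0.97
    baseline_mode: str = "onset-sample"
    window_s: float = 6.0
    max_invalid_fraction: float = 1.0 / 3.0
    alpha: float = 0.05
    output_dir: str = "fdnirs_out"

    def to_dict(self) -> dict:
        return {
            "subjects": self.subjects,
            "seed": self.seed,
            "geometry": {
                "distances_cm": list(self.geometry.distances_cm),
                "wavelengths_nm": list(self.geometry.wavelengths_nm),
                "modulation_frequency_hz": self.geometry.modulation_frequency_hz,
                "refractive_index": self.geometry.refractive_index,
            },
            "filter": {
                "low_cut_hz": self.filter_spec.low_cut_hz,
                "high_cut_hz": self.filter_spec.high_cut_hz,
                "taps": self.filter_spec.taps,
            },
            "hrf": self.hrf.to_dict(),
            "noise": self.noise.to_dict(),
            "extinction": self.extinction.to_dict(),
            "baseline_uM": list(self.baseline_uM),
            "musp_cm": list(self.musp_cm),
            "fs_hz": self.fs_hz,
            "r2_threshold": self.r2_threshold,
            "baseline_mode": self.baseline_mode,
            "window_s": self.window_s,
            "max_invalid_fraction": self.max_invalid_fraction,
            "alpha": self.alpha,
            "output_dir": self.output_dir,
        }


def _require(mapping, key, kind, path, default=None):
    if key not in mapping:
        if default is not None:
            return default
        raise ConfigError(f"{path}.{key}: missing required field")
    value = mapping[key]
    if kind is float and isinstance(value, int):
        value = float(value)
    if not isinstance(value, kind):
        raise ConfigError(
            f"{path}.{key}: expected {getattr(kind, '__name__', kind)}, "
            f"got {type(value).__name__}"
        )
    return value


def _parse_amplitudes(raw: dict, path: str) -> dict:
    out = {}
    for key, value in raw.items():
        parts = str(key).split("|")
        if len(parts) != 3:
            raise ConfigError(
                f"{path}.{key}: amplitude keys are 'modality|epoch|paradigm'"
            )
        modality, epoch, paradigm = parts
        if modality not in MODALITIES or epoch not in EPOCHS or paradigm not in PARADIGMS:
            raise ConfigError(f"{path}.{key}: unknown condition label")
        out[(modality, epoch, paradigm)] = float(value)
    return out


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config: top level must be a mapping")
    cfg = RunConfig()
    try:
        if "subjects" in raw:
            subjects = raw["subjects"]
            if not isinstance(subjects, dict) or not subjects:
                raise ConfigError("config.subjects: must be a non-empty mapping")
            for sid, paradigms in subjects.items():
                if not isinstance(paradigms, list) or not paradigms:
                    raise ConfigError(f"config.subjects.{sid}: must be a non-empty list")
                for p in paradigms:
                    if p not in PARADIGMS:
                        raise ConfigError(
                            f"config.subjects.{sid}: unknown paradigm {p!r} "
                            f"(expected one of {list(PARADIGMS)})"
                        )
            cfg.subjects = {str(k): [str(p) for p in v] for k, v in subjects.items()}
        if "seed" in raw:
            cfg.seed = _require(raw, "seed", int, "config")
        if "geometry" in raw:
            g = raw["geometry"]
            cfg.geometry = Geometry(
                distances_cm=tuple(g.get("distances_cm", Geometry().distances_cm)),
                wavelengths_nm=tuple(g.get("wavelengths_nm", Geometry().wavelengths_nm)),
                modulation_frequency_hz=float(
                    g.get("modulation_frequency_hz", Geometry().modulation_frequency_hz)
                ),
                refractive_index=float(
                    g.get("refractive_index", Geometry().refractive_index)
                ),
            )
        if "filter" in raw:
            f = raw["filter"]
            cfg.filter_spec = FilterSpec(
                low_cut_hz=float(f.get("low_cut_hz", 0.02)),
                high_cut_hz=float(f.get("high_cut_hz", 0.7)),
                taps=int(f.get("taps", 1001)),
            )
        if "hrf" in raw:
            h = raw["hrf"]
            cfg.hrf = HemodynamicResponseModel(
                amplitudes=_parse_amplitudes(
                    h.get("amplitudes_pct",
                          {"|".join(k): v for k, v in default_amplitudes().items()}),
                    "config.hrf.amplitudes_pct",
                ),
                peak_latency_s=float(h.get("peak_latency_s", 3.5)),
                dispersion_s=float(h.get("dispersion_s", 1.5)),
                hbo2_share=float(h.get("hbo2_share", 0.8)),
            )
        if "noise" in raw:
            nz = raw["noise"]
            defaults = NoiseModel()
            cfg.noise = NoiseModel(
                cardiac=tuple(nz.get("cardiac", defaults.cardiac)),
                respiratory=tuple(nz.get("respiratory", defaults.respiratory)),
                mayer=tuple(nz.get("mayer", defaults.mayer)),
                drift_sd_pct=float(nz.get("drift_sd_pct", defaults.drift_sd_pct)),
                optical_rel_sd=float(nz.get("optical_rel_sd", defaults.optical_rel_sd)),
                phase_sd_rad=float(nz.get("phase_sd_rad", defaults.phase_sd_rad)),
                artifact_rate_per_min=float(
                    nz.get("artifact_rate_per_min", defaults.artifact_rate_per_min)
                ),
                artifact_magnitude=float(
                    nz.get("artifact_magnitude", defaults.artifact_magnitude)
                ),
                artifact_duration_s=float(
                    nz.get("artifact_duration_s", defaults.artifact_duration_s)
                ),
            )
        if "extinction" in raw:
            table = {
                float(w): {str(c): float(e) for c, e in row.items()}
                for w, row in raw["extinction"].items()
            }
            cfg.extinction = ExtinctionTable(table)
        if "baseline_uM" in raw:
            b = raw["baseline_uM"]
            if isinstance(b, dict):
                cfg.baseline_uM = (float(b["HbO2"]), float(b["HHb"]))
            else:
                cfg.baseline_uM = (float(b[0]), float(b[1]))
        if "musp_cm" in raw:
            cfg.musp_cm = tuple(float(m) for m in raw["musp_cm"])
        for key, kind in (
            ("fs_hz", float), ("r2_threshold", float), ("window_s", float),
            ("max_invalid_fraction", float), ("alpha", float),
        ):
            if key in raw:
                setattr(cfg, key, _require(raw, key, kind, "config"))
        if "baseline_mode" in raw:
            mode = raw["baseline_mode"]
            if mode not in ("onset-sample", "pre-window"):
                raise ConfigError(
                    "config.baseline_mode: must be 'onset-sample' or 'pre-window'"
                )
            cfg.baseline_mode = mode
        if "output_dir" in raw:
            cfg.output_dir = str(raw["output_dir"])
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"config: {exc}") from exc
    if cfg.fs_hz <= 2 * cfg.filter_spec.high_cut_hz:
        raise ConfigError("config.fs_hz: must exceed twice the filter high cut")
    if len(cfg.musp_cm) != cfg.geometry.n_wavelengths:
        raise ConfigError("config.musp_cm: one value per geometry wavelength required")
    return cfg


def load_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    return config_from_dict(raw or {})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False),
                          encoding="utf-8")
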