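"""Flat key-value configuration shared by the CLI and the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .registration import GridSpec


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, with the standard defaults.

    Physical scales are in micrometres.  ``sigma_um`` is the Gaussian scale
    of the G2 ridge filters (1.8 um, the calibre of an axon bundle); set
    ``sigma_is_fwhm`` to reinterpret that width as FWHM.
    ``smoothing_sigma_um`` is the direction-field smoothing length (30 um,
    well above the axon-scale noise, below the trajectory scale).
    ``axis_order`` only affects how (m, p) tuples are written in output
    headers; the internal convention is always m first.
    """

    sigma_um: float = 1.8
    sigma_is_fwhm: bool = False
    pixel_size_um: float | None = None
    threshold_factor: float = 2.0
    smoothing_sigma_um: float = 30.0
    nms_flank_mode: str = "interpolated"  # or "snapped"
    saturation_level: float | None = None
    channel: int | None = None
    grid_rows: int = 32
    grid_cols: int = 32
    region_m: tuple[float, float] = (0.4, 0.6)
    region_p: tuple[float, float] = (0.05, 0.25)
    alpha: float = 0.05
    chiasm_side: int = 1
    axis_order: str = "mp"  # or "pm"
    eye_distance_limit: float = 0.08
    second_nms_target: str = "response"  # or "curvature"

    def __post_init__(self) -> None:
        if self.nms_flank_mode not in {"interpolated", "snapped"}:
            raise InvalidParameterError(
                f"nms_flank_mode must be interpolated|snapped, got {self.nms_flank_mode!r}"
            )
        if self.axis_order not in {"mp", "pm"}:
            raise InvalidParameterError("axis_order must be 'mp' or 'pm'")
        if self.second_nms_target not in {"response", "curvature"}:
            raise InvalidParameterError(
                "second_nms_target must be 'response' or 'curvature'"
            )

    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.grid_rows,
            n_cols=self.grid_cols,
            m_range=tuple(self.region_m),
            p_range=tuple(self.region_p),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_m"] = list(d["region_m"])
        d["region_p"] = list(d["region_p"])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("region_m", "region_p"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
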