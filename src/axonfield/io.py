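"""Tabular text I/O: landmark files, vector tables, binned maps, manifests.

Every output table starts with ``#`` header lines naming the coordinate
convention, the units and the configuration hash, so any file can be traced
back to the exact parameters that produced it.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InputFormatError
from .registration import BinnedSample, EmbryoLandmarks, GridSpec

_CONVENTION = (
    "coordinates: x=column (px), y=row (px, downward); angles: radians from +x "
    "toward +y; orientations axial in [0, pi); normalized frame: left eye -> "
    "(m=0, p=0), right eye -> (m=1, p=0), p positive toward the chiasm"
)

LANDMARK_COLUMNS = [
    "specimen_id",
    "genotype",
    "left_eye_x",
    "left_eye_y",
    "right_eye_x",
    "right_eye_y",
    "injected_eye",
]


def _header(config: PipelineConfig | None, extra: dict | None = None) -> str:
    lines = [f"# {_CONVENTION}"]
    lines.append("# units: positions um/px as named, curvature rad/um")
    if config is not None:
        lines.append(f"# config_hash: {config.hash()}")
        lines.append(f"# axis_order: {config.axis_order}")
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: PipelineConfig | None = None,
    extra: dict | None = None,
) -> None:
    """Write a DataFrame as commented TSV."""
    with open(path, "w") as fh:
        fh.write(_header(config, extra))
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_landmarks(path: str | Path) -> list[EmbryoLandmarks]:
    """One row per specimen: id, genotype, eye coordinates, injected side."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(
            f"{path}: landmark file lacks columns {sorted(missing)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            EmbryoLandmarks(
                left_eye=(float(row.left_eye_x), float(row.left_eye_y)),
                right_eye=(float(row.right_eye_x), float(row.right_eye_y)),
                injected_eye=str(row.injected_eye),
                specimen_id=str(row.specimen_id),
                genotype=str(row.genotype),
            )
        )
    return out


def write_landmarks(landmarks: list[EmbryoLandmarks], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": lm.specimen_id,
            "genotype": lm.genotype,
            "left_eye_x": lm.left_eye[0],
            "left_eye_y": lm.left_eye[1],
            "right_eye_x": lm.right_eye[0],
            "right_eye_y": lm.right_eye[1],
            "injected_eye": lm.injected_eye,
        }
        for lm in landmarks
    ]
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def binned_to_frame(sample: BinnedSample, grid: GridSpec | None = None) -> pd.DataFrame:
    """Long-format (row, col) table of one specimen's binned summaries."""
    grid = grid or GridSpec()
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "count": sample.count.ravel(),
            "mean_orientation_rad": sample.mean_orientation.ravel(),
            "mean_curv_direction_rad": sample.mean_curv_direction.ravel(),
            "mean_curv_magnitude": sample.mean_curv_magnitude.ravel(),
        }
    )


def map_to_frame(values: np.ndarray, name: str = "value") -> pd.DataFrame:
    rows, cols = np.indices(values.shape)
    return pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), name: values.ravel()}
    )


def write_manifest(
    path: str | Path, config: PipelineConfig, inputs: dict, seed: int | None = None
) -> None:
    """Record every parameter actually used for a run."""
    import axonfield

    manifest = {
        "package": "axonfield",
        "version": getattr(axonfield, "__version__", "unknown"),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "convention": _CONVENTION,
        "inputs": inputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
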