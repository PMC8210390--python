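"""File formats: TIFF stacks with JSON timing sidecars, contour and cohort CSV.

Conventions: images are row/column 0-based rasters; contour files carry mm
coordinates with an explicit origin; parametric maps are 32-bit float TIFF
with NaN sentinels.  Every writer can attach a provenance record (tool
version, config hash, input hashes, seed, timestamp).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cohort_stats import COHORT_COLUMNS
from .errors import InputError
from .geometry import PlanarContour, SliceGeometry
from .histology import StainImage
from .relaxometry import EchoSeries, ParametricMap, RecoverySeries

__all__ = [
    "RunConfig",
    "ProvenanceRecord",
    "read_image_stack",
    "write_image_stack",
    "write_map",
    "read_map",
    "read_contours_csv",
    "write_contours_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]


@dataclass
class RunConfig:
    """Run-wide configuration; defaults are the pipeline's study settings."""

    output_dir: str = "results"
    seed: int = 0
    offset_fraction: float = 0.15
    kmeans_k: int = 3
    kmeans_max_iter: int = 100
    kmeans_restarts: int = 10
    hct_unit_policy: str = "auto"  # percent inputs >1 are divided by 100
    alpha: float = 0.05
    power: float = 0.80
    septal_direction_deg: float = 180.0
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ProvenanceRecord:
    tool_version: str
    config_hash: str
    input_hashes: dict
    seed: int
    timestamp: str

    @classmethod
    def create(cls, config: RunConfig, inputs: dict | None = None) -> "ProvenanceRecord":
        cfg = json.dumps(config.__dict__, sort_keys=True, default=str)
        return cls(
            tool_version=__version__,
            config_hash=hashlib.sha256(cfg.encode()).hexdigest(),
            input_hashes={k: _sha256(v) for k, v in (inputs or {}).items()},
            seed=config.seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def write_image_stack(path, series, sidecar_path=None) -> None:
    """Write a recovery/echo series as multi-page float TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(series.frames, dtype=np.float32), photometric="minisblack"
    )
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if isinstance(series, RecoverySeries):
        meta = {"delays_ms": list(map(float, series.delays))}
    else:
        meta = {"echoes_ms": list(map(float, series.echoes))}
    meta["pixel_spacing_mm"] = series.pixel_spacing
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)


def read_image_stack(path, sidecar_path=None, mask=None):
    """Read a TIFF stack plus timing sidecar into a typed series.

    The sidecar decides the type: ``delays_ms`` yields a
    :class:`RecoverySeries`, ``echoes_ms`` an :class:`EchoSeries`.  A frame
    count that disagrees with the timing vector is an input error.
    """
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    spacing = float(meta.get("pixel_spacing_mm", 0.39))
    if "delays_ms" in meta:
        return RecoverySeries(frames=frames, delays=np.asarray(meta["delays_ms"]), mask=mask, pixel_spacing=spacing)
    if "echoes_ms" in meta:
        return EchoSeries(frames=frames, echoes=np.asarray(meta["echoes_ms"]), mask=mask, pixel_spacing=spacing)
    raise InputError("sidecar must contain 'delays_ms' or 'echoes_ms'")


def read_stain_image(path, **meta) -> StainImage:
    from imageio.v3 import imread

    return StainImage(pixels=imread(path), **meta)


def write_map(path, pmap: ParametricMap, summary_path=None) -> None:
    """Write a parametric map as 32-bit float TIFF plus a JSON summary."""
    tifffile.imwrite(Path(path), pmap.values.astype(np.float32))
    if summary_path:
        valid = pmap.values[pmap.valid]
        summary = {
            "kind": pmap.kind,
            "n_valid": int(valid.size),
            "mean": float(valid.mean()) if valid.size else None,
            "sd": float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)


def read_map(path, kind: str) -> ParametricMap:
    values = tifffile.imread(Path(path)).astype(float)
    return ParametricMap(values=values, quality=np.full_like(values, np.nan), kind=kind)


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

CONTOUR_COLUMNS = ["slice", "phase", "role", "x_mm", "y_mm"]


def write_contours_csv(path, stacks: dict) -> None:
    """Write ``{"ED": [SliceGeometry...], ...}`` as an ordered-vertex CSV."""
    rows = []
    for phase, slices in stacks.items():
        for s in slices:
            for role, contour in (("endo", s.endo), ("epi", s.epi)):
                for x, y in contour.vertices:
                    rows.append(
                        {"slice": contour.slice_index, "phase": phase, "role": role, "x_mm": x, "y_mm": y}
                    )
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_contours_csv(path, thickness_mm: float = 2.0, gap_mm: float = 0.0) -> dict:
    """Read an ordered-vertex contour CSV back into slice geometries."""
    df = pd.read_csv(path)
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"contour CSV missing columns: {sorted(missing)}")
    stacks: dict[str, list[SliceGeometry]] = {}
    for (phase, slc), grp in df.groupby(["phase", "slice"], sort=True):
        contours = {}
        for role in ("endo", "epi"):
            verts = grp.loc[grp.role == role, ["x_mm", "y_mm"]].to_numpy(float)
            if len(verts) < 3:
                raise InputError(f"{phase}/slice {slc}: missing {role} contour")
            contours[role] = PlanarContour(verts, slice_index=int(slc), phase=str(phase))
        stacks.setdefault(str(phase), []).append(
            SliceGeometry(endo=contours["endo"], epi=contours["epi"], thickness=thickness_mm, gap=gap_mm)
        )
    return stacks


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

NON_NEGATIVE = ["hct", "HR", "LVEDV", "LVESV", "LVSV", "CO", "LVmass", "LVEF",
                "native_t1", "t2", "ecv", "vacuolar_pct", "fibrosis_pct",
                "inflammation_score", "edema_score"]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a per-subject cohort table.

    Unknown columns warn; schema violations (bad group id, negative
    measurements) are errors.  Missing values stay explicit as NaN.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {sorted(unknown)}", stacklevel=2)
    if "group" not in df.columns:
        raise InputError("cohort CSV needs a 'group' column")
    if not df["group"].dropna().isin(range(6)).all():
        raise InputError("group ids must be integers 0..5")
    for col in NON_NEGATIVE:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise InputError(f"negative values in column {col!r}")
    return df


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
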