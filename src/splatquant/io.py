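"""File I/O: strip images, measurement tables, site layouts, configs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .aggregate import SiteRecord
from .quant import Scan, StripMeasurement
from .spatial import SiteLocation


def read_scan(
    path,
    dpi: int = 600,
    site_id: Optional[str] = None,
    procedure_code: Optional[str] = None,
    crop_margin_px: int = 0,
) -> Scan:
    """Read a PNG/TIFF strip image as a Scan; alpha channels are dropped."""
    pixels = iio.imread(path)
    if pixels.ndim == 2:  # greyscale: replicate channels so thresholds apply
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[-1] == 4:
        pixels = pixels[..., :3]
    scan = Scan(pixels, dpi=dpi, site_id=site_id, procedure_code=procedure_code)
    return scan.cropped(crop_margin_px)


def write_scan(path, scan: Scan) -> None:
    """Write a Scan as 8-bit RGB PNG/TIFF (by extension)."""
    iio.imwrite(path, scan.pixels)


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV mapping image paths to identifiers.

    Columns: ``path``, ``procedure_code``, ``site_id``.
    """
    df = pd.read_csv(path)
    missing = {"path", "procedure_code", "site_id"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def write_measurements(path, measurements: Sequence[StripMeasurement]) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def measurements_to_frame(measurements: Sequence[StripMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "procedure_code": [m.procedure_code for m in measurements],
            "site_id": [m.site_id for m in measurements],
            "intensity_pct": [m.intensity_pct for m in measurements],
            "contaminated": [m.contaminated for m in measurements],
        }
    )


def read_records(path) -> pd.DataFrame:
    """Read a strip-records table (one row per strip)."""
    df = pd.read_csv(path)
    df["contaminated"] = df["contaminated"].astype(bool)
    return df


def write_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_site_layout(path) -> list[SiteLocation]:
    """Read a site-layout CSV.

    Accepts either polar columns (``distance_m``, ``clock_angle_deg``) or
    Cartesian ones (``x_m``, ``y_m``), plus ``site_id``, ``role`` and
    optionally ``height_class``.
    """
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        height = getattr(r, "height_class", "floor")
        if hasattr(r, "distance_m") and hasattr(r, "clock_angle_deg"):
            out.append(
                SiteLocation.from_polar(
                    str(r.site_id), str(r.role), float(r.distance_m),
                    float(r.clock_angle_deg), str(height),
                )
            )
        else:
            out.append(
                SiteLocation(str(r.site_id), str(r.role), float(r.x_m), float(r.y_m), str(height))
            )
    return out


def site_records_from_frame(frame: pd.DataFrame) -> list[SiteRecord]:
    return [
        SiteRecord(
            procedure_code=str(r.procedure_code),
            site_id=str(r.site_id),
            role=str(r.role),
            intensity_pct=float(r.intensity_pct),
            contaminated=bool(r.contaminated),
        )
        for r in frame.itertuples(index=False)
    ]


def load_config(path) -> dict:
    """Load a YAML config file (simulation parameters etc.)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
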