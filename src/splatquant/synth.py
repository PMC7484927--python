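"""Synthetic indicator-paper strips and synthetic splatter studies.

No raw scans or per-strip records from the original experiment are
published, so every downstream stage is exercised against synthetic inputs
with known ground truth:

* :func:`generate_strip_image` renders a yellow strip speckled with red
  quasi-circular splatter marks and returns the exact pixel mask that was
  painted — the oracle for the percentage-coverage statistic.
* :func:`generate_study` simulates a whole study matrix (procedures × sites)
  with controllable mitigation effect sizes: hit probability decays
  exponentially with distance from the patient's mouth, and mitigation
  devices (extraoral scavenger, high-volume suction, rubber dam) act
  multiplicatively on hit probability and/or intensity.

Droplets are filled discs with lognormal radii at uniform-random centres,
overlap allowed, union taken — the simplest model matching the speckled
appearance of real scans.  Colours: background hue ≈ 55° (yellow),
contaminated hue ≈ 5° (red), with optional per-pixel hue jitter and additive
8-bit sensor noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk

from .quant import Scan
from .spatial import SiteLocation

BACKGROUND_HUE_DEG = 55.0
SPLATTER_HUE_DEG = 5.0
_MAX_DROPLETS = 50_000


@dataclass(frozen=True)
class StripGenParams:
    """Parameters for one synthetic strip.

    Exactly one of ``n_droplets`` / ``target_coverage`` drives generation;
    ``n_droplets`` takes precedence when both are given (``n_droplets=0``
    forces an empty mask).  With ``target_coverage``, droplets from a
    seed-fixed schedule are painted until the painted-pixel count reaches
    ``round(target_coverage × total)``, so increasing the target with the
    same seed only ever adds pixels.
    """

    width_px: int = 200
    height_px: int = 400
    dpi: int = 600
    target_coverage: Optional[float] = None
    n_droplets: Optional[int] = None
    radius_px_log_mean: float = math.log(5.0)
    radius_px_log_sd: float = 0.4
    hue_jitter_deg: float = 3.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.dpi <= 0:
            raise ValueError("image dimensions and dpi must be positive")
        if self.target_coverage is None and self.n_droplets is None:
            raise ValueError("one of target_coverage or n_droplets is required")
        if self.target_coverage is not None and not 0.0 <= self.target_coverage <= 1.0:
            raise ValueError("target_coverage must lie in [0, 1]")
        if self.n_droplets is not None and self.n_droplets < 0:
            raise ValueError("n_droplets must be non-negative")
        if self.hue_jitter_deg < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise must be non-negative")


@dataclass
class GroundTruth:
    """Exact pixel mask painted before jitter/noise, plus its coverage."""

    mask: np.ndarray
    coverage_pct: float


def _paint_droplet(mask: np.ndarray, rng: np.random.Generator, params: StripGenParams) -> None:
    r = rng.uniform(0, mask.shape[0])
    c = rng.uniform(0, mask.shape[1])
    radius = max(1.0, rng.lognormal(params.radius_px_log_mean, params.radius_px_log_sd))
    rr, cc = disk((r, c), radius, shape=mask.shape)
    mask[rr, cc] = True


def generate_strip_image(params: StripGenParams) -> tuple[Scan, GroundTruth]:
    """Render one synthetic strip; reproducible for a fixed seed.

    Returns the 8-bit RGB scan and the exact ground-truth mask (the pixels
    painted red before hue jitter and noise were applied).
    """
    rng = np.random.default_rng(params.seed)
    mask = np.zeros((params.height_px, params.width_px), dtype=bool)

    if params.n_droplets is not None:
        for _ in range(params.n_droplets):
            _paint_droplet(mask, rng, params)
    elif params.target_coverage >= 1.0:
        mask[:] = True
    else:
        target_px = int(round(params.target_coverage * mask.size))
        n = 0
        while int(mask.sum()) < target_px:
            if n >= _MAX_DROPLETS:
                warnings.warn(
                    f"droplet cap reached at coverage {100 * mask.mean():.2f}% "
                    f"(target {100 * params.target_coverage:.2f}%)"
                )
                break
            _paint_droplet(mask, rng, params)
            n += 1

    hue = np.where(mask, SPLATTER_HUE_DEG, BACKGROUND_HUE_DEG).astype(float)
    if params.hue_jitter_deg > 0:
        hue = hue + rng.normal(0.0, params.hue_jitter_deg, size=hue.shape)
    hue %= 360.0
    sat = np.where(mask, 0.85, 0.75)
    val = np.where(mask, 0.82, 0.92)
    rgb = hsv2rgb(np.stack([hue / 360.0, sat, val], axis=-1)) * 255.0
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, size=rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    coverage_pct = 100.0 * int(mask.sum()) / mask.size
    return Scan(pixels, dpi=params.dpi), GroundTruth(mask=mask, coverage_pct=coverage_pct)


@dataclass(frozen=True)
class ProcedureSpec:
    """Metadata for one simulated procedure run."""

    code: str
    procedure: str = "simulated procedure"
    operatory_type: str = "closed"
    eos: bool = False
    hvs: bool = False
    se: bool = False
    rubber_dam: bool = False
    short_visor: bool = False
    duration_min: float = 10.0

    @property
    def variation(self) -> str:
        """Human-readable scavenging-variation descriptor (pairing key)."""
        tokens = []
        if self.rubber_dam:
            tokens.append("RD")
        if self.eos:
            tokens.append("EOS")
        if self.hvs:
            tokens.append("HVS")
        if self.se:
            tokens.append("SE")
        label = ", ".join(tokens[:-1]) + " and " + tokens[-1] if len(tokens) > 1 else (
            tokens[0] if tokens else "No suction"
        )
        if self.short_visor:
            label += " (short visor)"
        return label


@dataclass(frozen=True)
class StudyGenParams:
    """Generative model for a synthetic study matrix.

    For each procedure × site, the strip is contaminated with probability
    ``base_hit_prob × exp(−distance_decay × distance) × hit multipliers``;
    contaminated strips draw a lognormal intensity scaled by the applicable
    intensity multipliers and clipped to [0, 100].
    """

    site_layout: Sequence[SiteLocation]
    procedures: Sequence[ProcedureSpec]
    base_hit_prob: float = 0.6
    distance_decay: float = 1.5
    intensity_log_mean: float = 0.0
    intensity_log_sd: float = 1.0
    eos_intensity_multiplier: float = 0.25
    eos_hit_multiplier: float = 0.8
    hvs_multiplier: float = 0.7
    rd_multiplier: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.site_layout) == 0:
            raise ValueError("site layout must contain at least one site")
        if len(self.procedures) == 0:
            raise ValueError("at least one procedure is required")
        if not 0.0 <= self.base_hit_prob <= 1.0:
            raise ValueError("base_hit_prob must lie in [0, 1]")
        if self.distance_decay < 0:
            raise ValueError("distance_decay must be non-negative")
        for name in (
            "eos_intensity_multiplier",
            "eos_hit_multiplier",
            "hvs_multiplier",
            "rd_multiplier",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


#: Column order of the strip-level records table.
RECORD_COLUMNS = [
    "procedure_code",
    "site_id",
    "role",
    "distance_m",
    "clock_angle_deg",
    "contaminated",
    "intensity_pct",
]


@dataclass
class StudyDataset:
    """Strip-level records plus the procedure metadata that produced them."""

    records: pd.DataFrame
    procedures: pd.DataFrame
    params: StudyGenParams

    def render_strip(self, index: int, **strip_kwargs) -> tuple[Scan, GroundTruth]:
        """Render the scan for one record, at its recorded intensity."""
        row = self.records.iloc[index]
        params = StripGenParams(
            target_coverage=float(row.intensity_pct) / 100.0,
            seed=int(self.params.seed + index),
            **strip_kwargs,
        )
        scan, truth = generate_strip_image(params)
        scan.site_id = row.site_id
        scan.procedure_code = row.procedure_code
        return scan, truth


def generate_study(params: StudyGenParams) -> StudyDataset:
    """Simulate strip-level contamination for every procedure × site."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for proc in params.procedures:
        for site in params.site_layout:
            p = params.base_hit_prob * math.exp(-params.distance_decay * site.distance_m)
            if proc.eos:
                p *= params.eos_hit_multiplier
            if proc.hvs:
                p *= params.hvs_multiplier
            if proc.rubber_dam:
                p *= params.rd_multiplier
            hit = bool(rng.random() < min(p, 1.0))
            intensity = 0.0
            if hit:
                intensity = rng.lognormal(params.intensity_log_mean, params.intensity_log_sd)
                if proc.eos:
                    intensity *= params.eos_intensity_multiplier
                intensity = min(intensity, 100.0)
            rows.append(
                (
                    proc.code,
                    site.site_id,
                    site.role,
                    site.distance_m,
                    site.clock_angle_deg,
                    hit,
                    intensity,
                )
            )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    procedures = pd.DataFrame(
        {
            "code": [p.code for p in params.procedures],
            "procedure": [p.procedure for p in params.procedures],
            "operatory_type": [p.operatory_type for p in params.procedures],
            "variation": [p.variation for p in params.procedures],
        }
    )
    return StudyDataset(records=records, procedures=procedures, params=params)


def replicate_eos_pairs(
    n_pairs: int,
    procedure: str = "simulated air-turbine preparation",
    operatory_type: str = "closed",
    hvs: bool = True,
    se: bool = True,
) -> list[ProcedureSpec]:
    """Build ``n_pairs`` procedure pairs identical except for the EOS flag.

    Codes are ``P0001``/``P0001E`` etc.; each pair differs only in ``eos``,
    so the pairing step recovers exactly these pairs.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    procs: list[ProcedureSpec] = []
    for i in range(1, n_pairs + 1):
        base = ProcedureSpec(
            code=f"P{i:04d}",
            procedure=f"{procedure} #{i}",
            operatory_type=operatory_type,
            hvs=hvs,
            se=se,
        )
        procs.append(base)
        procs.append(replace(base, code=f"P{i:04d}E", eos=True))
    return procs
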