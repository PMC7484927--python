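"""Colour-threshold quantification of contamination on indicator-paper scans.

A universal-indicator-paper (UIP) strip is yellow when clean and turns red
where acidic splatter has landed.  Each scanned strip is decomposed into red
(contaminated) and yellow (uncontaminated) pixels by thresholding in
hue/saturation/value space, and the contamination *intensity* of the strip is
the percentage of its pixels classified red.  A strip with any red pixel at
all — even a single point — counts as contaminated.

The threshold itself is a free choice; :func:`threshold_sweep` quantifies how
sensitive a strip's intensity is to that choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

#: Hue (degrees) of the clean yellow paper, used only for the off-palette check.
YELLOW_HUE_DEG = 55.0
#: Fraction of pixels that are neither red nor yellow before a warning is logged.
OFF_PALETTE_WARN_FRACTION = 0.05


@dataclass
class Scan:
    """One scanned indicator-paper strip.

    Parameters
    ----------
    pixels
        ``(rows, cols, 3)`` 8-bit RGB array, row-major, origin top-left.
    dpi
        Scan resolution in dots per inch (nominally 600).
    site_id, procedure_code
        Optional provenance identifiers carried through to measurements.
    """

    pixels: np.ndarray
    dpi: int = 600
    site_id: Optional[str] = None
    procedure_code: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("scan must contain at least one pixel")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        self.pixels = px.astype(np.uint8, copy=False)

    def cropped(self, margin_px: int) -> "Scan":
        """Return a copy with ``margin_px`` trimmed from every edge.

        Hook for excluding strip borders or mounting tape from the analysed
        area.  Raises if the margin would leave no pixels.
        """
        if margin_px < 0:
            raise ValueError("margin must be non-negative")
        if margin_px == 0:
            return self
        h, w = self.pixels.shape[:2]
        if 2 * margin_px >= h or 2 * margin_px >= w:
            raise ValueError("crop margin leaves an empty image")
        return Scan(
            self.pixels[margin_px:-margin_px, margin_px:-margin_px],
            dpi=self.dpi,
            site_id=self.site_id,
            procedure_code=self.procedure_code,
        )


@dataclass(frozen=True)
class ThresholdSpec:
    """Red-pixel classification rule in HSV space.

    A pixel is contaminated iff its hue lies on the (possibly wrap-around)
    arc ``red_hue_window`` *and* its saturation and value are at least the
    stated floors.  The default window is a ±20° arc around 0° (pure red),
    far from the ≈55° hue of clean yellow paper.
    """

    red_hue_window: tuple[float, float] = (340.0, 20.0)
    min_saturation: float = 0.3
    min_value: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.red_hue_window
        if not (0.0 <= lo < 360.0 and 0.0 <= hi < 360.0):
            raise ValueError("hue window endpoints must lie in [0, 360)")
        for name in ("min_saturation", "min_value"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def hue_in_window(self, hue_deg: np.ndarray) -> np.ndarray:
        lo, hi = self.red_hue_window
        hue_deg = np.asarray(hue_deg) % 360.0
        if lo <= hi:
            return (hue_deg >= lo) & (hue_deg <= hi)
        return (hue_deg >= lo) | (hue_deg <= hi)  # wrap-around arc


@dataclass
class ContaminationMask:
    """Boolean contamination mask congruent with one scan."""

    mask: np.ndarray
    n_contaminated_px: int
    n_total_px: int

    @property
    def intensity_pct(self) -> float:
        return 100.0 * self.n_contaminated_px / self.n_total_px


@dataclass
class StripMeasurement:
    """Per-strip contamination intensity (% of pixels red) and flag."""

    site_id: Optional[str]
    procedure_code: Optional[str]
    intensity_pct: float
    contaminated: bool
    n_contaminated_px: int = 0
    n_total_px: int = 0


@dataclass
class SensitivityReport:
    """Spread of a strip's intensity under a sweep of threshold choices."""

    baseline_intensity_pct: float
    intensities_by_threshold: list[tuple[ThresholdSpec, float]]
    range_pct: float
    flagged: bool
    tolerance_pct: float


def classify_pixels(scan: Scan, spec: ThresholdSpec | None = None) -> ContaminationMask:
    """Classify every pixel of ``scan`` as contaminated (red) or not.

    Deterministic: a pixel is contaminated iff hue ∈ ``red_hue_window`` and
    saturation ≥ ``min_saturation`` and value ≥ ``min_value``.  Pixels that
    are neither red nor yellow (shadows, scanner artefacts) count as
    uncontaminated; a warning is logged when they exceed
    ``OFF_PALETTE_WARN_FRACTION`` of the strip.
    """
    if spec is None:
        spec = ThresholdSpec()
    hsv = rgb2hsv(scan.pixels)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    mask = spec.hue_in_window(hue_deg) & (sat >= spec.min_saturation) & (val >= spec.min_value)

    yellowish = (np.abs(hue_deg - YELLOW_HUE_DEG) <= 30.0) & (sat >= 0.1)
    off_palette = ~mask & ~yellowish
    frac_off = float(off_palette.mean())
    if frac_off > OFF_PALETTE_WARN_FRACTION:
        logger.warning(
            "%.1f%% of pixels are neither red nor yellow (site=%s, procedure=%s); "
            "they are counted as uncontaminated",
            100.0 * frac_off,
            scan.site_id,
            scan.procedure_code,
        )
    return ContaminationMask(
        mask=mask, n_contaminated_px=int(mask.sum()), n_total_px=int(mask.size)
    )


def measure_strip(scan: Scan, spec: ThresholdSpec | None = None) -> StripMeasurement:
    """Measure one strip: intensity % and contaminated flag.

    Any contamination, including a single red pixel, marks the strip
    contaminated.
    """
    cm = classify_pixels(scan, spec)
    return StripMeasurement(
        site_id=scan.site_id,
        procedure_code=scan.procedure_code,
        intensity_pct=cm.intensity_pct,
        contaminated=cm.n_contaminated_px >= 1,
        n_contaminated_px=cm.n_contaminated_px,
        n_total_px=cm.n_total_px,
    )


def threshold_sweep(
    scan: Scan,
    base: ThresholdSpec,
    perturbations: Sequence[ThresholdSpec],
    tolerance_pct: float = 1.0,
) -> SensitivityReport:
    """Re-measure one strip under each perturbed threshold and report spread.

    The baseline spec is included in the sweep, so ``range_pct`` is the
    max−min intensity over {base} ∪ perturbations and the baseline intensity
    always lies inside the reported range.  The strip is flagged when
    ``range_pct`` exceeds ``tolerance_pct``.
    """
    if len(perturbations) == 0:
        raise ValueError("perturbation list must be non-empty")
    baseline = measure_strip(scan, base).intensity_pct
    results = [(base, baseline)]
    for spec in perturbations:
        if not isinstance(spec, ThresholdSpec):
            raise ValueError("perturbations must be ThresholdSpec instances")
        results.append((spec, measure_strip(scan, spec).intensity_pct))
    values = [v for _, v in results]
    rng_pct = max(values) - min(values)
    return SensitivityReport(
        baseline_intensity_pct=baseline,
        intensities_by_threshold=results,
        range_pct=rng_pct,
        flagged=rng_pct > tolerance_pct,
        tolerance_pct=tolerance_pct,
    )
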