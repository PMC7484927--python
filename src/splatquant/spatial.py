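"""Spatial distribution of splatter contamination around the dental chair.

All site positions are horizontal coordinates in metres relative to the
incisal edge of the maxillary left central incisor (tooth 21), which sits at
the origin; vertical position is carried as a categorical height class but
never enters the distance (distances are measured horizontally).  Directions
are reported as clock positions: 12 o'clock points toward the top of the
operatory plan (behind the patient's head) and angles increase clockwise
viewed from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

HEIGHT_CLASSES = ("floor", "chair", "table", "person", "ceiling")


@dataclass(frozen=True)
class SiteLocation:
    """One labelled indicator-paper site in the operatory plan."""

    site_id: str
    role: str
    x_m: float
    y_m: float
    height_class: str = "floor"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_m) and math.isfinite(self.y_m)):
            raise ValueError("coordinates must be finite")
        if self.height_class not in HEIGHT_CLASSES:
            raise ValueError(
                f"height_class must be one of {HEIGHT_CLASSES}, got {self.height_class!r}"
            )

    @classmethod
    def from_polar(
        cls,
        site_id: str,
        role: str,
        distance_m: float,
        clock_angle_deg: float,
        height_class: str = "floor",
    ) -> "SiteLocation":
        """Build a site from (distance, clock angle); 0° is 12 o'clock."""
        if distance_m < 0:
            raise ValueError("distance must be non-negative")
        theta = math.radians(clock_angle_deg)
        return cls(
            site_id=site_id,
            role=role,
            x_m=distance_m * math.sin(theta),
            y_m=distance_m * math.cos(theta),
            height_class=height_class,
        )

    @property
    def distance_m(self) -> float:
        """Horizontal Euclidean distance from the reference tooth (m)."""
        return math.hypot(self.x_m, self.y_m)

    @property
    def clock_angle_deg(self) -> float:
        """Degrees clockwise from 12 o'clock, in [0, 360)."""
        if self.x_m == 0.0 and self.y_m == 0.0:
            return 0.0
        return math.degrees(math.atan2(self.x_m, self.y_m)) % 360.0


def site_distance(location: SiteLocation) -> float:
    """Horizontal distance (m) of a site from the reference tooth."""
    return location.distance_m


def clock_position(angle_deg: float) -> int:
    """Map an angle to the nearest of twelve 30° clock sectors (1–12).

    0° is 12 o'clock; sector boundaries are resolved toward the later hour
    (15° → 1 o'clock).
    """
    if not math.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    sector = int(((angle_deg % 360.0) + 15.0) // 30.0) % 12
    return 12 if sector == 0 else sector


@dataclass
class DistanceProfile:
    """Contaminated-strip counts and mean intensities per distance bin."""

    bin_edges_m: np.ndarray
    frequency_per_bin: np.ndarray
    mean_intensity_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_m": self.bin_edges_m[:-1],
                "bin_end_m": self.bin_edges_m[1:],
                "frequency_n": self.frequency_per_bin,
                "mean_intensity_pct": self.mean_intensity_per_bin,
            }
        )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(records)


def furthest_contaminated(records) -> Optional[tuple[str, float]]:
    """The contaminated site furthest from the reference tooth.

    ``records`` is a DataFrame (or convertible) with at least ``site_id``,
    ``distance_m`` and ``contaminated`` columns.  Returns ``(site_id,
    distance_m)`` with distance rounded to 2 decimals for reporting, or
    ``None`` when no record is contaminated.  Ties go to the earlier record.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("record table must be non-empty")
    hit = df[df["contaminated"].astype(bool)]
    if len(hit) == 0:
        return None
    i = int(np.argmax(hit["distance_m"].to_numpy()))
    row = hit.iloc[i]
    return str(row["site_id"]), round(float(row["distance_m"]), 2)


def distance_profile(records, bin_width_m: float) -> DistanceProfile:
    """Bin contaminated records by distance into half-open bins [a, b).

    Counts conserve the total number of contaminated records; empty bins
    report a mean intensity of 0.
    """
    if bin_width_m <= 0:
        raise ValueError("bin width must be positive")
    df = _as_frame(records)
    hit = df[df["contaminated"].astype(bool)]
    if len(hit) == 0:
        edges = np.array([0.0, bin_width_m])
        return DistanceProfile(edges, np.zeros(1, dtype=int), np.zeros(1))
    d = hit["distance_m"].to_numpy(dtype=float)
    idx = np.floor(d / bin_width_m).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=hit["intensity_pct"].to_numpy(dtype=float), minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    edges = np.arange(n_bins + 1) * bin_width_m
    return DistanceProfile(edges, counts, means)


def height_report(records) -> pd.DataFrame:
    """Count contaminated strips by height class.

    Companion to the horizontal-distance profile: vertical position is
    excluded from distances, so it is summarised separately.
    """
    df = _as_frame(records)
    hit = df[df["contaminated"].astype(bool)]
    out = (
        hit.groupby("height_class", observed=True)
        .size()
        .reindex(HEIGHT_CLASSES, fill_value=0)
        .rename("frequency_n")
        .reset_index()
        .rename(columns={"index": "height_class"})
    )
    return out


def join_records_with_layout(
    records: pd.DataFrame, layout: Sequence[SiteLocation]
) -> pd.DataFrame:
    """Attach distance/clock/height columns from a layout to strip records."""
    meta = pd.DataFrame(
        {
            "site_id": [s.site_id for s in layout],
            "distance_m": [s.distance_m for s in layout],
            "clock_angle_deg": [s.clock_angle_deg for s in layout],
            "height_class": [s.height_class for s in layout],
        }
    )
    return records.drop(
        columns=[c for c in ("distance_m", "clock_angle_deg", "height_class") if c in records],
    ).merge(meta, on="site_id", how="left")


def plot_plan_view(records, layout: Sequence[SiteLocation], ax=None, annotate: bool = True):
    """Plan-view scatter of contamination frequency per site.

    Marker size encodes how often each site was contaminated across the
    records; the reference tooth sits at the origin.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    df = _as_frame(records)
    freq = df[df["contaminated"].astype(bool)].groupby("site_id").size()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for site in layout:
        n = int(freq.get(site.site_id, 0))
        ax.scatter(
            site.x_m,
            site.y_m,
            s=20 + 40 * n,
            c="firebrick" if n else "gold",
            edgecolors="black",
            linewidths=0.5,
            zorder=3,
        )
        if annotate:
            ax.annotate(site.site_id, (site.x_m, site.y_m), fontsize=6,
                        textcoords="offset points", xytext=(4, 4))
    ax.scatter([0], [0], marker="+", c="black", s=60, zorder=4)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    return ax
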