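"""Bundled study tables and site layouts.

``appendix_contamination.csv`` transcribes the published per-procedure
summary tables (air-turbine, ultrasonic/triple-air and surgical procedures):
for each procedure run, the operatory type, duration, scavenging variation,
and the frequency / mean intensity / maximum intensity (+ site) of
contamination for operatory, clinician and assistant separately.  Empty
assistant cells mark runs performed with no assistant present.

``table1_pooled.csv`` holds the published pooled without/with-EOS means.
The per-strip data behind them were not released, so these pooled means are
inputs to the comparison arithmetic, not recomputed quantities.

The site layouts are *synthetic*: only the distances and clock positions
quoted in the text (patient 0.35 m, bracket table 0.6 m, assistant's chair
0.24 m, light 0.75 m, site 28 at 1.34 m / 8 o'clock, site 43 at 1.33 m /
4 o'clock, site 71 at 0.22 m / 1 o'clock) are factual; every other
coordinate is invented to complete a plausible operatory plan.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aggregate import GroupSummary, PooledSummary
from .spatial import SiteLocation

_ROLE_PREFIXES = {"operatory": "operatory", "clinician": "clinician", "assistant": "assistant"}


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("splatquant.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_appendix_table() -> pd.DataFrame:
    """The transcribed per-procedure contamination table (wide form)."""
    return _read_data("appendix_contamination.csv")


def load_procedure_metadata() -> pd.DataFrame:
    """Procedure code / description / operatory type / variation columns."""
    return load_appendix_table()[["code", "procedure", "operatory_type", "duration", "variation"]]


def appendix_group_summaries() -> list[GroupSummary]:
    """The appendix table as one :class:`GroupSummary` per procedure × role.

    Runs with no assistant present contribute no assistant summary.
    """
    df = load_appendix_table()
    out: list[GroupSummary] = []
    for row in df.itertuples(index=False):
        for role, prefix in _ROLE_PREFIXES.items():
            freq = getattr(row, f"{prefix}_frequency_n")
            if pd.isna(freq):
                continue  # role absent for this run
            site = getattr(row, f"{prefix}_max_site")
            out.append(
                GroupSummary(
                    procedure_code=row.code,
                    role=role,
                    frequency_n=int(freq),
                    mean_intensity_pct=float(getattr(row, f"{prefix}_mean_intensity_pct")),
                    max_intensity_pct=float(getattr(row, f"{prefix}_max_intensity_pct")),
                    max_site=None if pd.isna(site) else str(site),
                )
            )
    return out


def load_table1_pooled() -> tuple[list[PooledSummary], list[PooledSummary]]:
    """Published pooled without/with-EOS values as two PooledSummary lists."""
    df = _read_data("table1_pooled.csv")
    without: dict[str, dict[str, float]] = {}
    with_: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        without.setdefault(row.role, {})[row.metric] = float(row.without_eos)
        with_.setdefault(row.role, {})[row.metric] = float(row.with_eos)

    def build(values: dict[str, dict[str, float]], label: str) -> list[PooledSummary]:
        return [
            PooledSummary(
                role=role,
                condition=label,
                mean_frequency=v["mean_frequency"],
                mean_intensity_pct=v["mean_intensity_pct"],
                n_procedures=0,  # underlying per-procedure values unpublished
            )
            for role, v in values.items()
        ]

    return build(without, "without EOS"), build(with_, "with EOS")


def _layout_from_frame(df: pd.DataFrame) -> list[SiteLocation]:
    return [
        SiteLocation.from_polar(
            site_id=str(r.site_id),
            role=str(r.role),
            distance_m=float(r.distance_m),
            clock_angle_deg=float(r.clock_angle_deg),
            height_class=str(r.height_class),
        )
        for r in df.itertuples(index=False)
    ]


def closed_surgery_layout() -> list[SiteLocation]:
    """Synthetic closed-surgery site layout (see module docstring)."""
    return _layout_from_frame(_read_data("sites_closed_synthetic.csv"))


def open_clinic_layout() -> list[SiteLocation]:
    """Synthetic open-clinic site layout (see module docstring)."""
    return _layout_from_frame(_read_data("sites_open_synthetic.csv"))
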