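"""Aggregation of strip measurements into the study's summary statistics.

For each procedure × role group the three reported statistics are:

* **frequency (n)** — the number of contaminated strips in the group;
* **mean intensity** — the average percentage coverage over the
  *contaminated* strips only (0 when none are contaminated);
* **maximum intensity** — the largest single-strip coverage, with the site
  where it occurred.

Pooling over a set of procedures takes the unweighted arithmetic mean of the
per-procedure frequencies and mean intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

ROLES = ("operatory", "clinician", "assistant", "patient")


@dataclass(frozen=True)
class SiteRecord:
    """One strip's measurement in study context."""

    procedure_code: str
    site_id: str
    role: str
    intensity_pct: float
    contaminated: bool

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.intensity_pct < 0 or self.intensity_pct > 100:
            raise ValueError("intensity_pct must lie in [0, 100]")
        # after quantification a contaminated strip has >= 1 red pixel
        if self.contaminated != (self.intensity_pct > 0):
            raise ValueError(
                "contaminated flag inconsistent with intensity "
                f"({self.contaminated} vs {self.intensity_pct}%)"
            )


@dataclass(frozen=True)
class GroupSummary:
    """Frequency / mean / max summary for one procedure × role group."""

    procedure_code: str
    role: str
    frequency_n: int
    mean_intensity_pct: float
    max_intensity_pct: float
    max_site: Optional[str]


@dataclass(frozen=True)
class PooledSummary:
    """Unweighted means over a set of procedures, for one role."""

    role: str
    condition: str
    mean_frequency: float
    mean_intensity_pct: float
    n_procedures: int


def summarize_group(records: Sequence[SiteRecord]) -> GroupSummary:
    """Summarise the strips of one procedure × role group.

    The mean divides by the number of contaminated strips only; a group with
    no contamination reports mean = max = 0 and no max site.  Ties for the
    maximum go to the earliest record.
    """
    if len(records) == 0:
        raise ValueError("record list must be non-empty")
    codes = {r.procedure_code for r in records}
    roles = {r.role for r in records}
    if len(codes) != 1:
        raise ValueError(f"records mix procedure codes: {sorted(codes)}")
    if len(roles) != 1:
        raise ValueError(f"records mix roles: {sorted(roles)}")

    hits = [r for r in records if r.contaminated]
    if not hits:
        return GroupSummary(codes.pop(), roles.pop(), 0, 0.0, 0.0, None)
    best = hits[0]
    for r in hits[1:]:
        if r.intensity_pct > best.intensity_pct:
            best = r
    return GroupSummary(
        procedure_code=codes.pop(),
        role=roles.pop(),
        frequency_n=len(hits),
        mean_intensity_pct=sum(r.intensity_pct for r in hits) / len(hits),
        max_intensity_pct=best.intensity_pct,
        max_site=best.site_id,
    )


def pool_procedures(summaries: Sequence[GroupSummary], condition: str) -> PooledSummary:
    """Pool per-procedure summaries of one role under a condition label."""
    if len(summaries) == 0:
        raise ValueError("summary list must be non-empty")
    roles = {s.role for s in summaries}
    if len(roles) != 1:
        raise ValueError(f"summaries mix roles: {sorted(roles)}")
    n = len(summaries)
    return PooledSummary(
        role=roles.pop(),
        condition=condition,
        mean_frequency=sum(s.frequency_n for s in summaries) / n,
        mean_intensity_pct=sum(s.mean_intensity_pct for s in summaries) / n,
        n_procedures=n,
    )


def max_over_table(summaries: Sequence[GroupSummary], role: str) -> tuple[float, str, str]:
    """Global maximum intensity for a role across a table of group summaries.

    Returns ``(max_intensity_pct, procedure_code, site)``; ties go to the
    earliest row.
    """
    rows = [s for s in summaries if s.role == role]
    if not rows:
        raise ValueError(f"no summaries for role {role!r}")
    best = rows[0]
    for s in rows[1:]:
        if s.max_intensity_pct > best.max_intensity_pct:
            best = s
    return best.max_intensity_pct, best.procedure_code, best.max_site


def records_from_frame(frame: pd.DataFrame) -> list[SiteRecord]:
    """Build :class:`SiteRecord` objects from a strip-records table."""
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


def summarize_frame(
    frame: pd.DataFrame, pool_patient_with_operatory: bool = True
) -> list[GroupSummary]:
    """Summarise a strip-records table into per procedure × role groups.

    The patient site is grouped under *operatory* by default, matching how
    the study tables place the patient among the operatory maxima.
    """
    df = frame.copy()
    if pool_patient_with_operatory:
        df["role"] = df["role"].replace({"patient": "operatory"})
    out: list[GroupSummary] = []
    for (_, _), grp in df.groupby(["procedure_code", "role"], sort=False):
        out.append(summarize_group(records_from_frame(grp)))
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "procedure_code": [s.procedure_code for s in summaries],
            "role": [s.role for s in summaries],
            "frequency_n": [s.frequency_n for s in summaries],
            "mean_intensity_pct": [s.mean_intensity_pct for s in summaries],
            "max_intensity_pct": [s.max_intensity_pct for s in summaries],
            "max_site": [s.max_site for s in summaries],
        }
    )
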