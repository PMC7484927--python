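"""Paired comparison of procedures with and without the extraoral scavenger.

Procedures are paired when their scavenging-variation descriptors are
identical after removing the EOS token (and they share the procedure
description and operatory type), i.e. the two runs differ only in whether
the extraoral scavenger was present.  For each role and metric the report
gives the absolute difference and the percent reduction

    reduction% = 100 × (value_without − value_with) / value_without,

with the convention that a zero baseline reports a 0% reduction (logged),
and increases appear as negative reductions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import PooledSummary, pool_procedures, summarize_frame, summaries_to_frame

logger = logging.getLogger(__name__)

METRICS = ("mean_frequency", "mean_intensity_pct")


@dataclass(frozen=True)
class ProcedurePair:
    """Two procedure runs identical except for the EOS flag."""

    code_without: str
    code_with: str
    matched_on: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class ComparisonRow:
    """One role × metric row of the without/with-EOS comparison table."""

    role: str
    metric: str
    value_without: float
    value_with: float
    difference: float
    reduction_pct: float


def _normalise_variation(variation: str) -> tuple[bool, frozenset[str]]:
    """Split a variation descriptor into tokens; return (has_eos, tokens).

    Case-insensitive; tokens are split on commas and the word "and", so
    "RD, EOS, HVS and SE" → {"rd", "hvs", "se"} with has_eos=True.
    Parenthesised qualifiers like "(short visor)" stay attached to their
    token and therefore participate in matching.
    """
    parts = re.split(r",|\band\b", str(variation).lower())
    tokens = {p.strip() for p in parts if p.strip()}
    has_eos = "eos" in tokens
    tokens.discard("eos")
    return has_eos, frozenset(tokens)


def pair_by_eos(procedures: pd.DataFrame) -> list[ProcedurePair]:
    """Pair procedures differing only by EOS use.

    ``procedures`` needs columns ``code``, ``procedure``, ``operatory_type``
    and ``variation``.  Within each (procedure, operatory type, normalised
    token set) group, non-EOS and EOS runs are paired in input order; every
    procedure appears in at most one pair.
    """
    codes = procedures["code"].tolist()
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate procedure codes in metadata table")

    groups: dict[tuple, dict[str, list[str]]] = {}
    for row in procedures.itertuples(index=False):
        has_eos, tokens = _normalise_variation(row.variation)
        key = (str(row.procedure).strip().lower(), str(row.operatory_type).strip().lower(), tokens)
        bucket = groups.setdefault(key, {"without": [], "with": []})
        bucket["with" if has_eos else "without"].append(str(row.code))

    pairs: list[ProcedurePair] = []
    for key, bucket in groups.items():
        procedure, operatory, tokens = key
        for wo, wi in zip(bucket["without"], bucket["with"]):
            pairs.append(
                ProcedurePair(
                    code_without=wo,
                    code_with=wi,
                    matched_on=(
                        ("procedure", procedure),
                        ("operatory_type", operatory),
                        ("variation_tokens", ", ".join(sorted(tokens))),
                    ),
                )
            )
    pairs.sort(key=lambda p: p.code_without)
    return pairs


def percent_reduction(value_without: float, value_with: float) -> float:
    """Percent reduction from the without-EOS baseline (full precision).

    Defined as 0 when the baseline is 0 (with a logged warning); an increase
    yields a negative reduction.  Report tables round to integer percent for
    display; see :func:`comparison_to_frame`.
    """
    if value_without < 0 or value_with < 0:
        raise ValueError("values must be non-negative")
    if value_without == 0:
        if value_with != 0:
            logger.warning(
                "percent reduction undefined for zero baseline (with=%s); reporting 0",
                value_with,
            )
        return 0.0
    if value_with == 0:
        return 100.0  # total elimination; avoids 100*a/a float round-off
    return 100.0 * (value_without - value_with) / value_without


def absolute_difference(value_without: float, value_with: float) -> float:
    """Signed difference without − with."""
    if not (np.isfinite(value_without) and np.isfinite(value_with)):
        raise ValueError("values must be finite")
    return value_without - value_with


def build_comparison_table(
    pooled_without: Sequence[PooledSummary],
    pooled_with: Sequence[PooledSummary],
) -> list[ComparisonRow]:
    """One row per role × metric comparing the two pooled conditions.

    Roles must match between conditions; a role present on only one side is
    an error.
    """
    without_by_role = {s.role: s for s in pooled_without}
    with_by_role = {s.role: s for s in pooled_with}
    if set(without_by_role) != set(with_by_role):
        raise ValueError(
            f"role mismatch between conditions: {sorted(without_by_role)} vs {sorted(with_by_role)}"
        )
    rows: list[ComparisonRow] = []
    for role, wo in without_by_role.items():
        wi = with_by_role[role]
        for metric in METRICS:
            vw = getattr(wo, metric)
            vv = getattr(wi, metric)
            rows.append(
                ComparisonRow(
                    role=role,
                    metric=metric,
                    value_without=vw,
                    value_with=vv,
                    difference=absolute_difference(vw, vv),
                    reduction_pct=percent_reduction(vw, vv),
                )
            )
    return rows


def comparison_to_frame(rows: Sequence[ComparisonRow], round_reduction: bool = True) -> pd.DataFrame:
    """Tabulate comparison rows; reductions rounded to integer % for display."""
    df = pd.DataFrame(
        {
            "role": [r.role for r in rows],
            "metric": [r.metric for r in rows],
            "without_eos": [r.value_without for r in rows],
            "with_eos": [r.value_with for r in rows],
            "difference": [r.difference for r in rows],
            "reduction_pct": [r.reduction_pct for r in rows],
        }
    )
    if round_reduction:
        df["reduction_pct"] = df["reduction_pct"].round().astype(int)
    return df


def compare_study(
    records: pd.DataFrame, procedures: pd.DataFrame
) -> tuple[list[ComparisonRow], list[ProcedurePair]]:
    """End-to-end comparison for a strip-records table.

    Summarises per procedure × role, pairs procedures by EOS, pools the two
    arms per role, and builds the comparison table.  Roles appearing in only
    one arm (e.g. no assistant present) are dropped with a log message.
    """
    pairs = pair_by_eos(procedures)
    if not pairs:
        raise ValueError("no EOS pairs found in procedure metadata")
    summaries = summarize_frame(records)
    by_code_role = {(s.procedure_code, s.role): s for s in summaries}
    roles = sorted({s.role for s in summaries})
    pooled_wo, pooled_wi = [], []
    for role in roles:
        wo = [by_code_role[(p.code_without, role)] for p in pairs if (p.code_without, role) in by_code_role]
        wi = [by_code_role[(p.code_with, role)] for p in pairs if (p.code_with, role) in by_code_role]
        if not wo or not wi:
            logger.info("role %s missing from one arm; skipped", role)
            continue
        pooled_wo.append(pool_procedures(wo, condition="without EOS"))
        pooled_wi.append(pool_procedures(wi, condition="with EOS"))
    return build_comparison_table(pooled_wo, pooled_wi), pairs


@dataclass(frozen=True)
class ReductionEstimate:
    """Monte-Carlo estimate of the pooled intensity reduction with a CI."""

    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n_pairs: int
    n_boot: int


def estimate_eos_intensity_reduction(
    records: pd.DataFrame,
    procedures: pd.DataFrame,
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
) -> ReductionEstimate:
    """Pooled mean-intensity reduction over EOS pairs, with a bootstrap CI.

    Per procedure, the mean intensity over its contaminated strips (0 when
    none); pooled per arm by the unweighted mean over procedures; the CI is
    a percentile bootstrap over procedure pairs.
    """
    pairs = pair_by_eos(procedures)
    if not pairs:
        raise ValueError("no EOS pairs found")
    hit = records[records["contaminated"].astype(bool)]
    per_proc = hit.groupby("procedure_code")["intensity_pct"].mean()
    wo = np.array([per_proc.get(p.code_without, 0.0) for p in pairs])
    wi = np.array([per_proc.get(p.code_with, 0.0) for p in pairs])
    point = percent_reduction(float(wo.mean()), float(wi.mean()))

    rng = np.random.default_rng(seed)
    n = len(pairs)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = percent_reduction(float(wo[idx].mean()), float(wi[idx].mean()))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ReductionEstimate(point, float(lo), float(hi), n, n_boot)
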