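"""Distances, clock positions, furthest sites and distance profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splatquant import (
    SiteLocation,
    clock_position,
    datasets,
    distance_profile,
    furthest_contaminated,
    height_report,
    join_records_with_layout,
    site_distance,
)


def layout_records(layout, contaminated_ids, intensity=5.0):
    """Strip records for a layout with the given sites contaminated."""
    return pd.DataFrame(
        {
            "procedure_code": "P1",
            "site_id": [s.site_id for s in layout],
            "role": [s.role for s in layout],
            "distance_m": [s.distance_m for s in layout],
            "height_class": [s.height_class for s in layout],
            "contaminated": [s.site_id in contaminated_ids for s in layout],
            "intensity_pct": [intensity if s.site_id in contaminated_ids else 0.0 for s in layout],
        }
    )


class TestSiteDistance:
    def test_origin(self):
        assert site_distance(SiteLocation("o", "operatory", 0.0, 0.0)) == 0.0

    def test_three_four_five_triangle(self):
        assert site_distance(SiteLocation("t", "operatory", 0.3, 0.4)) == pytest.approx(0.5)

    def test_closed_surgery_far_corner_site(self):
        layout = {s.site_id: s for s in datasets.closed_surgery_layout()}
        site = layout["site_28"]
        assert site_distance(site) == pytest.approx(1.34)
        assert clock_position(site.clock_angle_deg) == 8

    def test_height_is_ignored(self):
        a = SiteLocation("a", "operatory", 0.3, 0.4, height_class="floor")
        b = SiteLocation("b", "operatory", 0.3, 0.4, height_class="ceiling")
        assert site_distance(a) == site_distance(b)


class TestClockPosition:
    @pytest.mark.parametrize("angle,label", [(0, 12), (90, 3), (240, 8), (150, 5), (359, 12)])
    def test_anchor_angles(self, angle, label):
        assert clock_position(angle) == label

    @given(st.floats(min_value=-720, max_value=720, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_label_is_nearest_sector(self, angle):
        label = clock_position(angle)
        assert 1 <= label <= 12
        centre = (label % 12) * 30.0
        gap = abs((angle - centre + 180.0) % 360.0 - 180.0)
        assert gap <= 15.0 + 1e-9

    def test_rotation_shifts_labels_but_not_distances(self):
        layout = datasets.closed_surgery_layout()
        for s in layout:
            rotated = SiteLocation.from_polar(
                s.site_id, s.role, s.distance_m, (s.clock_angle_deg + 60.0) % 360.0,
                s.height_class,
            )
            assert rotated.distance_m == pytest.approx(s.distance_m)
            if s.distance_m > 0:
                expected = clock_position(s.clock_angle_deg + 60.0)
                assert clock_position(rotated.clock_angle_deg) == expected


class TestFurthestContaminated:
    def test_closed_surgery_fixture(self):
        layout = datasets.closed_surgery_layout()
        records = layout_records(layout, {s.site_id for s in layout})
        assert furthest_contaminated(records) == ("site_28", 1.34)

    def test_open_clinic_fixture(self):
        layout = datasets.open_clinic_layout()
        records = layout_records(layout, {s.site_id for s in layout})
        assert furthest_contaminated(records) == ("site_43", 1.33)

    def test_no_contamination_returns_empty_signal(self):
        records = layout_records(datasets.closed_surgery_layout(), set())
        assert furthest_contaminated(records) is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            furthest_contaminated(pd.DataFrame(columns=["site_id", "distance_m", "contaminated"]))

    def test_result_bounds_every_contaminated_distance(self):
        rng = np.random.default_rng(8)
        records = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(40)],
                "distance_m": rng.uniform(0, 2, 40),
                "contaminated": rng.random(40) < 0.5,
                "intensity_pct": rng.uniform(0.1, 10, 40),
            }
        )
        _, dist = furthest_contaminated(records)
        hit = records[records.contaminated]
        assert all(dist >= round(d, 2) for d in hit.distance_m)


class TestDistanceProfile:
    def test_single_record_lands_in_first_bin(self):
        records = pd.DataFrame(
            {"site_id": ["p"], "distance_m": [0.35], "contaminated": [True],
             "intensity_pct": [12.0]}
        )
        profile = distance_profile(records, 0.5)
        assert profile.frequency_per_bin[0] == 1
        assert profile.mean_intensity_per_bin[0] == 12.0
        assert profile.bin_edges_m[0] == 0.0 and profile.bin_edges_m[1] == 0.5

    def test_contamination_confined_within_one_metre(self):
        # open-clinic pattern: splatter concentrated near the patient
        layout = datasets.open_clinic_layout()
        near = {s.site_id for s in layout if s.distance_m < 1.0}
        profile = distance_profile(layout_records(layout, near), 0.25)
        beyond = profile.bin_edges_m[:-1] >= 1.0
        assert profile.frequency_per_bin[beyond].sum() == 0

    def test_counts_conserved(self):
        layout = datasets.closed_surgery_layout()
        records = layout_records(layout, {"patient", "site_28", "bracket_table"})
        profile = distance_profile(records, 0.3)
        assert profile.frequency_per_bin.sum() == 3

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_binning(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(1, 60))
        records = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "distance_m": rng.uniform(0, 3, n),
                "contaminated": rng.random(n) < 0.6,
                "intensity_pct": rng.uniform(0.1, 50, n),
            }
        )
        width = float(rng.uniform(0.1, 0.8))
        profile = distance_profile(records, width)
        edges = profile.bin_edges_m
        hit = records[records.contaminated]
        for k in range(len(edges) - 1):
            members = [
                r.intensity_pct
                for r in hit.itertuples(index=False)
                if edges[k] <= r.distance_m < edges[k + 1]
            ]
            assert profile.frequency_per_bin[k] == len(members)
            expected_mean = sum(members) / len(members) if members else 0.0
            assert profile.mean_intensity_per_bin[k] == pytest.approx(expected_mean)
        assert profile.frequency_per_bin.sum() == len(hit)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_profile(pd.DataFrame({"distance_m": [], "contaminated": [],
                                           "intensity_pct": []}), 0.0)


def test_height_report_counts_contaminated_by_class():
    layout = datasets.closed_surgery_layout()
    records = layout_records(layout, {"patient", "site_28", "bracket_table"})
    report = height_report(records)
    counts = dict(zip(report.height_class, report.frequency_n))
    assert counts["chair"] == 1 and counts["floor"] == 1 and counts["table"] == 1
    assert counts["ceiling"] == 0


def test_join_records_with_layout_attaches_geometry():
    layout = datasets.open_clinic_layout()
    bare = pd.DataFrame(
        {
            "procedure_code": ["P1", "P1"],
            "site_id": ["site_71", "site_43"],
            "role": ["operatory", "operatory"],
            "contaminated": [True, True],
            "intensity_pct": [3.0, 1.0],
        }
    )
    joined = join_records_with_layout(bare, layout)
    d = dict(zip(joined.site_id, joined.distance_m))
    assert d["site_71"] == pytest.approx(0.22)
    assert d["site_43"] == pytest.approx(1.33)
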