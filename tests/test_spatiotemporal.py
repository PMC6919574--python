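"""Clone detection, persistence, dispersal distances and temporal bins."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonalscope.genotype_io import GenotypeError, genotype_is_complete, genotype_key
from clonalscope.spatiotemporal import (
    EARTH_RADIUS_KM,
    bin_distances,
    clone_pair_distances,
    find_clone_groups,
    haversine_km,
    region_group_distribution,
    sample_group_diversity,
    temporal_group_proportions,
    vintage_bin,
    winery_persistence,
)
from clonalscope.synthetic import SimulationConfig, simulate_population

from conftest import make_table


# --- clone groups -----------------------------------------------------------


def test_identical_isolates_form_a_clone_pair(trio_table):
    groups = find_clone_groups(trio_table)
    assert len(groups) == 1
    assert groups[0].members == ["s1", "s2"]
    assert groups[0].size == 2


def test_missing_locus_excludes_isolate_from_clone_groups(panel, uniform_diploid_lists):
    holed = list(uniform_diploid_lists)
    holed[3] = None
    table = make_table(
        panel,
        [("s1", uniform_diploid_lists), ("s2", uniform_diploid_lists), ("s4", holed)],
    )
    groups = find_clone_groups(table)
    assert len(groups) == 1
    assert "s4" not in groups[0].members


def test_clone_partition_is_an_equivalence(panel):
    """Blocks are disjoint, members within a block share their key, and
    members of different blocks differ (reflexive/symmetric/transitive)."""
    cfg = dataclasses.replace(
        SimulationConfig().scaled(0.08),
        missing_rate=0.0, plate_offset_choices=(0,), plate_offset_probs=(1.0,),
    )
    table, _ = simulate_population(cfg, seed=2)
    groups = find_clone_groups(table)
    seen = set()
    keys = {}
    for g in groups:
        assert not (set(g.members) & seen)
        seen |= set(g.members)
        member_keys = {
            genotype_key(table.get(s).genotype, table.panel) for s in g.members
        }
        assert member_keys == {g.genotype_key}
        keys[g.clone_id] = g.genotype_key
    assert len(set(keys.values())) == len(keys)


def test_planted_clone_partition_recovered_exactly():
    """Without missing data the recovered partition equals the planted one."""
    cfg = dataclasses.replace(
        SimulationConfig().scaled(0.12),
        missing_rate=0.0, plate_offset_choices=(0,), plate_offset_probs=(1.0,),
    )
    table, truth = simulate_population(cfg, seed=6)
    from clonalscope.genotype_io import drop_plate_controls

    table = drop_plate_controls(table, cfg.plate_control())
    groups = find_clone_groups(table)
    recovered = {frozenset(g.members) for g in groups}
    planted = {
        frozenset(sub["strain_id"])
        for _, sub in truth.isolates.groupby("clone_id")
        if len(sub) >= 2
    }
    assert recovered == planted


# --- persistence ------------------------------------------------------------


def _persistence_table(panel, vintages, winery="B1"):
    lists = [(100, 150)] * 12
    rows = [
        (f"p{i}", lists, {"winery": winery, "vintage_year": v, "isolation_year": 2015})
        for i, v in enumerate(vintages)
    ]
    return make_table(panel, rows)


def test_persistence_interval_spans_decades(panel):
    table = _persistence_table(panel, [1926, 2012])
    groups = find_clone_groups(table)
    (rec,) = winery_persistence(groups, table)
    assert rec.interval_years == 86
    assert rec.vintages == (1926, 2012)


def test_persistence_interval_three_vintages(panel):
    table = _persistence_table(panel, [1909, 1948, 1970])
    (rec,) = winery_persistence(find_clone_groups(table), table)
    assert rec.interval_years == 61


def test_single_vintage_produces_no_persistence_record(panel):
    table = _persistence_table(panel, [2012, 2012])
    assert winery_persistence(find_clone_groups(table), table) == []


# --- haversine --------------------------------------------------------------


def test_haversine_analytic_points():
    assert haversine_km(44.8, -0.6, 44.8, -0.6) == 0.0
    assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
        math.pi * EARTH_RADIUS_KM
    )
    assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(
        EARTH_RADIUS_KM * math.pi / 180.0
    )


def test_haversine_rejects_invalid_coordinates():
    with pytest.raises(GenotypeError):
        haversine_km(91.0, 0.0, 0.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
    st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
    st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
)
def test_haversine_symmetric_and_triangle_inequality(a, b, c):
    ab = haversine_km(*a, *b)
    ba = haversine_km(*b, *a)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert ab <= haversine_km(*a, *c) + haversine_km(*c, *b) + 1e-6


# --- pair distances and classes ---------------------------------------------


def test_clone_of_three_yields_three_pairs(panel, uniform_diploid_lists):
    rows = [
        (f"m{i}", uniform_diploid_lists, {"latitude": 44.0, "longitude": 0.0})
        for i in range(3)
    ]
    table = make_table(panel, rows)
    pairs = clone_pair_distances(find_clone_groups(table), table)
    assert len(pairs) == 3
    assert all(km == 0.0 for _, km in pairs)


def test_planted_remote_member_distance(panel, uniform_diploid_lists):
    rows = [
        ("a", uniform_diploid_lists, {"latitude": 44.84, "longitude": -0.58}),
        ("b", uniform_diploid_lists, {"latitude": 44.84, "longitude": -0.58}),
        ("c", uniform_diploid_lists, {"latitude": 38.50, "longitude": -122.45}),
    ]
    table = make_table(panel, rows)
    pairs = clone_pair_distances(find_clone_groups(table), table)
    expected = haversine_km(44.84, -0.58, 38.50, -122.45)
    assert max(km for _, km in pairs) == pytest.approx(expected, rel=1e-3)


def test_distance_binning():
    dist = bin_distances([0.4, 55, 300, 5500])
    assert dist.counts == (1, 1, 1, 0, 1)
    assert dist.local_fraction == pytest.approx(0.5)
    assert sum(dist.fractions) == pytest.approx(1.0)


def test_distance_binning_degenerate_and_boundary():
    zeros = bin_distances([0.0, 0.0])
    assert zeros.local_fraction == 1.0 and zeros.fractions[0] == 1.0
    exactly_100 = bin_distances([100.0])
    assert exactly_100.counts == (0, 0, 1, 0, 0)  # half-open classes
    assert bin_distances([]).n_pairs == 0


# --- regional and per-sample distributions ----------------------------------


def test_region_distribution_reproduces_two_group_arithmetic(panel):
    """A region of 732 isolates split 345/373/14 across three groups."""
    lists = [(100, 150)] * 12
    rows = []
    for i in range(345):
        rows.append((f"a{i}", lists, {"region": "Bordeaux", "group_label": "Wine 2N"}))
    for i in range(373):
        rows.append((f"b{i}", lists, {"region": "Bordeaux", "group_label": "1st Wine 3N"}))
    for i in range(14):
        rows.append((f"c{i}", lists, {"region": "Bordeaux", "group_label": "other"}))
    table = make_table(panel, rows)
    dist = region_group_distribution(table, by="region").set_index("group")
    assert dist.loc["Wine 2N", "fraction"] == pytest.approx(345 / 732)
    assert dist.loc["1st Wine 3N", "fraction"] == pytest.approx(373 / 732)
    assert dist["count"].sum() == 732
    assert dist["fraction"].sum() == pytest.approx(1.0)


def test_sample_group_diversity_threshold_and_flags(panel, uniform_diploid_lists):
    rows = []
    # sample A: 5 isolates, 2 groups -> counted, multi-group
    for i in range(3):
        rows.append((f"a{i}", uniform_diploid_lists,
                     {"sample_id": "A", "group_label": "G1"}))
    for i in range(2):
        rows.append((f"b{i}", uniform_diploid_lists,
                     {"sample_id": "A", "group_label": "G2"}))
    # sample B: 4 isolates -> excluded at the default threshold
    for i in range(4):
        rows.append((f"c{i}", uniform_diploid_lists,
                     {"sample_id": "B", "group_label": "G1"}))
    table = make_table(panel, rows)
    summary = sample_group_diversity(table)
    assert summary.n_samples == 1
    assert summary.n_multi_group == 1
    assert summary.per_sample.loc[0, "n_groups"] == 2


# --- vintage bins and temporal proportions ----------------------------------


@pytest.mark.parametrize(
    "year,label",
    [(1990, "1981-2000"), (2001, "2001-2020"), (1980, "1961-1980"),
     (2000, "1981-2000"), (1909, "1901-1920")],
)
def test_vintage_bins_are_anchored(year, label):
    assert vintage_bin(year).label == label


def test_vintage_bin_rejects_implausible_year():
    with pytest.raises(GenotypeError):
        vintage_bin(1492)


def test_single_group_bin_has_degenerate_ci(panel, uniform_diploid_lists):
    rows = [
        (f"s{i}", uniform_diploid_lists,
         {"vintage_year": 1995, "isolation_year": 2000, "group_label": "G"})
        for i in range(6)
    ]
    table = make_table(panel, rows)
    df = temporal_group_proportions(table, n_boot=50, seed=0)
    assert len(df) == 1
    assert df.loc[0, "proportion"] == 1.0
    assert (df.loc[0, "ci_low"], df.loc[0, "ci_high"]) == (1.0, 1.0)


def test_planted_temporal_shift_recovered(panel, uniform_diploid_lists):
    """Group A falls from 67% to 32% across two bins; estimates are exact
    and bracketed by their bootstrap CIs."""
    rows = []
    i = 0
    for vintage, n_a, n_b in [(1990, 67, 33), (2010, 32, 68)]:
        for _ in range(n_a):
            rows.append((f"s{i}", uniform_diploid_lists,
                         {"vintage_year": vintage, "isolation_year": 2015,
                          "group_label": "A"}))
            i += 1
        for _ in range(n_b):
            rows.append((f"s{i}", uniform_diploid_lists,
                         {"vintage_year": vintage, "isolation_year": 2015,
                          "group_label": "B"}))
            i += 1
    table = make_table(panel, rows)
    df = temporal_group_proportions(table, n_boot=100, seed=1)
    a = df[df["group"] == "A"].set_index("bin")
    assert a.loc["1981-2000", "proportion"] == pytest.approx(0.67)
    assert a.loc["2001-2020", "proportion"] == pytest.approx(0.32)
    assert (df["ci_low"] <= df["proportion"]).all()
    assert (df["proportion"] <= df["ci_high"]).all()
    # conservation: per-bin counts sum to the eligible isolates
    assert df.groupby("bin")["count"].sum().sum() == len(rows)


def test_temporal_proportions_seed_reproducible(panel, uniform_diploid_lists):
    rows = [
        (f"s{i}", uniform_diploid_lists,
         {"vintage_year": 1985 + i, "isolation_year": 2015,
          "group_label": "A" if i % 3 else "B"})
        for i in range(30)
    ]
    table = make_table(panel, rows)
    df1 = temporal_group_proportions(table, n_boot=40, seed=5)
    df2 = temporal_group_proportions(table, n_boot=40, seed=5)
    assert df1.equals(df2)
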