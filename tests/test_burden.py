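"""DALY allocation: direct links, equal-split disaggregation, nominal fallback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpriority.burden import (
    AllocationSource,
    allocate_dalys,
    cluster_daly_totals,
    cumulative_daly_shares,
)
from idpriority.clustering import assign_clusters
from idpriority.errors import ValidationError
from idpriority.registry import BurdenCategory, BurdenLink, DiseaseRecord, LinkKind


def _rec(name, link, option=4, transmission="t"):
    return DiseaseRecord(name, option, "virus", "", transmission,
                         burden_link=BurdenLink.parse(link))


def test_direct_link_identity():
    recs = [_rec("a", "direct:C1")]
    cats = [BurdenCategory("C1", "c", 1234.5)]
    (alloc,) = allocate_dalys(recs, cats)
    assert alloc.dalys == 1234.5 and alloc.source is AllocationSource.DIRECT


def test_equal_split_conserves():
    recs = [_rec(n, "member_of:C1") for n in "abc"]
    cats = [BurdenCategory("C1", "c", 3000.0, ["a", "b", "c"])]
    allocs = allocate_dalys(recs, cats)
    assert [a.dalys for a in allocs] == [1000.0] * 3


def test_unreconciled_gets_nominal():
    (alloc,) = allocate_dalys([_rec("a", "none")], [])
    assert alloc.dalys == 100.0 and alloc.source is AllocationSource.NOMINAL
    (alloc,) = allocate_dalys([_rec("a", "none")], [], nominal=7.0)
    assert alloc.dalys == 7.0


def test_zero_valued_direct_category_is_not_nominal():
    """A measured zero keeps 0 with source=direct — distinct from
    'could not be reconciled'."""
    recs = [_rec("a", "direct:C1")]
    cats = [BurdenCategory("C1", "c", 0.0)]
    (alloc,) = allocate_dalys(recs, cats)
    assert alloc.dalys == 0.0 and alloc.source is AllocationSource.DIRECT


def test_double_membership_names_both_categories():
    recs = [_rec("a", "member_of:C1")]
    cats = [
        BurdenCategory("C1", "c", 10.0, ["a"]),
        BurdenCategory("C2", "c", 20.0, ["a"]),
    ]
    with pytest.raises(ValidationError, match="C1.*C2"):
        allocate_dalys(recs, cats)


def test_member_link_must_agree_with_category():
    recs = [_rec("a", "member_of:C1")]
    cats = [BurdenCategory("C1", "c", 10.0, [])]
    with pytest.raises(ValidationError, match="does not list"):
        allocate_dalys(recs, cats)


def test_weighted_split_option():
    recs = [_rec("a", "member_of:C1"), _rec("b", "member_of:C1")]
    cats = [BurdenCategory("C1", "c", 300.0, ["a", "b"])]
    allocs = allocate_dalys(recs, cats, weights={"C1": {"a": 2.0, "b": 1.0}})
    assert [a.dalys for a in allocs] == [200.0, 100.0]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_conservation_property(data):
    """Sum of allocations == sum of category values + nominal * n_unlinked."""
    n_direct = data.draw(st.integers(0, 5))
    groups = data.draw(st.lists(st.integers(1, 6), max_size=4))
    n_none = data.draw(st.integers(0, 5))
    values = st.floats(0, 1e8, allow_nan=False, allow_infinity=False)
    recs, cats = [], []
    for i in range(n_direct):
        recs.append(_rec(f"d{i}", f"direct:D{i}"))
        cats.append(BurdenCategory(f"D{i}", "x", data.draw(values)))
    for g, size in enumerate(groups):
        names = [f"m{g}_{j}" for j in range(size)]
        recs += [_rec(n, f"member_of:G{g}") for n in names]
        cats.append(BurdenCategory(f"G{g}", "x", data.draw(values), names))
    recs += [_rec(f"n{i}", "none") for i in range(n_none)]
    allocs = allocate_dalys(recs, cats)
    assert len(allocs) == len(recs)
    expected = sum(c.daly_value for c in cats) + 100.0 * n_none
    assert sum(a.dalys for a in allocs) == pytest.approx(expected, rel=1e-9)
    # equal-split symmetry within each aggregated category
    for g, size in enumerate(groups):
        shares = {a.dalys for a in allocs if a.disease.startswith(f"m{g}_")}
        assert len(shares) == 1


def test_cluster_totals_include_all_options():
    recs = [
        _rec("a", "direct:C1", option=4),
        _rec("b", "direct:C2", option=2),  # occurrence-mapping member still counts
    ]
    cats = [BurdenCategory("C1", "c", 10.0), BurdenCategory("C2", "c", 5.0)]
    clusters = assign_clusters(recs)
    clusters = cluster_daly_totals(clusters, allocate_dalys(recs, cats))
    assert clusters[0].total_dalys == 15.0


def test_singleton_total_is_identity():
    recs = [_rec("a", "direct:C1")]
    cats = [BurdenCategory("C1", "c", 42.0)]
    clusters = cluster_daly_totals(assign_clusters(recs),
                                   allocate_dalys(recs, cats))
    assert clusters[0].total_dalys == 42.0


def test_missing_allocation_rejected():
    recs = [_rec("a", "direct:C1")]
    clusters = assign_clusters(recs)
    with pytest.raises(ValidationError, match="no burden allocation"):
        cluster_daly_totals(clusters, [])


def _clusters_with_totals(totals):
    recs = [_rec(f"d{i}", "none", transmission=f"t{i}") for i in range(len(totals))]
    clusters = assign_clusters(recs)
    by_member = {c.members[0]: c for c in clusters}
    for i, t in enumerate(totals):
        by_member[f"d{i}"].total_dalys = float(t)
    return [by_member[f"d{i}"] for i in range(len(totals))]


def test_cumulative_shares_arithmetic():
    assert cumulative_daly_shares(_clusters_with_totals([60, 30, 10])) == pytest.approx(
        [60.0, 90.0, 100.0]
    )
    assert cumulative_daly_shares(_clusters_with_totals([7])) == [100.0]


def test_cumulative_shares_all_zero_rejected():
    with pytest.raises(ValidationError, match="undefined"):
        cumulative_daly_shares(_clusters_with_totals([0, 0]))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1e9, allow_nan=False), min_size=1).filter(
    lambda xs: sum(xs) > 0))
def test_cumulative_shares_monotone_end_at_100(totals):
    shares = cumulative_daly_shares(_clusters_with_totals(totals))
    assert all(b >= a - 1e-9 for a, b in zip(shares, shares[1:]))
    assert shares[-1] == 100.0
    assert np.all(np.asarray(shares) <= 100.0 + 1e-9)
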