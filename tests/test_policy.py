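"""Policy scoring: h-index, banding, stakeholder/notifiable points,
cluster means, and the stakeholder accumulation curve."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpriority.clustering import assign_clusters
from idpriority.errors import ValidationError
from idpriority.policy import (
    accumulation_curve,
    cluster_policy_mean,
    expand_portfolio,
    hindex_from_citations,
    hindex_points,
    notifiable_points,
    policy_score,
    stakeholder_points,
)
from idpriority.registry import (
    DiseaseRecord,
    NotifiableList,
    StakeholderPortfolio,
    canonical,
)


def brute_force_hindex(counts):
    """Independent oracle: try every candidate h from 0 to len(counts)."""
    return max(
        (h for h in range(len(counts) + 1)
         if sum(1 for c in counts if c >= h) >= h),
        default=0,
    )


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([], 0),
        ([10, 9, 8, 7, 7, 7, 7, 2], 7),
        ([1, 1, 1], 1),
        ([0, 0], 0),
        ([5], 1),
    ],
)
def test_hindex_examples(counts, expected):
    assert hindex_from_citations(counts) == expected
    assert brute_force_hindex(counts) == expected


def test_hindex_negative_rejected():
    with pytest.raises(ValidationError):
        hindex_from_citations([3, -1])


def test_hindex_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        counts = rng.integers(0, 40, size=rng.integers(0, 30)).tolist()
        assert hindex_from_citations(counts) == brute_force_hindex(counts)


@pytest.mark.parametrize(
    "h, points",
    [(461, 2), (101, 2), (100, 1.5), (75, 1.5), (51, 1.5), (50, 1), (0, 1)],
)
def test_hindex_bands_closed_at_50_and_100(h, points):
    assert hindex_points(h) == points


MALARIA = ["Plasmodium falciparum", "P. vivax", "P. knowlesi"]
LABELS = {"Malaria": MALARIA}


def test_stakeholder_points_zero_without_interest():
    portfolios = [StakeholderPortfolio("s1", ["Dengue"])]
    assert stakeholder_points("HIV", portfolios, ["Dengue", "HIV"], {}) == 0


def test_cluster_label_propagates_to_members():
    portfolios = [StakeholderPortfolio("s1", ["malaria"])]
    for disease in MALARIA:
        assert stakeholder_points(disease, portfolios, MALARIA, LABELS) == 1


def test_disease_and_label_from_same_stakeholder_count_once():
    portfolios = [StakeholderPortfolio("s1", ["Malaria", "P. vivax"])]
    assert stakeholder_points("P. vivax", portfolios, MALARIA, LABELS) == 1


def test_unresolvable_interest_rejected():
    with pytest.raises(ValidationError, match="matches no registry disease"):
        expand_portfolio(StakeholderPortfolio("s1", ["Dragon pox"]), MALARIA, LABELS)


LISTS = [
    NotifiableList("USA", {"Dengue"}),
    NotifiableList("Brazil", {"Dengue", "HIV"}),
]


def test_notifiable_modes():
    assert notifiable_points("Cholera", LISTS) == 0
    assert notifiable_points("HIV", LISTS, mode="any") == 1
    assert notifiable_points("Dengue", LISTS, mode="any") == 1
    assert notifiable_points("Dengue", LISTS, mode="per_country") == 2
    with pytest.raises(ValidationError, match="unknown notifiable mode"):
        notifiable_points("Dengue", LISTS, mode="sometimes")


@pytest.mark.parametrize(
    "n_stake, notifiable, h, expected",
    [(8, True, 120, 11.0), (0, False, 3, 1.0), (6, False, 60, 7.5)],
)
def test_policy_score_arithmetic(n_stake, notifiable, h, expected):
    portfolios = [StakeholderPortfolio(f"s{i}", ["Dengue"]) for i in range(n_stake)]
    portfolios = portfolios or [StakeholderPortfolio("s0", ["Other"])]
    lists = [NotifiableList("USA", {"Dengue"} if notifiable else {"Other"})]
    comp = policy_score("Dengue", portfolios, lists, h, ["Dengue", "Other"], {})
    assert comp.total == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 20), st.booleans(), st.integers(0, 500))
def test_policy_total_bounds(n_stake, notifiable, h):
    """With S stakeholders and mode 'any', every total lies in [1, S + 3]."""
    S = 20
    portfolios = [
        StakeholderPortfolio(f"s{i}", ["Dengue" if i < n_stake else "Other"])
        for i in range(S)
    ]
    lists = [NotifiableList("USA", {"Dengue"} if notifiable else set())]
    total = policy_score("Dengue", portfolios, lists, h,
                         ["Dengue", "Other"], {}).total
    assert 1 <= total <= S + 1 + 2


def _scored_cluster(names_options, scores):
    recs = [
        DiseaseRecord(n, opt, "virus", "", "t") for n, opt in names_options
    ]
    clusters = assign_clusters(recs)
    from idpriority.registry import PolicyComponents

    comp = {}
    for (n, _), total in zip(names_options, scores):
        s = total - 1.0
        comp[canonical(n)] = PolicyComponents(int(s), s - int(s), 1.0)
    by_name = {canonical(r.name): r for r in recs}
    return clusters[0], comp, by_name


def test_cluster_mean_over_priority_only():
    cluster, scores, recs = _scored_cluster(
        [("a", 4), ("b", 2)], [10.0, 2.0]
    )
    mean, defined = cluster_policy_mean(cluster, scores, recs)
    assert mean == 10.0 and defined


def test_cluster_mean_matches_table_precision():
    cluster, scores, recs = _scored_cluster(
        [("a", 4), ("b", 5), ("c", 4)], [12.0, 11.5, 12.0]
    )
    mean, _ = cluster_policy_mean(cluster, scores, recs)
    assert mean == pytest.approx(11.8333, abs=1e-4)
    assert f"{mean:.1f}" == "11.8"


def test_cluster_without_priority_flagged_not_failed():
    cluster, scores, recs = _scored_cluster([("a", 2), ("b", 3)], [5.0, 5.0])
    mean, defined = cluster_policy_mean(cluster, scores, recs)
    assert mean == 0.0 and not defined


# ---------------------------------------------------------------------------
# accumulation curve
# ---------------------------------------------------------------------------


def _portfolios(sets):
    return [StakeholderPortfolio(f"s{i}", sorted(s)) for i, s in enumerate(sets)]


def exhaustive_curve(sets):
    """Oracle: enumerate every stakeholder ordering and average the running
    unique-disease counts."""
    S = len(sets)
    sums = [0.0] * S
    for order in itertools.permutations(range(S)):
        seen = set()
        for k, idx in enumerate(order):
            seen |= sets[idx]
            sums[k] += len(seen)
    return [s / math.factorial(S) for s in sums]


def test_identical_portfolios_flat_curve():
    sets = [{"a", "b", "c"}] * 4
    names = ["a", "b", "c"]
    curve = accumulation_curve(_portfolios(sets), names, {}, exact=True)
    assert curve.mean_unique == [3.0] * 4
    assert curve.union_size == 3


def test_disjoint_portfolios_closed_form():
    """For disjoint portfolios the exact mean at k is (k/S) * total."""
    sets = [{"a"}, {"b", "c"}, {"d", "e", "f"}]
    names = list("abcdef")
    curve = accumulation_curve(_portfolios(sets), names, {}, exact=True)
    total = 6
    assert curve.mean_unique == pytest.approx([k / 3 * total for k in (1, 2, 3)])
    assert curve.mean_unique == pytest.approx(exhaustive_curve(sets))


def test_single_portfolio_curve():
    curve = accumulation_curve(_portfolios([{"a", "b"}]), ["a", "b"], {}, exact=True)
    assert curve.mean_unique == [2.0]


@pytest.mark.parametrize("seed", [0, 1])
def test_exact_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    universe = [f"d{i}" for i in range(8)]
    sets = [
        set(rng.choice(universe, size=rng.integers(1, 5), replace=False))
        for _ in range(4)
    ]
    curve = accumulation_curve(_portfolios(sets), universe, {}, exact=True)
    assert curve.mean_unique == pytest.approx(exhaustive_curve(sets))


def test_monte_carlo_monotone_terminal_and_deterministic():
    rng = np.random.default_rng(3)
    universe = [f"d{i}" for i in range(40)]
    sets = [
        set(rng.choice(universe, size=rng.integers(1, 12), replace=False))
        for _ in range(20)
    ]
    union = set().union(*sets)
    a = accumulation_curve(_portfolios(sets), universe, {}, n_permutations=199, seed=5)
    b = accumulation_curve(_portfolios(sets), universe, {}, n_permutations=199, seed=5)
    c = accumulation_curve(_portfolios(sets), universe, {}, n_permutations=199, seed=6)
    assert a.mean_unique == b.mean_unique  # deterministic given seed
    assert a.mean_unique[-1] == len(union) == c.mean_unique[-1]  # seed-free terminal
    assert all(y >= x for x, y in zip(a.mean_unique, a.mean_unique[1:]))


def test_duplicate_stakeholder_keeps_union():
    sets = [{"a", "b"}, {"c"}]
    names = ["a", "b", "c"]
    before = accumulation_curve(_portfolios(sets), names, {}, exact=True)
    after = accumulation_curve(_portfolios(sets + [{"a", "b"}]), names, {}, exact=True)
    assert before.union_size == after.union_size == 3


def test_cluster_names_expanded_before_counting():
    portfolios = [StakeholderPortfolio("s1", ["Malaria"])]
    curve = accumulation_curve(portfolios, MALARIA, LABELS, exact=True)
    assert curve.mean_unique == [3.0]


def test_accumulation_validation():
    with pytest.raises(ValidationError):
        accumulation_curve([], ["a"], {})
    with pytest.raises(ValidationError, match="n_permutations"):
        accumulation_curve(_portfolios([{"a"}]), ["a"], {}, n_permutations=0)
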