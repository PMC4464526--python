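"""Projection ranking toward the hypothetical ideal cluster."""

import math
import random

import numpy as np
import pytest

from idpriority.clustering import ClusterKey, ClusterSummary
from idpriority.errors import ValidationError
from idpriority.ranking import (
    RankingConfig,
    project_cluster,
    rank_clusters,
    select_top,
)
from idpriority.synthetic import generate_planted_clusters


def _cluster(label, dalys, policy, n_priority=1, n_total=1):
    members = [f"{label} m{i}" for i in range(n_total)]
    return ClusterSummary(
        key=ClusterKey("virus", "", label),
        label=label,
        members=members,
        n_total=n_total,
        n_priority=n_priority,
        total_dalys=float(dalys),
        mean_policy=float(policy),
        priority_members=members[:n_priority],
    )


def test_ideal_cluster_scores_sqrt2():
    c = _cluster("ideal", 1e6, 10.0)
    x, y, score = project_cluster(c, RankingConfig(), (10.0, 1e6))
    assert (x, y) == (1.0, 1.0)
    assert score == pytest.approx(math.sqrt(2))


def test_origin_scores_zero():
    c = _cluster("origin", 1.0, 0.0)  # log10(1) = 0 on the burden axis
    _, _, score = project_cluster(c, RankingConfig(), (10.0, 1e6))
    assert score == 0.0


def test_log10_rejects_nonpositive_dalys():
    c = _cluster("zero", 0.0, 5.0)
    with pytest.raises(ValidationError, match="floor|linear"):
        project_cluster(c, RankingConfig(), (10.0, 1e6))
    x, y, _ = project_cluster(c, RankingConfig(daly_transform="linear"), (10.0, 1e6))
    assert y == 0.0


def test_printed_top_three_order():
    """From the printed (policy, DALY) pairs: malaria above HIV above
    tuberculosis under the default log/ratio projection."""
    malaria = _cluster("Malaria", 65_493_135, 11.8)
    hiv = _cluster("HIV", 69_480_661, 11.0)
    tb = _cluster("Tuberculosis", 49_816_215, 11.0)
    result = rank_clusters([tb, hiv, malaria])
    assert result.labels() == ["Malaria", "HIV", "Tuberculosis"]


def test_dominance_implies_better_rank():
    a = _cluster("a", 2e6, 8.0)
    b = _cluster("b", 1e6, 7.0)
    result = rank_clusters([b, a])
    assert result.labels() == ["a", "b"]


def test_order_invariance():
    clusters, _ = generate_planted_clusters(n_clusters=9, seed=2)
    base = rank_clusters(clusters).labels()
    shuffled = list(clusters)
    random.Random(0).shuffle(shuffled)
    assert rank_clusters(shuffled).labels() == base


def test_tie_break_deterministic():
    # identical clusters: adjacent ranks, label order decides
    a = _cluster("alpha", 1e6, 5.0)
    b = _cluster("beta", 1e6, 5.0)
    assert rank_clusters([b, a]).labels() == ["alpha", "beta"]
    # equal projections with unequal burden: higher DALYs first
    # (x, y) = (1, 0.5) vs (0.5, 1) given maxima (10, 1e6)
    lo = _cluster("low-burden", 1e3, 10.0)
    hi = _cluster("high-burden", 1e6, 5.0)
    assert rank_clusters([lo, hi]).labels() == ["high-burden", "low-burden"]


def test_ranks_contiguous_and_scores_non_increasing():
    clusters, _ = generate_planted_clusters(n_clusters=15, seed=4)
    result = rank_clusters(clusters)
    assert [e.rank for e in result.entries] == list(range(1, 16))
    scores = [e.projection_score for e in result.entries]
    assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))


def test_priority_members_alphabetical(published_clusters):
    result = rank_clusters(published_clusters)
    for names in result.priority_diseases.values():
        assert names == sorted(names, key=str.lower)


def test_empty_input_rejected():
    with pytest.raises(ValidationError):
        rank_clusters([])


def test_pareto_consistency_random():
    """Improving a cluster on either axis (others fixed) never worsens its
    rank."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = 8
        clusters = [
            _cluster(f"c{i}", 10 ** rng.uniform(3, 7.5), rng.integers(2, 25) / 2)
            for i in range(n)
        ]
        result = rank_clusters(clusters)
        ranks = {e.cluster.label: e.rank for e in result.entries}
        i = int(rng.integers(n))
        improved = [
            _cluster(c.label, c.total_dalys, c.mean_policy) for c in clusters
        ]
        if rng.random() < 0.5:
            improved[i].total_dalys *= 1.5
        else:
            improved[i].mean_policy += 1.0
        new_ranks = {e.cluster.label: e.rank for e in rank_clusters(improved).entries}
        assert new_ranks[f"c{i}"] <= ranks[f"c{i}"]


def test_ideal_point_maximality():
    """A cluster at the observed maxima on both axes always ranks first."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        clusters = [
            _cluster(f"c{i}", 10 ** rng.uniform(3, 7), rng.integers(2, 21) / 2)
            for i in range(6)
        ]
        dmax = max(c.total_dalys for c in clusters)
        pmax = max(c.mean_policy for c in clusters)
        best = _cluster("best", dmax, pmax)
        first = rank_clusters(clusters + [best]).entries[0].cluster
        assert (first.total_dalys, first.mean_policy) == (dmax, pmax)


def test_planted_order_recovery():
    for seed in range(100):
        clusters, planted = generate_planted_clusters(n_clusters=10, seed=seed)
        assert rank_clusters(clusters).labels() == planted


def test_select_top_shares_and_clamp():
    clusters = [_cluster("a", 60, 3.0), _cluster("b", 30, 2.0), _cluster("c", 10, 1.0)]
    result = rank_clusters(clusters)
    assert select_top(result, 1).cumulative_share_pct == pytest.approx(60.0)
    assert select_top(result, 3).cumulative_share_pct == 100.0
    with pytest.warns(UserWarning, match="clamping"):
        top = select_top(result, 10)
    assert len(top.entries) == 3
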