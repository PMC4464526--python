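"""Composite policy-interest scoring and the stakeholder accumulation curve.

A disease's policy score is the sum of three components:

* stakeholder points — one point per distinct surveyed stakeholder whose
  portfolio names the disease, either directly or through its cluster-level
  label ("malaria", "leishmaniasis"); a cluster-level mention propagates to
  every member disease, and naming a disease both ways earns one point only;
* a notifiable point — 1 if the disease is notifiable in at least one of the
  sampled countries (default), or one point per listing country in the
  optional ``per_country`` mode;
* an h-index band — 2 for very high academic output (h > 100), 1.5 for
  intermediate (50 < h <= 100), 1 otherwise (h <= 50).

Only Option 4/5 diseases enter a cluster's average score: averaging over the
whole cluster would let many low-scoring occurrence-mapping diseases mask
the high-priority ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .registry import (
    DiseaseRecord,
    NotifiableList,
    PolicyComponents,
    StakeholderPortfolio,
    canonical,
)
from .clustering import ClusterSummary

NOTIFIABLE_MODES = ("any", "per_country")


def hindex_from_citations(counts: Sequence[int]) -> int:
    """The h-index of a citation-count list: the largest h such that at
    least h entries are >= h.  Empty list -> 0."""
    for c in counts:
        if c < 0:
            raise ValidationError(f"citation count must be >= 0, got {c}")
    ordered = sorted(counts, reverse=True)
    h = 0
    for i, c in enumerate(ordered, start=1):
        if c >= i:
            h = i
        else:
            break
    return h


def hindex_points(h: int) -> float:
    """Band an h-index into the score {1, 1.5, 2}.  The bands are closed at
    50 and 100 (h <= 50 -> 1, 50 < h <= 100 -> 1.5, h > 100 -> 2) so they
    are exhaustive."""
    if h < 0:
        raise ValidationError(f"h-index must be >= 0, got {h}")
    if h > 100:
        return 2.0
    if h > 50:
        return 1.5
    return 1.0


def resolve_hindex(
    disease: str, citations: Mapping[str, Union[Sequence[int], int]]
) -> int:
    """Look up a disease's h-index: precomputed integer or computed from its
    citation-count list.  Mapping keys are matched case-insensitively."""
    key = canonical(disease)
    citations = {canonical(k): v for k, v in citations.items()}
    if key not in citations:
        raise ValidationError(
            f"disease {disease!r}: no h-index and no citation list supplied"
        )
    value = citations[key]
    if isinstance(value, (int, np.integer)):
        if value < 0:
            raise ValidationError(f"disease {disease!r}: h-index must be >= 0")
        return int(value)
    return hindex_from_citations(value)


def expand_portfolio(
    portfolio: StakeholderPortfolio,
    registry_names: Iterable[str],
    cluster_labels: Mapping[str, Sequence[str]],
) -> set[str]:
    """Resolve a portfolio's interest names to a set of canonical disease
    names.  Each name must match a registry disease or a cluster label
    (case-insensitively); cluster labels expand to every member disease.
    Unresolvable names are an error — silent misses would bias scores
    downward invisibly."""
    known = {canonical(n) for n in registry_names}
    labels = {canonical(lab): members for lab, members in cluster_labels.items()}
    diseases: set[str] = set()
    for interest in portfolio.interests:
        key = canonical(interest)
        if key in known:
            diseases.add(key)
        elif key in labels:
            diseases.update(canonical(m) for m in labels[key])
        else:
            raise ValidationError(
                f"stakeholder {portfolio.stakeholder_id!r}: interest "
                f"{interest!r} matches no registry disease or cluster label"
            )
    return diseases


def _expanded_portfolios(
    portfolios: Sequence[StakeholderPortfolio],
    registry_names: Iterable[str],
    cluster_labels: Mapping[str, Sequence[str]],
) -> list[set[str]]:
    names = list(registry_names)
    return [expand_portfolio(p, names, cluster_labels) for p in portfolios]


def stakeholder_points(
    disease: str,
    portfolios: Sequence[StakeholderPortfolio],
    registry_names: Iterable[str],
    cluster_labels: Mapping[str, Sequence[str]],
) -> int:
    """One point per distinct stakeholder interested in the disease, whether
    named directly or through its cluster label."""
    key = canonical(disease)
    expanded = _expanded_portfolios(portfolios, registry_names, cluster_labels)
    return sum(1 for s in expanded if key in s)


def notifiable_points(
    disease: str, lists: Sequence[NotifiableList], mode: str = "any"
) -> float:
    if mode not in NOTIFIABLE_MODES:
        raise ValidationError(
            f"unknown notifiable mode {mode!r}; expected one of {NOTIFIABLE_MODES}"
        )
    key = canonical(disease)
    n = sum(1 for lst in lists if key in {canonical(d) for d in lst.diseases})
    if mode == "any":
        return 1.0 if n >= 1 else 0.0
    return float(n)


def policy_score(
    disease: str,
    portfolios: Sequence[StakeholderPortfolio],
    lists: Sequence[NotifiableList],
    hindex: int,
    registry_names: Iterable[str],
    cluster_labels: Mapping[str, Sequence[str]],
    notifiable_mode: str = "any",
) -> PolicyComponents:
    """Assemble the three score components for one disease."""
    return PolicyComponents(
        stakeholder_points=stakeholder_points(
            disease, portfolios, registry_names, cluster_labels
        ),
        notifiable_points=notifiable_points(disease, lists, notifiable_mode),
        hindex_points=hindex_points(hindex),
    )


def score_all(
    records: Sequence[DiseaseRecord],
    portfolios: Sequence[StakeholderPortfolio],
    lists: Sequence[NotifiableList],
    citations: Mapping[str, Union[Sequence[int], int]],
    cluster_labels: Mapping[str, Sequence[str]],
    notifiable_mode: str = "any",
) -> dict[str, PolicyComponents]:
    """Score every registry disease; returns a canonical-name-keyed dict.

    Portfolios are expanded once, so this is the efficient path for the
    pipeline (stakeholder_points re-expands per call).
    """
    names = [r.name for r in records]
    expanded = _expanded_portfolios(portfolios, names, cluster_labels)
    notif_sets = [{canonical(d) for d in lst.diseases} for lst in lists]
    if notifiable_mode not in NOTIFIABLE_MODES:
        raise ValidationError(
            f"unknown notifiable mode {notifiable_mode!r}; "
            f"expected one of {NOTIFIABLE_MODES}"
        )
    scores: dict[str, PolicyComponents] = {}
    for rec in records:
        key = canonical(rec.name)
        s = sum(1 for e in expanded if key in e)
        n_countries = sum(1 for ns in notif_sets if key in ns)
        notif = (
            float(n_countries)
            if notifiable_mode == "per_country"
            else (1.0 if n_countries else 0.0)
        )
        h = resolve_hindex(rec.name, citations)
        rec.hindex = h
        comp = PolicyComponents(s, notif, hindex_points(h))
        rec.policy = comp
        scores[key] = comp
    return scores


def cluster_policy_mean(
    cluster: ClusterSummary,
    scores: Mapping[str, PolicyComponents],
    records: Mapping[str, DiseaseRecord],
) -> tuple[float, bool]:
    """Arithmetic mean of total policy scores over the cluster's Option 4/5
    members only.  Returns (mean, defined); a cluster with no Option 4/5
    member gets mean 0 and defined=False (flagged, not failed)."""
    totals = []
    for member in cluster.members:
        key = canonical(member)
        rec = records[key]
        if not rec.is_priority:
            continue
        if key not in scores:
            raise ValidationError(
                f"cluster {cluster.label!r}: Option 4/5 member {member!r} "
                f"has no policy score"
            )
        totals.append(scores[key].total)
    if not totals:
        return 0.0, False
    return sum(totals) / len(totals), True


def apply_cluster_policy(
    clusters: Sequence[ClusterSummary],
    scores: Mapping[str, PolicyComponents],
    records: Sequence[DiseaseRecord],
) -> list[ClusterSummary]:
    by_name = {canonical(r.name): r for r in records}
    for cluster in clusters:
        mean, defined = cluster_policy_mean(cluster, scores, by_name)
        cluster.mean_policy = mean
        cluster.policy_defined = defined
    return list(clusters)


@dataclass
class AccumulationCurve:
    """Mean number of unique diseases covered by the first k stakeholders,
    averaged over random stakeholder orderings, for k = 1..S."""

    n_permutations: int
    mean_unique: list[float]
    union_size: int

    def __post_init__(self) -> None:
        if any(b < a - 1e-9 for a, b in zip(self.mean_unique, self.mean_unique[1:])):
            raise ValidationError("accumulation curve must be non-decreasing")


def accumulation_curve(
    portfolios: Sequence[StakeholderPortfolio],
    registry_names: Iterable[str],
    cluster_labels: Mapping[str, Sequence[str]],
    n_permutations: int = 999,
    seed: Optional[int] = None,
    exact: bool = False,
) -> AccumulationCurve:
    """Stakeholder ("species") accumulation curve.

    Cluster-level interests are expanded to member diseases before counting.
    With ``exact=True`` all S! stakeholder orderings are enumerated (use for
    small S); otherwise ``n_permutations`` Monte-Carlo orderings are drawn
    from a generator seeded with ``seed``, making the curve reproducible.
    The terminal value equals the union size exactly in both modes.
    """
    if not portfolios:
        raise ValidationError("accumulation_curve: need at least one portfolio")
    if not exact and n_permutations < 1:
        raise ValidationError("accumulation_curve: n_permutations must be >= 1")
    expanded = _expanded_portfolios(portfolios, registry_names, cluster_labels)
    S = len(expanded)
    union = set().union(*expanded)

    if exact:
        orderings = list(itertools.permutations(range(S)))
    else:
        rng = np.random.default_rng(seed)
        orderings = [rng.permutation(S) for _ in range(n_permutations)]

    sums = np.zeros(S)
    for order in orderings:
        seen: set[str] = set()
        for k, idx in enumerate(order):
            seen |= expanded[idx]
            sums[k] += len(seen)
    means = sums / len(orderings)
    means[-1] = float(len(union))  # invariant: exact terminal union size
    return AccumulationCurve(
        n_permutations=len(orderings),
        mean_unique=[float(m) for m in means],
        union_size=len(union),
    )


def coverage_summary(
    records: Sequence[DiseaseRecord],
    portfolios: Sequence[StakeholderPortfolio],
    lists: Sequence[NotifiableList],
    cluster_labels: Mapping[str, Sequence[str]],
) -> dict:
    """Fraction of registry diseases prioritised by >= 1 stakeholder (after
    cluster-label expansion) and notifiable in >= 1 sampled country."""
    names = [r.name for r in records]
    expanded = _expanded_portfolios(portfolios, names, cluster_labels)
    covered = set().union(*expanded) if expanded else set()
    notif = set()
    for lst in lists:
        notif |= {canonical(d) for d in lst.diseases}
    keys = {canonical(n) for n in names}
    n = len(keys)
    n_cov = len(covered & keys)
    n_notif = len(notif & keys)
    return {
        "n_diseases": n,
        "n_stakeholder_covered": n_cov,
        "n_notifiable": n_notif,
        "stakeholder_coverage_pct": 100.0 * n_cov / n if n else math.nan,
        "notifiable_coverage_pct": 100.0 * n_notif / n if n else math.nan,
    }
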