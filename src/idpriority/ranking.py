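"""Rank mapping clusters by projection toward a hypothetical ideal cluster.

Each cluster is placed on a plane whose axes are its mean policy score of
Option 4/5 diseases (linear) and its total DALY burden (log scale by
default, mirroring the spread of burdens over five orders of magnitude).
The hypothetical ideal cluster sits at the observed maxima of both axes —
the burden of the biggest-burden cluster and the policy score of the most
favoured cluster.  After normalising both axes by their maxima so the ideal
is at (1, 1), clusters are ordered by their scalar projection onto the
origin→ideal diagonal, (x + y)/√2: the further along that axis, the higher
the priority.  Projection toward the ideal and distance from the ideal along
the same axis induce the same order; the projection form is used because it
is also defined at the origin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .burden import cumulative_daly_shares
from .clustering import ClusterSummary
from .errors import ValidationError
from .registry import canonical

DALY_TRANSFORMS = ("log10", "linear")
TIE_BREAKS = ("higher_dalys_first",)


@dataclass
class RankingConfig:
    daly_transform: str = "log10"
    tie_break: str = "higher_dalys_first"
    top_k: int = 15

    def __post_init__(self) -> None:
        if self.daly_transform not in DALY_TRANSFORMS:
            raise ValidationError(
                f"daly_transform must be one of {DALY_TRANSFORMS}, "
                f"got {self.daly_transform!r}"
            )
        if self.tie_break not in TIE_BREAKS:
            raise ValidationError(
                f"tie_break must be one of {TIE_BREAKS}, got {self.tie_break!r}"
            )
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


@dataclass
class RankedCluster:
    rank: int
    cluster: ClusterSummary
    x: float
    y: float
    projection_score: float


@dataclass
class PrioritisationResult:
    entries: list[RankedCluster]
    priority_diseases: dict[str, list[str]] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return [e.cluster.label for e in self.entries]


@dataclass
class TopSelection:
    entries: list[RankedCluster]
    pooled_priority_count: int
    cumulative_share_pct: float


def _transform(dalys: float, transform: str, max_dalys: float) -> float:
    if transform == "linear":
        return dalys / max_dalys if max_dalys > 0 else 0.0
    if dalys <= 0:
        raise ValidationError(
            "log10 DALY transform undefined for non-positive totals; "
            "apply a floor to the allocations or use the linear transform"
        )
    denom = math.log10(max_dalys)
    if denom <= 0:
        raise ValidationError(
            "log10 DALY transform needs the maximum cluster total > 1"
        )
    return math.log10(dalys) / denom


def project_cluster(
    cluster: ClusterSummary,
    config: RankingConfig,
    maxima: tuple[float, float],
) -> tuple[float, float, float]:
    """Project one cluster onto the origin→ideal axis.

    ``maxima`` = (max mean policy, max total DALYs) — the observed maxima
    that define the hypothetical ideal cluster.  Returns (x, y, projection);
    x and y lie in [0, 1] with the ideal at (1, 1) and projection =
    (x + y)/√2, maximal (= √2) at the ideal itself.
    """
    policy_max, daly_max = maxima
    if cluster.total_dalys is None or cluster.mean_policy is None:
        raise ValidationError(
            f"cluster {cluster.label!r}: totals/means not computed; "
            f"run the burden and scoring stages first"
        )
    x = cluster.mean_policy / policy_max if policy_max > 0 else 0.0
    y = _transform(cluster.total_dalys, config.daly_transform, daly_max)
    return x, y, (x + y) / math.sqrt(2.0)


def rank_clusters(
    clusters: Sequence[ClusterSummary],
    config: Optional[RankingConfig] = None,
) -> PrioritisationResult:
    """Order clusters by projection score, descending.

    Ties are broken by higher total DALYs then label; ranks run 1..N without
    gaps.  Option 4/5 members are listed alphabetically within each cluster —
    they should be considered equal within it.
    """
    if not clusters:
        raise ValidationError("rank_clusters: empty cluster list")
    config = config or RankingConfig()
    policy_max = max(c.mean_policy or 0.0 for c in clusters)
    daly_max = max(c.total_dalys or 0.0 for c in clusters)
    projected = []
    for c in clusters:
        x, y, score = project_cluster(c, config, (policy_max, daly_max))
        projected.append((c, x, y, score))
    projected.sort(
        key=lambda t: (-t[3], -(t[0].total_dalys or 0.0), canonical(t[0].label))
    )
    entries = [
        RankedCluster(rank=i, cluster=c, x=x, y=y, projection_score=score)
        for i, (c, x, y, score) in enumerate(projected, start=1)
    ]
    priority = {
        e.cluster.label: sorted(e.cluster.priority_members, key=canonical)
        for e in entries
    }
    return PrioritisationResult(entries=entries, priority_diseases=priority)


def select_top(result: PrioritisationResult, top_k: int) -> TopSelection:
    """Take the top_k ranked clusters; report their pooled Option 4/5
    disease count and their share of the all-cluster DALY total."""
    n = len(result.entries)
    if top_k > n:
        warnings.warn(
            f"select_top: top_k={top_k} exceeds the {n} ranked clusters; clamping"
        )
        top_k = n
    shares = cumulative_daly_shares([e.cluster for e in result.entries])
    top = result.entries[:top_k]
    pooled = sum(e.cluster.n_priority for e in top)
    return TopSelection(
        entries=top,
        pooled_priority_count=pooled,
        cumulative_share_pct=shares[top_k - 1],
    )
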