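"""Partition the disease registry into mapping clusters.

Diseases that share data sources, covariates and mapping methodology are
grouped together: first by agent type (virus / bacteria / fungus / other),
then — for the larger agent groups — by phylum-level subgroup (e.g. Nematoda,
Platyhelminths), and finally by mode of transmission.  Two diseases belong to
the same cluster iff all three attributes are equal; an empty subgroup is a
legal key component for the small agent groups that are not split by phylum.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import ValidationError
from .registry import DiseaseRecord, canonical


@dataclass(frozen=True)
class ClusterKey:
    """Equality on all three fields defines cluster membership.  Fields are
    canonicalised (trimmed, lower-cased) so that key equality follows the
    same matching rule as disease names."""

    agent_type: str
    subgroup: str
    transmission_mode: str

    @classmethod
    def for_record(cls, record: DiseaseRecord) -> "ClusterKey":
        return cls(
            canonical(record.agent_type),
            canonical(record.subgroup),
            canonical(record.transmission_mode),
        )

    def default_label(self) -> str:
        return f"{self.agent_type}:{self.subgroup}:{self.transmission_mode}"


@dataclass
class ClusterSummary:
    key: ClusterKey
    label: str
    members: list[str]
    n_total: int
    n_priority: int
    total_dalys: Optional[float] = None
    mean_policy: Optional[float] = None
    policy_defined: bool = True  # False when no Option 4/5 member exists
    priority_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"cluster {self.label!r}: members must be non-empty")
        if self.n_total != len(self.members):
            raise ValidationError(
                f"cluster {self.label!r}: n_total != number of members"
            )
        if self.n_priority > self.n_total:
            raise ValidationError(
                f"cluster {self.label!r}: n_priority exceeds n_total"
            )


LabelMap = dict[ClusterKey, str]


def read_label_map(path: Union[str, Path]) -> LabelMap:
    """Read an optional display-label map CSV with columns agent_type,
    subgroup, transmission_mode, label."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["agent_type", "subgroup", "transmission_mode", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"label map {path}: missing column(s) {missing}")
    out: LabelMap = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = ClusterKey(
            canonical(row.agent_type),
            canonical(row.subgroup),
            canonical(row.transmission_mode),
        )
        if key in out:
            raise ValidationError(f"label map row {i}: duplicate cluster key {key}")
        out[key] = row.label.strip()
    return out


def write_label_map(labels: LabelMap, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "agent_type": [k.agent_type for k in labels],
            "subgroup": [k.subgroup for k in labels],
            "transmission_mode": [k.transmission_mode for k in labels],
            "label": list(labels.values()),
        }
    )
    df.to_csv(path, index=False)


def assign_clusters(
    records: list[DiseaseRecord], label_map: Optional[LabelMap] = None
) -> list[ClusterSummary]:
    """Group registry records into mapping clusters by ClusterKey equality.

    Every disease lands in exactly one cluster (the clusters partition the
    registry); burden and policy fields are left unset.  The returned list is
    sorted by label so the output is independent of the registry row order.
    """
    label_map = label_map or {}
    groups: "OrderedDict[ClusterKey, list[DiseaseRecord]]" = OrderedDict()
    for rec in records:
        if not rec.transmission_mode.strip():
            raise ValidationError(
                f"disease {rec.name!r}: transmission_mode missing; cannot cluster"
            )
        groups.setdefault(ClusterKey.for_record(rec), []).append(rec)
    clusters = []
    for key, members in groups.items():
        names = sorted((m.name for m in members), key=canonical)
        priority = sorted((m.name for m in members if m.is_priority), key=canonical)
        clusters.append(
            ClusterSummary(
                key=key,
                label=label_map.get(key, key.default_label()),
                members=names,
                n_total=len(names),
                n_priority=len(priority),
                priority_members=priority,
            )
        )
    clusters.sort(key=lambda c: canonical(c.label))
    return clusters


def cluster_census(clusters: list[ClusterSummary]) -> dict:
    """Census statistics for a clustering: total cluster count, number of
    single-disease clusters and the (label, size) of the largest cluster."""
    if not clusters:
        raise ValidationError("cluster_census: empty cluster list")
    largest = max(clusters, key=lambda c: (c.n_total, canonical(c.label)))
    return {
        "n_clusters": len(clusters),
        "n_singletons": sum(1 for c in clusters if c.n_total == 1),
        "largest_label": largest.label,
        "largest_size": largest.n_total,
    }
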