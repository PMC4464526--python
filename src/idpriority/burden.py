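"""DALY burden allocation and aggregation.

GBD cause categories (ICD-10 derived) do not map one-to-one onto the disease
registry: some diseases have a direct category, some share an aggregated
category whose DALY value must be split across its member diseases, and a
few cannot be reconciled at all and receive a small nominal value so they
stay in the analysis without skewing it.

The split of an aggregated category is an equal share per member disease;
an optional per-member weight vector is accepted for future use.  A disease
whose own category reports 0 DALYs keeps 0 with source "direct" — a measured
zero is not the same thing as "could not be reconciled".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .clustering import ClusterSummary
from .errors import ValidationError
from .registry import BurdenCategory, DiseaseRecord, LinkKind, canonical

NOMINAL_DALY_DEFAULT = 100.0


class AllocationSource(str, Enum):
    DIRECT = "direct"
    DISAGGREGATED = "disaggregated"
    NOMINAL = "nominal"


@dataclass
class BurdenAllocation:
    disease: str
    dalys: float
    source: AllocationSource

    def __post_init__(self) -> None:
        if self.dalys < 0:
            raise ValidationError(f"allocation for {self.disease!r}: dalys < 0")


def allocate_dalys(
    records: list[DiseaseRecord],
    categories: list[BurdenCategory],
    nominal: float = NOMINAL_DALY_DEFAULT,
    weights: Optional[dict[str, dict[str, float]]] = None,
) -> list[BurdenAllocation]:
    """Assign one DALY allocation to every registry disease.

    Direct-linked diseases receive their category's full value; each member
    of an aggregated category receives an equal share of the category value
    (or a weighted share when ``weights[category_id]`` supplies per-member
    weights); diseases in no category receive the nominal value.  A disease
    claimed by two categories is an error naming both.
    """
    cat_by_id = {canonical(c.category_id): c for c in categories}
    claimed: dict[str, str] = {}  # canonical disease -> category_id
    alloc: dict[str, BurdenAllocation] = {}

    # Aggregated categories distribute their value over member diseases.
    for cat in categories:
        if not cat.member_diseases:
            continue
        w = None
        if weights and cat.category_id in weights:
            w = weights[cat.category_id]
            total_w = sum(w.get(canonical(m), 0.0) for m in cat.member_diseases)
            if total_w <= 0:
                raise ValidationError(
                    f"category {cat.category_id!r}: member weights sum to 0"
                )
        for m in cat.member_diseases:
            mkey = canonical(m)
            if mkey in claimed:
                raise ValidationError(
                    f"disease {m!r} appears in two categories: "
                    f"{claimed[mkey]!r} and {cat.category_id!r}"
                )
            claimed[mkey] = cat.category_id
            if w is None:
                share = cat.daly_value / len(cat.member_diseases)
            else:
                share = cat.daly_value * w.get(mkey, 0.0) / total_w
            alloc[mkey] = BurdenAllocation(m, share, AllocationSource.DISAGGREGATED)

    out: list[BurdenAllocation] = []
    for rec in records:
        key = canonical(rec.name)
        link = rec.burden_link
        if link.kind is LinkKind.DIRECT:
            cid = canonical(link.category_id)
            if cid not in cat_by_id:
                raise ValidationError(
                    f"disease {rec.name!r}: direct category "
                    f"{link.category_id!r} not in burden table"
                )
            if key in claimed:
                raise ValidationError(
                    f"disease {rec.name!r} appears in two categories: "
                    f"{claimed[key]!r} and {link.category_id!r}"
                )
            cat = cat_by_id[cid]
            if cat.member_diseases:
                raise ValidationError(
                    f"disease {rec.name!r}: direct category "
                    f"{cat.category_id!r} has member diseases"
                )
            out.append(
                BurdenAllocation(rec.name, cat.daly_value, AllocationSource.DIRECT)
            )
        elif link.kind is LinkKind.MEMBER_OF:
            if key not in alloc or canonical(claimed.get(key, "")) != canonical(
                link.category_id
            ):
                raise ValidationError(
                    f"disease {rec.name!r} declares member_of "
                    f"{link.category_id!r} but that category does not list it"
                )
            out.append(alloc[key])
        else:
            if key in alloc:
                # member lists are authoritative even when the registry says none
                out.append(alloc[key])
            else:
                out.append(
                    BurdenAllocation(rec.name, nominal, AllocationSource.NOMINAL)
                )
    return out


def cluster_daly_totals(
    clusters: list[ClusterSummary], allocations: list[BurdenAllocation]
) -> list[ClusterSummary]:
    """Fill each cluster's total_dalys with the sum over ALL its members —
    Option 2/3 diseases included, so a cluster of many minor diseases still
    registers its collective burden."""
    by_disease = {canonical(a.disease): a.dalys for a in allocations}
    for cluster in clusters:
        total = 0.0
        for member in cluster.members:
            key = canonical(member)
            if key not in by_disease:
                raise ValidationError(
                    f"cluster {cluster.label!r}: member {member!r} has no "
                    f"burden allocation"
                )
            total += by_disease[key]
        cluster.total_dalys = total
    return clusters


def cumulative_daly_shares(
    ranked_clusters: Sequence[ClusterSummary],
) -> list[float]:
    """Cumulative percentage of the all-cluster DALY total at each rank.

    The sequence is non-decreasing and ends at exactly 100%.
    """
    totals = []
    for c in ranked_clusters:
        if c.total_dalys is None:
            raise ValidationError(f"cluster {c.label!r}: total_dalys not computed")
        totals.append(c.total_dalys)
    grand = sum(totals)
    if grand <= 0:
        raise ValidationError(
            "cumulative_daly_shares: all-cluster DALY total is 0; shares undefined"
        )
    shares = []
    acc = 0.0
    for t in totals:
        acc += t
        shares.append(100.0 * acc / grand)
    shares[-1] = 100.0  # guard the terminal value against float drift
    return shares
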