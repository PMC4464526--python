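"""Synthetic input bundles with planted ground truth.

None of the study's machine-readable inputs (disease registry with burden
linkage, stakeholder portfolios, notifiable lists, citation data) are
deposited anywhere, so this module generates them:

* :func:`study_scenario` — a fully synthetic stand-in for the study inputs,
  constructed so the published structural marginals hold by construction:
  176 diseases in 33 clusters (7 singletons, largest 26), burden links
  partitioned 34 direct / 131 aggregated / 11 nominal, the printed
  per-cluster DALY totals and policy means for the 15 top-ranked clusters,
  42 diseases (24%) named by at least one of 20 stakeholders and 97 (55%)
  notifiable in at least one of 7 sampled countries.  Disease names are
  synthetic; only structure is reproduced.
* :func:`published_ranking_fixture` — the 15 printed (total DALYs, mean policy,
  n = priority/total) rows of the published ranking table, as ready-to-rank
  cluster summaries.
* :func:`generate_scenario` — randomised bundles from a
  :class:`SyntheticScenario` plan, for parameter-recovery testing.
* :func:`generate_planted_clusters` — cluster sets with strictly separated
  projection scores and a known order.

Ground truth is always computed at construction time, never by running the
pipeline, and is written to a separate file so tests cannot leak it into
pipeline inputs.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .clustering import ClusterKey, ClusterSummary, LabelMap, write_label_map
from .errors import ValidationError
from .registry import (
    BurdenCategory,
    BurdenLink,
    DiseaseRecord,
    LinkKind,
    NotifiableList,
    StakeholderPortfolio,
    canonical,
    write_burden_table,
    write_citations,
    write_notifiable_lists,
    write_portfolios,
    write_registry,
)

N_STAKEHOLDERS = 20
COUNTRIES = (
    "USA",
    "Brazil",
    "Zambia",
    "United Arab Emirates",
    "India",
    "Malaysia",
    "Croatia",
)

# ---------------------------------------------------------------------------
# printed ranking-table rows: label, n_priority, n_total, priority diseases,
# total cluster DALYs, average policy score
# ---------------------------------------------------------------------------
PUBLISHED_RANKING_ROWS: list[tuple[str, int, int, list[str], float, float]] = [
    ("Malaria", 3, 5,
     ["Plasmodium falciparum", "P. knowlesi", "P. vivax"], 65_493_135, 11.8),
    ("HIV", 1, 1, ["HIV"], 69_480_661, 11.0),
    ("Tuberculosis", 1, 1, ["Tuberculosis"], 49_816_215, 11.0),
    ("Food/Water-borne (Bacteria)", 1, 4, ["Cholera"], 9_962_003, 8.0),
    ("Water-borne (Platyhelminth)", 3, 7,
     ["Schistosoma haematobium", "S. japonicum", "S. mansoni"], 3_062_843, 7.7),
    ("Trypanosomiasis", 2, 2,
     ["African trypanosomiasis", "American trypanosomiasis"], 728_564, 7.5),
    ("Filariasis", 3, 3,
     ["Bancroftian filariasis", "Brugia malayi", "B. timori"], 2_022_099, 6.2),
    ("Soil Transmitted Helminths", 3, 3,
     ["Ascariasis", "Hookworm", "Trichuriasis"], 4_029_403, 5.3),
    ("Leishmaniasis", 3, 3,
     ["Cutaneous leishmaniasis (Old World)",
      "Cutaneous leishmaniasis (New World)",
      "Visceral leishmaniasis"], 4_283_139, 5.2),
    ("Unknown agent", 1, 4, ["Tropical sprue"], 3_609_400, 4.0),
    ("Picornaviridae", 1, 1, ["Polio"], 116_065, 6.0),
    ("Food/Water-borne (Nematode)", 1, 13, ["Dracunculiasis"], 422_476, 2.5),
    ("Fly-borne (Nematode)", 2, 5, ["Loiasis", "Onchocerciasis"], 711_246, 4.3),
    ("Direct contact (Bacteria)", 4, 6,
     ["Anthrax", "Brazilian purpuric fever", "Leprosy", "Trachoma"],
     1_030_777, 4.0),
    ("Mosquito-borne (Virus)", 15, 26,
     ["Barmah Forest disease", "California serogroup viruses", "Chikungunya",
      "Dengue", "Japanese encephalitis", "Murray Valley encephalitis",
      "Rift Valley fever", "Rocio", "Ross River virus", "Sindbis",
      "St. Louis encephalitis", "Venezuelan equine encephalitis",
      "Western equine encephalitis", "West Nile fever", "Yellow fever"],
     4_219_569, 2.6),
]

_FIXTURE_KEYS: dict[str, tuple[str, str, str]] = {
    "Malaria": ("other", "Apicomplexa", "mosquito-borne"),
    "HIV": ("virus", "", "sexual-contact"),
    "Tuberculosis": ("bacteria", "", "respiratory"),
    "Food/Water-borne (Bacteria)": ("bacteria", "", "food-water-borne"),
    "Water-borne (Platyhelminth)": ("other", "Platyhelminths", "water-contact"),
    "Trypanosomiasis": ("other", "Euglenozoa", "insect-vector"),
    "Filariasis": ("other", "Nematoda", "mosquito-borne"),
    "Soil Transmitted Helminths": ("other", "Nematoda", "soil-contact"),
    "Leishmaniasis": ("other", "Euglenozoa", "sandfly-borne"),
    "Unknown agent": ("other", "", "unknown"),
    "Picornaviridae": ("virus", "", "fecal-oral"),
    "Food/Water-borne (Nematode)": ("other", "Nematoda", "food-water-borne"),
    "Fly-borne (Nematode)": ("other", "Nematoda", "fly-borne"),
    "Direct contact (Bacteria)": ("bacteria", "", "direct-contact"),
    "Mosquito-borne (Virus)": ("virus", "", "mosquito-borne"),
}


def published_ranking_fixture() -> list[ClusterSummary]:
    """The 15 printed ranking-table rows as ready-to-rank cluster summaries.

    Each pseudo-cluster carries exactly the printed total DALYs, average
    policy score and priority/total member counts; non-priority members get
    placeholder names (they are never printed).
    """
    clusters = []
    for label, n_pri, n_tot, priority, dalys, policy in PUBLISHED_RANKING_ROWS:
        members = list(priority) + [
            f"{label} unmapped {i}" for i in range(1, n_tot - n_pri + 1)
        ]
        agent, subgroup, transmission = _FIXTURE_KEYS[label]
        clusters.append(
            ClusterSummary(
                key=ClusterKey(agent, subgroup, transmission),
                label=label,
                members=sorted(members, key=canonical),
                n_total=n_tot,
                n_priority=n_pri,
                total_dalys=float(dalys),
                mean_policy=policy,
                priority_members=sorted(priority, key=canonical),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# bundles and ground truth
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """A complete set of pipeline inputs, writable as the CSVs the registry
    reader consumes."""

    records: list[DiseaseRecord]
    categories: list[BurdenCategory]
    portfolios: list[StakeholderPortfolio]
    notifiable_lists: list[NotifiableList]
    citations: dict[str, Union[list[int], int]]
    label_map: LabelMap

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "registry": outdir / "registry.csv",
            "burden": outdir / "burden.csv",
            "portfolios": outdir / "portfolios.csv",
            "notifiable": outdir / "notifiable.csv",
            "citations": outdir / "citations.csv",
            "labels": outdir / "labels.csv",
        }
        write_registry(self.records, paths["registry"])
        write_burden_table(self.categories, paths["burden"])
        write_portfolios(self.portfolios, paths["portfolios"])
        write_notifiable_lists(self.notifiable_lists, paths["notifiable"])
        write_citations(self.citations, paths["citations"])
        write_label_map(self.label_map, paths["labels"])
        return paths


@dataclass
class GroundTruth:
    """Construction-time truth for a synthetic bundle, kept apart from the
    bundle so pipeline inputs cannot contain it."""

    census: dict
    link_counts: dict[str, int]
    allocations: dict[str, tuple[float, str]]
    cluster_totals: dict[str, float]
    cluster_means: dict[str, float]
    scores: dict[str, float]
    ranking: list[str]
    coverage: dict

    def write(self, path: Union[str, Path]) -> None:
        payload = {
            "census": self.census,
            "link_counts": self.link_counts,
            "allocations": {
                k: {"dalys": v[0], "source": v[1]}
                for k, v in self.allocations.items()
            },
            "cluster_totals": self.cluster_totals,
            "cluster_means": self.cluster_means,
            "scores": self.scores,
            "ranking": self.ranking,
            "coverage": self.coverage,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _slug(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", label.lower()).strip("-")


def _decompose_score(total: float) -> tuple[int, float, float]:
    """Split a policy total on the 0.5 grid into feasible components
    (stakeholder points, notifiable point, h-index band points)."""
    if total < 1 or (total * 2) != int(total * 2):
        raise ValidationError(f"policy total {total} not representable")
    h = 1.5 if (total % 1) == 0.5 else 1.0
    rest = total - h
    n = 1.0 if rest >= 1 else 0.0
    s = rest - n
    return int(s), n, h

def _h_for_points(points: float) -> int:
    return {1.0: 25, 1.5: 70, 2.0: 150}[points]


def _expected_ranking(
    clusters: list[tuple[str, float, float]]
) -> list[str]:
    """Construction-side ranking arithmetic on (label, total, mean) triples:
    normalise to observed maxima (log10 burden axis), project onto the
    diagonal, sort descending with the higher-DALY/label tie-break."""
    policy_max = max(m for _, _, m in clusters)
    daly_max = max(t for _, t, _ in clusters)
    scored = []
    for label, total, mean in clusters:
        x = mean / policy_max if policy_max > 0 else 0.0
        y = math.log10(total) / math.log10(daly_max)
        scored.append((label, total, (x + y) / math.sqrt(2)))
    scored.sort(key=lambda t: (-t[2], -t[1], canonical(t[0])))
    return [label for label, _, _ in scored]


# ---------------------------------------------------------------------------
# study-structure scenario
# ---------------------------------------------------------------------------

# Per-cluster plan: label, (agent, subgroup, transmission), size, total DALYs,
# priority = [(stakeholder pts, notifiable pt, h-index)], mention level,
# n_direct / n_nominal burden slots, extra covered / notifiable counts among
# non-priority members.  The 15 leading clusters carry the printed totals and
# the nearest representable policy sums; 18 filler clusters carry small
# burdens and low scores so the leading order is not disturbed.
_STUDY_PLAN: list[dict] = [
    dict(label="Malaria", key=("other", "Apicomplexa", "mosquito-borne"), size=5,
         total=65_493_135, priority=[(9, 1, 150), (9, 1, 150), (9, 1, 70)],
         mention="cluster", n_direct=2, n_nominal=0, extra_cov=0, extra_notif=1),
    dict(label="HIV", key=("virus", "", "sexual-contact"), size=1,
         total=69_480_661, priority=[(8, 1, 461)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Tuberculosis", key=("bacteria", "", "respiratory"), size=1,
         total=49_816_215, priority=[(8, 1, 150)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Food/Water-borne (Bacteria)", key=("bacteria", "", "food-water-borne"),
         size=4, total=9_962_003, priority=[(5, 1, 150)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=2),
    dict(label="Water-borne (Platyhelminth)",
         key=("other", "Platyhelminths", "water-contact"), size=7,
         total=3_062_843, priority=[(5, 1, 150), (5, 1, 70), (5, 1, 70)],
         mention="disease", n_direct=3, n_nominal=0, extra_cov=0, extra_notif=3),
    dict(label="Trypanosomiasis", key=("other", "Euglenozoa", "insect-vector"),
         size=2, total=728_564, priority=[(5, 1, 70), (5, 1, 70)],
         mention="cluster", n_direct=2, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Filariasis", key=("other", "Nematoda", "mosquito-borne"), size=3,
         total=2_022_099, priority=[(4, 1, 70), (4, 1, 25), (4, 1, 25)],
         mention="cluster", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Soil Transmitted Helminths", key=("other", "Nematoda", "soil-contact"),
         size=3, total=4_029_403, priority=[(3, 1, 70), (3, 1, 70), (3, 1, 25)],
         mention="cluster", n_direct=3, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Leishmaniasis", key=("other", "Euglenozoa", "sandfly-borne"), size=3,
         total=4_283_139, priority=[(3, 1, 70), (3, 1, 25), (3, 1, 25)],
         mention="cluster", n_direct=3, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Unknown agent", key=("other", "", "unknown"), size=4,
         total=3_609_400, priority=[(2, 1, 25)], priority_role="nominal",
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=1),
    dict(label="Picornaviridae", key=("virus", "", "fecal-oral"), size=1,
         total=116_065, priority=[(3, 1, 150)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Food/Water-borne (Nematode)", key=("other", "Nematoda", "food-water-borne"),
         size=13, total=422_476, priority=[(0, 1, 70)],
         mention="disease", n_direct=2, n_nominal=2, extra_cov=1, extra_notif=7),
    dict(label="Fly-borne (Nematode)", key=("other", "Nematoda", "fly-borne"), size=5,
         total=711_246, priority=[(2, 1, 70), (2, 1, 25)],
         mention="disease", n_direct=2, n_nominal=0, extra_cov=0, extra_notif=2),
    dict(label="Direct contact (Bacteria)", key=("bacteria", "", "direct-contact"),
         size=6, total=1_030_777,
         priority=[(3, 1, 25), (2, 1, 25), (2, 1, 25), (1, 1, 25)],
         mention="disease", n_direct=3, n_nominal=0, extra_cov=0, extra_notif=2),
    dict(label="Mosquito-borne (Virus)", key=("virus", "", "mosquito-borne"), size=26,
         total=4_219_569,
         priority=[(0, 1, 25)] * 4 + [(0, 1, 70)] * 4 + [(1, 1, 25)] * 7,
         mention="disease", n_direct=4, n_nominal=1, extra_cov=1, extra_notif=8),
    # --- singleton fillers -------------------------------------------------
    dict(label="Avian contact (Virus)", key=("virus", "", "avian-contact"), size=1,
         total=45_000, priority=[(4, 1, 25)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Tick-borne (Apicomplexa)", key=("other", "Apicomplexa", "tick-borne"),
         size=1, total=30_000, priority=[],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Water contact (Fungus)", key=("fungus", "", "water-contact"), size=1,
         total=100, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=0),
    dict(label="Sandfly-borne (Bacteria)", key=("bacteria", "", "sandfly-borne"),
         size=1, total=20_000, priority=[],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=0),
    # --- multi-member fillers ---------------------------------------------
    dict(label="Tick-borne (Bacteria)", key=("bacteria", "", "tick-borne"), size=12,
         total=2_400_000, priority=[(1, 1, 25)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=4),
    dict(label="Tick-borne (Virus)", key=("virus", "", "tick-borne"), size=10,
         total=1_800_000, priority=[(0, 1, 70)],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=3),
    dict(label="Mammal contact (Virus)", key=("virus", "", "mammal-contact"), size=9,
         total=1_500_000, priority=[(2, 1, 25)],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=3),
    dict(label="Food/Water-borne (Virus)", key=("virus", "", "food-water-borne"),
         size=8, total=1_200_000, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=3),
    dict(label="Respiratory (Virus)", key=("virus", "", "respiratory"), size=8,
         total=1_000_000, priority=[],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=2),
    dict(label="Flea-borne (Bacteria)", key=("bacteria", "", "flea-borne"), size=7,
         total=900_000, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=2),
    dict(label="Soil contact (Fungus)", key=("fungus", "", "soil-contact"), size=6,
         total=800_000, priority=[],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=2),
    dict(label="Water contact (Bacteria)", key=("bacteria", "", "water-contact"),
         size=6, total=500_000, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=1),
    dict(label="Food/Water-borne (Amoebozoa)", key=("other", "Amoebozoa", "food-water-borne"),
         size=5, total=400_000, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=1),
    dict(label="Louse-borne (Bacteria)", key=("bacteria", "", "louse-borne"), size=5,
         total=300_000, priority=[],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=1),
    dict(label="Rodent contact (Virus)", key=("virus", "", "rodent-contact"), size=4,
         total=250_000, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=1),
    dict(label="Mammal contact (Bacteria)", key=("bacteria", "", "mammal-contact"),
         size=4, total=150_000, priority=[],
         mention="disease", n_direct=0, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Water contact (Nematode)", key=("other", "Nematoda", "water-contact"),
         size=2, total=100_000, priority=[],
         mention="disease", n_direct=1, n_nominal=0, extra_cov=0, extra_notif=0),
    dict(label="Sexual contact (Bacteria)", key=("bacteria", "", "sexual-contact"),
         size=2, total=99_900, priority=[],
         mention="disease", n_direct=0, n_nominal=1, extra_cov=0, extra_notif=0),
]

_DIRECT_FRACTIONS = (0.45, 0.25, 0.12, 0.08)
_FILLER_H = (5, 12, 18, 30, 44)


def study_scenario() -> tuple[Bundle, GroundTruth]:
    """Deterministic synthetic stand-in for the full study inputs.

    The bundle's structure (cluster census, burden-link partition, printed
    per-cluster totals and representable policy sums, stakeholder and
    notifiable coverage) is planted by construction; see the module
    docstring.  Returns (bundle, ground truth).
    """
    records: list[DiseaseRecord] = []
    categories: list[BurdenCategory] = []
    label_map: LabelMap = {}
    portfolios_sets: dict[str, list[str]] = {
        f"stakeholder-{i + 1:02d}": [] for i in range(N_STAKEHOLDERS)
    }
    stakeholder_ids = list(portfolios_sets)
    notifiable_names: list[str] = []
    citations: dict[str, Union[list[int], int]] = {}

    truth_alloc: dict[str, tuple[float, str]] = {}
    truth_scores: dict[str, float] = {}
    cluster_totals: dict[str, float] = {}
    cluster_means: dict[str, float] = {}
    covered: set[str] = set()
    link_counts = {"direct": 0, "disaggregated": 0, "nominal": 0}
    rotation = 0  # staggers stakeholder assignment across the survey

    def assign_stakeholders(name: str, s: int) -> None:
        nonlocal rotation
        for j in range(s):
            portfolios_sets[stakeholder_ids[(rotation + j) % N_STAKEHOLDERS]].append(
                name
            )
        rotation += max(s, 1)

    for plan in _STUDY_PLAN:
        label = plan["label"]
        agent, subgroup, transmission = plan["key"]
        key = ClusterKey(canonical(agent), canonical(subgroup), canonical(transmission))
        label_map[key] = label
        size = plan["size"]
        n_direct, n_nominal = plan["n_direct"], plan["n_nominal"]
        n_member = size - n_direct - n_nominal
        priority = plan["priority"]
        n_priority = len(priority)
        slug = _slug(label)

        names = [f"{label} disease {i + 1:02d}" for i in range(size)]
        # priority diseases occupy the leading burden slots unless the plan
        # pins them to the nominal slots (the unreconcilable-priority case)
        if plan.get("priority_role") == "nominal":
            priority_names = names[size - n_priority:]
            nonpriority_names = names[: size - n_priority]
        else:
            priority_names = names[:n_priority]
            nonpriority_names = names[n_priority:]

        # burden roles by slot position
        roles = (
            ["direct"] * n_direct + ["member"] * n_member + ["nominal"] * n_nominal
        )
        total = float(plan["total"])
        direct_values: list[float] = []
        if n_direct:
            if n_member == 0 and n_nominal == 0:
                for f in _DIRECT_FRACTIONS[: n_direct - 1]:
                    direct_values.append(float(math.floor(total * f)))
                direct_values.append(total - sum(direct_values))
            else:
                for f in _DIRECT_FRACTIONS[:n_direct]:
                    direct_values.append(float(math.floor(total * f)))
        member_value = total - sum(direct_values) - 100.0 * n_nominal
        if member_value < 0 or (n_member == 0 and abs(member_value) > 1e-6):
            raise ValidationError(f"study plan for {label!r}: burden does not balance")

        member_names = [n for n, r in zip(names, roles) if r == "member"]
        agg_id = f"AGG-{slug}"
        if member_names:
            categories.append(
                BurdenCategory(agg_id, f"{label} (aggregated)", member_value,
                               list(member_names))
            )

        d_idx = 0
        for name, role in zip(names, roles):
            if role == "direct":
                cat_id = f"GBD-{slug}-{d_idx + 1}"
                categories.append(
                    BurdenCategory(cat_id, f"{label} (direct {d_idx + 1})",
                                   direct_values[d_idx])
                )
                link = BurdenLink(LinkKind.DIRECT, cat_id)
                truth_alloc[name] = (direct_values[d_idx], "direct")
                link_counts["direct"] += 1
                d_idx += 1
            elif role == "member":
                link = BurdenLink(LinkKind.MEMBER_OF, agg_id)
                truth_alloc[name] = (member_value / len(member_names), "disaggregated")
                link_counts["disaggregated"] += 1
            else:
                link = BurdenLink(LinkKind.NONE)
                truth_alloc[name] = (100.0, "nominal")
                link_counts["nominal"] += 1

            is_priority = name in priority_names
            option = (5 if priority_names.index(name) % 2 == 0 else 4) \
                if is_priority else (2 if names.index(name) % 2 == 0 else 3)
            records.append(
                DiseaseRecord(
                    name=name,
                    mapping_option=option,
                    agent_type=canonical(agent),
                    subgroup=subgroup,
                    transmission_mode=transmission,
                    burden_link=link,
                )
            )

        # ---- policy inputs ------------------------------------------------
        if plan["mention"] == "cluster" and priority:
            s_values = {s for s, _, _ in priority}
            if len(s_values) != 1:
                raise ValidationError(
                    f"study plan for {label!r}: cluster-level mention needs a "
                    f"single stakeholder count"
                )
            s_common = priority[0][0]
            assign_stakeholders(label, s_common)
            covered.update(canonical(n) for n in names)
        score_sum = 0.0
        for name, (s, n_pt, h) in zip(priority_names, priority):
            if plan["mention"] == "disease":
                assign_stakeholders(name, s)
                if s > 0:
                    covered.add(canonical(name))
            if n_pt:
                notifiable_names.append(name)
            citations[name] = [h] * h if h > 0 else [0]
            h_pts = 2.0 if h > 100 else (1.5 if h > 50 else 1.0)
            score = s + n_pt + h_pts
            truth_scores[name] = score
            score_sum += score
        cluster_means[label] = score_sum / n_priority if n_priority else 0.0
        cluster_totals[label] = total

        cluster_mentioned = plan["mention"] == "cluster" and priority
        for i, name in enumerate(nonpriority_names):
            s_np = priority[0][0] if cluster_mentioned else 0
            if i < plan["extra_cov"]:
                assign_stakeholders(name, 1)
                covered.add(canonical(name))
                s_np += 1
            n_np = 0.0
            if i < plan["extra_notif"]:
                notifiable_names.append(name)
                n_np = 1.0
            h = _FILLER_H[i % len(_FILLER_H)]
            citations[name] = [h] * h
            truth_scores[name] = s_np + n_np + 1.0  # filler h-indices band at 1

    portfolios = [
        StakeholderPortfolio(sid, interests)
        for sid, interests in portfolios_sets.items()
        if interests
    ]
    lists = [NotifiableList(c, set()) for c in COUNTRIES]
    for i, name in enumerate(notifiable_names):
        lists[i % len(COUNTRIES)].diseases.add(name)

    n = len(records)
    census = {
        "n_clusters": len(_STUDY_PLAN),
        "n_singletons": sum(1 for p in _STUDY_PLAN if p["size"] == 1),
        "largest_label": max(_STUDY_PLAN, key=lambda p: p["size"])["label"],
        "largest_size": max(p["size"] for p in _STUDY_PLAN),
    }
    ranking = _expected_ranking(
        [(p["label"], cluster_totals[p["label"]], cluster_means[p["label"]])
         for p in _STUDY_PLAN]
    )
    coverage = {
        "n_diseases": n,
        "n_stakeholder_covered": len(covered),
        "n_notifiable": len(notifiable_names),
        "stakeholder_coverage_pct": 100.0 * len(covered) / n,
        "notifiable_coverage_pct": 100.0 * len(notifiable_names) / n,
    }
    truth = GroundTruth(
        census=census,
        link_counts=link_counts,
        allocations=truth_alloc,
        cluster_totals=cluster_totals,
        cluster_means=cluster_means,
        scores=truth_scores,
        ranking=ranking,
        coverage=coverage,
    )
    bundle = Bundle(records, categories, portfolios, lists, citations, label_map)
    return bundle, truth


# ---------------------------------------------------------------------------
# randomised scenarios
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Plan for a randomised input bundle.

    Defaults mirror the study's shape: 176 diseases over 33 (agent,
    subgroup, transmission) cells including singletons and one 26-member
    cell, 20 stakeholders with geometric-rank (heavy-tailed) disease
    popularity, about 55% of diseases notifiable, h-indices spread over the
    three scoring bands, and burden links split roughly 0.2/0.74/0.06 over
    direct/aggregated/nominal.
    """

    n_diseases: int = 176
    cluster_plan: list[tuple[str, str, str, int]] = field(
        default_factory=lambda: [
            (p["key"][0], p["key"][1], p["key"][2], p["size"]) for p in _STUDY_PLAN
        ]
    )
    option_mix: dict[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.2, 4: 0.2, 5: 0.25}
    )
    burden_mix: tuple[float, float, float] = (0.20, 0.74, 0.06)
    daly_log_range: tuple[float, float] = (2.0, 7.5)
    n_stakeholders: int = N_STAKEHOLDERS
    popularity_base: float = 0.55
    popularity_decay: float = 0.88
    cluster_mention_prob: float = 0.15
    hindex_band_probs: dict[float, float] = field(
        default_factory=lambda: {1.0: 0.64, 1.5: 0.19, 2.0: 0.17}
    )
    notifiable_frac: float = 0.55

    def validate(self) -> None:
        if sum(s for *_, s in self.cluster_plan) != self.n_diseases:
            raise ValidationError(
                "scenario plan: cluster sizes do not sum to n_diseases"
            )
        for mix, what in (
            (self.option_mix.values(), "option_mix"),
            (self.burden_mix, "burden_mix"),
            (self.hindex_band_probs.values(), "hindex_band_probs"),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValidationError(f"scenario plan: {what} must sum to 1")


def generate_scenario(
    scenario: Optional[SyntheticScenario] = None, seed: int = 0
) -> tuple[Bundle, GroundTruth]:
    """Generate a randomised bundle plus its construction-time ground truth.

    Deterministic given ``seed``: two calls with the same plan and seed give
    identical bundles.
    """
    scenario = scenario or SyntheticScenario()
    scenario.validate()
    rng = np.random.default_rng(seed)

    records: list[DiseaseRecord] = []
    categories: list[BurdenCategory] = []
    label_map: LabelMap = {}
    truth_alloc: dict[str, tuple[float, str]] = {}
    link_counts = {"direct": 0, "disaggregated": 0, "nominal": 0}
    cluster_totals: dict[str, float] = {}
    cluster_members: dict[str, list[DiseaseRecord]] = {}

    options = sorted(scenario.option_mix)
    option_p = [scenario.option_mix[o] for o in options]
    lo, hi = scenario.daly_log_range

    for ci, (agent, subgroup, transmission, size) in enumerate(scenario.cluster_plan):
        label = f"cluster-{ci + 1:02d}"
        label_map[
            ClusterKey(canonical(agent), canonical(subgroup), canonical(transmission))
        ] = label
        members: list[DiseaseRecord] = []
        roles = rng.choice(
            ["direct", "member", "nominal"], size=size, p=list(scenario.burden_mix)
        )
        member_names = []
        total = 0.0
        for di in range(size):
            name = f"{label} disease {di + 1:02d}"
            option = int(rng.choice(options, p=option_p))
            role = roles[di]
            if role == "direct":
                value = float(np.round(10 ** rng.uniform(lo, hi), 2))
                cat_id = f"GBD-{label}-{di + 1}"
                categories.append(BurdenCategory(cat_id, cat_id, value))
                link = BurdenLink(LinkKind.DIRECT, cat_id)
                truth_alloc[name] = (value, "direct")
                link_counts["direct"] += 1
                total += value
            elif role == "member":
                link = BurdenLink(LinkKind.MEMBER_OF, f"AGG-{label}")
                member_names.append(name)
                link_counts["disaggregated"] += 1
            else:
                link = BurdenLink(LinkKind.NONE)
                truth_alloc[name] = (100.0, "nominal")
                link_counts["nominal"] += 1
                total += 100.0
            rec = DiseaseRecord(
                name=name,
                mapping_option=option,
                agent_type=canonical(agent),
                subgroup=subgroup,
                transmission_mode=transmission,
                burden_link=link,
            )
            members.append(rec)
            records.append(rec)
        if member_names:
            value = float(np.round(10 ** rng.uniform(lo, hi), 2))
            categories.append(
                BurdenCategory(f"AGG-{label}", f"AGG-{label}", value,
                               list(member_names))
            )
            share = value / len(member_names)
            for m in member_names:
                truth_alloc[m] = (share, "disaggregated")
            total += value
        cluster_totals[label] = total
        cluster_members[label] = members

    # --- stakeholder portfolios with heavy-tailed popularity ---------------
    n_stake = scenario.n_stakeholders
    stakeholder_ids = [f"stakeholder-{i + 1:02d}" for i in range(n_stake)]
    interest_sets: dict[str, set[str]] = {s: set() for s in stakeholder_ids}
    # per-disease sets of interested stakeholders (the construction truth)
    interested: dict[str, set[str]] = {r.name: set() for r in records}

    shuffled = list(records)
    rng.shuffle(shuffled)
    for rank, rec in enumerate(shuffled):
        p = scenario.popularity_base * scenario.popularity_decay**rank
        chosen = [s for s in stakeholder_ids if rng.random() < p]
        for s in chosen:
            interest_sets[s].add(rec.name)
            interested[rec.name].add(s)
    labels_by_cluster = {v: k for k, v in label_map.items()}
    for label, members in cluster_members.items():
        if rng.random() < scenario.cluster_mention_prob:
            for s in rng.choice(stakeholder_ids, size=rng.integers(1, 4),
                                replace=False):
                interest_sets[s].add(label)
                for m in members:
                    interested[m.name].add(s)
    most_popular = max(interested, key=lambda n: (len(interested[n]), n))
    for s in stakeholder_ids:  # portfolios must be non-empty
        if not interest_sets[s]:
            interest_sets[s].add(most_popular)
            interested[most_popular].add(s)
    portfolios = [
        StakeholderPortfolio(s, sorted(interest_sets[s], key=canonical))
        for s in stakeholder_ids
    ]

    # --- notifiable lists ---------------------------------------------------
    n_notif = int(round(scenario.notifiable_frac * len(records)))
    notif_diseases = list(
        rng.choice([r.name for r in records], size=n_notif, replace=False)
    )
    lists = [NotifiableList(c, set()) for c in COUNTRIES]
    for i, name in enumerate(notif_diseases):
        lists[i % len(COUNTRIES)].diseases.add(name)
    notif_set = set(notif_diseases)

    # --- citation data -------------------------------------------------------
    bands = sorted(scenario.hindex_band_probs)
    band_p = [scenario.hindex_band_probs[b] for b in bands]
    citations: dict[str, Union[list[int], int]] = {}
    truth_scores: dict[str, float] = {}
    for rec in records:
        band = float(rng.choice(bands, p=band_p))
        if band == 1.0:
            h = int(rng.integers(0, 51))
        elif band == 1.5:
            h = int(rng.integers(51, 101))
        else:
            h = int(rng.integers(101, 301))
        if rng.random() < 0.5:
            citations[rec.name] = h  # precomputed h-index
        else:
            citations[rec.name] = [h] * h if h > 0 else [0]
        truth_scores[rec.name] = (
            len(interested[rec.name])
            + (1.0 if rec.name in notif_set else 0.0)
            + band
        )

    cluster_means = {}
    for label, members in cluster_members.items():
        pri = [truth_scores[m.name] for m in members if m.is_priority]
        cluster_means[label] = sum(pri) / len(pri) if pri else 0.0

    sizes = [s for *_, s in scenario.cluster_plan]
    largest = int(np.argmax(sizes))
    census = {
        "n_clusters": len(scenario.cluster_plan),
        "n_singletons": sum(1 for s in sizes if s == 1),
        "largest_label": f"cluster-{largest + 1:02d}",
        "largest_size": max(sizes),
    }
    ranking = _expected_ranking(
        [(label, cluster_totals[label], cluster_means[label])
         for label in cluster_totals]
    )
    n_cov = sum(1 for name in interested if interested[name])
    coverage = {
        "n_diseases": len(records),
        "n_stakeholder_covered": n_cov,
        "n_notifiable": len(notif_set),
        "stakeholder_coverage_pct": 100.0 * n_cov / len(records),
        "notifiable_coverage_pct": 100.0 * len(notif_set) / len(records),
    }
    truth = GroundTruth(
        census=census,
        link_counts=link_counts,
        allocations=truth_alloc,
        cluster_totals=cluster_totals,
        cluster_means=cluster_means,
        scores=truth_scores,
        ranking=ranking,
        coverage=coverage,
    )
    return Bundle(records, categories, portfolios, lists, citations, label_map), truth


def generate_planted_clusters(
    n_clusters: int = 12, seed: int = 0, min_gap: float = 1e-3
) -> tuple[list[ClusterSummary], list[str]]:
    """Cluster summaries whose projection scores are strictly separated by at
    least ``min_gap``, plus the planted priority order (best first).

    Policy means live on the representable 0.5 grid; DALY totals span several
    orders of magnitude.  Draws are rejected until all pairwise projection
    gaps hold, so recovering the planted order is unambiguous.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        policies = rng.integers(2, 27, size=n_clusters) / 2.0  # 1.0 .. 13.0
        dalys = 10 ** rng.uniform(3.0, 7.5, size=n_clusters)
        pmax, dmax = policies.max(), dalys.max()
        proj = policies / pmax + np.log10(dalys) / math.log10(dmax)
        order = np.argsort(-proj)
        if np.all(np.diff(proj[order]) < -min_gap):
            break
    else:  # pragma: no cover - rejection loop converges in a few draws
        raise ValidationError("could not plant strictly separated projections")
    clusters = []
    for i in range(n_clusters):
        label = f"planted-{i + 1:02d}"
        name = f"{label} disease"
        clusters.append(
            ClusterSummary(
                key=ClusterKey("virus", "", f"mode-{i + 1}"),
                label=label,
                members=[name],
                n_total=1,
                n_priority=1,
                total_dalys=float(dalys[i]),
                mean_policy=float(policies[i]),
                priority_members=[name],
            )
        )
    planted = [f"planted-{i + 1:02d}" for i in order]
    return clusters, planted
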