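"""Domain types and tabular input/output.

All tables are comma-separated UTF-8 with a header row; list-valued cells use
";" as the internal separator.  Disease and cluster names are matched
case-insensitively after trimming whitespace; no fuzzy matching is attempted.

The central object is the disease registry: one :class:`DiseaseRecord` per
disease, carrying the taxonomy and transmission attributes that define the
mapping clusters, the mapping-option class (2-5; Option 1 diseases are
unmappable by occurrence methods and excluded upstream), and the link into
the burden table.  DALYs and policy scores accumulate onto the record as the
pipeline runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ValidationError

LIST_SEP = ";"

AGENT_TYPES = ("virus", "bacteria", "fungus", "other")


def canonical(name: str) -> str:
    """Canonical form used for all name matching: trimmed, lower-cased."""
    return name.strip().lower()


class LinkKind(str, Enum):
    DIRECT = "direct"
    MEMBER_OF = "member_of"
    NONE = "none"


@dataclass(frozen=True)
class BurdenLink:
    """How a disease connects to the burden table.

    ``direct:<category-id>`` — the category's DALY value belongs to this
    disease alone; ``member_of:<category-id>`` — the disease shares an
    aggregated (ICD-10 style) category with other diseases; ``none`` — the
    disease could not be reconciled and receives the nominal value.
    """

    kind: LinkKind
    category_id: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "BurdenLink":
        text = text.strip()
        if text == "" or text.lower() == "none":
            return cls(LinkKind.NONE)
        if ":" in text:
            kind, _, cat = text.partition(":")
            kind = kind.strip().lower()
            cat = cat.strip()
            if kind in (LinkKind.DIRECT.value, LinkKind.MEMBER_OF.value) and cat:
                return cls(LinkKind(kind), cat)
        raise ValidationError(
            f"burden_link {text!r} is not 'direct:<id>', 'member_of:<id>' or 'none'"
        )

    def __str__(self) -> str:
        if self.kind is LinkKind.NONE:
            return "none"
        return f"{self.kind.value}:{self.category_id}"


@dataclass
class PolicyComponents:
    """The three additive parts of a disease's policy-interest score.

    stakeholder_points: one point per distinct stakeholder naming the disease
    (directly or through its cluster label); notifiable_points: 1 if
    notifiable in any sampled country (or a per-country count in the optional
    mode); hindex_points: banded academic-output score in {1, 1.5, 2}.
    """

    stakeholder_points: int
    notifiable_points: float
    hindex_points: float

    def __post_init__(self) -> None:
        if self.stakeholder_points < 0:
            raise ValidationError("stakeholder_points must be >= 0")
        if self.notifiable_points < 0:
            raise ValidationError("notifiable_points must be >= 0")
        if self.hindex_points not in (1, 1.5, 2):
            raise ValidationError(
                f"hindex_points must be one of 1, 1.5, 2; got {self.hindex_points}"
            )

    @property
    def total(self) -> float:
        return self.stakeholder_points + self.notifiable_points + self.hindex_points


@dataclass
class DiseaseRecord:
    name: str
    mapping_option: int
    agent_type: str
    subgroup: str
    transmission_mode: str
    burden_link: BurdenLink = field(default_factory=lambda: BurdenLink(LinkKind.NONE))
    dalys: Optional[float] = None
    hindex: Optional[int] = None
    policy: Optional[PolicyComponents] = None

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValidationError("disease name must be non-empty")
        if self.mapping_option not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"disease {self.name!r}: mapping_option must be in 1..5, "
                f"got {self.mapping_option}"
            )
        if self.agent_type not in AGENT_TYPES:
            raise ValidationError(
                f"disease {self.name!r}: agent_type must be one of {AGENT_TYPES}, "
                f"got {self.agent_type!r}"
            )
        if not self.transmission_mode.strip():
            raise ValidationError(
                f"disease {self.name!r}: transmission_mode must be non-empty"
            )
        if self.dalys is not None and self.dalys < 0:
            raise ValidationError(f"disease {self.name!r}: dalys must be >= 0")

    @property
    def is_priority(self) -> bool:
        """Option 4/5 diseases need niche or geostatistical modelling and are
        the ones listed for dedicated mapping."""
        return self.mapping_option in (4, 5)


@dataclass
class BurdenCategory:
    """One burden-table row: a GBD/ICD-10 style cause category.

    Direct one-to-one categories have an empty ``member_diseases`` list; an
    aggregated category names the registry diseases its DALY value must be
    split across.
    """

    category_id: str
    label: str
    daly_value: float
    member_diseases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.category_id.strip():
            raise ValidationError("category_id must be non-empty")
        if self.daly_value < 0:
            raise ValidationError(
                f"category {self.category_id!r}: daly_value must be >= 0"
            )


@dataclass
class StakeholderPortfolio:
    stakeholder_id: str
    interests: list[str]

    def __post_init__(self) -> None:
        if not self.interests:
            raise ValidationError(
                f"stakeholder {self.stakeholder_id!r}: interests must be non-empty"
            )


@dataclass
class NotifiableList:
    country: str
    diseases: set[str]


def _read_table(path: Union[str, Path], required: Iterable[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{table} file {path}: missing required column(s) {missing}"
        )
    return df


def _parse_list(cell: str) -> list[str]:
    return [part.strip() for part in cell.split(LIST_SEP) if part.strip()]


def read_registry(path: Union[str, Path]) -> list[DiseaseRecord]:
    """Read and validate a disease registry CSV.

    Required columns: name, mapping_option, agent_type, subgroup,
    transmission_mode.  Optional column: burden_link.  Every row becomes
    exactly one record; duplicate names (case-insensitive) are rejected.
    """
    df = _read_table(
        path,
        ["name", "mapping_option", "agent_type", "subgroup", "transmission_mode"],
        "registry",
    )
    records: list[DiseaseRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            option = int(str(row.mapping_option))
        except ValueError:
            raise ValidationError(
                f"registry row {i}, field 'mapping_option': "
                f"{row.mapping_option!r} is not an integer"
            ) from None
        link = BurdenLink(LinkKind.NONE)
        if "burden_link" in df.columns:
            try:
                link = BurdenLink.parse(getattr(row, "burden_link"))
            except ValidationError as exc:
                raise ValidationError(
                    f"registry row {i}, field 'burden_link': {exc}"
                ) from None
        try:
            rec = DiseaseRecord(
                name=row.name.strip(),
                mapping_option=option,
                agent_type=row.agent_type.strip().lower(),
                subgroup=row.subgroup.strip(),
                transmission_mode=row.transmission_mode.strip(),
                burden_link=link,
            )
        except ValidationError as exc:
            raise ValidationError(f"registry row {i}: {exc}") from None
        key = canonical(rec.name)
        if key in seen:
            raise ValidationError(
                f"registry row {i}, field 'name': duplicate disease name "
                f"{rec.name!r} (first seen at row {seen[key]})"
            )
        seen[key] = i
        records.append(rec)
    return records


def write_registry(records: list[DiseaseRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "mapping_option": [r.mapping_option for r in records],
            "agent_type": [r.agent_type for r in records],
            "subgroup": [r.subgroup for r in records],
            "transmission_mode": [r.transmission_mode for r in records],
            "burden_link": [str(r.burden_link) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_burden_table(
    path: Union[str, Path], registry: Optional[list[DiseaseRecord]] = None
) -> list[BurdenCategory]:
    """Read a burden-table CSV (category_id, label, daly_value,
    member_diseases).  When a registry is supplied, every member disease must
    resolve to a registered name."""
    df = _read_table(path, ["category_id", "label", "daly_value"], "burden table")
    known = None
    if registry is not None:
        known = {canonical(r.name) for r in registry}
    categories: list[BurdenCategory] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            value = float(str(row.daly_value))
        except ValueError:
            raise ValidationError(
                f"burden table row {i}, field 'daly_value': "
                f"{row.daly_value!r} is not a number"
            ) from None
        members = (
            _parse_list(getattr(row, "member_diseases"))
            if "member_diseases" in df.columns
            else []
        )
        if known is not None:
            for m in members:
                if canonical(m) not in known:
                    raise ValidationError(
                        f"burden table row {i}, field 'member_diseases': "
                        f"{m!r} is not a registered disease"
                    )
        try:
            cat = BurdenCategory(
                category_id=row.category_id.strip(),
                label=row.label.strip(),
                daly_value=value,
                member_diseases=members,
            )
        except ValidationError as exc:
            raise ValidationError(f"burden table row {i}: {exc}") from None
        cid = canonical(cat.category_id)
        if cid in seen:
            raise ValidationError(
                f"burden table row {i}, field 'category_id': duplicate id "
                f"{cat.category_id!r} (first seen at row {seen[cid]})"
            )
        seen[cid] = i
        categories.append(cat)
    return categories


def write_burden_table(categories: list[BurdenCategory], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "category_id": [c.category_id for c in categories],
            "label": [c.label for c in categories],
            "daly_value": [_format_number(c.daly_value) for c in categories],
            "member_diseases": [LIST_SEP.join(c.member_diseases) for c in categories],
        }
    )
    df.to_csv(path, index=False)


def read_portfolios(path: Union[str, Path]) -> list[StakeholderPortfolio]:
    df = _read_table(path, ["stakeholder_id", "interests"], "portfolio")
    out: list[StakeholderPortfolio] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.stakeholder_id.strip()
        key = canonical(sid)
        if key in seen:
            raise ValidationError(
                f"portfolio row {i}, field 'stakeholder_id': duplicate id {sid!r}"
            )
        seen[key] = i
        try:
            out.append(StakeholderPortfolio(sid, _parse_list(row.interests)))
        except ValidationError as exc:
            raise ValidationError(f"portfolio row {i}: {exc}") from None
    return out


def write_portfolios(portfolios: list[StakeholderPortfolio], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "stakeholder_id": [p.stakeholder_id for p in portfolios],
            "interests": [LIST_SEP.join(p.interests) for p in portfolios],
        }
    )
    df.to_csv(path, index=False)


def read_notifiable_lists(path: Union[str, Path]) -> list[NotifiableList]:
    df = _read_table(path, ["country", "diseases"], "notifiable list")
    out: list[NotifiableList] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        country = row.country.strip()
        key = canonical(country)
        if key in seen:
            raise ValidationError(
                f"notifiable list row {i}, field 'country': duplicate country "
                f"{country!r}"
            )
        seen[key] = i
        out.append(NotifiableList(country, set(_parse_list(row.diseases))))
    return out


def write_notifiable_lists(lists: list[NotifiableList], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "country": [n.country for n in lists],
            "diseases": [LIST_SEP.join(sorted(n.diseases)) for n in lists],
        }
    )
    df.to_csv(path, index=False)


def read_citations(path: Union[str, Path]) -> dict[str, Union[list[int], int]]:
    """Read citation data: either per-publication citation counts
    (column ``citation_counts``, ";"-separated) or precomputed ``hindex``
    values.  Returns a canonical-name-keyed dict whose values are count lists
    or plain integers respectively."""
    df = _read_table(path, ["disease"], "citation")
    has_counts = "citation_counts" in df.columns
    has_h = "hindex" in df.columns
    if not has_counts and not has_h:
        raise ValidationError(
            "citation file must have a 'citation_counts' or 'hindex' column"
        )
    out: dict[str, Union[list[int], int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = canonical(row.disease)
        if name in out:
            raise ValidationError(
                f"citation row {i}, field 'disease': duplicate disease "
                f"{row.disease!r}"
            )
        cell = getattr(row, "citation_counts", "") if has_counts else ""
        if has_counts and cell.strip():
            try:
                counts = [int(c) for c in _parse_list(cell)]
            except ValueError:
                raise ValidationError(
                    f"citation row {i}, field 'citation_counts': "
                    f"non-integer entry in {cell!r}"
                ) from None
            if any(c < 0 for c in counts):
                raise ValidationError(
                    f"citation row {i}, field 'citation_counts': negative count"
                )
            out[name] = counts
        elif has_h and str(getattr(row, "hindex", "")).strip():
            try:
                h = int(str(row.hindex))
            except ValueError:
                raise ValidationError(
                    f"citation row {i}, field 'hindex': {row.hindex!r} "
                    f"is not an integer"
                ) from None
            if h < 0:
                raise ValidationError(
                    f"citation row {i}, field 'hindex': must be >= 0"
                )
            out[name] = h
        else:
            raise ValidationError(
                f"citation row {i}: neither citation_counts nor hindex given "
                f"for {row.disease!r}"
            )
    return out


def write_citations(
    citations: dict[str, Union[list[int], int]], path: Union[str, Path]
) -> None:
    rows = []
    for disease in citations:
        val = citations[disease]
        if isinstance(val, int):
            rows.append({"disease": disease, "citation_counts": "", "hindex": val})
        else:
            rows.append(
                {
                    "disease": disease,
                    "citation_counts": LIST_SEP.join(str(c) for c in val),
                    "hindex": "",
                }
            )
    pd.DataFrame(rows, columns=["disease", "citation_counts", "hindex"]).to_csv(
        path, index=False
    )


def _format_number(x: float) -> str:
    if math.isfinite(x) and float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_result_table(result, path: Union[str, Path]) -> None:
    """Write the ranked-cluster table: one row per cluster with rank, label,
    "n = priority/total", the alphabetical list of diseases to map, the total
    cluster DALYs, the average policy score (1 decimal) and the projection
    score (4 decimals)."""
    rows = []
    for entry in result.entries:
        c = entry.cluster
        rows.append(
            {
                "rank": entry.rank,
                "cluster": c.label,
                "n": f"n = {c.n_priority}/{c.n_total}",
                "diseases_to_map": LIST_SEP.join(
                    result.priority_diseases.get(c.label, [])
                ),
                "total_dalys": _format_number(c.total_dalys),
                "mean_policy": f"{c.mean_policy:.1f}",
                "projection_score": f"{entry.projection_score:.4f}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "rank",
            "cluster",
            "n",
            "diseases_to_map",
            "total_dalys",
            "mean_policy",
            "projection_score",
        ],
    ).to_csv(path, index=False)


def read_result_table(path: Union[str, Path]) -> pd.DataFrame:
    """Parse a written result table back into typed columns (used for
    round-trip checks and by downstream consumers of the CSV)."""
    df = _read_table(
        path,
        ["rank", "cluster", "n", "total_dalys", "mean_policy", "projection_score"],
        "result table",
    )
    if len(df) == 0:
        return df.assign(n_priority=[], n_total=[])
    df = df.assign(
        rank=df["rank"].astype(int),
        total_dalys=df["total_dalys"].astype(float),
        mean_policy=df["mean_policy"].astype(float),
        projection_score=df["projection_score"].astype(float),
    )
    frac = df["n"].str.extract(r"n = (\d+)/(\d+)")
    df["n_priority"] = frac[0].astype(int)
    df["n_total"] = frac[1].astype(int)
    return df
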