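"""End-to-end orchestration: cluster → allocate → score → rank → select.

Every stage reads its inputs from disk and writes its outputs to disk, so
the stages compose: running them one at a time over the same output
directory produces byte-identical files to a single :func:`run_pipeline`
call.  All analysis choices the method leaves open (nominal DALY, notifiable
scoring mode, DALY transform, top-k) surface in the config with the
published defaults, so the default run is the published analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .burden import (
    NOMINAL_DALY_DEFAULT,
    allocate_dalys,
    cluster_daly_totals,
    cumulative_daly_shares,
)
from .clustering import (
    ClusterKey,
    ClusterSummary,
    assign_clusters,
    cluster_census,
    read_label_map,
)
from .errors import ValidationError
from .policy import (
    accumulation_curve,
    apply_cluster_policy,
    coverage_summary,
    score_all,
)
from .ranking import PrioritisationResult, RankedCluster, RankingConfig, rank_clusters, select_top
from .registry import (
    LIST_SEP,
    read_burden_table,
    read_citations,
    read_notifiable_lists,
    read_portfolios,
    read_registry,
    write_result_table,
)

log = logging.getLogger("idpriority")

INPUT_KEYS = ("registry", "burden", "portfolios", "notifiable", "citations")


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    output_dir: str
    labels: Optional[str] = None
    nominal_daly: float = NOMINAL_DALY_DEFAULT
    notifiable_mode: str = "any"
    ranking: RankingConfig = field(default_factory=RankingConfig)
    accumulation_permutations: int = 999
    accumulation_seed: Optional[int] = None

    @classmethod
    def from_dict(cls, raw: dict, base: Optional[Path] = None) -> "PipelineConfig":
        base = base or Path(".")
        inputs = raw.get("inputs", {})
        missing = [k for k in INPUT_KEYS if k not in inputs]
        if missing:
            raise ValidationError(f"config: missing input path(s) {missing}")
        resolved = {k: str(base / v) for k, v in inputs.items() if k != "labels"}
        labels = inputs.get("labels")
        rank_raw = raw.get("ranking", {})
        acc = raw.get("accumulation", {})
        if "output_dir" not in raw:
            raise ValidationError("config: missing output_dir")
        return cls(
            inputs=resolved,
            output_dir=str(base / raw["output_dir"]),
            labels=str(base / labels) if labels else None,
            nominal_daly=float(raw.get("nominal_daly", NOMINAL_DALY_DEFAULT)),
            notifiable_mode=raw.get("notifiable_mode", "any"),
            ranking=RankingConfig(
                daly_transform=rank_raw.get("daly_transform", "log10"),
                tie_break=rank_raw.get("tie_break", "higher_dalys_first"),
                top_k=int(rank_raw.get("top_k", 15)),
            ),
            accumulation_permutations=int(acc.get("n_permutations", 999)),
            accumulation_seed=(
                int(acc["seed"]) if "seed" in acc and acc["seed"] is not None else None
            ),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path}: expected a mapping")
        return cls.from_dict(raw, base=path.parent)

    def to_dict(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "labels": self.labels,
            "output_dir": self.output_dir,
            "nominal_daly": self.nominal_daly,
            "notifiable_mode": self.notifiable_mode,
            "ranking": {
                "daly_transform": self.ranking.daly_transform,
                "tie_break": self.ranking.tie_break,
                "top_k": self.ranking.top_k,
            },
            "accumulation": {
                "n_permutations": self.accumulation_permutations,
                "seed": self.accumulation_seed,
            },
        }


# ---------------------------------------------------------------------------
# intermediate cluster table
# ---------------------------------------------------------------------------

_CLUSTER_COLS = [
    "label", "agent_type", "subgroup", "transmission_mode", "members",
    "n_total", "n_priority", "priority_members", "total_dalys",
    "mean_policy", "policy_defined",
]


def _write_clusters(clusters: list[ClusterSummary], path: Path) -> None:
    rows = []
    for c in clusters:
        rows.append(
            {
                "label": c.label,
                "agent_type": c.key.agent_type,
                "subgroup": c.key.subgroup,
                "transmission_mode": c.key.transmission_mode,
                "members": LIST_SEP.join(c.members),
                "n_total": c.n_total,
                "n_priority": c.n_priority,
                "priority_members": LIST_SEP.join(c.priority_members),
                "total_dalys": "" if c.total_dalys is None else repr(c.total_dalys),
                "mean_policy": "" if c.mean_policy is None else repr(c.mean_policy),
                "policy_defined": int(c.policy_defined),
            }
        )
    pd.DataFrame(rows, columns=_CLUSTER_COLS).to_csv(path, index=False)


def _read_clusters(path: Path) -> list[ClusterSummary]:
    if not path.exists():
        raise ValidationError(
            f"intermediate cluster table {path} not found; run the cluster "
            f"stage first"
        )
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    clusters = []
    for row in df.itertuples(index=False):
        clusters.append(
            ClusterSummary(
                key=ClusterKey(row.agent_type, row.subgroup, row.transmission_mode),
                label=row.label,
                members=row.members.split(LIST_SEP) if row.members else [],
                n_total=int(row.n_total),
                n_priority=int(row.n_priority),
                priority_members=(
                    row.priority_members.split(LIST_SEP)
                    if row.priority_members
                    else []
                ),
                total_dalys=float(row.total_dalys) if row.total_dalys else None,
                mean_policy=float(row.mean_policy) if row.mean_policy else None,
                policy_defined=bool(int(row.policy_defined)),
            )
        )
    return clusters


class _StageWriter:
    """Tracks files written by a stage so a failed stage leaves no partial
    outputs behind."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _run_stage(name, fn, config: PipelineConfig, *args, **kwargs):
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    writer = _StageWriter(outdir)
    try:
        return fn(config, writer, *args, **kwargs)
    except (ValidationError, OSError) as exc:
        writer.cleanup()
        log.error("stage %s failed; partial outputs removed", name)
        raise type(exc)(f"stage {name!r}: {exc}") from None


def _load_registry(config: PipelineConfig):
    records = read_registry(config.inputs["registry"])
    labels = read_label_map(config.labels) if config.labels else {}
    return records, labels


def _cluster_label_members(clusters: list[ClusterSummary]) -> dict[str, list[str]]:
    return {c.label: c.members for c in clusters}


def _stage_cluster(config: PipelineConfig, writer: _StageWriter) -> list[ClusterSummary]:
    records, labels = _load_registry(config)
    log.info("cluster: %d registry records", len(records))
    clusters = assign_clusters(records, labels)
    census = cluster_census(clusters)
    _write_clusters(clusters, writer.path("clusters.csv"))
    writer.path("census.json").write_text(json.dumps(census, indent=1, sort_keys=True))
    log.info("cluster: %d clusters (%d singletons, largest %d)",
             census["n_clusters"], census["n_singletons"], census["largest_size"])
    return clusters


def stage_cluster(config: PipelineConfig) -> list[ClusterSummary]:
    return _run_stage("cluster", _stage_cluster, config)


def _stage_burden(config: PipelineConfig, writer: _StageWriter) -> list[ClusterSummary]:
    records, _ = _load_registry(config)
    categories = read_burden_table(config.inputs["burden"], records)
    clusters = _read_clusters(Path(config.output_dir) / "clusters.csv")
    log.info("burden: %d categories over %d diseases", len(categories), len(records))
    allocations = allocate_dalys(records, categories, nominal=config.nominal_daly)
    clusters = cluster_daly_totals(clusters, allocations)
    pd.DataFrame(
        {
            "disease": [a.disease for a in allocations],
            "dalys": [repr(a.dalys) for a in allocations],
            "source": [a.source.value for a in allocations],
        }
    ).to_csv(writer.path("allocations.csv"), index=False)
    _write_clusters(clusters, writer.path("clusters.csv"))
    log.info("burden: %d allocations written", len(allocations))
    return clusters


def stage_burden(config: PipelineConfig) -> list[ClusterSummary]:
    return _run_stage("burden", _stage_burden, config)


def _stage_score(config: PipelineConfig, writer: _StageWriter) -> list[ClusterSummary]:
    records, _ = _load_registry(config)
    portfolios = read_portfolios(config.inputs["portfolios"])
    lists = read_notifiable_lists(config.inputs["notifiable"])
    citations = read_citations(config.inputs["citations"])
    clusters = _read_clusters(Path(config.output_dir) / "clusters.csv")
    label_members = _cluster_label_members(clusters)
    log.info("score: %d portfolios, %d notifiable lists", len(portfolios), len(lists))
    scores = score_all(
        records, portfolios, lists, citations, label_members,
        notifiable_mode=config.notifiable_mode,
    )
    clusters = apply_cluster_policy(clusters, scores, records)
    by_name = {r.name: r for r in records}
    pd.DataFrame(
        {
            "disease": [r.name for r in records],
            "stakeholder_points": [r.policy.stakeholder_points for r in records],
            "notifiable_points": [r.policy.notifiable_points for r in records],
            "hindex": [r.hindex for r in records],
            "hindex_points": [r.policy.hindex_points for r in records],
            "total": [r.policy.total for r in records],
        }
    ).to_csv(writer.path("policy_scores.csv"), index=False)
    cov = coverage_summary(records, portfolios, lists, label_members)
    writer.path("coverage.json").write_text(json.dumps(cov, indent=1, sort_keys=True))
    _write_clusters(clusters, writer.path("clusters.csv"))
    log.info("score: %d diseases scored", len(by_name))
    return clusters


def stage_score(config: PipelineConfig) -> list[ClusterSummary]:
    return _run_stage("score", _stage_score, config)


def _stage_curve(config: PipelineConfig, writer: _StageWriter):
    records, _ = _load_registry(config)
    portfolios = read_portfolios(config.inputs["portfolios"])
    clusters = _read_clusters(Path(config.output_dir) / "clusters.csv")
    if config.accumulation_seed is None:
        raise ValidationError("accumulation requested but no seed configured")
    curve = accumulation_curve(
        portfolios,
        [r.name for r in records],
        _cluster_label_members(clusters),
        n_permutations=config.accumulation_permutations,
        seed=config.accumulation_seed,
    )
    pd.DataFrame(
        {
            "k": range(1, len(curve.mean_unique) + 1),
            "mean_unique": [repr(v) for v in curve.mean_unique],
        }
    ).to_csv(writer.path("accumulation_curve.csv"), index=False)
    log.info("curve: union of %d diseases over %d stakeholders",
             curve.union_size, len(portfolios))
    return curve


def stage_curve(config: PipelineConfig):
    return _run_stage("curve", _stage_curve, config)


def _stage_rank(config: PipelineConfig, writer: _StageWriter):
    clusters = _read_clusters(Path(config.output_dir) / "clusters.csv")
    result = rank_clusters(clusters, config.ranking)
    top = select_top(result, config.ranking.top_k)
    shares = cumulative_daly_shares([e.cluster for e in result.entries])
    write_result_table(result, writer.path("ranked.csv"))
    pd.DataFrame(
        {
            "rank": [e.rank for e in result.entries],
            "cluster": [e.cluster.label for e in result.entries],
            "x": [repr(e.x) for e in result.entries],
            "y": [repr(e.y) for e in result.entries],
            "projection_score": [repr(e.projection_score) for e in result.entries],
        }
    ).to_csv(writer.path("projection_scores.csv"), index=False)
    pd.DataFrame(
        {
            "rank": [e.rank for e in result.entries],
            "cluster": [e.cluster.label for e in result.entries],
            "cumulative_percent": [repr(s) for s in shares],
        }
    ).to_csv(writer.path("cumulative_shares.csv"), index=False)
    payload = {
        "ranking": [
            {
                "rank": e.rank,
                "cluster": e.cluster.label,
                "n_priority": e.cluster.n_priority,
                "n_total": e.cluster.n_total,
                "total_dalys": e.cluster.total_dalys,
                "mean_policy": e.cluster.mean_policy,
                "policy_defined": e.cluster.policy_defined,
                "x": e.x,
                "y": e.y,
                "projection_score": e.projection_score,
                "diseases_to_map": result.priority_diseases[e.cluster.label],
            }
            for e in result.entries
        ],
        "top_k": config.ranking.top_k,
        "top_pooled_priority_count": top.pooled_priority_count,
        "top_cumulative_daly_share_pct": top.cumulative_share_pct,
    }
    writer.path("result.json").write_text(json.dumps(payload, indent=1))
    log.info("rank: %d clusters ranked; top %d pool %d priority diseases",
             len(result.entries), len(top.entries), top.pooled_priority_count)
    return result, top


def stage_rank(config: PipelineConfig):
    return _run_stage("rank", _stage_rank, config)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig) -> Path:
    """Machine-readable run manifest: config, input hashes, package version.
    Deliberately carries no timestamps so identical runs are byte-identical."""
    inputs = dict(config.inputs)
    if config.labels:
        inputs["labels"] = config.labels
    manifest = {
        "package": "idpriority",
        "version": __version__,
        "config": config.to_dict(),
        "input_sha256": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }
    path = Path(config.output_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_pipeline(config: PipelineConfig):
    """Execute all stages in order and write the manifest.

    Returns the (result, top selection) pair from the ranking stage.
    """
    stage_cluster(config)
    stage_burden(config)
    stage_score(config)
    stage_curve(config)
    result, top = stage_rank(config)
    write_manifest(config)
    return result, top
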