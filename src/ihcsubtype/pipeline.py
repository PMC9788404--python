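"""End-to-end orchestration: cohort -> classify -> cluster -> concordance -> survival.

A :class:`PipelineConfig` names the cohort source (bundled reference cohort,
simulator, or CSV files) and the stage parameters.  :func:`run_pipeline`
executes every stage, writes each stage's tables as CSV (with a provenance
comment header carrying the config hash, seed and package version), optional
figures, and a Markdown summary.  Identical (config, seed) yields
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .classify import calls_to_frame, classify_cohort, classify_two_marker, cutoff_sensitivity
from .clustering import (
    DEFAULT_R_GRID,
    attach_support,
    average_linkage_tree,
    correlation_distance,
    label_cluster,
    significant_clusters,
)
from .concordance import (
    bilateral_paired_summary,
    transition_matrix_estimate,
    unilateral_concordance,
)
from .datamodel import CohortMatrix, LesionSite, ValidationError
from .io import read_cohort, write_clinical_csv, write_ihc_csv, _write_with_header
from .reference import designated_node_records, reference_cohort
from .survival import assemble_survival, km_by_group, logrank_test
from .synthetic import SimulatedCohort, SyntheticCohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

_SOURCES = ("fixture", "simulate", "files")


@dataclass
class PipelineConfig:
    """Validated pipeline parameters."""

    source: str = "fixture"
    ihc_path: str | None = None
    clinical_path: str | None = None
    n_patients: int = 38
    cutoff: float = 20.0
    nboot: int = 1000
    r_grid: tuple[float, ...] = DEFAULT_R_GRID
    alpha: float = 0.95
    seed: int = 0
    endpoint: str = "pfs"
    grouping: str = "two_marker"
    output_dir: str = "ihcsubtype_output"
    make_figures: bool = True

    def config_hash(self) -> str:
        """Hash of the analysis parameters (where outputs land doesn't count)."""
        payload = asdict(self)
        payload.pop("output_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class ConfigError(ValueError):
    """All configuration problems, reported at once."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file or a dict.

    Every constraint violation is collected and reported together; unknown
    keys are flagged; a missing seed gets the default (0) with a log note.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError([f"{source}: config document must be a mapping"])
    else:
        raw = dict(source)

    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        errors.append(f"unknown config keys: {unknown}")
    raw = {k: v for k, v in raw.items() if k in known}

    if "seed" not in raw:
        logger.info("no seed in config; using default seed 0")
    if "r_grid" in raw:
        raw["r_grid"] = tuple(float(r) for r in raw["r_grid"])

    config = PipelineConfig(**raw)
    if config.source not in _SOURCES:
        errors.append(f"source must be one of {_SOURCES}, got {config.source!r}")
    if config.source == "files":
        if not config.ihc_path or not config.clinical_path:
            errors.append("source 'files' requires ihc_path and clinical_path")
    elif config.ihc_path or config.clinical_path:
        errors.append(
            f"source {config.source!r} conflicts with explicit input paths"
        )
    if not 0 < config.cutoff < 100:
        errors.append(f"cutoff must be in (0, 100), got {config.cutoff}")
    if config.nboot < 1:
        errors.append("nboot must be >= 1")
    if not 0 < config.alpha <= 1:
        errors.append(f"alpha must be in (0, 1], got {config.alpha}")
    if config.n_patients < 2:
        errors.append("n_patients must be >= 2")
    if config.endpoint not in ("pfs", "os"):
        errors.append(f"endpoint must be pfs or os, got {config.endpoint!r}")
    if config.grouping not in ("two_marker", "cluster", "nodal_pattern"):
        errors.append(f"unknown grouping {config.grouping!r}")
    if errors:
        raise ConfigError(errors)
    return config


def _stage(name: str, n_records: int) -> None:
    logger.info("stage %-10s | %d records", name, n_records)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``output_dir``.

    Returns a dict of the key in-memory results (proportion table,
    concordance tables, log-rank result, output paths).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }

    # --- acquire cohort -----------------------------------------------------
    truth = None
    if config.source == "fixture":
        cohort = reference_cohort()
        ihc, clinical = cohort.ihc_records, cohort.clinical_records
    elif config.source == "simulate":
        sim: SimulatedCohort = simulate_cohort(
            SyntheticCohortConfig(n_patients=config.n_patients, seed=config.seed)
        )
        ihc, clinical, truth = sim.ihc_records, sim.clinical_records, sim.truth
    else:
        ihc, clinical = read_cohort(config.ihc_path, config.clinical_path)
    _stage("cohort", len(ihc))
    write_ihc_csv(ihc, out / "ihc.csv", metadata=meta)
    write_clinical_csv(clinical, out / "clinical.csv", metadata=meta)
    if truth is not None:
        _write_with_header(truth, out / "truth.csv", meta)

    # --- classify -----------------------------------------------------------
    calls, proportions = classify_cohort(ihc, cutoff=config.cutoff)
    _stage("classify", len(calls))
    node_calls = [
        classify_two_marker(r, cutoff=config.cutoff)
        for r in ihc
        if r.lesion_site != LesionSite.PRIMARY
    ]
    _write_with_header(calls_to_frame(calls + node_calls), out / "subtype_calls.csv", meta)
    _write_with_header(proportions.reset_index(), out / "subtype_proportions.csv", meta)
    sweep = cutoff_sensitivity(ihc, [5, 10, 20, 30, 40, 50])
    _write_with_header(sweep.reset_index(), out / "cutoff_sensitivity.csv", meta)

    # --- cluster ------------------------------------------------------------
    matrix = CohortMatrix.from_records(ihc, LesionSite.PRIMARY)
    tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
    attach_support(tree, matrix, r_grid=config.r_grid, nboot=config.nboot, seed=config.seed)
    clusters, unassigned = significant_clusters(tree, alpha=config.alpha)
    _stage("cluster", len(clusters))
    cluster_rows = []
    cluster_labels: dict[str, str] = {}
    for rank, node in enumerate(clusters, start=1):
        members = tree.member_labels(node)
        label = label_cluster(members, matrix, cutoff=config.cutoff)
        name = f"cluster{rank}_{label.major}_{label.sub}"
        for pid in members:
            cluster_labels[pid] = name
        cluster_rows.append(
            {
                "cluster": rank,
                "node": node.id,
                "n_members": len(members),
                "au": round(float(tree.support.loc[node.id, "au"]), 4),
                "bp": round(float(tree.support.loc[node.id, "bp"]), 4),
                "major": label.major,
                "sub": label.sub,
                "members": ";".join(members),
            }
        )
    cluster_table = pd.DataFrame(
        cluster_rows,
        columns=["cluster", "node", "n_members", "au", "bp", "major", "sub", "members"],
    )
    _write_with_header(cluster_table, out / "cluster_table.csv", meta)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")

    # --- concordance --------------------------------------------------------
    primary_by_id = {c.patient_id: c for c in calls}
    designated = [
        classify_two_marker(r, cutoff=config.cutoff)
        for r in designated_node_records(ihc)
    ]
    pooled = unilateral_concordance(
        [primary_by_id[c.patient_id] for c in designated], designated
    )
    _stage("concord", pooled.n_patients)
    _write_with_header(pooled.counts.reset_index(), out / "concordance_pooled.csv", meta)

    nodal = {c.patient_id: c.nodal_pattern for c in clinical}
    uni_ids = {pid for pid, pat in nodal.items() if pat == "unilateral"}
    uni_table = unilateral_concordance(
        [c for c in calls if c.patient_id in uni_ids],
        [c for c in designated if c.patient_id in uni_ids],
    )
    _write_with_header(
        uni_table.counts.reset_index(), out / "concordance_unilateral.csv", meta
    )

    bilateral = None
    bi_ids = {pid for pid, pat in nodal.items() if pat == "bilateral"}
    right = [
        classify_two_marker(r, cutoff=config.cutoff)
        for r in ihc
        if r.lesion_site == LesionSite.NODE_RIGHT and r.patient_id in bi_ids
    ]
    left = [
        classify_two_marker(r, cutoff=config.cutoff)
        for r in ihc
        if r.lesion_site == LesionSite.NODE_LEFT and r.patient_id in bi_ids
    ]
    if right and left:
        bilateral = bilateral_paired_summary(
            [c for c in calls if c.patient_id in bi_ids], right, left
        )
        _write_with_header(bilateral.triples, out / "bilateral_triples.csv", meta)

    transition = transition_matrix_estimate(pooled, seed=config.seed)
    trans_out = transition.matrix.round(4).reset_index()
    _write_with_header(trans_out, out / "transition_estimate.csv", meta)

    # --- survival -----------------------------------------------------------
    dataset = assemble_survival(
        clinical,
        calls=calls,
        endpoint=config.endpoint,
        grouping=config.grouping,
        cluster_labels=cluster_labels if config.grouping == "cluster" else None,
    )
    curves = km_by_group(dataset)
    logrank = logrank_test(dataset)
    _stage("survive", len(dataset))
    km_frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    _write_with_header(
        km_frame, out / f"km_{config.grouping}_{config.endpoint}.csv", meta
    )

    # --- figures ------------------------------------------------------------
    if config.make_figures:
        from . import plotting

        plotting.heatmap_with_dendrogram(matrix, tree, out / "heatmap.svg")
        plotting.cutoff_sweep_plot(sweep, out / "cutoff_sweep.svg", config.cutoff)
        plotting.km_plot(curves, out / f"km_{config.grouping}_{config.endpoint}.svg",
                         endpoint=config.endpoint.upper())

    # --- summary ------------------------------------------------------------
    summary = _summary_markdown(
        config, meta, proportions, cluster_table, pooled, bilateral, logrank
    )
    (out / "summary.md").write_text(summary, encoding="utf-8")

    return {
        "proportions": proportions,
        "cluster_table": cluster_table,
        "pooled_concordance": pooled,
        "unilateral_concordance": uni_table,
        "bilateral": bilateral,
        "transition": transition,
        "logrank": logrank,
        "unassigned": unassigned,
        "output_dir": str(out),
    }


def _summary_markdown(config, meta, proportions, cluster_table, pooled, bilateral, logrank) -> str:
    lines = [
        "# IHC subtyping summary",
        "",
        f"- config hash: `{meta['config_sha256']}`",
        f"- seed: {meta['seed']}",
        f"- package version: {meta['package_version']}",
        f"- cutoff: {config.cutoff}%",
        "",
        "## Two-marker subtype shares (primary lesions)",
        "",
        proportions.to_markdown(),
        "",
        "## Significant clusters (AU >= %.2f)" % config.alpha,
        "",
        cluster_table.drop(columns=["members"]).to_markdown(index=False)
        if len(cluster_table)
        else "(no cluster reached the AU threshold)",
        "",
        "## Primary vs designated nodal metastasis (all patients)",
        "",
        pooled.counts.to_markdown(),
        "",
        "Per-row stability (%):",
        "",
        pooled.row_stability.to_frame("stability").to_markdown(),
        "",
    ]
    if bilateral is not None:
        lines += [
            "## Bilateral paired metastases",
            "",
            "Right-node subtype shares:",
            "",
            bilateral.right_marginal.to_markdown(),
            "",
            f"Fully concordant triples: {bilateral.n_fully_concordant}",
            "",
        ]
    lines += [
        "## Survival",
        "",
        f"Log-rank ({config.grouping}, {config.endpoint.upper()}): "
        f"chi2 = {logrank.statistic:.3f}, df = {logrank.df}, p = {logrank.p_value:.4f}",
        "",
    ]
    return "\n".join(lines)
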