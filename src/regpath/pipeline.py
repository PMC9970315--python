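"""Configuration-driven orchestration: generate → consensus → build →
search → stats.

A single YAML config drives a full run.  In synthetic mode the bundled
generator produces all interaction tables (with planted ground-truth
paths); in file mode the same stages run on user-supplied PPI, TF→miRNA
and per-tool prediction tables.  Every stage writes machine-readable
outputs into the run directory and the run ends with a manifest listing
each produced file with its SHA-256 checksum, so identical config+seed
gives identical checksums.

Config dialect (YAML)::

    seed: 7
    output_dir: out
    synthetic:
      network:
        planted_paths: [[TGFB1, TFX, miR-378a-3p, CTGF]]
        n_decoy_genes: 20
        n_tfs: 3
        n_mirnas: 2
        ppi_edge_prob: 0.1
      qpcr:                    # optional stats stage
        genes: [TGFB1, GAPDH]
        fold_changes: {OM: {TGFB1: 0.42}}
      cohort: default          # optional; 'default' = bundled 24/11 arms
    # -- or, instead of `synthetic:` --
    inputs:
      ppi: ppi.tsv
      tf_mirna: tf_mirna.tsv
      predictions: {DIANA: diana.tsv, ...}
      sources: [TGFB1]
      targets: [CTGF]
    consensus: {min_tools: 3}
    search: {max_depth: 4, edge_types: [ppi, tf_mirna, mirna_target]}
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_targets, load_predictions, write_consensus
from .network import (
    build_network,
    normalize_id,
    validate_network,
    write_graphml,
    write_network,
    write_sif,
)
from .search import (
    SearchConfig,
    build_search_tree,
    enumerate_paths,
    paths_to_table,
)
from .simulate import (
    CohortGroupSpec,
    CohortSimConfig,
    NetworkSimConfig,
    QpcrSimConfig,
    default_cohort_config,
    gen_cohort,
    gen_interaction_db,
    gen_qpcr,
)
from .stats import cohort_summary, delta_delta_ct, pooled_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunManifest",
    "run_pipeline",
    "validate_config",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Parsed and structurally validated run configuration."""

    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ValueError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls(raw=raw, path=path)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        base = Path(self.raw.get("output_dir", "regpath_out"))
        if not base.is_absolute() and self.path is not None:
            base = self.path.parent / base
        return base

    @property
    def synthetic(self) -> bool:
        return "synthetic" in self.raw

    @property
    def min_tools(self) -> int:
        return int(self.raw.get("consensus", {}).get("min_tools", 3))

    def network_sim_config(self) -> NetworkSimConfig:
        net = dict(self.raw["synthetic"]["network"])
        net.setdefault("seed", self.seed)
        net["planted_paths"] = [list(p) for p in net["planted_paths"]]
        net.setdefault("min_tools", self.min_tools)
        return NetworkSimConfig(**net)

    def search_config(self) -> SearchConfig:
        s = self.raw.get("search", {})
        etf = s.get("edge_types")
        return SearchConfig(
            max_depth=int(s.get("max_depth", 4)),
            edge_type_filter=frozenset(etf) if etf else None,
        )

    def qpcr_sim_config(self) -> QpcrSimConfig | None:
        q = self.raw.get("synthetic", {}).get("qpcr")
        if q is None:
            return None
        q = dict(q)
        q.setdefault("seed", self.seed)
        return QpcrSimConfig(**q)

    def cohort_sim_config(self) -> CohortSimConfig | None:
        c = self.raw.get("synthetic", {}).get("cohort")
        if c is None:
            return None
        if c == "default":
            return default_cohort_config(seed=self.seed)
        c = dict(c)
        c.setdefault("seed", self.seed)
        c["group_specs"] = [CohortGroupSpec(**g) for g in c["group_specs"]]
        return CohortSimConfig(**c)


def validate_config(path_or_config) -> list:
    """List schema violations without running anything (empty = valid)."""
    try:
        cfg = (
            path_or_config
            if isinstance(path_or_config, PipelineConfig)
            else PipelineConfig.from_yaml(path_or_config)
        )
    except ValueError as exc:
        return [str(exc)]
    raw = cfg.raw
    problems = []
    if "synthetic" not in raw and "inputs" not in raw:
        problems.append("config must declare either 'synthetic' or 'inputs'")
    if "synthetic" in raw:
        net = raw["synthetic"].get("network")
        if not net:
            problems.append("synthetic mode requires synthetic.network")
        elif not net.get("planted_paths"):
            problems.append(
                "synthetic.network.planted_paths must declare at least one "
                "source→target path"
            )
        else:
            try:
                cfg.network_sim_config()
            except (ValueError, TypeError) as exc:
                problems.append(f"synthetic.network: {exc}")
        if raw["synthetic"].get("qpcr") is not None:
            try:
                cfg.qpcr_sim_config()
            except (ValueError, TypeError) as exc:
                problems.append(f"synthetic.qpcr: {exc}")
        if raw["synthetic"].get("cohort") is not None:
            try:
                cfg.cohort_sim_config()
            except (ValueError, TypeError) as exc:
                problems.append(f"synthetic.cohort: {exc}")
    if "inputs" in raw:
        inputs = raw["inputs"]
        for key in ("ppi", "tf_mirna"):
            p = inputs.get(key)
            if p is None:
                problems.append(f"inputs.{key} is required in file mode")
            elif not Path(_resolve(cfg, p)).exists():
                problems.append(f"inputs.{key}: file not found: {p}")
        preds = inputs.get("predictions") or {}
        if not preds:
            problems.append("inputs.predictions must map tool → file")
        for tool, p in preds.items():
            if not Path(_resolve(cfg, p)).exists():
                problems.append(
                    f"inputs.predictions.{tool}: file not found: {p}"
                )
        n_tools = len(preds)
        if preds and cfg.min_tools > n_tools:
            problems.append(
                f"consensus.min_tools={cfg.min_tools} exceeds the "
                f"{n_tools} prediction tools declared"
            )
        if not inputs.get("sources"):
            problems.append("inputs.sources must declare at least one source")
        if not inputs.get("targets"):
            problems.append("inputs.targets must declare at least one target")
    if cfg.min_tools < 1:
        problems.append("consensus.min_tools must be >= 1")
    if "synthetic" in raw:
        n_tools = len(
            raw["synthetic"].get("network", {}).get("tools", [])
            or ("DIANA", "Miranda", "PicTar", "TargetScan", "miRDB")
        )
        if cfg.min_tools > n_tools:
            problems.append(
                f"consensus.min_tools={cfg.min_tools} exceeds the "
                f"{n_tools} prediction tools"
            )
    try:
        cfg.search_config()
    except ValueError as exc:
        problems.append(f"search: {exc}")
    return problems


def _resolve(cfg: PipelineConfig, p) -> Path:
    p = Path(p)
    if not p.is_absolute() and cfg.path is not None:
        p = cfg.path.parent / p
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config echo, file checksums, counts."""

    config: dict
    files: dict = field(default_factory=dict)  # relative path -> sha256
    counts: dict = field(default_factory=dict)
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = ""

    def add_file(self, outdir: Path, path: Path):
        self.files[str(path.relative_to(outdir))] = _sha256(path)

    def write(self, path: Path):
        payload = {
            "config": self.config,
            "files": self.files,
            "counts": self.counts,
            "version": self.version,
            "python": self.python,
            "timestamp": self.timestamp,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage and write outputs + manifest.

    Stage order: simulate (synthetic mode only) → consensus → build →
    search → stats (optional).  Any stage failure raises
    :class:`PipelineError` naming the stage; no stage mutates a prior
    stage's outputs.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.raw)

    # -- stage: simulate / load inputs ----------------------------------
    if config.synthetic:
        try:
            db = gen_interaction_db(config.network_sim_config())
        except ValueError as exc:
            raise PipelineError("simulate", str(exc)) from exc
        ppi_path = outdir / "ppi.tsv"
        tfm_path = outdir / "tf_mirna.tsv"
        db.ppi_edges.to_csv(ppi_path, sep="\t", index=False)
        db.tf_mirna_edges.to_csv(tfm_path, sep="\t", index=False)
        pred_dir = outdir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        pred_paths, tool_names = [], []
        for tool, table in db.prediction_tables.items():
            p = pred_dir / f"{tool}.tsv"
            table.to_csv(p, sep="\t", index=False)
            pred_paths.append(p)
            tool_names.append(tool)
        truth = [
            {
                "nodes": [normalize_id(n) for n in t.nodes],
                "edge_types": list(t.edge_types),
            }
            for t in db.truth
        ]
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=2))
        sources = [db.source]
        targets = [db.target]
        tf_ids = db.tf_ids
        for p in [ppi_path, tfm_path, truth_path, *pred_paths]:
            manifest.add_file(outdir, p)
    else:
        inputs = config.raw["inputs"]
        ppi_path = _resolve(config, inputs["ppi"])
        tfm_path = _resolve(config, inputs["tf_mirna"])
        pred_items = sorted(inputs["predictions"].items())
        tool_names = [t for t, _ in pred_items]
        pred_paths = [_resolve(config, p) for _, p in pred_items]
        sources = list(inputs["sources"])
        targets = list(inputs["targets"])
        tf_ids = set(inputs.get("tf_ids", []))
        truth = None

    # -- stage: consensus ------------------------------------------------
    try:
        records = load_predictions(pred_paths, tool_names)
        consensus = consensus_targets(records, min_tools=config.min_tools)
    except ValueError as exc:
        raise PipelineError("consensus", str(exc)) from exc
    cons_tsv = outdir / "consensus.tsv"
    cons_json = outdir / "consensus_summary.json"
    write_consensus(consensus, cons_tsv, cons_json, tool_names=tool_names)
    manifest.add_file(outdir, cons_tsv)
    manifest.add_file(outdir, cons_json)
    manifest.counts["prediction_records"] = len(records)
    manifest.counts["consensus_targets"] = sum(
        len(c.targets) for c in consensus
    )

    # -- stage: build ----------------------------------------------------
    try:
        ppi_df = pd.read_csv(ppi_path, sep="\t")
        tfm_df = pd.read_csv(tfm_path, sep="\t")
        net = build_network(
            ppi_df, tfm_df, consensus, sources, targets, tf_ids=tf_ids
        )
    except ValueError as exc:
        raise PipelineError("build", str(exc)) from exc
    violations = validate_network(net)
    if violations:  # pragma: no cover - build_network output is valid
        raise PipelineError("build", "; ".join(violations))
    nodes_path, edges_path = outdir / "nodes.tsv", outdir / "edges.tsv"
    write_network(net, nodes_path, edges_path)
    write_graphml(net, outdir / "network.graphml")
    write_sif(net, outdir / "network.sif")
    for p in [nodes_path, edges_path, outdir / "network.graphml",
              outdir / "network.sif"]:
        manifest.add_file(outdir, p)
    manifest.counts["nodes"] = net.graph.number_of_nodes()
    manifest.counts["edges"] = net.graph.number_of_edges()
    manifest.counts["edges_by_type"] = net.n_edges_by_type()

    # -- stage: search ---------------------------------------------------
    search_cfg = config.search_config()
    try:
        paths = []
        for s in net.source_ids:
            for t in net.target_ids:
                paths.extend(enumerate_paths(net, s, t, search_cfg))
        tree = build_search_tree(net, net.source_ids[0], search_cfg)
    except KeyError as exc:
        raise PipelineError("search", str(exc)) from exc
    paths_table = paths_to_table(paths)
    paths_path = outdir / "paths.csv"
    paths_table.to_csv(paths_path, index=False)
    tree.to_json(outdir / "search_tree.json")
    (outdir / "search_tree.txt").write_text(tree.to_text() + "\n")
    for p in [paths_path, outdir / "search_tree.json",
              outdir / "search_tree.txt"]:
        manifest.add_file(outdir, p)
    manifest.counts["paths"] = len(paths)
    if config.synthetic and truth is not None:
        found = {tuple(p.nodes) for p in paths}
        recovered = sum(
            1 for t in truth if tuple(t["nodes"]) in found
        )
        manifest.counts["planted_paths"] = len(truth)
        manifest.counts["planted_recovered"] = recovered
        logger.info("recovered %d/%d planted paths", recovered, len(truth))

    # -- stage: stats (optional) ----------------------------------------
    qpcr_cfg = config.qpcr_sim_config() if config.synthetic else None
    if qpcr_cfg is not None:
        qpcr = gen_qpcr(qpcr_cfg)
        qpcr_path = outdir / "qpcr.csv"
        qpcr.to_csv(qpcr_path, index=False)
        results = []
        for group in qpcr_cfg.groups:
            if group == qpcr_cfg.control_group:
                continue
            for gene in qpcr_cfg.genes:
                if gene == qpcr_cfg.reference_gene:
                    continue
                fc = delta_delta_ct(
                    qpcr, gene, qpcr_cfg.reference_gene, group,
                    qpcr_cfg.control_group,
                )
                results.append(
                    {
                        "gene": gene,
                        "treated": group,
                        "control": qpcr_cfg.control_group,
                        "delta_delta_ct": fc.delta_delta_ct,
                        "fold_change": fc.fold_change,
                        "percent_change": fc.percent_change,
                        "percent_suppression": fc.percent_suppression,
                    }
                )
        ddct_path = outdir / "ddct_results.json"
        ddct_path.write_text(json.dumps(results, indent=2))
        manifest.add_file(outdir, qpcr_path)
        manifest.add_file(outdir, ddct_path)
        manifest.counts["ddct_contrasts"] = len(results)

    cohort_cfg = config.cohort_sim_config() if config.synthetic else None
    if cohort_cfg is not None:
        cohort = gen_cohort(cohort_cfg)
        cohort_path = outdir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        summary = cohort_summary(cohort, sex_category=cohort_cfg.sex_category)
        labels = [g.label for g in cohort_cfg.group_specs]
        tests = {}
        if len(labels) >= 2:
            a = cohort[cohort["group"] == labels[0]]
            b = cohort[cohort["group"] == labels[1]]
            for name in sorted(cohort_cfg.group_specs[0].biomarkers):
                res = pooled_t_test(a[name], b[name])
                tests[name] = {
                    "t": res.t, "df": res.df, "p": round(res.p, 3),
                    f"mean_{labels[0]}": res.mean1,
                    f"mean_{labels[1]}": res.mean2,
                }
        stats_path = outdir / "cohort_stats.json"
        stats_path.write_text(
            json.dumps(
                {
                    "total_n": summary.total_n,
                    "sex_percent": summary.sex_percent,
                    "t_tests": tests,
                },
                indent=2,
            )
        )
        manifest.add_file(outdir, cohort_path)
        manifest.add_file(outdir, stats_path)
        manifest.counts["cohort_n"] = summary.total_n

    manifest.timestamp = datetime.now(timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest
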