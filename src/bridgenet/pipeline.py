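"""Full-pipeline orchestration and the report bundle.

Runs ingest -> completeness filter -> scoring -> EBIC-glasso estimation ->
bridge centrality -> bootstrap robustness -> layout, and writes the whole
report bundle (CSV/JSON) atomically to an output directory.  The bundle is
a pure function of (input file, config, master seed): stage seeds are
derived deterministically from the master seed so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import bridge as bridge_mod
from . import network as network_mod
from . import robustness as robust_mod
from . import scales as scales_mod
from .exceptions import BridgenetError, ConfigError, ValidationError
from .network import PartialCorrelationNetwork
from .robustness import DEFAULT_DROP_PROPORTIONS, BootstrapConfig
from .scales import NODE_COMMUNITIES, NODE_IDS, NodeScoreTable, RetentionSummary

logger = logging.getLogger(__name__)

#: seed offsets per stochastic stage (master + offset)
STAGE_SEEDS = {"edge_bootstrap": 1, "case_drop": 2, "layout": 3}


@dataclass
class PipelineConfig:
    """Validated settings for one end-to-end run."""

    input: str
    outdir: str
    input_kind: str = "scores"  # scores | items
    codebook: str | None = None
    method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    B: int = 1000
    proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_kind not in ("scores", "items"):
            raise ConfigError(f"input_kind must be 'scores' or 'items', got {self.input_kind!r}")
        if self.method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation method {self.method!r}")
        if self.B < 2:
            raise ConfigError("B must be at least 2")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_lambda < 2:
            raise ConfigError("n_lambda must be at least 2")
        if not 0.0 < self.min_ratio < 1.0:
            raise ConfigError("min_ratio must lie in (0, 1)")
        self.proportions = tuple(float(q) for q in self.proportions)
        if any(not 0.0 <= q < 1.0 for q in self.proportions):
            raise ConfigError("drop proportions must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid config key: {exc}") from exc

    def bootstrap_config(self, stage: str) -> BootstrapConfig:
        return BootstrapConfig(
            B=self.B,
            seed=self.seed + STAGE_SEEDS[stage],
            alpha=self.alpha,
            gamma=self.gamma,
            method=self.method,
            n_lambda=self.n_lambda,
            min_ratio=self.min_ratio,
        )


@dataclass
class ReportBundle:
    """Paths of every artifact written by :func:`run_pipeline`."""

    outdir: str
    files: dict[str, str] = field(default_factory=dict)

    def path(self, name: str) -> str:
        return self.files[name]


def read_scores(path: str) -> tuple[NodeScoreTable, RetentionSummary]:
    """Read a node-level scores CSV, dropping incomplete rows.

    The file must carry the 21 standard node columns (EXT..OPE, A1..A7,
    D1..D9).  Rows with any blank entry are excluded, mirroring the
    questionnaire completeness rule.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in NODE_IDS if c not in df.columns]
    if missing:
        raise ValidationError(f"scores file lacks node columns: {missing}")
    df = df[list(NODE_IDS)]
    mask = df.notna().all(axis=1)
    summary = RetentionSummary(n_submitted=len(df), n_valid=int(mask.sum()))
    kept = df.loc[mask].reset_index(drop=True)
    return NodeScoreTable(values=kept, community=dict(NODE_COMMUNITIES)), summary


def fr_layout(
    net: PartialCorrelationNetwork, seed: int = 0, iterations: int = 500
) -> pd.DataFrame:
    """Fruchterman-Reingold coordinates, normalized to [-1, 1]^2.

    Edge attraction uses |weight|; placement is seeded so coordinates are
    reproducible.  A single node sits at the origin.
    """
    if net.p == 1:
        return pd.DataFrame({"node": [net.node_ids[0]], "x": [0.0], "y": [0.0]})
    G = nx.Graph()
    G.add_nodes_from(net.node_ids)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = abs(net.W[i, j])
            if w > network_mod.ZERO_TOL:
                G.add_edge(net.node_ids[i], net.node_ids[j], weight=w)
    pos = nx.spring_layout(G, seed=seed, iterations=iterations, weight="weight")
    coords = np.array([pos[nid] for nid in net.node_ids])
    scale = np.abs(coords).max()
    if scale > 0:
        coords = coords / scale
    return pd.DataFrame(
        {"node": list(net.node_ids), "x": coords[:, 0], "y": coords[:, 1]}
    )


def _write_atomic(path: str, writer) -> None:
    tmp = path + ".tmp"
    writer(tmp)
    os.replace(tmp, path)


def _write_csv(df: pd.DataFrame, path: str) -> None:
    _write_atomic(path, lambda t: df.to_csv(t, index=False))


def _write_json(obj, path: str) -> None:
    _write_atomic(
        path,
        lambda t: open(t, "w", encoding="utf-8").write(
            json.dumps(obj, indent=2, sort_keys=True) + "\n"
        ),
    )


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Any stage failure aborts with a stage-named diagnostic and removes the
    partial outputs already written to the output directory.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    bundle = ReportBundle(outdir=cfg.outdir)
    log_path = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        reliability = None
        if cfg.input_kind == "items":
            cb = (
                scales_mod.read_codebook(cfg.codebook)
                if cfg.codebook
                else scales_mod.default_codebook()
            )
            raw = scales_mod.read_responses(cfg.input, cb)
            complete, retention = scales_mod.filter_complete(raw)
            scores = scales_mod.score_nodes(complete)
            if complete.n >= 2:
                reliability = {}
                for scale in ("GAD-7", "PHQ-9"):
                    cols = [it.item_id for it in cb.by_scale(scale)]
                    res = scales_mod.cronbach_alpha(
                        complete.values[cols].to_numpy(), scale=scale
                    )
                    reliability[scale] = {"alpha": res.alpha, "k": res.k}
        else:
            scores, retention = read_scores(cfg.input)
        if scores.n == 0:
            raise ValidationError("no complete questionnaires after filtering")
        logger.info(
            "ingest: %d submitted, %d valid (%.2f%%) [%.2fs]",
            retention.n_submitted, retention.n_valid, retention.percent_valid,
            time.perf_counter() - t0,
        )

        stage = "descriptives"
        desc = scales_mod.descriptives(scores)

        stage = "estimate"
        t0 = time.perf_counter()
        net, path = network_mod.ebic_glasso(
            scores,
            gamma=cfg.gamma,
            method=cfg.method,
            n_lambda=cfg.n_lambda,
            min_ratio=cfg.min_ratio,
        )
        logger.info(
            "estimate: %d edges at lambda=%.4g [%.2fs]",
            network_mod.n_edges(net.W), net.provenance["lambda_selected"],
            time.perf_counter() - t0,
        )

        stage = "bridge"
        bei = bridge_mod.bridge_expected_influence(net)
        cross = bridge_mod.cross_community_edges(net)
        desc_bei = desc.merge(bei[["node", "bei"]], on="node")

        stage = "edge_bootstrap"
        t0 = time.perf_counter()
        boot = robust_mod.bootstrap_edges(scores, cfg.bootstrap_config("edge_bootstrap"))
        edge_labels, edge_reps = boot.edge_replicates()
        diff_edges = robust_mod.difference_test(edge_reps, edge_labels, alpha=cfg.alpha)
        bei_reps = robust_mod.bei_replicates(boot, net.community)
        diff_bei = robust_mod.difference_test(bei_reps, list(net.node_ids), alpha=cfg.alpha)
        logger.info("edge_bootstrap: B=%d [%.2fs]", cfg.B, time.perf_counter() - t0)

        stage = "case_drop"
        t0 = time.perf_counter()
        drop = robust_mod.case_drop_bootstrap(
            scores, cfg.bootstrap_config("case_drop"), proportions=cfg.proportions
        )
        try:
            stability = robust_mod.cs_coefficient(drop)
        except ValidationError:
            # constant BEI (no bridges detected): stability is undefined
            stability = None
        logger.info(
            "case_drop: CS=%s over %d proportions [%.2fs]",
            "NA" if stability is None else f"{stability.cs:.2f}",
            len(drop.proportions), time.perf_counter() - t0,
        )

        stage = "layout"
        layout = fr_layout(net, seed=cfg.seed + STAGE_SEEDS["layout"])

        stage = "write"
        out = cfg.outdir
        files = bundle.files
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "n_submitted": retention.n_submitted,
                        "n_valid": retention.n_valid,
                        "percent_valid": bridge_mod.round_half_up(retention.percent_valid),
                    }
                ]
            ),
            files.setdefault("retention", os.path.join(out, "retention.csv")),
        )
        _write_csv(desc_bei, files.setdefault("descriptives_bei", os.path.join(out, "descriptives_bei.csv")))
        _write_csv(
            pd.DataFrame({"node": list(net.node_ids),
                          "community": [net.community[n] for n in net.node_ids]}),
            files.setdefault("nodes", os.path.join(out, "nodes.csv")),
        )
        _write_csv(net.edge_list(), files.setdefault("edges", os.path.join(out, "edges.csv")))
        Wdf = pd.DataFrame(net.W, columns=list(net.node_ids))
        Wdf.insert(0, "node", list(net.node_ids))
        _write_csv(Wdf, files.setdefault("network_matrix", os.path.join(out, "network_matrix.csv")))
        _write_csv(path.table, files.setdefault("ebic_path", os.path.join(out, "ebic_path.csv")))
        _write_json(
            {
                "n_nonzero_edges": cross.n_nonzero_edges,
                "n_bridge_edges": cross.n_bridge_edges,
                "percent_bridge": cross.percent_bridge,
            },
            files.setdefault("cross_edges", os.path.join(out, "cross_edges.json")),
        )
        _write_csv(cross.bridge_edges, files.setdefault("bridge_edges", os.path.join(out, "bridge_edges.csv")))
        _write_csv(boot.table(), files.setdefault("edge_ci", os.path.join(out, "edge_ci.csv")))
        _write_csv(diff_edges.long_table(), files.setdefault("difference_edges", os.path.join(out, "difference_edges.csv")))
        _write_csv(diff_bei.long_table(), files.setdefault("difference_bei", os.path.join(out, "difference_bei.csv")))
        _write_json(
            {
                "cs": None if stability is None else stability.cs,
                "r_crit": None if stability is None else stability.r_crit,
                "certainty": None if stability is None else stability.certainty,
                "proportions": list(drop.proportions),
                "pass_fraction": {}
                if stability is None
                else {str(k): v for k, v in stability.pass_fraction.items()},
            },
            files.setdefault("stability", os.path.join(out, "stability.json")),
        )
        if reliability is not None:
            _write_json(
                reliability,
                files.setdefault("reliability", os.path.join(out, "reliability.json")),
            )
        _write_csv(layout, files.setdefault("layout", os.path.join(out, "layout.csv")))
        try:
            pkg_version = _pkg_version("bridgenet")
        except Exception:
            pkg_version = "unknown"
        _write_json(
            {
                "package_version": pkg_version,
                "seed": cfg.seed,
                "stage_seeds": {k: cfg.seed + v for k, v in STAGE_SEEDS.items()},
                "input": os.path.basename(cfg.input),
                "input_kind": cfg.input_kind,
                "settings": {
                    "method": cfg.method,
                    "gamma": cfg.gamma,
                    "n_lambda": cfg.n_lambda,
                    "min_ratio": cfg.min_ratio,
                    "B": cfg.B,
                    "alpha": cfg.alpha,
                    "proportions": list(cfg.proportions),
                },
                "estimation": net.provenance,
            },
            files.setdefault("provenance", os.path.join(out, "provenance.json")),
        )
        return bundle
    except Exception as exc:
        for f in bundle.files.values():
            if os.path.exists(f):
                os.remove(f)
        if isinstance(exc, BridgenetError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise BridgenetError(f"[stage: {stage}] {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
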