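"""Readers and writers for the graph and results formats.

Graph bundles are a node-table CSV (columns ``node_id, class, role`` with
role in {source, target, distractor, none}) plus an edge-list CSV
(columns ``src, dst, weight``); comma- or tab-delimited, auto-detected,
header row required.  Node order in the file fixes the matrix index order.
Duplicate edges are summed with a logged warning; edges referencing
undeclared nodes are rejected with their line number.

Results are persisted as a long-format CSV (floats at 17 significant
digits) with a JSON config sidecar, an inference JSON, and a log file;
every artifact embeds the base seed, a config hash and the graph
fingerprint so identical inputs rewrite identical artifacts.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError, require
from .graph import ConnectomeGraph, RoleAssignment
from .sweep import SweepTable

__all__ = ["BenchmarkBundle", "read_benchmark_graph", "write_benchmark_graph", "write_results"]

logger = logging.getLogger(__name__)

_ROLES = {"source", "target", "distractor", "none"}


@dataclass
class BenchmarkBundle:
    """A graph plus roles plus provenance (paths and content hashes)."""

    graph: ConnectomeGraph
    roles: RoleAssignment
    source: str = ""
    file_hashes: dict | None = None


def _sniff_read(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8")
    data_lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    require(len(data_lines) >= 1, f"{path}: empty file")
    delim = csv.Sniffer().sniff(data_lines[0], delimiters=",\t").delimiter
    return pd.read_csv(path, sep=delim, comment="#", dtype=str)


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_benchmark_graph(node_path: str | Path, edge_path: str | Path, directed: bool = True) -> BenchmarkBundle:
    """Load and validate a node-table + edge-list bundle."""
    nodes = _sniff_read(node_path)
    edges = _sniff_read(edge_path)
    for col in ("node_id", "class", "role"):
        require(col in nodes.columns, f"{node_path}: missing column {col!r}")
    for col in ("src", "dst", "weight"):
        require(col in edges.columns, f"{edge_path}: missing column {col!r}")

    ids = nodes["node_id"].tolist()
    dup = nodes["node_id"][nodes["node_id"].duplicated()].tolist()
    require(not dup, f"{node_path}: duplicate node ids {sorted(set(dup))}")
    bad_roles = [
        f"line {i + 2}: {r!r}"
        for i, r in enumerate(nodes["role"])
        if r not in _ROLES
    ]
    require(not bad_roles, f"{node_path}: unknown role strings ({'; '.join(bad_roles)})")

    index = {n: i for i, n in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    n_dup = 0
    for line_no, row in enumerate(edges.itertuples(index=False), start=2):
        for endpoint in (row.src, row.dst):
            if endpoint not in index:
                raise ValidationError(
                    f"{edge_path} line {line_no}: edge endpoint {endpoint!r} is not a declared node"
                )
        try:
            weight = float(row.weight)
        except ValueError:
            raise ValidationError(f"{edge_path} line {line_no}: non-numeric weight {row.weight!r}")
        require(weight >= 0, f"{edge_path} line {line_no}: negative weight")
        i, j = index[row.src], index[row.dst]
        key = (i, j) if directed else (min(i, j), max(i, j))
        if key in seen:
            n_dup += 1
        seen.add(key)
        w[i, j] += weight
        if not directed and i != j:
            w[j, i] += weight
    if n_dup:
        logger.warning("%s: %d duplicate edges summed", edge_path, n_dup)

    roles = RoleAssignment(
        source_nodes=tuple(nodes.loc[nodes["role"] == "source", "node_id"]),
        target_sinks=tuple(nodes.loc[nodes["role"] == "target", "node_id"]),
        distractor_sinks=tuple(nodes.loc[nodes["role"] == "distractor", "node_id"]),
    )
    graph = ConnectomeGraph(tuple(ids), tuple(nodes["class"]), w, directed=directed)
    roles.validate_against(graph)
    return BenchmarkBundle(
        graph=graph,
        roles=roles,
        source=f"{node_path};{edge_path}",
        file_hashes={"nodes": _file_hash(node_path), "edges": _file_hash(edge_path)},
    )


def write_benchmark_graph(
    graph: ConnectomeGraph,
    roles: RoleAssignment,
    node_path: str | Path,
    edge_path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write a bundle in the node/edge CSV schema, with '#' provenance header lines."""
    role_of = {}
    for s in roles.source_nodes:
        role_of[s] = "source"
    for t in roles.target_sinks:
        role_of[t] = "target"
    for d in roles.distractor_sinks:
        role_of[d] = "distractor"

    header = ""
    if provenance:
        header = "".join(f"# {k}: {v}\n" for k, v in sorted(provenance.items()))

    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("node_id,class,role\n")
        for nid, cls in zip(graph.node_ids, graph.node_classes):
            fh.write(f"{nid},{cls},{role_of.get(nid, 'none')}\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("src,dst,weight\n")
        for u, v, w in graph.edge_list():
            fh.write(f"{u},{v},{float(w)!r}\n")


def write_trace_csv(trace, path: str | Path, node_ids=None, provenance: dict | None = None) -> None:
    """Long CSV of a propagation trace: time, node_or_sink_id, population."""
    n_nodes = trace.site_populations.shape[1]
    n_sinks = trace.sink_populations.shape[1]
    labels = list(node_ids) if node_ids is not None else [f"node{i}" for i in range(n_nodes)]
    labels += [f"sink{s}" for s in range(n_sinks)]
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.writelines(f"# {k}: {v}\n" for k, v in sorted(provenance.items()))
        fh.write("time,node_or_sink_id,population\n")
        both = np.hstack([trace.site_populations, trace.sink_populations])
        for t, row in zip(trace.times, both):
            for label, p in zip(labels, row):
                fh.write(f"{float(t)!r},{label},{float(p)!r}\n")


def _config_dict(table: SweepTable) -> dict:
    cfg = table.config
    return {
        "kappa_grid": list(cfg.kappa_grid),
        "epsilon_grid": list(cfg.epsilon_grid),
        "variants": list(cfg.variants),
        "n_trials": cfg.n_trials,
        "n_surrogates": cfg.n_surrogates,
        "engine": cfg.engine,
        "base_seed": cfg.base_seed,
        "substrate": cfg.substrate,
        "t_env": cfg.t_env,
        "coherent_init": cfg.coherent_init,
        "run_params": {
            "eta_sink": cfg.run_params.eta_sink,
            "dt": cfg.run_params.dt,
            "t_end": cfg.run_params.t_end,
        },
        "metrics": {
            "delta": cfg.metrics.delta,
            "lam": cfg.metrics.lam,
            "chi": cfg.metrics.chi,
            "s_thr": cfg.metrics.s_thr,
            "pt_min": cfg.metrics.pt_min,
        },
        "graph_fingerprint": table.graph_fingerprint,
    }


def write_results(table: SweepTable, report, out_dir: str | Path) -> dict[str, Path]:
    """Persist a sweep (results CSV + config JSON + inference JSON + log).

    ``report`` may be None when no inference was run.  Returns the paths
    written.  Re-running with identical inputs overwrites identically.
    """
    require(len(table.records) > 0, "refusing to write an empty results table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config = _config_dict(table)
    config_text = json.dumps(config, indent=2, sort_keys=True)
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()[:16]

    paths = {
        "results": out / "results.csv",
        "config": out / "config.json",
        "inference": out / "inference.json",
        "log": out / "run.log",
    }
    header = (
        f"# base_seed: {table.config.base_seed}\n"
        f"# config_hash: {config_hash}\n"
        f"# graph_fingerprint: {table.graph_fingerprint}\n"
    )
    with open(paths["results"], "w", encoding="utf-8") as fh:
        fh.write(header)
        table.records.to_csv(fh, index=False, float_format="%.17g")
    paths["config"].write_text(config_text + "\n", encoding="utf-8")
    if report is not None:
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        payload = dict(payload)
        payload["config_hash"] = config_hash
        payload["graph_fingerprint"] = table.graph_fingerprint
        paths["inference"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        paths.pop("inference")
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write(header)
        fh.write(f"records: {len(table.records)}\nfailed: {table.n_failed}\n")
    return paths
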