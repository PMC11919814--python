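"""Lipid-class reaction networks and pathway-activity scoring.

Lipid metabolism interconverts classes along well-known enzymatic routes
(e.g. PA -> DAG -> TAG in glycerolipid synthesis, PE -> PC via the
methylation pathway, Cer <-> SM in sphingolipid turnover).  Given a
two-group experiment, each directed class-conversion edge gets a
direction-aware activity score: per sample we take the log2 ratio of
product-class to substrate-class total abundance, and the edge z-score is
the Welch-standardized difference of that ratio between case and control.
A positive z means the conversion's product gains on its substrate in
cases — the edge looks activated; negative means repressed.  The score is
scale-free (ratios cancel global intensity) and exactly antisymmetric
under swapping the group labels.

Paths chain edges: a path's score is the mean of its member edge
z-scores, and paths whose absolute score exceeds a highlight threshold
(default 1.5) are flagged for display.

The bundled topology is a curated convenience covering the glycerolipid,
glycerophospholipid and sphingolipid backbones; it is replaceable by any
user edge list over registered classes and is not claimed to be complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .characterization import CharacteristicRecord, aggregate_by_characteristic
from .nomenclature import ClassRegistry, default_registry
from .profiling import Experiment

__all__ = [
    "ReactionGraph",
    "EdgeActivity",
    "PathScore",
    "builtin_reaction_graph",
    "read_edge_list",
    "edge_activity",
    "pathway_activity",
    "to_graphml",
]

#: z sentinel for degenerate (zero-variance) ratio comparisons
_DEGENERATE_Z = 1e6

# Curated class-conversion edges (substrate, product, reaction label).
_BUILTIN_EDGES = [
    ("PA", "DAG", "PAP"),
    ("DAG", "PA", "DGK"),
    ("DAG", "TAG", "DGAT"),
    ("TAG", "DAG", "ATGL"),
    ("DAG", "MG", "DAGL"),
    ("DAG", "PC", "CPT"),
    ("DAG", "PE", "EPT"),
    ("PE", "PC", "PEMT"),
    ("PC", "PE", "base_exchange"),
    ("PE", "PS", "PSS2"),
    ("PS", "PE", "PSD"),
    ("PC", "PS", "PSS1"),
    ("PC", "PA", "PLD"),
    ("PC", "LPC", "PLA2"),
    ("LPC", "PC", "LPCAT"),
    ("PE", "LPE", "PLA2"),
    ("LPE", "PE", "LPEAT"),
    ("PA", "PI", "CDS_PIS"),
    ("PA", "PG", "PGS"),
    ("Cer", "SM", "SMS"),
    ("SM", "Cer", "SMase"),
    ("Cer", "HexCer", "UGCG"),
    ("HexCer", "Cer", "GBA"),
]


@dataclass
class ReactionGraph:
    """Directed lipid-class conversion graph."""

    nodes: frozenset[str]
    edges: list[tuple[str, str, str]]  # (substrate, product, label)

    def __post_init__(self):
        for sub, prod, _ in self.edges:
            if sub == prod:
                raise ValueError(f"self-loop {sub}->{prod} not allowed")
            if sub not in self.nodes or prod not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {sub}->{prod}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for sub, prod, label in self.edges:
            g.add_edge(sub, prod, reaction=label)
        return g


@dataclass
class EdgeActivity:
    edge: tuple[str, str]
    reaction: str
    log_ratios: pd.Series  # per-sample log2(product total / substrate total)
    z_score: float
    p_value: float
    call: str  # "active" | "repressed" | "neutral"
    note: str = ""


@dataclass
class PathScore:
    path: tuple[str, ...]
    score: float
    highlighted: bool


def builtin_reaction_graph() -> ReactionGraph:
    """The bundled curated class-conversion graph."""
    nodes = frozenset(n for e in _BUILTIN_EDGES for n in e[:2])
    return ReactionGraph(nodes=nodes, edges=list(_BUILTIN_EDGES))


def read_edge_list(path: str | Path, registry: ClassRegistry | None = None) -> ReactionGraph:
    """Load a user reaction graph from TSV (substrate, product, label).

    Endpoints must be registered class codes.
    """
    if registry is None:
        registry = default_registry()
    table = pd.read_csv(path, sep="\t")
    required = {"substrate", "product"}
    if not required <= set(table.columns):
        raise ValueError("edge list needs columns 'substrate' and 'product'")
    edges = []
    for _, row in table.iterrows():
        sub, prod = str(row["substrate"]).strip(), str(row["product"]).strip()
        label = str(row.get("label", "")) if "label" in table.columns else ""
        for cls in (sub, prod):
            if registry.resolve(cls) is None:
                raise ValueError(f"edge endpoint {cls!r} is not a registered class")
        edges.append((registry.resolve(sub), registry.resolve(prod), label))
    nodes = frozenset(n for e in edges for n in e[:2])
    return ReactionGraph(nodes=nodes, edges=edges)


def edge_activity(
    exp: Experiment,
    records: list[CharacteristicRecord],
    graph: ReactionGraph | None = None,
    threshold: float = 1.96,
) -> list[EdgeActivity]:
    """Score every scorable edge of the reaction graph.

    Edges whose substrate or product class has no annotated species, or a
    zero class total in any sample, are skipped with a log entry in the
    experiment's processing log.
    """
    if graph is None:
        graph = builtin_reaction_graph()
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    class_matrix = aggregate_by_characteristic(exp, records, "class").values
    case_cols = exp.samples_in("case")
    ctrl_cols = exp.samples_in("control")
    out: list[EdgeActivity] = []
    for sub, prod, label in graph.edges:
        skip = None
        if sub not in class_matrix.index or prod not in class_matrix.index:
            skip = "class not annotated in experiment"
        else:
            sub_tot = class_matrix.loc[sub]
            prod_tot = class_matrix.loc[prod]
            if (sub_tot <= 0).any() or (prod_tot <= 0).any():
                skip = "zero class total in at least one sample"
        if skip:
            exp.processing_log.append(f"edge_activity: skipped {sub}->{prod} ({skip})")
            continue
        r = np.log2(prod_tot) - np.log2(sub_tot)
        z, p, note = _welch_z(r[case_cols].to_numpy(), r[ctrl_cols].to_numpy())
        call = "active" if z > threshold else "repressed" if z < -threshold else "neutral"
        out.append(
            EdgeActivity(
                edge=(sub, prod),
                reaction=label,
                log_ratios=r,
                z_score=z,
                p_value=p,
                call=call,
                note=note,
            )
        )
    return out


def _welch_z(case: np.ndarray, ctrl: np.ndarray) -> tuple[float, float, str]:
    diff = case.mean() - ctrl.mean()
    se2 = case.var(ddof=1) / case.size + ctrl.var(ddof=1) / ctrl.size
    if se2 == 0:
        if diff == 0:
            return 0.0, 1.0, "zero_variance"
        return float(np.copysign(_DEGENERATE_Z, diff)), 0.0, "zero_variance_sentinel"
    z = float(diff / np.sqrt(se2))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p, ""


def pathway_activity(
    activities: list[EdgeActivity],
    graph: ReactionGraph | None = None,
    max_path_len: int = 4,
    highlight_threshold: float = 1.5,
) -> list[PathScore]:
    """Score all simple paths (1..max_path_len edges) over scored edges.

    A path's score is the mean z-score of its member edges; paths with
    |score| > highlight_threshold are flagged.  Results are sorted by
    |score| descending, ties broken lexicographically on the node list.
    """
    if graph is None:
        graph = builtin_reaction_graph()
    zmap = {a.edge: a.z_score for a in activities}
    g = nx.DiGraph()
    g.add_edges_from(zmap)  # only edges with computed activity
    scores: list[PathScore] = []
    for source in sorted(g.nodes):
        for target in sorted(g.nodes):
            if source == target:
                continue
            for path in nx.all_simple_paths(g, source, target, cutoff=max_path_len):
                zs = [zmap[(path[i], path[i + 1])] for i in range(len(path) - 1)]
                score = float(np.mean(zs))
                scores.append(
                    PathScore(
                        path=tuple(path),
                        score=score,
                        highlighted=abs(score) > highlight_threshold,
                    )
                )
    scores.sort(key=lambda ps: (-abs(ps.score), ps.path))
    return scores


def to_graphml(
    activities: list[EdgeActivity],
    graph: ReactionGraph,
    path: str | Path,
    highlight_threshold: float = 1.5,
) -> None:
    """Export the scored network as GraphML with z/call/highlight attributes."""
    g = graph.to_networkx()
    scored = {a.edge: a for a in activities}
    for u, v in list(g.edges):
        a = scored.get((u, v))
        if a is None:
            g.edges[u, v].update(scored_flag=False)
            continue
        g.edges[u, v].update(
            scored_flag=True,
            z_score=float(a.z_score),
            p_value=float(a.p_value),
            call=a.call,
            highlighted=bool(abs(a.z_score) > highlight_threshold),
        )
    nx.write_graphml(g, path)
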