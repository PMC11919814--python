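"""End-to-end analysis pipeline and run configuration.

One call runs the full workflow — recognize lipid names, characterize,
preprocess, species- and class-level differential testing, the
dual-characteristic grid, ORA + LSEA enrichment, reaction-network
scoring, and sample profiling — and writes every result as TSV plus a
JSON manifest recording versions, parameters, seeds, the recognition
report and the processing log.  Identical configuration and seed produce
byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterization import aggregate_by_characteristic, characterize
from .differential import (
    differential_characteristic,
    differential_species,
    dual_characteristic_grid,
    results_to_frame,
    top_k_table,
)
from .enrichment import derive_lipid_sets, enrichment_to_frame, lsea, ora, read_gmt
from .io import read_abundance_table, write_tsv
from .network import builtin_reaction_graph, edge_activity, pathway_activity, read_edge_list, to_graphml
from .nomenclature import recognize_batch
from .profiling import PreprocessOptions, preprocess, reduce_dimensions, sample_correlation

logger = logging.getLogger("lipidomix")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one seed, one output directory)."""

    abundance_path: str
    metadata_path: str
    output_dir: str
    group_col: str = "group"
    case_label: str | None = None
    test: str = "welch_t"
    alpha: float = 0.05
    fc_cut: float = 1.0
    max_missing_fraction: float = 0.5
    normalization: str = "none"
    dual_class: str = "TAG"
    set_source: str = "class"
    set_file: str | None = None
    lsea_weight_p: float = 1.0
    n_perm: int = 1000
    min_set_size: int = 3
    graph_path: str | None = None
    call_threshold: float = 1.96
    highlight_threshold: float = 1.5
    max_path_len: int = 4
    embedding_method: str = "pca"
    seed: int = 0
    top_k: int = 10

    def validate(self) -> None:
        for p in (self.abundance_path, self.metadata_path):
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if self.set_file and not Path(self.set_file).exists():
            raise ValueError(f"set file does not exist: {self.set_file}")
        if self.graph_path and not Path(self.graph_path).exists():
            raise ValueError(f"graph path does not exist: {self.graph_path}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_cut < 0:
            raise ValueError("fc_cut must be >= 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.highlight_threshold <= 0 or self.call_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the output manifest (also written).

    Any stage failure raises with a stage-named message; partial outputs
    of completed stages remain on disk.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lipidomix",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": {},
    }
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4)
    seeds = {
        "embedding": int(rng_seeds[0] % (2**31 - 1)),
        "lsea": int(rng_seeds[1] % (2**31 - 1)),
    }
    manifest["derived_seeds"] = seeds

    def record(key: str, path: Path):
        manifest["outputs"][key] = str(path.relative_to(outdir))

    try:
        _stage("read")
        raw, metadata = read_abundance_table(
            config.abundance_path, config.metadata_path, group_col=config.group_col
        )
    except Exception as err:
        raise RuntimeError(f"[read] {err}") from err

    try:
        _stage("recognize")
        parsed, report = recognize_batch(list(raw.index))
        manifest["recognition_report"] = report.to_dict()
        records = characterize(parsed)
        by_raw = {p.raw_name: p.canonical_name for p in parsed}
        recognized = raw.loc[[n for n in raw.index if n in by_raw]]
        recognized.index = pd.Index(
            [by_raw[n] for n in recognized.index], name="lipid"
        )
        if recognized.index.duplicated().any():
            recognized = recognized.groupby(level=0).sum(min_count=1)
            logger.warning("merged duplicate canonical species by summation")
        parsed_frame = pd.DataFrame(
            [
                {
                    "raw_name": p.raw_name,
                    "canonical_name": p.canonical_name,
                    "lipid_class": p.lipid_class,
                    "category": p.category,
                    "ether_type": p.ether_type,
                    "total_carbons": p.total_carbons,
                    "total_double_bonds": p.total_double_bonds,
                    "parse_level": p.parse_level,
                }
                for p in parsed
            ]
        )
        write_tsv(parsed_frame, outdir / "parsed.tsv", index=False)
        record("parsed", outdir / "parsed.tsv")
    except Exception as err:
        raise RuntimeError(f"[recognize] {err}") from err

    try:
        _stage("preprocess")
        options = PreprocessOptions(
            max_missing_fraction=config.max_missing_fraction,
            normalization=config.normalization,
        )
        exp = preprocess(
            recognized,
            metadata,
            options=options,
            group_col=config.group_col,
            case_label=config.case_label,
        )
        write_tsv(exp.log2, outdir / "processed_log2.tsv")
        record("processed_log2", outdir / "processed_log2.tsv")
        records = [r for r in records if r.canonical_name in exp.abundance.index]
    except Exception as err:
        raise RuntimeError(f"[preprocess] {err}") from err

    try:
        _stage("differential")
        de = differential_species(
            exp, test=config.test, alpha=config.alpha, fc_cut=config.fc_cut
        )
        de_frame = results_to_frame(de)
        write_tsv(de_frame, outdir / "de_species.tsv", index=False)
        record("de_species", outdir / "de_species.tsv")

        class_matrix = aggregate_by_characteristic(exp, records, "class")
        de_class = differential_characteristic(
            exp, class_matrix, test=config.test, alpha=config.alpha, fc_cut=config.fc_cut
        )
        write_tsv(results_to_frame(de_class), outdir / "de_class.tsv", index=False)
        record("de_class", outdir / "de_class.tsv")

        ups, downs = top_k_table(de, k=config.top_k)
        top_frame = pd.concat(
            [results_to_frame(ups).assign(side="up"),
             results_to_frame(downs).assign(side="down")],
            ignore_index=True,
        )
        write_tsv(top_frame, outdir / "top_k.tsv", index=False)
        record("top_k", outdir / "top_k.tsv")

        if any(r.lipid_class == config.dual_class for r in records):
            grid = dual_characteristic_grid(
                exp, records, config.dual_class, test=config.test, alpha=config.alpha
            )
            write_tsv(
                grid.to_long_frame(),
                outdir / f"dual_grid_{config.dual_class}.tsv",
                index=False,
            )
            record("dual_grid", outdir / f"dual_grid_{config.dual_class}.tsv")
        else:
            logger.warning("dual-grid class %s absent; grid skipped", config.dual_class)
    except Exception as err:
        raise RuntimeError(f"[differential] {err}") from err

    try:
        _stage("enrichment")
        if config.set_file:
            sets = read_gmt(config.set_file)
        else:
            sets = derive_lipid_sets(records, by=config.set_source)
        ora_frames = []
        for direction in ("up", "down"):
            res = ora(de, sets, direction=direction, alpha=config.alpha, fc_cut=config.fc_cut)
            ora_frames.append(enrichment_to_frame(res))
        write_tsv(pd.concat(ora_frames, ignore_index=True), outdir / "ora.tsv", index=False)
        record("ora", outdir / "ora.tsv")

        ranked_frame = de_frame.sort_values(
            ["statistic", "feature"], ascending=[False, True]
        )
        ranked = list(zip(ranked_frame["feature"], ranked_frame["statistic"]))
        lsea_res = lsea(
            ranked,
            sets,
            weight_p=config.lsea_weight_p,
            n_perm=config.n_perm,
            seed=seeds["lsea"],
            min_size=config.min_set_size,
        )
        write_tsv(enrichment_to_frame(lsea_res), outdir / "lsea.tsv", index=False)
        record("lsea", outdir / "lsea.tsv")
    except Exception as err:
        raise RuntimeError(f"[enrichment] {err}") from err

    try:
        _stage("network")
        graph = (
            read_edge_list(config.graph_path)
            if config.graph_path
            else builtin_reaction_graph()
        )
        activities = edge_activity(exp, records, graph, threshold=config.call_threshold)
        edge_frame = pd.DataFrame(
            [
                {
                    "substrate": a.edge[0],
                    "product": a.edge[1],
                    "reaction": a.reaction,
                    "z_score": a.z_score,
                    "p_value": a.p_value,
                    "call": a.call,
                }
                for a in activities
            ]
        )
        write_tsv(edge_frame, outdir / "network_edges.tsv", index=False)
        record("network_edges", outdir / "network_edges.tsv")
        paths = pathway_activity(
            activities,
            graph,
            max_path_len=config.max_path_len,
            highlight_threshold=config.highlight_threshold,
        )
        path_frame = pd.DataFrame(
            [
                {"path": "->".join(p.path), "score": p.score, "highlighted": p.highlighted}
                for p in paths
            ]
        )
        write_tsv(path_frame, outdir / "network_paths.tsv", index=False)
        record("network_paths", outdir / "network_paths.tsv")
        to_graphml(activities, graph, outdir / "network.graphml",
                   highlight_threshold=config.highlight_threshold)
        record("network_graphml", outdir / "network.graphml")
    except Exception as err:
        raise RuntimeError(f"[network] {err}") from err

    try:
        _stage("profiling")
        emb = reduce_dimensions(
            exp, method=config.embedding_method, k=2, seed=seeds["embedding"]
        )
        coords = emb.coordinates.copy()
        coords.insert(0, "group", [exp.group_of[s] for s in coords.index])
        write_tsv(coords, outdir / f"embedding_{config.embedding_method}.tsv")
        record("embedding", outdir / f"embedding_{config.embedding_method}.tsv")
        corr, order = sample_correlation(exp)
        write_tsv(corr, outdir / "sample_correlation.tsv")
        record("sample_correlation", outdir / "sample_correlation.tsv")
        manifest["correlation_leaf_order"] = order
        if emb.explained_variance_ratio is not None:
            manifest["explained_variance_ratio"] = emb.explained_variance_ratio
    except Exception as err:
        raise RuntimeError(f"[profiling] {err}") from err

    manifest["processing_log"] = list(exp.processing_log)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
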