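"""End-to-end orchestration: expression -> DE -> biclustering -> per-time-point
Bayesian networks -> statistics -> miRNA prioritisation.

Each stage draws randomness from its own stream derived from the master seed,
so stages are individually reproducible regardless of execution order. Every
stage's output is persisted under the output directory and a manifest records
the configuration, derived seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesnet import (
    LearnConfig,
    StrengthNetwork,
    bootstrap_strength,
    classify_edges,
    quartile_filter,
)
from .bicluster import (
    Bicluster,
    biclusters_by_timepoint,
    build_response_graph,
    filter_overlap,
    find_biclusters,
    merge_per_timepoint,
    response_profile,
    write_modules,
)
from .errors import ConfigurationError, EmptyModelError
from .io import (
    read_expression_tsv,
    read_id_list,
    read_mature_fasta,
    read_orthology_map,
    read_pair_list,
    read_prediction_table,
    write_expression_tsv,
    write_graph,
    write_scenario_edges,
)
from .netstats import (
    beta_index,
    degree_stats,
    edge_sets,
    membership_matrix,
    overlap_counts,
    pairwise_intersections,
)
from .preprocess import (
    de_entities,
    de_table_for_dataset,
    read_de_table,
    select_model_variables,
    write_de_table,
)
from .prioritize import (
    annotate_resources,
    build_mirna_records,
    clean_symbols,
    confidence_matrix,
    extract_mti,
    normalized_degree_heat,
    recurrence_tables,
    shortlist_cascade,
)
from .resources import ResourceBundle, generate_resources
from .simulate import (
    DEFAULT_TIMEPOINTS,
    ExpressionDataset,
    generate_scenario,
    simulate_expression,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "de", "bicluster", "learn", "stats", "prioritize")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-loadable.

    When ``expression_path`` is unset a synthetic scenario is generated with
    the ``synthetic_*`` parameters. Thresholds carry the analysis defaults:
    BH alpha 0.05, 10% bicluster overlap, 1000 bootstrap replicates, highest
    quartile (0.75) strength filter, seed region nt 2-8. ``max_parents``
    (default 3) regularises structure learning in the 15-sample design, where
    unconstrained per-node fits would exhaust the residual degrees of freedom.
    """

    output_dir: str = "temponet_run"
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    alpha: float = 0.05
    bicluster_overlap: float = 0.10
    response_threshold: float = 1.0
    B: int = 1000
    quartile: float = 0.75
    max_parents: int | None = 3
    rng_seed: int = 0
    log_level: str = "INFO"

    expression_path: str | None = None
    de_table_path: str | None = None
    orthology_path: str | None = None
    rat_fasta_path: str | None = None
    human_fasta_path: str | None = None
    prediction_path: str | None = None
    validated_path: str | None = None
    iclip_path: str | None = None
    human_de_mirna_path: str | None = None
    human_de_mrna_path: str | None = None

    synthetic_n_mirna: int = 20
    synthetic_n_mrna: int = 60
    synthetic_edge_density: float = 0.02
    synthetic_frac_repressive: float = 0.8
    synthetic_frac_timepoint_specific: float = 0.5

    def validate(self) -> None:
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigurationError("time-point labels must be unique")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 <= self.bicluster_overlap <= 1:
            raise ConfigurationError("bicluster_overlap must be in [0, 1]")
        if not 0 < self.quartile < 1:
            raise ConfigurationError("quartile must be in (0, 1)")
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")
        for name in (
            "expression_path",
            "de_table_path",
            "orthology_path",
            "rat_fasta_path",
            "human_fasta_path",
            "prediction_path",
            "validated_path",
            "iclip_path",
            "human_de_mirna_path",
            "human_de_mrna_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.rng_seed).spawn(len(_STAGES))
        return {
            stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(_STAGES, children)
        }


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's principal outputs."""

    dataset: ExpressionDataset
    de: pd.DataFrame
    modules: list[Bicluster]
    biclustered: dict[str, set[str]]
    networks: dict[str, StrengthNetwork]
    node_stats: pd.DataFrame
    edge_type_counts: dict[str, dict[str, int]]
    beta_indices: dict[str, float]
    mti: pd.DataFrame
    cascade_counts: dict[str, int]
    records: pd.DataFrame
    annotated: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _load_resources(config: PipelineConfig) -> ResourceBundle | None:
    if config.orthology_path is None:
        return None
    return ResourceBundle(
        orthology=read_orthology_map(config.orthology_path),
        rat_seqs=read_mature_fasta(config.rat_fasta_path) if config.rat_fasta_path else {},
        human_seqs=read_mature_fasta(config.human_fasta_path)
        if config.human_fasta_path
        else {},
        prediction=read_prediction_table(config.prediction_path)
        if config.prediction_path
        else pd.DataFrame(columns=["mirna", "mrna", "confidence"]),
        validated_pairs=read_pair_list(config.validated_path)
        if config.validated_path
        else set(),
        iclip_pairs=read_pair_list(config.iclip_path) if config.iclip_path else set(),
        human_de_mirnas=read_id_list(config.human_de_mirna_path)
        if config.human_de_mirna_path
        else set(),
        human_de_mrnas=read_id_list(config.human_de_mrna_path)
        if config.human_de_mrna_path
        else set(),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    # --- expression data -------------------------------------------------
    resources: ResourceBundle | None
    if config.expression_path is not None:
        dataset = read_expression_tsv(config.expression_path)
        resources = _load_resources(config)
    else:
        scenario = generate_scenario(
            config.synthetic_n_mirna,
            config.synthetic_n_mrna,
            config.synthetic_edge_density,
            config.synthetic_frac_repressive,
            config.synthetic_frac_timepoint_specific,
            seed=seeds["simulate"],
            timepoints=config.timepoints,
        )
        dataset = simulate_expression(scenario)
        write_scenario_edges(scenario, out / "ground_truth_edges.tsv")
        loaded = _load_resources(config)
        resources = loaded if loaded is not None else generate_resources(
            scenario, seed=seeds["simulate"]
        )
    write_expression_tsv(dataset, out / "expression.tsv")

    # --- differential expression -----------------------------------------
    if config.de_table_path is not None:
        de = read_de_table(config.de_table_path)
    else:
        de = de_table_for_dataset(dataset, alpha=config.alpha)
    write_de_table(de, out / "de_table.tsv")

    # --- biclustering ------------------------------------------------------
    de_mrnas = sorted(
        set(de.loc[(de["type"] == "mRNA") & de["de"], "entity"])
    )
    if de_mrnas:
        profile = response_profile(dataset, de_mrnas)
        profile = profile[[tp for tp in config.timepoints if tp in profile.columns]]
        graph = build_response_graph(profile, config.response_threshold)
        modules = filter_overlap(
            find_biclusters(graph, seed=seeds["bicluster"]),
            config.bicluster_overlap,
        )
    else:
        modules = []
    biclustered = biclusters_by_timepoint(modules, tuple(config.timepoints))
    write_modules(modules, out / "bicluster_modules.tsv")

    # --- structure learning ------------------------------------------------
    networks: dict[str, StrengthNetwork] = {}
    for i, tp in enumerate(config.timepoints):
        try:
            model_input = select_model_variables(de, biclustered, tp, dataset)
        except EmptyModelError:
            logger.warning("no model variables at %s; time-point skipped", tp)
            continue
        learn = LearnConfig(
            B=config.B,
            rng_seed=(seeds["learn"] + i) % (2**31),
            quartile=config.quartile,
            max_parents=config.max_parents,
        )
        net = quartile_filter(bootstrap_strength(model_input, learn), config.quartile)
        networks[tp] = net
        write_graph(net, out / f"network_{tp}.tsv", "tsv")
        write_graph(net, out / f"network_{tp}.graphml", "graphml")

    # --- network statistics ------------------------------------------------
    stats_frames = [degree_stats(net) for net in networks.values()]
    node_stats = (
        pd.concat(stats_frames, ignore_index=True)
        if stats_frames
        else pd.DataFrame(columns=["node", "type", "timepoint", "degree", "betweenness"])
    )
    node_stats.to_csv(out / "node_stats.tsv", sep="\t", index=False)
    edge_type_counts = {tp: classify_edges(net) for tp, net in networks.items()}
    beta_indices = {tp: beta_index(net) for tp, net in networks.items()}

    mirna_sets = {tp: de_entities(de, tp, "miRNA") for tp in config.timepoints}
    overlap_reports = {
        "de_mirna": overlap_counts(mirna_sets),
        "biclustered_mrna": overlap_counts(biclustered),
    }
    if networks:
        overlap_reports["edges"] = overlap_counts(edge_sets(networks))
        membership_matrix(edge_sets(networks)).to_csv(
            out / "edge_membership.tsv", sep="\t"
        )
    for name, report in overlap_reports.items():
        report.to_csv(out / f"overlap_{name}.tsv", sep="\t", index=False)
    pairwise = {
        name: pairwise_intersections(sets)
        for name, sets in [("de_mirna", mirna_sets), ("biclustered_mrna", biclustered)]
    }

    # --- prioritisation ----------------------------------------------------
    mti = extract_mti(networks)
    mti, removed = clean_symbols(mti)
    de_mirnas_all = set().union(*mirna_sets.values()) if mirna_sets else set()
    records = build_mirna_records(
        de_mirnas_all,
        mti,
        orthology=resources.orthology if resources else {},
        rat_seqs=resources.rat_seqs if resources else {},
        human_seqs=resources.human_seqs if resources else {},
        timepoints=tuple(config.timepoints),
    )
    cascade = shortlist_cascade(records)
    cascade.records.to_csv(out / "mirna_records.tsv", sep="\t", index=False)
    shortlist = set(
        cascade.records.loc[cascade.records["stage4_seed_conserved"], "mirna"]
    )
    table1, table2 = recurrence_tables(mti, shortlist, de)
    table1.to_csv(out / "recurrent_mtis.tsv", sep="\t", index=False)
    table2.to_csv(out / "recurrent_targets.tsv", sep="\t", index=False)
    heat, flags = normalized_degree_heat(
        cascade.records[cascade.records["stage4_seed_conserved"]]
    ) if shortlist else (pd.DataFrame(), pd.Series(dtype=bool))
    if not heat.empty:
        heat.to_csv(out / "degree_heat.tsv", sep="\t")

    annotated = None
    if resources is not None:
        annotated = annotate_resources(
            mti,
            prediction_table=resources.prediction,
            validated_pairs=resources.validated_pairs,
            iclip_pairs=resources.iclip_pairs,
            human_de_mirnas=resources.human_de_mirnas,
            human_de_mrnas=resources.human_de_mrnas,
            orthology=resources.orthology,
        )
        annotated.to_csv(out / "mti_annotated.tsv", sep="\t", index=False)
        cmatrix = confidence_matrix(annotated)
        if not cmatrix.empty:
            cmatrix.to_csv(out / "mti_confidence_matrix.tsv", sep="\t")

    # --- manifest ----------------------------------------------------------
    cfg_dict = asdict(config)
    cfg_dict["timepoints"] = list(config.timepoints)
    manifest = {
        "temponet_version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "timepoints_modelled": list(networks),
        "n_removed_symbols": len(removed),
        "cascade_counts": cascade.stage_counts,
        "beta_indices": beta_indices,
        "pairwise_overlaps": {
            name: frame.to_dict(orient="records") for name, frame in pairwise.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        dataset=dataset,
        de=de,
        modules=modules,
        biclustered=biclustered,
        networks=networks,
        node_stats=node_stats,
        edge_type_counts=edge_type_counts,
        beta_indices=beta_indices,
        mti=mti,
        cascade_counts=cascade.stage_counts,
        records=cascade.records,
        annotated=annotated,
        manifest=manifest,
    )
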