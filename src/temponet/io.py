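"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as TSV (first column entity id, header of sample
ids) with two metadata sidecars; mature miRNA sequences as miRBase-dialect
FASTA; inferred networks as edge-list TSV and, for external viewers, GraphML
or GEXF.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .bayesnet import StrengthNetwork
from .errors import ParseError
from .netstats import to_digraph
from .simulate import ExpressionDataset, RegulatoryScenario

GRAPH_FORMATS = ("graphml", "gexf", "tsv")


def _sidecar_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("")
    return Path(f"{stem}.entities.tsv"), Path(f"{stem}.samples.tsv")


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    """Write the value matrix plus entity/sample metadata sidecars."""
    dataset.values.to_csv(path, sep="\t", index_label="entity")
    ent_path, samp_path = _sidecar_paths(path)
    dataset.entity_meta.to_csv(ent_path, sep="\t", index=False)
    dataset.sample_meta.to_csv(samp_path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionDataset:
    """Read a matrix TSV (with sidecars when present) back into a dataset.

    Duplicate entity ids, ragged rows and non-numeric cells are parse errors.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        raise ParseError(f"{path}: duplicate entity ids {dupes}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    if values.isna().any().any():
        rows = values.index[values.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing/ragged values in rows {rows}")
    values.index.name = "entity"

    ent_path, samp_path = _sidecar_paths(path)
    if ent_path.exists():
        entity_meta = pd.read_csv(ent_path, sep="\t")
    else:
        entity_meta = pd.DataFrame({"entity": values.index, "type": "unknown"})
    if samp_path.exists():
        sample_meta = pd.read_csv(samp_path, sep="\t")
        sample_meta["is_control"] = sample_meta["is_control"].astype(bool)
    else:
        sample_meta = pd.DataFrame(
            {
                "sample": values.columns,
                "timepoint": values.columns,
                "replicate": range(1, len(values.columns) + 1),
                "is_control": False,
            }
        )
    dataset = ExpressionDataset(values, entity_meta, sample_meta)
    dataset.validate()
    return dataset


def write_scenario_edges(scenario: RegulatoryScenario, path) -> None:
    """Ground-truth edge list: source, target, coefficient, active time-points."""
    rows = [
        {
            "source": e.source,
            "target": e.target,
            "coefficient": e.coefficient,
            "active_timepoints": ",".join(
                sorted(e.active_timepoints, key=list(scenario.timepoints).index)
            ),
        }
        for e in scenario.edges
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "coefficient", "active_timepoints"]
    ).to_csv(path, sep="\t", index=False)


def read_mature_fasta(path) -> dict[str, str]:
    """miRBase-dialect FASTA -> {id: uppercased sequence}.

    The id is the header token before the first whitespace. Duplicate headers
    and empty sequences are errors; U/T are preserved as read.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {record.id!r}")
        if record.id in seqs:
            raise ParseError(f"{path}: duplicate header {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise ParseError(f"{path}: no FASTA records")
    return seqs


def write_graph(network: StrengthNetwork, path, fmt: str = "tsv") -> None:
    """Write a strength network as edge TSV, GraphML or GEXF.

    Graph formats carry node type/degree and edge strength attributes so the
    files load directly into external viewers.
    """
    fmt = fmt.lower()
    if fmt not in GRAPH_FORMATS:
        raise ParseError(f"unknown graph format {fmt!r}; expected one of {GRAPH_FORMATS}")
    if fmt == "tsv":
        network.arcs.to_csv(path, sep="\t", index=False)
        return
    G = to_digraph(network, retained_only=False)
    for n in G.nodes:
        G.nodes[n]["degree"] = G.in_degree(n) + G.out_degree(n)
    for _, row in network.arcs.iterrows():
        G.edges[row["source"], row["target"]]["retained"] = bool(row["retained"])
    if fmt == "graphml":
        nx.write_graphml(G, path)
    else:
        nx.write_gexf(G, path)


def read_network_tsv(path, timepoint: str = "", B: int = 0) -> StrengthNetwork:
    """Read an edge-list TSV written by :func:`write_graph` back into memory."""
    arcs = pd.read_csv(path, sep="\t")
    required = {"source", "source_type", "target", "target_type", "strength", "retained"}
    missing = required - set(arcs.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    arcs["retained"] = arcs["retained"].astype(bool)
    node_types = {}
    for _, row in arcs.iterrows():
        node_types[row["source"]] = row["source_type"]
        node_types[row["target"]] = row["target_type"]
    return StrengthNetwork(arcs, node_types, timepoint, B)


def read_pair_list(path) -> set[tuple[str, str]]:
    """Two-column TSV (miRNA, gene) -> set of pairs (validated/iCLIP lists)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns")
    return set(zip(table[0].astype(str), table[1].astype(str)))


def read_id_list(path) -> set[str]:
    """One id per line (human DE lists, biotype filters)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def read_prediction_table(path) -> pd.DataFrame:
    """Predicted-MTI TSV with columns (mirna, mrna, confidence)."""
    table = pd.read_csv(path, sep="\t")
    missing = {"mirna", "mrna", "confidence"} - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return table


def read_orthology_map(path) -> dict[str, str]:
    """Two-column TSV (rat id, human id) -> mapping."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns")
    return dict(zip(table[0].astype(str), table[1].astype(str)))
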