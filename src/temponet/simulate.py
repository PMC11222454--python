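"""Synthetic temporal miRNA/mRNA expression with a planted regulatory network.

The generator emulates a longitudinal brain-injury study design: expression of
miRNAs and mRNAs is sampled at several post-insult time-points (default
24 h, 72 h, 10 d, day-of-first-seizure, chronic) with a small number of
biological replicates each, plus a separate set of control samples. A planted
directed regulatory network -- miRNA->mRNA edges predominantly repressive --
shapes the covariance of the non-control samples through a linear-Gaussian
structural equation model, so that downstream structure learning has a ground
truth to recover.

Sampling model: each sample at time-point ``t`` is drawn by evaluating nodes in
topological order,

    x_v = baseline(v, t) + sum_{u in parents_t(v)} beta_{uv} * x_u + eps_v,
    eps_v ~ N(0, noise_sd_v^2),

where ``parents_t`` are the edges active at ``t``. Control samples use zero
baselines and no active edges. The implied per-time-point covariance is
``(I - A)^-T D (I - A)^-1`` with ``A`` the active coefficient matrix and ``D``
the diagonal of noise variances; :func:`implied_covariance` exposes it for
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

DEFAULT_TIMEPOINTS: tuple[str, ...] = ("24h", "72h", "10d", "DOFS", "Chronic")
CONTROL_LABEL = "Control"

MIRNA = "miRNA"
MRNA = "mRNA"


@dataclass(frozen=True)
class RegulatoryEdge:
    """One planted directed edge with its coefficient and activity pattern."""

    source: str
    target: str
    coefficient: float
    active_timepoints: frozenset[str]


@dataclass
class RegulatoryScenario:
    """Planted ground truth for the synthetic expression generator.

    ``nodes`` maps node id to entity type (miRNA/mRNA); ``baseline`` maps
    ``(node, timepoint)`` to a mean shift relative to control (absent pairs
    default to 0); ``noise_sd`` maps node to its residual standard deviation.
    """

    nodes: dict[str, str]
    edges: list[RegulatoryEdge]
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    n_controls: int = 3
    baseline: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def node_order(self) -> list[str]:
        return list(self.nodes)

    def noise_sd_of(self, node: str) -> float:
        return self.noise_sd.get(node, 1.0)

    def active_edges(self, timepoint: str | None) -> list[RegulatoryEdge]:
        """Edges active at ``timepoint``; ``None`` (control) has no active edges."""
        if timepoint is None or timepoint == CONTROL_LABEL:
            return []
        return [e for e in self.edges if timepoint in e.active_timepoints]

    def validate(self) -> None:
        if not self.nodes:
            raise InvalidParameterError("scenario has no nodes")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        for node, sd in self.noise_sd.items():
            if sd < 0:
                raise InvalidParameterError(f"negative noise_sd for {node!r}")
        for e in self.edges:
            if e.source == e.target:
                raise InvalidParameterError(f"self-edge on {e.source!r}")
            if e.source not in self.nodes or e.target not in self.nodes:
                raise InvalidParameterError(
                    f"edge {e.source!r}->{e.target!r} references unknown node"
                )
        for tp in self.timepoints:
            _topological_order(self.node_order(), self.active_edges(tp))


@dataclass
class ExpressionDataset:
    """Entities x samples expression matrix with entity and sample metadata.

    ``values`` is indexed by entity id with sample ids as columns.
    ``entity_meta`` has columns (entity, type); ``sample_meta`` has columns
    (sample, timepoint, replicate, is_control).
    """

    values: pd.DataFrame
    entity_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise InvalidParameterError(f"duplicate entity ids: {dupes}")
        pairs = self.sample_meta[["timepoint", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise InvalidParameterError("duplicate (timepoint, replicate) pairs")
        if self.values.isna().any().any():
            raise InvalidParameterError("expression matrix contains missing values")

    def entity_types(self) -> dict[str, str]:
        return dict(zip(self.entity_meta["entity"], self.entity_meta["type"]))

    def samples_at(self, timepoint: str) -> list[str]:
        meta = self.sample_meta
        return meta.loc[meta["timepoint"] == timepoint, "sample"].tolist()

    def noncontrol_samples(self) -> list[str]:
        meta = self.sample_meta
        return meta.loc[~meta["is_control"], "sample"].tolist()


def _topological_order(nodes: list[str], edges: list[RegulatoryEdge]) -> list[str]:
    """Kahn topological sort; raises if the edge set is cyclic."""
    children: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for e in edges:
        children[e.source].append(e.target)
        indeg[e.target] += 1
    frontier = [n for n in nodes if indeg[n] == 0]
    order: list[str] = []
    while frontier:
        n = frontier.pop()
        order.append(n)
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                frontier.append(c)
    if len(order) != len(nodes):
        raise InvalidParameterError("active edge set contains a cycle")
    return order


def generate_scenario(
    n_mirna: int,
    n_mrna: int,
    edge_density: float,
    frac_repressive: float = 0.8,
    frac_timepoint_specific: float = 0.5,
    seed: int = 0,
    *,
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS,
    n_replicates: int = 3,
    n_controls: int = 3,
    coefficient_range: tuple[float, float] = (0.5, 1.0),
    frac_de: float = 0.4,
    de_shift: float = 5.0,
    noise_sd: float = 1.0,
) -> RegulatoryScenario:
    """Draw a random planted regulatory scenario.

    Acyclicity is enforced by sampling edges that respect a random topological
    order over all nodes, so every per-time-point restriction is acyclic by
    construction. ``edge_density`` is the fraction of order-respecting ordered
    pairs that receive an edge. miRNA->mRNA edges get a negative coefficient
    with probability ``frac_repressive``; other edge types get a random sign.
    Each edge is time-point specific (active at a random proper, non-empty
    subset of time-points) with probability ``frac_timepoint_specific`` and
    active everywhere otherwise. Differential expression against control is
    planted by giving each (node, time-point) a baseline shift of
    ``+-de_shift`` with probability ``frac_de``.
    """
    if n_mirna < 1 or n_mrna < 1:
        raise InvalidParameterError("n_mirna and n_mrna must both be >= 1")
    for name, frac in [
        ("edge_density", edge_density),
        ("frac_repressive", frac_repressive),
        ("frac_timepoint_specific", frac_timepoint_specific),
        ("frac_de", frac_de),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0, 1], got {frac}")
    if noise_sd <= 0:
        raise InvalidParameterError("noise_sd must be > 0")

    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i + 1}" for i in range(n_mirna)]
    mrnas = [f"Gene{i + 1}" for i in range(n_mrna)]
    nodes = {m: MIRNA for m in mirnas}
    nodes.update({g: MRNA for g in mrnas})

    ids = list(nodes)
    order = list(rng.permutation(len(ids)))
    rank = {ids[i]: r for r, i in enumerate(order)}

    pairs = [
        (u, v)
        for u in ids
        for v in ids
        if rank[u] < rank[v]
    ]
    n_edges = int(round(edge_density * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []

    edges: list[RegulatoryEdge] = []
    for idx in sorted(chosen):
        u, v = pairs[idx]
        mag = rng.uniform(*coefficient_range)
        if nodes[u] == MIRNA and nodes[v] == MRNA:
            sign = -1.0 if rng.random() < frac_repressive else 1.0
        else:
            sign = -1.0 if rng.random() < 0.5 else 1.0
        if rng.random() < frac_timepoint_specific and len(timepoints) > 1:
            k = int(rng.integers(1, len(timepoints)))
            active = frozenset(rng.choice(timepoints, size=k, replace=False))
        else:
            active = frozenset(timepoints)
        edges.append(RegulatoryEdge(u, v, sign * mag, active))

    baseline: dict[tuple[str, str], float] = {}
    for node in ids:
        for tp in timepoints:
            if rng.random() < frac_de:
                baseline[(node, tp)] = de_shift * (-1.0 if rng.random() < 0.5 else 1.0)

    scenario = RegulatoryScenario(
        nodes=nodes,
        edges=edges,
        timepoints=timepoints,
        n_replicates=n_replicates,
        n_controls=n_controls,
        baseline=baseline,
        noise_sd={n: noise_sd for n in ids},
        rng_seed=seed,
    )
    scenario.validate()
    return scenario


def _coefficient_matrix(scenario: RegulatoryScenario, timepoint: str | None) -> np.ndarray:
    ids = scenario.node_order()
    pos = {n: i for i, n in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for e in scenario.active_edges(timepoint):
        A[pos[e.source], pos[e.target]] = e.coefficient
    return A


def implied_covariance(scenario: RegulatoryScenario, timepoint: str | None) -> np.ndarray:
    """Closed-form SEM covariance ``(I - A)^-T D (I - A)^-1`` at a time-point."""
    ids = scenario.node_order()
    A = _coefficient_matrix(scenario, timepoint)
    D = np.diag([scenario.noise_sd_of(n) ** 2 for n in ids])
    inv = np.linalg.inv(np.eye(len(ids)) - A)
    return inv.T @ D @ inv


def simulate_expression(scenario: RegulatoryScenario) -> ExpressionDataset:
    """Sample an expression dataset from the planted scenario.

    Returns ``n_timepoints * n_replicates`` insult samples plus ``n_controls``
    control samples. Deterministic for a fixed ``scenario.rng_seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.rng_seed)
    ids = scenario.node_order()
    pos = {n: i for i, n in enumerate(ids)}
    sds = np.array([scenario.noise_sd_of(n) for n in ids])

    columns: list[str] = []
    meta_rows: list[dict] = []
    data: list[np.ndarray] = []

    groups: list[tuple[str | None, int]] = [
        (tp, scenario.n_replicates) for tp in scenario.timepoints
    ]
    groups.append((None, scenario.n_controls))

    for tp, n_rep in groups:
        label = tp if tp is not None else CONTROL_LABEL
        edges = scenario.active_edges(tp)
        order = _topological_order(ids, edges)
        parents: dict[str, list[RegulatoryEdge]] = {n: [] for n in ids}
        for e in edges:
            parents[e.target].append(e)
        base = np.array(
            [scenario.baseline.get((n, tp), 0.0) if tp is not None else 0.0 for n in ids]
        )
        for rep in range(1, n_rep + 1):
            eps = rng.normal(0.0, sds)
            x = np.empty(len(ids))
            for node in order:
                i = pos[node]
                val = base[i] + eps[i]
                for e in parents[node]:
                    val += e.coefficient * x[pos[e.source]]
                x[i] = val
            columns.append(f"{label}_r{rep}")
            meta_rows.append(
                {
                    "sample": f"{label}_r{rep}",
                    "timepoint": label,
                    "replicate": rep,
                    "is_control": tp is None,
                }
            )
            data.append(x)

    values = pd.DataFrame(np.column_stack(data), index=ids, columns=columns)
    values.index.name = "entity"
    entity_meta = pd.DataFrame(
        {"entity": ids, "type": [scenario.nodes[n] for n in ids]}
    )
    dataset = ExpressionDataset(values, entity_meta, pd.DataFrame(meta_rows))
    dataset.validate()
    return dataset


def ground_truth_arcs(scenario: RegulatoryScenario, timepoint: str | None = None) -> set[tuple[str, str]]:
    """Directed (source, target) pairs planted (at one time-point or overall)."""
    if timepoint is None:
        return {(e.source, e.target) for e in scenario.edges}
    return {(e.source, e.target) for e in scenario.active_edges(timepoint)}
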