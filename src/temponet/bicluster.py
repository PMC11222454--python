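"""Bipartite bi-clustering of differentially expressed mRNAs x time-points.

The module reduces a large DE mRNA list to per-time-point gene sets by
searching for heavy subgraphs of a bipartite response graph, in the spirit of
statistical-algorithmic bi-cluster analysis: genes and experimental conditions
(time-points) are the two node classes, an edge marks a gene responding in a
condition, and a module is a gene-set x condition-set whose submatrix is
unexpectedly dense under a null edge probability.

A module (G, C) is scored by the log-likelihood-ratio weight

    w(G, C) = sum_{g in G, c in C} [ edge(g,c) * log(p_c / p_0)
                                     + (1 - edge(g,c)) * log((1-p_c)/(1-p_0)) ]

with ``p_c > p_0``: edges are rewarded, non-edges penalised. Because the
weight is separable per gene and per condition, the greedy seed-and-extend
search alternates between the optimal gene set for the current conditions and
the optimal condition set for the current genes, which monotonically increases
the weight and terminates at a local optimum. Modules may overlap; a greedy
filter discards modules whose gene overlap with any better-scoring kept module
exceeds a fraction (default 10%) of the smaller gene set, and per-time-point
gene sets are the union of kept modules containing that time-point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import zscore_rows
from .simulate import ExpressionDataset

DEFAULT_P_MODULE = 0.9


@dataclass(frozen=True)
class Bicluster:
    """A set of mRNAs x set of time-points with its log-likelihood weight."""

    mrnas: frozenset[str]
    conditions: frozenset[str]
    weight: float

    def sort_key(self) -> tuple:
        return (-self.weight, tuple(sorted(self.mrnas)), tuple(sorted(self.conditions)))


def response_profile(dataset: ExpressionDataset, genes: list[str]) -> pd.DataFrame:
    """Replicate-averaged standardised response, genes x time-points.

    Rows are z-scored over all non-control samples, then averaged within each
    time-point, giving each gene a comparable per-condition response score.
    """
    samples = dataset.noncontrol_samples()
    z = zscore_rows(dataset.values.loc[genes, samples])
    meta = dataset.sample_meta.set_index("sample")
    tp_of = meta.loc[samples, "timepoint"]
    return z.T.groupby(tp_of.to_numpy()).mean().T


def build_response_graph(
    profile: pd.DataFrame, response_threshold: float = 1.0
) -> set[tuple[str, str]]:
    """Bipartite incidence: (gene, condition) iff |response| > threshold."""
    mask = profile.abs().to_numpy() > response_threshold
    rows, cols = np.nonzero(mask)
    return {(str(profile.index[i]), str(profile.columns[j])) for i, j in zip(rows, cols)}


def module_weight(
    edges: set[tuple[str, str]],
    genes: set[str],
    conditions: set[str],
    p_module: float,
    p_null: float,
) -> float:
    """Recompute the log-likelihood weight of a candidate module."""
    w_edge = math.log(p_module / p_null)
    w_gap = math.log((1.0 - p_module) / (1.0 - p_null))
    n_edges = sum(1 for g in genes for c in conditions if (g, c) in edges)
    return n_edges * w_edge + (len(genes) * len(conditions) - n_edges) * w_gap


def _null_probability(density: float) -> float:
    # keep the null strictly inside (0, p_module)
    return float(np.clip(density, 0.02, 0.5))


def find_biclusters(
    edges: set[tuple[str, str]],
    max_modules: int = 50,
    min_genes: int = 2,
    seed: int = 0,
    *,
    min_conditions: int = 2,
    p_module: float = DEFAULT_P_MODULE,
    p_null: float | None = None,
) -> list[Bicluster]:
    """Greedy seed-and-extend search for heavy bipartite modules.

    Seeds are single conditions and condition pairs with their common adjacent
    genes; each seed is refined by alternating optimal-gene-set /
    optimal-condition-set updates of the separable weight until a fixed point.
    Modules must span at least ``min_conditions`` conditions (default 2: a
    module is a pattern correlated *across* conditions, not a single
    condition's responder list). Deterministic for fixed input (``seed`` is
    accepted for interface stability; the search itself involves no
    randomness).
    """
    del seed
    if not edges:
        return []
    genes = sorted({g for g, _ in edges})
    conds = sorted({c for _, c in edges})
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(conds)}
    M = np.zeros((len(genes), len(conds)), dtype=bool)
    for g, c in edges:
        M[gi[g], ci[c]] = True

    density = M.mean()
    p0 = _null_probability(density) if p_null is None else p_null
    if not 0.0 < p0 < p_module < 1.0:
        raise ValueError("need 0 < p_null < p_module < 1")
    w_edge = math.log(p_module / p0)
    w_gap = math.log((1.0 - p_module) / (1.0 - p0))

    def refine(cond_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        for _ in range(100):
            n_c = int(cond_mask.sum())
            if n_c == 0:
                return None
            counts = M[:, cond_mask].sum(axis=1)
            gene_delta = counts * w_edge + (n_c - counts) * w_gap
            gene_mask = gene_delta > 0
            n_g = int(gene_mask.sum())
            if n_g == 0:
                return None
            ccounts = M[gene_mask, :].sum(axis=0)
            cond_delta = ccounts * w_edge + (n_g - ccounts) * w_gap
            new_cond = cond_delta > 0
            if not new_cond.any():
                return None
            if np.array_equal(new_cond, cond_mask):
                return gene_mask, cond_mask
            cond_mask = new_cond
        return gene_mask, cond_mask

    seen: set[tuple] = set()
    modules: list[Bicluster] = []
    seeds: list[np.ndarray] = []
    for j in range(len(conds)):
        mask = np.zeros(len(conds), dtype=bool)
        mask[j] = True
        seeds.append(mask)
    for j in range(len(conds)):
        for k in range(j + 1, len(conds)):
            mask = np.zeros(len(conds), dtype=bool)
            mask[j] = mask[k] = True
            seeds.append(mask)

    for cond_mask in seeds:
        result = refine(cond_mask.copy())
        if result is None:
            continue
        gene_mask, cmask = result
        gset = frozenset(genes[i] for i in np.flatnonzero(gene_mask))
        cset = frozenset(conds[j] for j in np.flatnonzero(cmask))
        if len(gset) < min_genes or len(cset) < min_conditions:
            continue
        key = (gset, cset)
        if key in seen:
            continue
        seen.add(key)
        n_edges = int(M[np.ix_(gene_mask, cmask)].sum())
        weight = n_edges * w_edge + (len(gset) * len(cset) - n_edges) * w_gap
        modules.append(Bicluster(gset, cset, weight))

    modules.sort(key=Bicluster.sort_key)
    return modules[:max_modules]


def filter_overlap(modules: list[Bicluster], max_overlap: float = 0.10) -> list[Bicluster]:
    """Greedy acceptance by descending weight; overlap relative to smaller set.

    A module is kept iff |genes intersect kept genes| / |smaller gene set| is
    at most ``max_overlap`` against every already-kept module.
    """
    ordered = sorted(modules, key=Bicluster.sort_key)
    kept: list[Bicluster] = []
    for mod in ordered:
        ok = True
        for acc in kept:
            inter = len(mod.mrnas & acc.mrnas)
            smaller = min(len(mod.mrnas), len(acc.mrnas))
            if smaller and inter / smaller > max_overlap:
                ok = False
                break
        if ok:
            kept.append(mod)
    return kept


def merge_per_timepoint(modules: list[Bicluster], timepoint: str) -> set[str]:
    """Union of gene sets of modules whose condition set contains the time-point."""
    out: set[str] = set()
    for mod in modules:
        if timepoint in mod.conditions:
            out |= mod.mrnas
    return out


def biclusters_by_timepoint(
    modules: list[Bicluster], timepoints: tuple[str, ...]
) -> dict[str, set[str]]:
    """Merged per-time-point mRNA sets for every time-point label."""
    return {tp: merge_per_timepoint(modules, tp) for tp in timepoints}


def write_modules(modules: list[Bicluster], path) -> None:
    rows = [
        {
            "module": i + 1,
            "weight": m.weight,
            "genes": ",".join(sorted(m.mrnas)),
            "conditions": ",".join(sorted(m.conditions)),
        }
        for i, m in enumerate(modules)
    ]
    pd.DataFrame(rows, columns=["module", "weight", "genes", "conditions"]).to_csv(
        path, sep="\t", index=False
    )
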