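"""Gaussian Bayesian network structure learning with bootstrap arc strengths.

Per time-point, the expression model input (z-scored entities x samples) is
fit with a linear-Gaussian Bayesian network. The network score is the
Bayesian information criterion in its decomposable per-family form

    family(v | P) = max-likelihood Gaussian log-likelihood of the OLS fit of
                    v on its parents P (with intercept)
                    - (|P| + 2) / 2 * log(n)

(|P| coefficients + intercept + residual variance are the |P| + 2 free
parameters), so the network score is the sum of family scores and structure
search only ever re-scores the families a move touches. Structures are
learned by greedy hill climbing over single-arc additions, deletions and
reversals from the empty graph, with lexicographic tie-breaking for
determinism.

Because the sample size is typically tiny relative to the variable count,
a single learned structure is unstable; nonparametric bootstrap model
averaging is used instead: the samples are resampled with replacement B times
(default 1000), a structure is learned from each resample, and the strength
of a directed arc is its empirical frequency across the B structures. Only
arcs in the highest quartile of positive strengths at a time-point are
retained.

Family scores are computed from the centred cross-product (Gram) matrix of
the data, which makes each candidate-move evaluation a small linear solve
independent of the sample count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .preprocess import ModelInput

logger = logging.getLogger(__name__)

EDGE_TYPES = ("miRNA->miRNA", "miRNA->mRNA", "mRNA->miRNA", "mRNA->mRNA")

_SINGULAR_RSS = 1e-10


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph over typed entities."""

    nodes: tuple[str, ...]
    node_types: dict[str, str] = field(hash=False)
    arcs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        for u, v in self.arcs:
            if u == v:
                raise InvalidParameterError(f"self-arc on {u!r}")
            if u not in self.node_types or v not in self.node_types:
                raise InvalidParameterError(f"arc ({u!r}, {v!r}) references unknown node")
        _assert_acyclic(self.nodes, self.arcs)


def _assert_acyclic(nodes, arcs) -> None:
    children: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in arcs:
        children[u].append(v)
        indeg[v] += 1
    stack = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while stack:
        n = stack.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if seen != len(list(nodes)):
        raise InvalidParameterError("arc set contains a cycle")


@dataclass
class LearnConfig:
    """Structure-learning configuration.

    ``B`` bootstrap replicates (default 1000); ``quartile`` the strength
    quantile above which arcs are retained (default 0.75, i.e. the highest
    quartile); ``strength_mode`` either ``"undirected"`` (the default:
    strength = frequency of the skeleton edge across bootstrap structures,
    reported on its majority orientation -- robust, because the orientation
    of a covered edge is arbitrary within a Markov equivalence class) or
    ``"directed"`` (strength = frequency of the directed arc);
    ``restarts`` extra seeded random-start climbs per structure search
    (escapes collider-type local optima of single-arc hill climbing).
    """

    B: int = 1000
    rng_seed: int = 0
    max_parents: int | None = None
    quartile: float = 0.75
    strength_mode: str = "undirected"
    restarts: int = 20

    def validate(self) -> None:
        if self.B < 1:
            raise InvalidParameterError("B must be >= 1")
        if self.restarts < 0:
            raise InvalidParameterError("restarts must be >= 0")
        if not 0.0 < self.quartile < 1.0:
            raise InvalidParameterError("quartile must be in (0, 1)")
        if self.strength_mode not in ("directed", "undirected"):
            raise InvalidParameterError(f"unknown strength_mode {self.strength_mode!r}")
        if self.max_parents is not None and self.max_parents < 0:
            raise InvalidParameterError("max_parents must be >= 0")


@dataclass
class StrengthNetwork:
    """Directed arcs with bootstrap strength scores for one time-point.

    ``arcs`` has columns (source, source_type, target, target_type, strength,
    retained). Before quartile filtering every arc is flagged retained and
    ``quartile_threshold`` is None.
    """

    arcs: pd.DataFrame
    node_types: dict[str, str]
    timepoint: str
    B: int
    quartile_threshold: float | None = None

    def retained_arcs(self) -> pd.DataFrame:
        return self.arcs[self.arcs["retained"]].reset_index(drop=True)

    def retained_pairs(self) -> set[tuple[str, str]]:
        r = self.retained_arcs()
        return set(zip(r["source"], r["target"]))


class _GramScorer:
    """Family BIC scores from the centred cross-product matrix."""

    def __init__(self, X: np.ndarray):
        # X: variables x samples
        self.n = X.shape[1]
        Xc = X - X.mean(axis=1, keepdims=True)
        self.S = Xc @ Xc.T
        self._const = np.log(2.0 * np.pi)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def _score_from_rss(self, rss: float, k: int) -> float:
        n = self.n
        if rss < _SINGULAR_RSS:
            return -np.inf
        ll = -0.5 * n * (self._const + np.log(rss / n) + 1.0)
        return ll - 0.5 * (k + 2) * np.log(n)

    def family_rss(self, v: int, parents: tuple[int, ...]) -> float:
        S = self.S
        if not parents:
            return float(S[v, v])
        P = list(parents)
        Spp = S[np.ix_(P, P)]
        spv = S[P, v]
        try:
            sol = np.linalg.solve(Spp, spv)
        except np.linalg.LinAlgError:
            return -1.0  # singular marker
        rss = float(S[v, v] - spv @ sol)
        return rss

    def family(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        rss = self.family_rss(v, parents)
        score = -np.inf if rss < 0 else self._score_from_rss(rss, len(parents))
        self._cache[key] = score
        return score

    def all_add_deltas(self, v: int, parents: tuple[int, ...], base_score: float) -> np.ndarray:
        """Score change of adding each node as a parent of v (vector over all
        nodes; the entries for v itself and current parents are -inf)."""
        S = self.S
        p = S.shape[0]
        k = len(parents)
        n = self.n
        if not parents:
            a = S[:, v].copy()
            b = np.diag(S).copy()
            rss0 = float(S[v, v])
        else:
            P = list(parents)
            Spp = S[np.ix_(P, P)]
            spv = S[P, v]
            try:
                W = np.linalg.solve(Spp, np.column_stack([spv, S[P, :]]))
            except np.linalg.LinAlgError:
                return np.full(p, -np.inf)
            sol_v = W[:, 0]
            T = W[:, 1:]  # k x p
            rss0 = float(S[v, v] - spv @ sol_v)
            ScP = S[:, P]  # p x k
            a = S[:, v] - ScP @ sol_v
            b = np.diag(S) - np.einsum("mk,km->m", ScP, T)
        if rss0 < _SINGULAR_RSS:
            return np.full(p, -np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_new = rss0 - a * a / b
        valid = (b > _SINGULAR_RSS) & (rss_new > _SINGULAR_RSS)
        scores = np.full(p, -np.inf)
        scores[valid] = (
            -0.5 * n * (self._const + np.log(rss_new[valid] / n) + 1.0)
            - 0.5 * (k + 3) * np.log(n)
        )
        deltas = scores - base_score
        deltas[v] = -np.inf
        deltas[list(parents)] = -np.inf
        return deltas


def _as_matrix(data) -> tuple[np.ndarray, list[str], dict[str, str]]:
    if isinstance(data, ModelInput):
        X = data.values.to_numpy(dtype=float)
        names = list(data.values.index)
        types = dict(data.entity_types)
        return X, names, types
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index), {}
    raise InvalidInputError("data must be a ModelInput or a DataFrame (entities x samples)")


def family_bic(data, child: str, parents) -> float:
    """Gaussian BIC family score of ``child`` given ``parents``.

    OLS fit with intercept; returns the Gaussian log-likelihood at the MLE
    residual variance minus ``(|parents| + 2)/2 * log(n)``. Collinear parents
    yield ``-inf`` (the arc set is disallowed).
    """
    X, names, _ = _as_matrix(data)
    idx = {name: i for i, name in enumerate(names)}
    if child not in idx:
        raise InvalidInputError(f"unknown child {child!r}")
    ps = tuple(idx[p] for p in parents)
    if X.shape[1] < len(ps) + 2:
        raise InvalidInputError("need n >= |parents| + 2 samples")
    return _GramScorer(X).family(idx[child], ps)


def network_score(data, dag: DAGStructure) -> float:
    """Decomposable network score: sum of family scores."""
    parents: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for u, v in dag.arcs:
        parents[v].append(u)
    return sum(family_bic(data, v, tuple(sorted(parents[v]))) for v in dag.nodes)


def _reachability(p: int, children: list[set[int]]) -> list[set[int]]:
    """reach[i] = set of nodes reachable from i by >= 1 arc (DFS per node)."""
    reach: list[set[int]] = []
    for i in range(p):
        seen: set[int] = set()
        stack = list(children[i])
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            stack.extend(children[w] - seen)
        reach.append(seen)
    return reach


def hill_climb(data, config: LearnConfig | None = None) -> DAGStructure:
    """Greedy BIC hill climbing with seeded random restarts.

    At each step the single arc addition, deletion or reversal with the
    greatest positive score improvement (acyclicity preserved) is applied;
    a climb stops when no move improves the score. Ties are broken by move
    kind (addition < deletion < reversal) then lexicographic (parent, child).
    Because single-arc moves cannot reorient a collider in one step, the
    search is repeated from ``config.restarts`` random starting DAGs (drawn
    from a generator seeded by ``config.rng_seed``) in addition to the empty
    graph, and the best-scoring local optimum is returned; the result is
    deterministic for fixed data and config.
    """
    config = config or LearnConfig()
    config.validate()
    X, names, _ = _as_matrix(data)
    p, n = X.shape
    if n < 3:
        raise InvalidInputError("need >= 3 samples for structure learning")
    scorer = _GramScorer(X)
    order = np.argsort(names)  # lexicographic positions for tie-breaking
    lex_rank = np.empty(p, dtype=int)
    lex_rank[order] = np.arange(p)
    # a family needs >= 1 residual degree of freedom (n - |parents| - 2 >= 1),
    # otherwise the ML variance collapses and the score diverges
    max_par = min(config.max_parents if config.max_parents is not None else p, n - 3)
    max_par = max(max_par, 0)

    best_parents, best_score = _climb(
        scorer, p, lex_rank, max_par, [set() for _ in range(p)]
    )
    rng = np.random.default_rng(config.rng_seed)
    arc_prob = min(0.5, 2.0 / p)  # sparse starts: ~p arcs, denser for tiny p
    for _ in range(config.restarts):
        topo = rng.permutation(p)
        start: list[set[int]] = [set() for _ in range(p)]
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < arc_prob and len(start[topo[j]]) < max_par:
                    start[topo[j]].add(int(topo[i]))
        cand_parents, cand_score = _climb(scorer, p, lex_rank, max_par, start)
        if cand_score > best_score + 1e-9:
            best_parents, best_score = cand_parents, cand_score

    arcs = frozenset(
        (names[u], names[v]) for v in range(p) for u in best_parents[v]
    )
    types = data.entity_types if isinstance(data, ModelInput) else {}
    node_types = {name: types.get(name, "unknown") for name in names}
    return DAGStructure(nodes=tuple(names), node_types=node_types, arcs=arcs)


def _climb(
    scorer: _GramScorer,
    p: int,
    lex_rank: np.ndarray,
    max_par: int,
    parents: list[set[int]],
) -> tuple[list[set[int]], float]:
    """Greedy single-arc local search from a given starting DAG (in place)."""
    children: list[set[int]] = [set() for _ in range(p)]
    for v in range(p):
        for u in parents[v]:
            children[u].add(v)
    fam = np.array([scorer.family(v, tuple(sorted(parents[v]))) for v in range(p)])

    # add_deltas[v][u]: score change of adding u -> v; valid while parents[v]
    # is unchanged (acyclicity is masked per iteration, not baked in).
    add_deltas = [
        scorer.all_add_deltas(v, tuple(sorted(parents[v])), fam[v]) for v in range(p)
    ]

    def refresh(v: int) -> None:
        P = tuple(sorted(parents[v]))
        fam[v] = scorer.family(v, P)
        add_deltas[v] = scorer.all_add_deltas(v, P, fam[v])

    while True:
        reach = _reachability(p, children)
        best_delta = 0.0
        best_key = None
        best_move = None

        def consider(delta: float, key: tuple, move: tuple) -> None:
            nonlocal best_delta, best_key, best_move
            if not delta > 1e-12 or not np.isfinite(delta):  # also drops NaN
                return
            if delta > best_delta + 1e-12 or (
                delta >= best_delta - 1e-12 and best_key is not None and key < best_key
            ):
                best_delta, best_key, best_move = delta, key, move

        for v in range(p):
            if len(parents[v]) >= max_par:
                continue
            deltas = add_deltas[v]
            top = best_delta - 1e-12
            for u in np.flatnonzero(deltas >= top if best_move else deltas > 1e-12):
                u = int(u)
                if u in reach[v]:  # v ~> u: adding u -> v would close a cycle
                    continue
                consider(deltas[u], (0, lex_rank[u], lex_rank[v]), ("add", u, v))

        for v in range(p):
            for u in sorted(parents[v]):
                P_minus = tuple(sorted(parents[v] - {u}))
                with np.errstate(invalid="ignore"):
                    d_del = scorer.family(v, P_minus) - fam[v]
                if np.isnan(d_del):  # both families singular
                    continue
                consider(d_del, (1, lex_rank[u], lex_rank[v]), ("del", u, v))
                # reversal u->v  =>  v->u
                if len(parents[u]) >= max_par:
                    continue
                # acyclic iff no alternative u ~> v path (all such paths avoid
                # the arc itself in a DAG)
                alt_path = any(w == v or v in reach[w] for w in children[u] if w != v)
                if alt_path:
                    continue
                P_u_plus = tuple(sorted(parents[u] | {v}))
                with np.errstate(invalid="ignore"):
                    d_rev = d_del + scorer.family(u, P_u_plus) - fam[u]
                if np.isnan(d_rev):
                    continue
                consider(d_rev, (2, lex_rank[v], lex_rank[u]), ("rev", u, v))

        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            parents[v].add(u)
            children[u].add(v)
            refresh(v)
        elif kind == "del":
            parents[v].discard(u)
            children[u].discard(v)
            refresh(v)
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            refresh(v)
            refresh(u)

    return parents, float(fam.sum())


def bootstrap_strength(
    data, config: LearnConfig | None = None, edge_set: str = "consensus"
) -> StrengthNetwork:
    """Bootstrap model averaging: arc strength = empirical frequency.

    Samples (columns) are resampled with replacement ``config.B`` times; a
    structure is hill-climbed from each resample; the strength of a directed
    arc is the fraction of the B structures containing it. A degenerate
    resample in which some variable becomes constant is re-drawn (logged).

    ``edge_set`` selects which arcs the returned network carries:
    ``"consensus"`` (default) restricts to the arcs of the structure learned
    from the original, un-resampled data, each annotated with its bootstrap
    strength -- this is the per-time-point inferred network whose edges the
    quartile filter then thins; ``"observed"`` returns every arc that appeared
    in at least one bootstrap structure (the full strength table).
    """
    config = config or LearnConfig()
    config.validate()
    if edge_set not in ("consensus", "observed"):
        raise InvalidParameterError(f"unknown edge_set {edge_set!r}")
    X, names, _ = _as_matrix(data)
    p, n = X.shape
    types = data.entity_types if isinstance(data, ModelInput) else {}
    timepoint = data.timepoint if isinstance(data, ModelInput) else ""
    rng = np.random.default_rng(config.rng_seed)

    counts: dict[tuple[str, str], int] = {}
    redraws = 0
    for b in range(config.B):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            Xb = X[:, idx]
            if np.all(Xb.std(axis=1) > 0):
                break
            redraws += 1
        else:
            raise InvalidInputError("could not draw a non-degenerate bootstrap resample")
        frame = pd.DataFrame(Xb, index=names)
        # plain greedy per replicate: averaging over B resamples already
        # smooths local-optimum noise, and restarts would multiply the cost
        dag = hill_climb(frame, replace(config, B=1, restarts=0))
        for arc in dag.arcs:
            counts[arc] = counts.get(arc, 0) + 1
    if redraws:
        logger.info("re-drew %d degenerate bootstrap resamples", redraws)

    keep: frozenset[tuple[str, str]] | None = None
    if edge_set == "consensus":
        keep = hill_climb(pd.DataFrame(X, index=names), replace(config, B=1)).arcs

    if config.strength_mode == "directed":
        rows = [
            {"source": u, "target": v, "strength": c / config.B}
            for (u, v), c in sorted(counts.items())
        ]
    else:
        skeleton: dict[tuple[str, str], tuple[int, int]] = {}
        for (u, v), c in counts.items():
            key = (u, v) if (u, v) <= (v, u) else (v, u)
            fwd, rev = skeleton.get(key, (0, 0))
            if (u, v) == key:
                fwd += c
            else:
                rev += c
            skeleton[key] = (fwd, rev)
        rows = []
        for (a, b2), (fwd, rev) in sorted(skeleton.items()):
            u, v = (a, b2) if fwd >= rev else (b2, a)
            rows.append({"source": u, "target": v, "strength": (fwd + rev) / config.B})

    if keep is not None:
        if config.strength_mode == "directed":
            rows = [
                {"source": u, "target": v, "strength": counts.get((u, v), 0) / config.B}
                for u, v in sorted(keep)
            ]
        else:
            rows = [
                {
                    "source": u,
                    "target": v,
                    "strength": (counts.get((u, v), 0) + counts.get((v, u), 0))
                    / config.B,
                }
                for u, v in sorted(keep)
            ]

    arcs = pd.DataFrame(rows, columns=["source", "target", "strength"])
    node_types = {name: types.get(name, "unknown") for name in names}
    arcs["source_type"] = arcs["source"].map(node_types)
    arcs["target_type"] = arcs["target"].map(node_types)
    arcs["retained"] = True
    arcs = arcs[["source", "source_type", "target", "target_type", "strength", "retained"]]
    return StrengthNetwork(
        arcs=arcs, node_types=node_types, timepoint=timepoint, B=config.B
    )


def quartile_filter(network: StrengthNetwork, quartile: float = 0.75) -> StrengthNetwork:
    """Retain arcs in the highest quartile of positive strengths.

    The threshold is the ``quartile`` sample quantile (linear interpolation)
    of the strengths of arcs ever observed in the bootstrap (strength > 0) at
    this time-point; arcs with strength >= threshold are retained.
    """
    if not 0.0 < quartile < 1.0:
        raise InvalidParameterError("quartile must be in (0, 1)")
    positive = network.arcs.loc[network.arcs["strength"] > 0, "strength"]
    arcs = network.arcs.copy()
    if positive.empty:
        logger.warning("no positive-strength arcs at %s; empty network", network.timepoint)
        arcs["retained"] = False
        return StrengthNetwork(arcs, network.node_types, network.timepoint, network.B, None)
    threshold = float(np.quantile(positive.to_numpy(), quartile))
    arcs["retained"] = arcs["strength"] >= threshold
    return StrengthNetwork(arcs, network.node_types, network.timepoint, network.B, threshold)


def classify_edges(network: StrengthNetwork) -> dict[str, int]:
    """Retained-arc counts per (source type -> target type) combination."""
    counts = {t: 0 for t in EDGE_TYPES}
    for _, row in network.retained_arcs().iterrows():
        key = f"{row['source_type']}->{row['target_type']}"
        if key not in counts:
            raise InvalidInputError(
                f"unknown node type on arc {row['source']!r}->{row['target']!r}"
            )
        counts[key] += 1
    return counts
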