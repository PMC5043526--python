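"""Dependency-network learning over binary occupancy data.

A Bayesian network over binary factors X = (X1..Xn) factorises the joint
distribution as P(X) = prod_i P(Xi | parents(Xi)). Structure is learned
either constraint-based (grow-shrink Markov-blanket search with a G²
mutual-information conditional-independence test) or score-based
(hill-climbing / tabu search maximising the decomposable BIC), and wrapped
in a bootstrap consensus: the learner runs on random row subsamples and
only edges appearing in at least a support threshold of the runs are
retained.

For <= 16 variables all contingency tables are marginalised from one joint
pattern-count table per (sub)sample, which makes the 100x100 bootstrap
loops affordable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_regions import GenomeTable, RegionSet, overlaps, random_regions

__all__ = [
    "DiscreteDataset",
    "BNStructure",
    "ConsensusNetwork",
    "ControlComparison",
    "occupancy_dataset",
    "mi_ci_test",
    "learn_grow_shrink",
    "learn_score",
    "bootstrap_consensus",
    "control_network",
]


@dataclass
class DiscreteDataset:
    """ROIs x binary variables, no missing cells, no constant columns."""

    names: list[str]
    data: np.ndarray  # (n, V) uint8

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("cells must be 0/1")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_vars(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_matrix(cls, df: pd.DataFrame) -> "DiscreteDataset":
        """Build from a 0/1 DataFrame, dropping constant columns with a warning."""
        keep, dropped = [], []
        for col in df.columns:
            v = df[col].to_numpy()
            (keep if len(np.unique(v)) > 1 else dropped).append(col)
        if dropped:
            warnings.warn(f"dropping constant column(s): {dropped}")
        if not keep:
            raise ValueError("no non-constant columns left")
        return cls([str(c) for c in keep], df[keep].to_numpy(dtype=np.uint8))


def occupancy_dataset(rois: RegionSet, factor_beds: dict[str, RegionSet],
                      annotations: dict[str, RegionSet] | None = None,
                      min_bp: int = 1) -> DiscreteDataset:
    """Presence/absence matrix of factors (and annotations) over ROIs."""
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    cols = {}
    for name, peaks in {**factor_beds, **(annotations or {})}.items():
        cols[name] = overlaps(rois, peaks, min_bp).astype(np.uint8)
    return DiscreteDataset.from_matrix(pd.DataFrame(cols))


class _Engine:
    """Contingency-table backend over a row subset of a DiscreteDataset."""

    _FAST_MAX = 16

    def __init__(self, data: np.ndarray, rows: np.ndarray | None = None):
        self.sub = data if rows is None else data[rows]
        self.N = len(self.sub)
        self.V = data.shape[1]
        if self.V <= self._FAST_MAX:
            weights = (1 << np.arange(self.V - 1, -1, -1)).astype(np.int64)
            codes = self.sub.astype(np.int64) @ weights
            self.table = np.bincount(codes, minlength=1 << self.V).reshape(
                (2,) * self.V)
        else:
            self.table = None

    def marginal(self, variables: tuple[int, ...]) -> np.ndarray:
        """Joint counts over the given variables, axes in the given order."""
        if self.table is not None:
            others = tuple(i for i in range(self.V) if i not in variables)
            marg = self.table.sum(axis=others)  # axes in sorted(variables) order
            srt = sorted(variables)
            perm = [srt.index(v) for v in variables]
            return np.transpose(marg, perm)
        cols = self.sub[:, list(variables)].astype(np.int64)
        k = len(variables)
        weights = 1 << np.arange(k - 1, -1, -1)
        codes = cols @ weights
        return np.bincount(codes, minlength=1 << k).reshape((2,) * k)

    def g2(self, x: int, y: int, z: tuple[int, ...] = ()
           ) -> tuple[float, int, float]:
        """G² = 2N·MI(x;y|z) in nats, df = 2^|z| (binary vars), chi² p."""
        tab = self.marginal((x, y) + tuple(z)).reshape(2, 2, -1).astype(float)
        n_k = tab.sum(axis=(0, 1), keepdims=True)
        n_xk = tab.sum(axis=1, keepdims=True)
        n_yk = tab.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = tab * n_k / (n_xk * n_yk)
            terms = tab * np.log(ratio)
        g2 = 2.0 * np.nansum(np.where(tab > 0, terms, 0.0))
        g2 = max(g2, 0.0)
        df = 1 << len(z)
        return g2, df, float(stats.chi2.sf(g2, df))

    def family_score(self, x: int, parents: tuple[int, ...]) -> float:
        """BIC family score: log-likelihood - 0.5·ln(N)·free parameters."""
        tab = self.marginal((x,) + tuple(parents)).reshape(2, -1).astype(float)
        n_pa = tab.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.nansum(np.where(tab > 0, tab * np.log(tab / n_pa), 0.0))
        nparams = 1 << len(parents)
        return float(ll - 0.5 * np.log(max(self.N, 1)) * nparams)


def mi_ci_test(x: int, y: int, z, data: DiscreteDataset,
               rows: np.ndarray | None = None) -> tuple[float, int, float]:
    """Conditional-independence test of x and y given z.

    Returns (G², df, p). G² equals twice the sample size times the
    conditional mutual information in nats, summed over the strata of z.
    """
    if data.n == 0:
        raise ValueError("empty dataset")
    return _Engine(data.data, rows).g2(x, y, tuple(z))


@dataclass
class BNStructure:
    """Partially directed acyclic structure (CPDAG-style output)."""

    nodes: list[str]
    directed: set[tuple[int, int]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def is_acyclic(self) -> bool:
        children: dict[int, list[int]] = {}
        indeg = {i: 0 for i in range(len(self.nodes))}
        for a, b in self.directed:
            children.setdefault(a, []).append(b)
            indeg[b] += 1
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for w in children.get(v, []):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        return seen == len(self.nodes)

    def edge_names(self) -> list[tuple[str, str, str]]:
        out = [(self.nodes[a], self.nodes[b], "->") for a, b in sorted(self.directed)]
        out += [tuple(sorted(self.nodes[i] for i in e)) + ("--",)
                for e in self.undirected]
        return out


def _guarded_p(engine: _Engine, x: int, y: int, z: tuple[int, ...],
               guard: float) -> float:
    """p value, with the small-sample guard: when the average cell count of
    the x,y|z table drops below `guard`, the test is skipped and the pair
    treated as independent (p = 1)."""
    if guard > 0 and engine.N / (4 << len(z)) < guard:
        return 1.0
    return engine.g2(x, y, z)[2]


def _grow_shrink_blanket(engine: _Engine, x: int, alpha: float,
                         guard: float) -> list[int]:
    blanket: list[int] = []
    # grow: repeatedly admit the most dependent remaining variable
    while True:
        best, best_p = None, alpha
        for y in range(engine.V):
            if y == x or y in blanket:
                continue
            p = _guarded_p(engine, x, y, tuple(blanket), guard)
            if p < best_p:
                best, best_p = y, p
        if best is None:
            break
        blanket.append(best)
    # shrink: drop members independent given the rest
    changed = True
    while changed:
        changed = False
        for y in list(blanket):
            rest = tuple(v for v in blanket if v != y)
            if _guarded_p(engine, x, y, rest, guard) >= alpha:
                blanket.remove(y)
                changed = True
    return blanket


def learn_grow_shrink(data: DiscreteDataset, alpha: float = 0.05, *,
                      rows: np.ndarray | None = None,
                      guard: float = 5.0) -> BNStructure:
    """Constraint-based structure learning via grow-shrink Markov blankets.

    Blankets are estimated per variable with the G² CI test at level alpha,
    symmetrised by intersection; direct neighbours are blanket members not
    separable by any subset of the smaller blanket; v-structures are
    oriented by the collider rule and remaining edges left undirected.
    """
    engine = _Engine(data.data, rows)
    V = engine.V
    blankets = [set(_grow_shrink_blanket(engine, x, alpha, guard)) for x in range(V)]
    for x in range(V):
        blankets[x] = {y for y in blankets[x] if x in blankets[y]}

    adjacent: set[frozenset] = set()
    sepsets: dict[frozenset, set[int]] = {}
    for x in range(V):
        for y in range(x + 1, V):
            if y not in blankets[x]:
                continue
            bx = blankets[x] - {y}
            by = blankets[y] - {x}
            # search separator subsets of both blankets: a true edge has no
            # separator anywhere, while a false adjacency that survives one
            # blanket's subsets is usually separated by the other's
            bases = [tuple(sorted(bx))]
            if by != bx:
                bases.append(tuple(sorted(by)))
            separated = False
            tried = set()
            for base in bases:
                for size in range(len(base) + 1):
                    for S in itertools.combinations(base, size):
                        if S in tried:
                            continue
                        tried.add(S)
                        if _guarded_p(engine, x, y, S, guard) >= alpha:
                            sepsets[frozenset((x, y))] = set(S)
                            separated = True
                            break
                    if separated:
                        break
                if separated:
                    break
            if not separated:
                adjacent.add(frozenset((x, y)))

    neighbours = {v: {w for e in adjacent if v in e for w in e if w != v}
                  for v in range(V)}
    directed: set[tuple[int, int]] = set()
    for pair, S in sepsets.items():
        x, y = tuple(pair)
        for z in neighbours[x] & neighbours[y]:
            if z not in S:
                directed.add((x, z))
                directed.add((y, z))
    # drop conflicting orientations (both directions demanded)
    conflicted = {frozenset((a, b)) for a, b in directed if (b, a) in directed}
    directed = {(a, b) for a, b in directed if frozenset((a, b)) not in conflicted}
    undirected = {e for e in adjacent
                  if not any(frozenset((a, b)) == e for a, b in directed)}
    structure = BNStructure(list(data.names), directed, undirected)
    if not structure.is_acyclic():  # extremely rare orientation clash
        structure = BNStructure(list(data.names), set(), structure.skeleton())
    return structure


class _ScoreSearch:
    def __init__(self, engine: _Engine, names: list[str]):
        self.engine = engine
        self.names = names
        self.V = engine.V
        self.parents: list[set[int]] = [set() for _ in range(self.V)]
        self.cache: dict[tuple[int, frozenset], float] = {}
        self.node_score = [self._fam(x, frozenset()) for x in range(self.V)]

    def _fam(self, x: int, ps: frozenset) -> float:
        key = (x, ps)
        if key not in self.cache:
            self.cache[key] = self.engine.family_score(x, tuple(sorted(ps)))
        return self.cache[key]

    def total(self) -> float:
        return float(sum(self.node_score))

    def _creates_cycle(self, frm: int, to: int, skip: tuple[int, int] | None = None
                       ) -> bool:
        """Would adding frm->to create a directed cycle (optionally ignoring
        the edge `skip`)? True iff `frm` is reachable from `to`."""
        children: dict[int, list[int]] = {}
        for child in range(self.V):
            for par in self.parents[child]:
                if skip and (par, child) == skip:
                    continue
                children.setdefault(par, []).append(child)
        stack, seen = [to], set()
        while stack:
            v = stack.pop()
            if v == frm:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(children.get(v, []))
        return False

    def legal_moves(self):
        for i in range(self.V):
            for j in range(self.V):
                if i == j:
                    continue
                if i in self.parents[j]:
                    yield ("del", i, j)
                    if not self._creates_cycle(j, i, skip=(i, j)):
                        yield ("rev", i, j)
                elif j not in self.parents[i]:
                    if not self._creates_cycle(i, j):
                        yield ("add", i, j)

    def delta(self, move) -> float:
        op, i, j = move
        if op == "add":
            return self._fam(j, frozenset(self.parents[j] | {i})) - self.node_score[j]
        if op == "del":
            return self._fam(j, frozenset(self.parents[j] - {i})) - self.node_score[j]
        d = self._fam(j, frozenset(self.parents[j] - {i})) - self.node_score[j]
        d += self._fam(i, frozenset(self.parents[i] | {j})) - self.node_score[i]
        return d

    def apply(self, move) -> None:
        op, i, j = move
        if op == "add":
            self.parents[j].add(i)
        elif op == "del":
            self.parents[j].discard(i)
        else:
            self.parents[j].discard(i)
            self.parents[i].add(j)
            self.node_score[i] = self._fam(i, frozenset(self.parents[i]))
        self.node_score[j] = self._fam(j, frozenset(self.parents[j]))

    def structure(self) -> BNStructure:
        directed = {(p, c) for c in range(self.V) for p in self.parents[c]}
        return BNStructure(list(self.names), directed, set())


_INVERSE = {"add": "del", "del": "add", "rev": "rev"}


def learn_score(data: DiscreteDataset, method: str = "hill_climbing", *,
                rows: np.ndarray | None = None, tabu_length: int = 10,
                max_nonimproving: int = 100) -> BNStructure:
    """Score-based structure learning by greedy BIC maximisation.

    Single-edge add/delete/reverse moves from the empty graph.
    'hill_climbing' stops at the first local optimum; 'tabu' keeps a
    move-exclusion list (last `tabu_length` inverse moves), accepts the
    best non-tabu move even when it degrades the score, and returns the
    best structure seen within `max_nonimproving` non-improving steps.
    """
    if method not in ("hill_climbing", "tabu"):
        raise ValueError("method must be 'hill_climbing' or 'tabu'")
    engine = _Engine(data.data, rows)
    search = _ScoreSearch(engine, data.names)

    if method == "hill_climbing":
        while True:
            moves = [(search.delta(m), m) for m in search.legal_moves()]
            if not moves:
                break
            best_delta, best_move = max(moves, key=lambda t: t[0])
            if best_delta <= 1e-9:
                break
            search.apply(best_move)
        return search.structure()

    from collections import deque

    tabu: deque = deque(maxlen=tabu_length)
    best_total = search.total()
    best_parents = [set(p) for p in search.parents]
    nonimproving = 0
    while nonimproving <= max_nonimproving:
        candidates = [(search.delta(m), m) for m in search.legal_moves()
                      if m not in tabu]
        if not candidates:
            break
        delta, move = max(candidates, key=lambda t: t[0])
        search.apply(move)
        op, i, j = move
        tabu.append((_INVERSE[op], i, j) if op != "rev" else ("rev", j, i))
        total = search.total()
        if total > best_total + 1e-9:
            best_total = total
            best_parents = [set(p) for p in search.parents]
            nonimproving = 0
        else:
            nonimproving += 1
    search.parents = best_parents
    return search.structure()


_LEARNERS = {
    "grow_shrink": lambda data, rows, kw: learn_grow_shrink(data, rows=rows, **kw),
    "hill_climbing": lambda data, rows, kw: learn_score(
        data, "hill_climbing", rows=rows, **kw),
    "tabu": lambda data, rows, kw: learn_score(data, "tabu", rows=rows, **kw),
}


@dataclass
class ConsensusNetwork:
    """Bootstrap-consensus edges with support frequencies."""

    nodes: list[str]
    support: dict[frozenset, float]          # skeleton support per edge
    direction: dict[frozenset, str]          # "a->b" majority, or "--"
    threshold: float
    params: dict

    @property
    def retained(self) -> set[frozenset]:
        return {e for e, s in self.support.items() if s >= self.threshold}

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.support, key=lambda e: -self.support[e]):
            a, b = sorted(e)
            rows.append({"from": a, "to": b, "support": self.support[e],
                         "direction": self.direction.get(e, "--"),
                         "retained": self.support[e] >= self.threshold})
        return pd.DataFrame(rows)


def bootstrap_consensus(data: DiscreteDataset, learner: str = "grow_shrink", *,
                        fraction: float = 0.9, iterations: int = 100,
                        threshold: float = 0.8, seed=None,
                        **learner_kwargs) -> ConsensusNetwork:
    """Learn a consensus structure over random row subsamples.

    Each iteration draws floor(fraction*N) rows without replacement and
    learns a structure; an edge's support is the fraction of iterations
    whose skeleton contains it (direction-agnostic), and edges at or above
    `threshold` are retained. Direction is annotated by majority vote of
    the directed occurrences.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_rows = int(fraction * data.n)
    if n_rows < 20:
        raise ValueError(f"subsample of {n_rows} rows is unlearnably small")
    if learner not in _LEARNERS:
        raise ValueError(f"unknown learner {learner!r}")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    dir_votes: dict[tuple[int, int], int] = {}
    for _ in range(iterations):
        rows = rng.choice(data.n, size=n_rows, replace=False)
        structure = _LEARNERS[learner](data, rows, learner_kwargs)
        for e in structure.skeleton():
            counts[e] = counts.get(e, 0) + 1
        for a, b in structure.directed:
            dir_votes[(a, b)] = dir_votes.get((a, b), 0) + 1
    support = {frozenset(data.names[i] for i in e): c / iterations
               for e, c in counts.items()}
    direction: dict[frozenset, str] = {}
    for e in counts:
        a, b = sorted(e)
        fwd, rev = dir_votes.get((a, b), 0), dir_votes.get((b, a), 0)
        key = frozenset(data.names[i] for i in e)
        if fwd == rev == 0:
            direction[key] = "--"
        elif fwd >= rev:
            direction[key] = f"{data.names[a]}->{data.names[b]}"
        else:
            direction[key] = f"{data.names[b]}->{data.names[a]}"
    params = {"learner": learner, "fraction": fraction,
              "iterations": iterations, "threshold": threshold,
              **learner_kwargs}
    return ConsensusNetwork(list(data.names), support, direction, threshold, params)


@dataclass
class ControlComparison:
    """Real vs random-region control consensus networks.

    Edges retained in both are flagged nonspecific: they reflect genome-wide
    co-occurrence rather than anything particular to the ROIs.
    """

    real: ConsensusNetwork
    control: ConsensusNetwork

    @property
    def nonspecific(self) -> set[frozenset]:
        return self.real.retained & self.control.retained

    @property
    def specific(self) -> set[frozenset]:
        return self.real.retained - self.control.retained


def control_network(rois: RegionSet, genome: GenomeTable,
                    factor_beds: dict[str, RegionSet],
                    annotations: dict[str, RegionSet] | None = None, *,
                    learner: str = "grow_shrink", seed=None,
                    min_bp: int = 1, **consensus_kwargs) -> ControlComparison:
    """Consensus networks over the real ROIs and a matched random-region set."""
    rng = np.random.default_rng(seed)
    real_data = occupancy_dataset(rois, factor_beds, annotations, min_bp)
    rand_rois = random_regions(rois, genome, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # random regions often give constant cols
        ctrl_data = occupancy_dataset(rand_rois, factor_beds, annotations, min_bp)
    real = bootstrap_consensus(real_data, learner,
                               seed=rng.integers(2**31), **consensus_kwargs)
    control = bootstrap_consensus(ctrl_data, learner,
                                  seed=rng.integers(2**31), **consensus_kwargs)
    return ControlComparison(real, control)
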