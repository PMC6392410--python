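"""Simulated-annealing modularity, run consensus, and topological node roles.

The interaction graph (one node per clade and per family, one edge per
recorded link) is partitioned by maximizing the Newman-Girvan modularity

    M = sum over modules s of [ l_s / L - (d_s / 2L)^2 ]

where l_s is the number of within-module edges, d_s the total degree of the
module's nodes and L the total number of edges.  The optimizer is a
simulated-annealing scheme over single-node moves plus module merge/split
proposals, the approach classically used for (unipartite) ecological
networks; the bipartite graph is treated as unipartite on purpose.

Because independent annealing runs can disagree, module membership is
consolidated across many runs: the highest-M run serves as the reference
partition and a node is assigned to its reference module only if it
co-occurs with that module's stable core in more than a threshold fraction
(default 90%) of the runs.

Node roles follow the z/c scheme: z is the standardized within-module
degree, c = 1 - sum_t (k_it / k_i)^2 the among-module connectivity
(participation coefficient), with the conventional cutoffs z = 2.5 and
c = 0.62 separating peripheral nodes, connectors, module hubs, and network
hubs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .matrix import BipartiteMatrix
from .nulls import NullEnsemble, null_ensemble

__all__ = [
    "Graph",
    "Partition",
    "ConsensusResult",
    "NodeRole",
    "SASchedule",
    "bipartite_to_graph",
    "modularity_index",
    "sa_modularity",
    "consensus_partition",
    "node_roles",
    "classify_role",
    "modularity_significance",
]

Z_CUTOFF = 2.5
C_CUTOFF = 0.62


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph with optional guild tags per node."""

    nodes: tuple
    edges: tuple
    guild: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        nodeset = set(self.nodes)
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self):
        """(neighbors per node index, degree vector, index lookup)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        nbrs = [[] for _ in self.nodes]
        for u, v in self.edges:
            nbrs[idx[u]].append(idx[v])
            nbrs[idx[v]].append(idx[u])
        nbrs = [np.array(sorted(a), dtype=np.int64) for a in nbrs]
        deg = np.array([len(a) for a in nbrs], dtype=np.int64)
        return nbrs, deg, idx


@dataclass(frozen=True)
class Partition:
    membership: dict  # node label -> contiguous module id
    n_modules: int
    m_index: float


@dataclass(frozen=True)
class ConsensusResult:
    runs: tuple
    mean_m: float
    sd_m: float
    module_count_distribution: dict
    co_membership: dict  # frozenset({u, v}) -> co-assignment frequency
    assigned_modules: dict  # node -> module id, or None if unstable
    reference: Partition


@dataclass(frozen=True)
class NodeRole:
    z: float
    c: float
    role: str


@dataclass(frozen=True)
class SASchedule:
    """Annealing schedule; ``None`` fields default to size-dependent values.

    t0 defaults to 1 / n_nodes and moves_per_temp to n_nodes**2; the
    temperature is multiplied by ``cooling`` each step until it falls below
    t0 * t_final_factor.  A deterministic greedy polish (single-node moves to
    a strict local optimum) always follows the annealing phase.
    """

    t0: float | None = None
    cooling: float = 0.995
    moves_per_temp: int | None = None
    t_final_factor: float = 1e-3
    kicks: int = 0  # basin-hopping restarts after the deterministic polish

    def __post_init__(self):
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        if not (0 < self.t_final_factor < 1):
            raise ValueError("t_final_factor must be in (0, 1)")
        if self.kicks < 0:
            raise ValueError("kicks must be >= 0")


def bipartite_to_graph(matrix: BipartiteMatrix) -> Graph:
    """One node per row/column label, one edge per 1-cell."""
    if set(matrix.rows) & set(matrix.cols):
        raise ValueError("row and column labels must be disjoint")
    nodes = tuple(matrix.rows) + tuple(matrix.cols)
    guild = {r: "plant_family" for r in matrix.rows}
    guild.update({c: "bird_clade" for c in matrix.cols})
    ii, jj = np.nonzero(matrix.cells)
    edges = tuple((matrix.rows[i], matrix.cols[j]) for i, j in zip(ii, jj))
    return Graph(nodes, edges, guild)


def modularity_index(graph: Graph, membership: dict) -> float:
    """Newman-Girvan M for a full node partition."""
    if graph.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise ValueError(f"membership misses nodes: {sorted(missing)}")
    L = graph.n_edges
    within = Counter()
    degree = Counter()
    for u, v in graph.edges:
        degree[membership[u]] += 1
        degree[membership[v]] += 1
        if membership[u] == membership[v]:
            within[membership[u]] += 1
    mods = set(membership[n] for n in graph.nodes)
    return sum(within[s] / L - (degree[s] / (2 * L)) ** 2 for s in mods)


def _links_to_modules(i, nbrs, m):
    out = Counter()
    for j in nbrs[i]:
        out[m[j]] += 1
    return out


def _greedy_polish(nbrs, deg, m, L):
    """Hill climb alternating single-node moves and module merges.

    Runs until neither a single-node reassignment nor a pairwise module
    merge improves M, giving a strict local optimum over both move classes.
    """
    n = len(nbrs)
    D = Counter()
    for i in range(n):
        D[m[i]] += deg[i]

    def node_pass():
        improved_any = False
        improved = True
        while improved:
            improved = False
            for i in range(n):
                s = m[i]
                e = _links_to_modules(i, nbrs, m)
                e_is = e.get(s, 0)
                best_gain, best_t = 1e-12, None
                targets = set(D) | {max(D) + 1}
                for t in targets:
                    if t == s:
                        continue
                    gain = (e.get(t, 0) - e_is) / L - deg[i] * (
                        D.get(t, 0) - D[s] + deg[i]
                    ) / (2 * L * L)
                    if gain > best_gain:
                        best_gain, best_t = gain, t
                if best_t is not None:
                    D[s] -= deg[i]
                    if D[s] == 0:
                        del D[s]
                    D[best_t] = D.get(best_t, 0) + deg[i]
                    m[i] = best_t
                    improved = improved_any = True
        return improved_any

    def merge_pass():
        # cross-module edge counts in one sweep
        e_between = Counter()
        for i in range(n):
            for j in nbrs[i]:
                if i < j and m[i] != m[j]:
                    e_between[frozenset((m[i], m[j]))] += 1
        best_gain, best_pair = 1e-12, None
        for pair in e_between:  # zero-cross-edge merges can never gain
            a, b = tuple(pair)
            gain = e_between[pair] / L - D[a] * D[b] / (2 * L * L)
            if gain > best_gain:
                best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            return False
        a, b = best_pair
        for i in range(n):
            if m[i] == b:
                m[i] = a
        D[a] += D.pop(b)
        return True

    def split_pass():
        # Kernighan-Lin-style: peel nodes one by one from a module into a
        # fresh one, tracking cumulative gain, and keep the best prefix if
        # it improves M.  Catches splits where every single move is negative.
        improved_any = False
        for s in list(D.keys()):
            members = [i for i in range(n) if m[i] == s]
            if len(members) < 2:
                continue
            fresh = max(D) + 1
            moved, gains = [], []
            d_s, d_t = D[s], 0
            in_t = set()
            remaining = set(members)
            total = 0.0
            for _ in range(len(members) - 1):
                best_gain, best_i = None, None
                for i in remaining:
                    e_s = e_t = 0
                    for j in nbrs[i]:
                        if j in in_t:
                            e_t += 1
                        elif m[j] == s and j not in in_t:
                            e_s += 1
                    gain = (e_t - e_s) / L - deg[i] * (d_t - d_s + deg[i]) / (2 * L * L)
                    if best_gain is None or gain > best_gain:
                        best_gain, best_i = gain, i
                total += best_gain
                moved.append(best_i)
                gains.append(total)
                remaining.discard(best_i)
                in_t.add(best_i)
                d_s -= deg[best_i]
                d_t += deg[best_i]
            best_k = int(np.argmax(gains)) + 1
            if gains[best_k - 1] > 1e-12:
                for i in moved[:best_k]:
                    m[i] = fresh
                    D[s] -= deg[i]
                    D[fresh] = D.get(fresh, 0) + deg[i]
                if D[s] == 0:
                    del D[s]
                improved_any = True
        return improved_any

    def kl_pass():
        # whole-graph Kernighan-Lin refinement: greedily apply the single
        # best move (any node, any module incl. a fresh one) even when it is
        # negative, locking each moved node, then keep the best prefix of the
        # move sequence if its cumulative gain is positive.  Escapes local
        # optima that need coordinated multi-node rearrangements.
        snapshot = list(m)
        locked = set()
        seq, cum = [], []
        total = 0.0
        for _ in range(n):
            best = None  # (gain, i, s, t)
            fresh = max(D) + 1
            for i in range(n):
                if i in locked:
                    continue
                s = m[i]
                e = _links_to_modules(i, nbrs, m)
                e_is = e.get(s, 0)
                for t in list(D.keys()) + [fresh]:
                    if t == s:
                        continue
                    gain = (e.get(t, 0) - e_is) / L - deg[i] * (
                        D.get(t, 0) - D[s] + deg[i]
                    ) / (2 * L * L)
                    if best is None or gain > best[0]:
                        best = (gain, i, s, t)
            if best is None:
                break
            gain, i, s, t = best
            m[i] = t
            D[s] -= deg[i]
            if D[s] == 0:
                del D[s]
            D[t] = D.get(t, 0) + deg[i]
            locked.add(i)
            total += gain
            seq.append(i)
            cum.append(total)
        if not cum:
            return False
        best_k = int(np.argmax(cum)) + 1
        if cum[best_k - 1] > 1e-12:
            keep = {i: m[i] for i in seq[:best_k]}
            for i in range(n):
                m[i] = keep.get(i, snapshot[i])
        else:
            m[:] = snapshot
        D.clear()
        for i in range(n):
            D[m[i]] += deg[i]
        return cum[best_k - 1] > 1e-12

    while True:
        node_pass()
        if merge_pass():
            continue
        if split_pass():
            continue
        if not kl_pass():
            break
    return m


def sa_modularity(graph: Graph, rng: np.random.Generator, schedule: SASchedule | None = None) -> Partition:
    """Anneal a partition maximizing M; deterministic under a seeded rng.

    Starts from singleton modules; each temperature step proposes
    ``moves_per_temp`` single-node moves (target drawn among existing
    modules plus a fresh one) followed by one merge and one split proposal,
    all accepted by the Metropolis criterion on the change in M.
    """
    if graph.n_edges == 0:
        raise ValueError("cannot partition an edgeless graph")
    schedule = schedule or SASchedule()
    nbrs, deg, idx = graph.adjacency()
    n = graph.n_nodes
    L = graph.n_edges
    t0 = schedule.t0 if schedule.t0 is not None else 1.0 / n
    moves = schedule.moves_per_temp if schedule.moves_per_temp is not None else n * n
    t_final = t0 * schedule.t_final_factor

    m = list(range(n))
    D = Counter({i: int(deg[i]) for i in range(n)})

    def accept(delta, T):
        return delta >= 0 or rng.random() < np.exp(delta / T)

    T = t0
    while T > t_final:
        # single-node moves
        nodes_pick = rng.integers(0, n, size=moves)
        for i in nodes_pick:
            s = m[i]
            labels = list(D.keys())
            fresh = max(labels) + 1
            t = labels[rng.integers(0, len(labels))] if rng.random() > 1.0 / (len(labels) + 1) else fresh
            if t == s:
                continue
            e = _links_to_modules(i, nbrs, m)
            delta = (e.get(t, 0) - e.get(s, 0)) / L - deg[i] * (D.get(t, 0) - D[s] + deg[i]) / (
                2 * L * L
            )
            if accept(delta, T):
                D[s] -= deg[i]
                if D[s] == 0:
                    del D[s]
                D[t] = D.get(t, 0) + deg[i]
                m[i] = t
        # merge proposal
        labels = list(D.keys())
        if len(labels) >= 2:
            a, b = rng.choice(len(labels), size=2, replace=False)
            a, b = labels[a], labels[b]
            e_ab = sum(1 for i in range(n) if m[i] == a for j in nbrs[i] if m[j] == b)
            delta = e_ab / L - D[a] * D[b] / (2 * L * L)
            if accept(delta, T):
                for i in range(n):
                    if m[i] == b:
                        m[i] = a
                D[a] += D.pop(b)
        # split proposal: random bipartition of one module
        labels = list(D.keys())
        s = labels[rng.integers(0, len(labels))]
        members = [i for i in range(n) if m[i] == s]
        if len(members) >= 2:
            side = rng.integers(0, 2, size=len(members))
            if 0 < side.sum() < len(members):
                g1 = [i for i, f in zip(members, side) if f]
                d1 = int(deg[g1].sum())
                d2 = D[s] - d1
                in_g1 = set(g1)
                e12 = sum(1 for i in g1 for j in nbrs[i] if m[j] == s and j not in in_g1)
                delta = -e12 / L + d1 * d2 / (2 * L * L)
                if accept(delta, T):
                    fresh = max(D) + 1
                    for i in g1:
                        m[i] = fresh
                    D[s] = d2
                    D[fresh] = d1
                    if D[s] == 0:
                        del D[s]
        T *= schedule.cooling

    def m_value(mm):
        D_ = Counter()
        within2 = 0
        for i in range(n):
            D_[mm[i]] += deg[i]
            for j in nbrs[i]:
                if mm[j] == mm[i]:
                    within2 += 1
        return within2 / (2 * L) - sum((d / (2 * L)) ** 2 for d in D_.values())

    # deterministic polish from the annealed state and from singletons
    candidates = [
        _greedy_polish(nbrs, deg, list(m), L),
        _greedy_polish(nbrs, deg, list(range(n)), L),
    ]
    m = max(candidates, key=m_value)
    best_val = m_value(m)
    # optional basin hopping: perturb a quarter of the nodes and re-polish
    for _ in range(schedule.kicks):
        trial = list(m)
        labels = sorted(set(trial))
        fresh = max(labels) + 1
        for i in rng.choice(n, size=max(1, n // 4), replace=False):
            trial[i] = int(rng.choice(labels + [fresh]))
        trial = _greedy_polish(nbrs, deg, trial, L)
        val = m_value(trial)
        if val > best_val + 1e-15:
            m, best_val = trial, val
    # contiguous ids in order of first appearance
    relabel = {}
    for v in m:
        if v not in relabel:
            relabel[v] = len(relabel)
    membership = {node: relabel[m[idx[node]]] for node in graph.nodes}
    return Partition(membership, len(relabel), modularity_index(graph, membership))


def consensus_partition(
    graph: Graph,
    n_runs: int = 50,
    threshold: float = 0.9,
    rng: np.random.Generator | None = None,
    schedule: SASchedule | None = None,
) -> ConsensusResult:
    """Consolidate repeated annealing runs into stable module memberships.

    Raw module ids are not comparable across runs, so stability is measured
    by pairwise co-membership frequency.  The highest-M run is the reference
    partition; each reference module's *core* is the subset of its members
    that always co-occur across runs (falling back to its most coherent
    member if no pair is fully stable), and a node is assigned iff its mean
    co-membership with the core exceeds ``threshold``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    runs = tuple(sa_modularity(graph, rng, schedule) for _ in range(n_runs))
    ms = np.array([p.m_index for p in runs])
    nodes = graph.nodes
    n = len(nodes)
    co = np.zeros((n, n))
    for p in runs:
        vec = np.array([p.membership[u] for u in nodes])
        co += vec[:, None] == vec[None, :]
    co /= n_runs

    ref = runs[int(np.argmax(ms))]
    assigned = {}
    for mod in range(ref.n_modules):
        members = [i for i, u in enumerate(nodes) if ref.membership[u] == mod]
        core = [i for i in members if all(co[i, j] == 1.0 for j in members)]
        if not core:
            core = [max(members, key=lambda i: co[i, members].mean())]
        for i, u in enumerate(nodes):
            if ref.membership[u] != mod:
                continue
            freq = co[i, core].mean()
            assigned[u] = mod if freq > threshold else None

    counts = Counter(p.n_modules for p in runs)
    co_dict = {
        frozenset((nodes[i], nodes[j])): co[i, j] for i in range(n) for j in range(i + 1, n)
    }
    return ConsensusResult(
        runs=runs,
        mean_m=float(ms.mean()),
        sd_m=float(ms.std(ddof=1)),
        module_count_distribution={k: v / n_runs for k, v in counts.items()},
        co_membership=co_dict,
        assigned_modules=assigned,
        reference=ref,
    )


def classify_role(z: float, c: float) -> str:
    """z/c quadrant at the conventional cutoffs (ties fall to the low side)."""
    hub = z > Z_CUTOFF
    conn = c > C_CUTOFF
    if hub and conn:
        return "network_hub"
    if hub:
        return "module_hub"
    if conn:
        return "connector"
    return "peripheral"


def node_roles(graph: Graph, partition: Partition) -> dict:
    """Standardized within-module degree z and participation coefficient c.

    z standardizes a node's within-module degree against its module's mean
    and (population) sd, with z = 0 for degenerate modules where the sd
    vanishes; c = 1 - sum over modules of the squared fraction of the node's
    links falling in each module.
    """
    nbrs, deg, idx = graph.adjacency()
    members = {}
    for u in graph.nodes:
        members.setdefault(partition.membership[u], []).append(idx[u])
    within = np.zeros(graph.n_nodes)
    m = [partition.membership[u] for u in graph.nodes]
    for u in graph.nodes:
        i = idx[u]
        within[i] = sum(1 for j in nbrs[i] if m[j] == m[i])

    roles = {}
    for u in graph.nodes:
        i = idx[u]
        mod = members[partition.membership[u]]
        mu, sd = within[mod].mean(), within[mod].std()
        z = (within[i] - mu) / sd if sd > 0 else 0.0
        counts = Counter(m[j] for j in nbrs[i])
        c = 1.0 - sum((v / deg[i]) ** 2 for v in counts.values())
        roles[u] = NodeRole(float(z), float(c), classify_role(z, c))
    return roles


def modularity_significance(
    matrix: BipartiteMatrix,
    consensus: ConsensusResult,
    rng: np.random.Generator,
    n_er: int = 100,
    n_ff: int = 100,
    schedule: SASchedule | None = None,
    best_of: int = 1,
) -> dict:
    """Observed mean M (over the consensus runs) vs ER and FF null networks.

    Each null matrix is converted to its interaction graph and annealed
    ``best_of`` times, keeping the best M.  SES can be negative -- a network
    *less* modular than chance is reported as such.
    """

    def stat(mat: BipartiteMatrix) -> float:
        g = bipartite_to_graph(mat)
        return max(sa_modularity(g, rng, schedule).m_index for _ in range(best_of))

    out = {}
    for model, reps in (("ER", n_er), ("FF", n_ff)):
        out[model] = null_ensemble(matrix, stat, model, reps, rng, observed=consensus.mean_m)
    return out
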