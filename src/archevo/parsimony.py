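"""Weighted-parsimony (Sankoff) reconstruction of ancestral genome profiles.

The character is the whole genome profile, so the state space is not fixed
in advance: a finite *state universe* is built from the observed tip
profiles (plus any root constraint) closed under a bounded number of
single grammar events, gains excluded.  Branch transition costs are
shortest-path costs in the event graph induced on that universe
(single-event edges between universe members, including finite-cost gain
edges), memoized as an all-pairs matrix.  Branch lengths are ignored:
parsimony weighs events, not time.

The dynamic program is the standard Sankoff bottom-up pass followed by a
top-down traceback that enumerates every minimum-cost assignment up to a
cap, with an explicit truncation flag — ties are surfaced, not hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .distance import DEFAULT_MAX_COST, EventPath
from .model import (
    DEFAULT_ALPHABET,
    DEFAULT_CAPS,
    DEFAULT_COSTS,
    Alphabet,
    CostModel,
    Event,
    EventType,
    Profile,
    StateCaps,
    classify_event,
    enumerate_events,
)
from .treeio import Node, Phylogeny

_TOL = 1e-9


class UniverseError(ValueError):
    """State-universe construction failed (too large or bad arguments)."""


@dataclass(frozen=True)
class StateUniverse:
    """Finite profile set over which ancestral states are searched."""

    profiles: tuple[Profile, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.profiles)) != len(self.profiles):
            raise UniverseError("universe contains duplicate profiles")

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, p: Profile) -> bool:
        return p in set(self.profiles)

    def index(self) -> dict[Profile, int]:
        return {p: i for i, p in enumerate(self.profiles)}


def build_universe(
    tips: Mapping[str, Profile],
    root_constraint: Optional[Profile] = None,
    depth: int = 2,
    caps: StateCaps = DEFAULT_CAPS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_states: int = 5000,
) -> StateUniverse:
    """Closure of tip profiles (∪ constraint) under ``depth`` single events.

    Gains are excluded from the closure (they would make it explode and
    are already reachable as direct edges in the induced graph).  Raises
    :class:`UniverseError` when the closure exceeds ``max_states``;
    reduce ``depth`` in that case.
    """
    if not tips:
        raise UniverseError("build_universe requires at least one tip profile")
    if depth < 0 or depth > 3:
        raise UniverseError("universe closure depth must be between 0 and 3")
    seeds = set(tips.values())
    if root_constraint is not None:
        seeds.add(root_constraint)
    for p in seeds:
        caps.check(p)
    universe = set(seeds)
    frontier = set(seeds)
    for _ in range(depth):
        new: set[Profile] = set()
        for profile in frontier:
            for _event, neighbor in enumerate_events(
                profile, caps, allow_gain=False, alphabet=alphabet
            ):
                if neighbor not in universe:
                    new.add(neighbor)
        universe |= new
        if len(universe) > max_states:
            raise UniverseError(
                f"universe exceeds {max_states} states at depth {depth}; "
                "use a smaller closure depth"
            )
        frontier = new
        if not frontier:
            break
    ordered = tuple(sorted(universe, key=lambda p: p.text))
    note = (
        f"{len(seeds)} seed profiles ({len(tips)} tips"
        + (", root constraint" if root_constraint is not None else "")
        + f") closed under <= {depth} single events (gains excluded)"
    )
    return StateUniverse(ordered, note)


@dataclass
class TransitionCosts:
    """Memoized all-pairs minimal event costs between universe states."""

    universe: StateUniverse
    costs: CostModel
    caps: StateCaps
    alphabet: Alphabet
    max_cost: float
    matrix: np.ndarray
    _adj: dict[int, list[tuple[int, float, Event]]]
    _path_cache: dict[tuple[int, int], EventPath] = field(default_factory=dict)

    def cost(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def path(self, i: int, j: int) -> EventPath:
        """Reconstruct one minimal event path between universe states i -> j."""
        key = (i, j)
        if key in self._path_cache:
            return self._path_cache[key]
        if i == j:
            path = EventPath((), 0.0)
        else:
            if not math.isfinite(self.matrix[i, j]):
                raise UniverseError(
                    f"no in-universe path {self.universe.profiles[i].text!r} -> "
                    f"{self.universe.profiles[j].text!r}"
                )
            # small Dijkstra with predecessor tracking, restricted to the universe
            import heapq

            best = {i: 0.0}
            prev: dict[int, tuple[int, Event]] = {}
            heap = [(0.0, self.universe.profiles[i].text, i)]
            while heap:
                cost, _text, u = heapq.heappop(heap)
                if cost > best.get(u, math.inf) + _TOL:
                    continue
                if u == j:
                    break
                for v, w, event in self._adj[u]:
                    nc = cost + w
                    if nc < best.get(v, math.inf) - _TOL:
                        best[v] = nc
                        prev[v] = (u, event)
                        heapq.heappush(heap, (nc, self.universe.profiles[v].text, v))
            events: list[Event] = []
            cur = j
            while cur != i:
                p, event = prev[cur]
                events.append(event)
                cur = p
            events.reverse()
            path = EventPath(tuple(events), float(self.matrix[i, j]))
        self._path_cache[key] = path
        return path


def transition_costs(
    universe: StateUniverse,
    costs: CostModel = DEFAULT_COSTS,
    caps: StateCaps = DEFAULT_CAPS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_cost: float = DEFAULT_MAX_COST,
) -> TransitionCosts:
    """All-pairs minimal costs over the universe-induced event graph."""
    idx = universe.index()
    n = len(universe)
    cost_table = dict(costs.items)
    gain_cost = cost_table[EventType.GENE_GAIN]
    allow_gain = math.isfinite(gain_cost)
    gain_pool = sorted({g for p in universe.profiles for g in p.genes}) if allow_gain else None

    adj: dict[int, list[tuple[int, float, Event]]] = {i: [] for i in range(n)}
    rows, cols, vals = [], [], []
    edge_best: dict[tuple[int, int], float] = {}
    for i, profile in enumerate(universe.profiles):
        for event, neighbor in enumerate_events(
            profile, caps, allow_gain=allow_gain, gain_pool=gain_pool, alphabet=alphabet
        ):
            j = idx.get(neighbor)
            if j is None or j == i:
                continue
            w = cost_table[event.type]
            adj[i].append((j, w, event))
            if w < edge_best.get((i, j), math.inf):
                edge_best[(i, j)] = w
    for (i, j), w in edge_best.items():
        rows.append(i)
        cols.append(j)
        vals.append(w)

    if n == 1:
        matrix = np.zeros((1, 1))
    elif all(v > 0 for v in vals):
        graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
        matrix = _sp_dijkstra(graph, directed=True, limit=max_cost)
    else:
        # zero-cost edges would be dropped by the sparse representation;
        # fall back to a dense Bellman-Ford-style relaxation
        matrix = np.full((n, n), np.inf)
        np.fill_diagonal(matrix, 0.0)
        dense = np.full((n, n), np.inf)
        np.fill_diagonal(dense, 0.0)
        for (i, j), w in edge_best.items():
            dense[i, j] = min(dense[i, j], w)
        for _ in range(n):
            updated = np.minimum(matrix, (matrix[:, :, None] + dense[None, :, :]).min(axis=1))
            if np.allclose(updated, matrix, equal_nan=True):
                break
            matrix = updated
        matrix[matrix > max_cost] = np.inf
    return TransitionCosts(universe, costs, caps, alphabet, max_cost, matrix, adj)


@dataclass
class Reconstruction:
    """One most-parsimonious assignment of profiles to every node."""

    assignment: dict[int, Profile]  # node id -> profile
    branch_paths: dict[int, EventPath]  # child node id -> path from parent state
    total_cost: float


@dataclass
class SankoffResult:
    """The full MPR set plus summary facts about the optimum."""

    reconstructions: list[Reconstruction]
    total_cost: float
    optimal_root_profiles: tuple[Profile, ...]
    truncated: bool
    universe: StateUniverse

    def __iter__(self):
        return iter(self.reconstructions)

    def __len__(self) -> int:
        return len(self.reconstructions)


def sankoff(
    tree: Phylogeny,
    tips: Mapping[str, Profile],
    costs: CostModel = DEFAULT_COSTS,
    universe: Optional[StateUniverse] = None,
    root_constraint: Optional[Profile] = None,
    max_mprs: int = 256,
    caps: StateCaps = DEFAULT_CAPS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_cost: float = DEFAULT_MAX_COST,
    universe_depth: int = 2,
    transitions: Optional[TransitionCosts] = None,
) -> SankoffResult:
    """Weighted-parsimony ancestral reconstruction on a rooted tree.

    Every tip named in the tree must appear in ``tips``.  When ``universe``
    is omitted it is built from the tips (and constraint) at
    ``universe_depth``.  All returned reconstructions share the same,
    minimal total cost; the enumeration stops at ``max_mprs`` and flags
    truncation.
    """
    for name in tree.tip_names():
        if name not in tips:
            raise KeyError(f"tip {name!r} has no profile")
    if universe is None:
        observed = {name: tips[name] for name in tree.tip_names()}
        universe = build_universe(
            observed, root_constraint, depth=universe_depth, caps=caps, alphabet=alphabet
        )
    if root_constraint is not None and root_constraint not in universe:
        raise UniverseError(f"root constraint {root_constraint.text!r} outside the universe")
    if transitions is None:
        transitions = transition_costs(universe, costs, caps, alphabet, max_cost)
    D = transitions.matrix
    idx = universe.index()
    n = len(universe)

    # bottom-up scores: S[node id] = vector of length n
    S: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            vec = np.full(n, np.inf)
            profile = tips[node.name]  # type: ignore[index]
            if profile not in idx:
                raise UniverseError(f"tip profile {profile.text!r} outside the universe")
            vec[idx[profile]] = 0.0
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec = vec + np.min(D + S[child.id][None, :], axis=1)
        S[node.id] = vec

    root_scores = S[tree.root.id]
    if root_constraint is not None:
        total = float(root_scores[idx[root_constraint]])
        root_states = [idx[root_constraint]]
        if not math.isfinite(total):
            raise UniverseError("root constraint unreachable from the observed tips")
    else:
        total = float(np.min(root_scores))
        if not math.isfinite(total):
            raise UniverseError(
                "no finite-cost reconstruction inside the universe; "
                "increase the closure depth or max_cost"
            )
        root_states = [int(s) for s in np.flatnonzero(root_scores <= total + _TOL)]

    # top-down traceback: enumerate optimal child states per (node, parent state)
    def child_choices(child: Node, parent_state: int) -> list[int]:
        vec = D[parent_state, :] + S[child.id]
        m = float(np.min(vec))
        return [int(s) for s in np.flatnonzero(vec <= m + _TOL)]

    internal = [node for node in tree.preorder()]
    reconstructions: list[dict[int, int]] = []

    def assign(order_pos: int, current: dict[int, int]) -> bool:
        """DFS over preorder nodes; returns False once one extra MPR past the cap is seen."""
        if order_pos == len(internal):
            reconstructions.append(dict(current))
            return len(reconstructions) <= max_mprs
        node = internal[order_pos]
        if node is tree.root:
            options = root_states
        else:
            options = child_choices(node, current[node.parent.id])  # type: ignore[union-attr]
        for state in options:
            current[node.id] = state
            if not assign(order_pos + 1, current):
                return False
            del current[node.id]
        return True

    assign(0, {})
    truncated = len(reconstructions) > max_mprs
    reconstructions = reconstructions[:max_mprs]

    out: list[Reconstruction] = []
    for rec in reconstructions:
        assignment = {nid: universe.profiles[s] for nid, s in rec.items()}
        branch_paths: dict[int, EventPath] = {}
        cost_sum = 0.0
        for node in tree.preorder():
            if node is tree.root:
                continue
            i, j = rec[node.parent.id], rec[node.id]  # type: ignore[union-attr]
            path = transitions.path(i, j)
            branch_paths[node.id] = path
            cost_sum += path.total_cost
        out.append(Reconstruction(assignment, branch_paths, cost_sum))
        if abs(cost_sum - total) > 1e-6:
            raise AssertionError(
                f"traceback produced cost {cost_sum}, expected {total}"
            )
    opt_roots = tuple(sorted({universe.profiles[s] for s in root_states}, key=lambda p: p.text))
    return SankoffResult(out, total, opt_roots, truncated, universe)


def extract_events(rec: Reconstruction) -> list[tuple[int, Event]]:
    """Flatten a reconstruction into (branch child-node id, event) pairs."""
    out: list[tuple[int, Event]] = []
    for child_id in sorted(rec.branch_paths):
        for event in rec.branch_paths[child_id].events:
            out.append((child_id, event))
    return out


def count_by_type(events: Sequence[tuple[object, Event]]) -> dict[str, int]:
    """Per-type event counts plus the ``fissions_total`` convenience sum."""
    counts = {t.value: 0 for t in EventType}
    for _branch, event in events:
        parent = event.inputs[0] if event.inputs else None
        counts[classify_event(parent, event).value] += 1
    counts["fissions_total"] = (
        counts[EventType.FISSION_SEPARATION.value]
        + counts[EventType.FISSION_DOMAIN_LOSS.value]
    )
    return counts
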