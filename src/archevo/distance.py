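"""Minimum-cost event paths between genome profiles.

``event_distance`` runs a deterministic uniform-cost (Dijkstra) search over
the directed profile graph generated by the event grammar.  Gene gains are
enabled only when their cost is finite; the search radius is capped by
``max_cost`` so that a pair that is only reachable through exorbitant gain
chains is reported as unreachable rather than searched forever.

``brute_force_distance`` is a depth-limited exhaustive enumeration kept
deliberately independent of the Dijkstra implementation; it serves as the
oracle in the test suite.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

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
    enumerate_events,
)

#: Default search radius; ample for the folate case study while preventing
#: runaway search when gains are disabled-by-cost.
DEFAULT_MAX_COST = 12.0


@dataclass(frozen=True)
class EventPath:
    """An ordered event list transforming a source profile into a target."""

    events: tuple[Event, ...]
    total_cost: float

    def __len__(self) -> int:
        return len(self.events)


@lru_cache(maxsize=200_000)
def _neighbors(
    profile: Profile,
    caps: StateCaps,
    allow_gain: bool,
    alphabet: Alphabet,
) -> tuple[tuple[Event, Profile], ...]:
    return tuple(enumerate_events(profile, caps, allow_gain=allow_gain, alphabet=alphabet))


def event_distance(
    source: Profile,
    target: Profile,
    costs: CostModel = DEFAULT_COSTS,
    caps: StateCaps = DEFAULT_CAPS,
    max_cost: float = DEFAULT_MAX_COST,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> Optional[EventPath]:
    """Minimum-total-cost event path, or ``None`` if unreachable within ``max_cost``.

    Deterministic tie-break: among equal-cost frontier entries the profile
    with the smallest canonical text is expanded first, so the reported
    path is stable across runs.
    """
    if max_cost < 0:
        raise ValueError("max_cost must be >= 0")
    caps.check(source)
    caps.check(target)
    if source == target:
        return EventPath((), 0.0)
    cost_table = dict(costs.items)
    allow_gain = math.isfinite(cost_table[EventType.GENE_GAIN])

    # admissible, consistent lower bound: a domain type present in the
    # target but absent from a profile can only appear through a gene gain;
    # a type present in a profile but absent from the target can only
    # vanish through a deletion or a gene loss.
    target_types = frozenset(t for g in target.genes for t in g.domains)
    gain_cost = cost_table[EventType.GENE_GAIN]
    removal_cost = min(
        cost_table[EventType.FISSION_DOMAIN_LOSS],
        cost_table[EventType.DOMAIN_CONTRACTION],
        cost_table[EventType.GENE_LOSS],
    )

    def remaining(profile: Profile) -> float:
        types = frozenset(t for g in profile.genes for t in g.domains)
        h = 0.0
        if target_types - types:
            h += gain_cost  # inf when gains are disabled-by-cost
        if types - target_types:
            h += removal_cost
        return h

    if not math.isfinite(remaining(source)):
        return None

    best: dict[str, float] = {source.text: 0.0}
    prev: dict[str, tuple[str, Event, Profile]] = {}
    heap: list[tuple[float, str]] = [(remaining(source), source.text)]
    state_of = {source.text: source}
    target_text = target.text

    while heap:
        fcost, text = heapq.heappop(heap)
        cost = best.get(text, math.inf)
        if fcost > cost + remaining(state_of[text]) + 1e-12:
            continue
        if text == target_text:
            events: list[Event] = []
            cur = text
            while cur != source.text:
                p_text, event, _ = prev[cur]
                events.append(event)
                cur = p_text
            events.reverse()
            return EventPath(tuple(events), cost)
        profile = state_of[text]
        for event, neighbor in _neighbors(profile, caps, allow_gain, alphabet):
            ncost = cost + cost_table[event.type]
            h = remaining(neighbor)
            if ncost + h > max_cost:
                continue
            ntext = neighbor.text
            if ncost < best.get(ntext, math.inf):
                best[ntext] = ncost
                prev[ntext] = (text, event, neighbor)
                state_of[ntext] = neighbor
                heapq.heappush(heap, (ncost + h, ntext))
    return None


def all_optimal_paths(
    source: Profile,
    target: Profile,
    costs: CostModel = DEFAULT_COSTS,
    caps: StateCaps = DEFAULT_CAPS,
    max_cost: float = DEFAULT_MAX_COST,
    max_paths: int = 64,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> list[EventPath]:
    """Enumerate minimum-cost paths (capped at ``max_paths``)."""
    shortest = event_distance(source, target, costs, caps, max_cost, alphabet)
    if shortest is None:
        return []
    opt = shortest.total_cost
    cost_table = dict(costs.items)
    allow_gain = math.isfinite(cost_table[EventType.GENE_GAIN])
    out: list[EventPath] = []

    def rec(profile: Profile, cost: float, events: tuple[Event, ...]) -> None:
        if len(out) >= max_paths:
            return
        if profile == target and math.isclose(cost, opt, abs_tol=1e-9):
            out.append(EventPath(events, cost))
            return
        for event, neighbor in _neighbors(profile, caps, allow_gain, alphabet):
            ncost = cost + cost_table[event.type]
            if ncost > opt + 1e-9:
                continue
            # tail search bounded by the remaining optimal budget
            tail = event_distance(neighbor, target, costs, caps, opt - ncost + 1e-9, alphabet)
            if tail is not None and math.isclose(ncost + tail.total_cost, opt, abs_tol=1e-9):
                rec(neighbor, ncost, events + (event,))

    rec(source, 0.0, ())
    return out


def brute_force_distance(
    source: Profile,
    target: Profile,
    costs: CostModel = DEFAULT_COSTS,
    caps: StateCaps = DEFAULT_CAPS,
    max_depth: int = 4,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> Optional[EventPath]:
    """Exhaustive enumeration of event sequences up to ``max_depth`` events.

    Runs iterative deepening: every sequence length up to ``max_depth`` is
    enumerated, with two exactness-preserving prunes — branch-and-bound
    against the best complete path found in earlier (shorter) rounds, and
    dominance pruning of branches reaching an already-seen profile at no
    lower cost and no greater depth.  Intended for small depths (<= 4) as
    a test oracle; independent of the uniform-cost search.
    """
    if max_depth < 1 or max_depth > 6:
        raise ValueError("brute_force_distance expects 1 <= max_depth <= 6")
    caps.check(source)
    caps.check(target)
    if source == target:
        return EventPath((), 0.0)
    cost_table = dict(costs.items)
    allow_gain = math.isfinite(cost_table[EventType.GENE_GAIN])

    best_path: list[Optional[EventPath]] = [None]
    best_cost = [math.inf]

    for depth_cap in range(1, max_depth + 1):
        # text -> list of (cost, depth) pareto records for this round
        seen: dict[str, list[tuple[float, int]]] = {}

        def dominated(text: str, cost: float, depth: int) -> bool:
            for c, d in seen.get(text, ()):
                if c <= cost + 1e-12 and d <= depth:
                    return True
            return False

        def rec(profile: Profile, cost: float, depth: int, events: tuple[Event, ...]) -> None:
            if profile == target and cost < best_cost[0] - 1e-12:
                best_cost[0] = cost
                best_path[0] = EventPath(events, cost)
            if depth >= depth_cap:
                return
            for event, neighbor in _neighbors(profile, caps, allow_gain, alphabet):
                ncost = cost + cost_table[event.type]
                if ncost >= best_cost[0] - 1e-12:
                    continue
                ntext = neighbor.text
                if dominated(ntext, ncost, depth + 1):
                    continue
                seen.setdefault(ntext, []).append((ncost, depth + 1))
                rec(neighbor, ncost, depth + 1, events + (event,))

        rec(source, 0.0, 0, ())
    return best_path[0]
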