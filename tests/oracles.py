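"""Independent oracles for the test suite.

These deliberately avoid the production search/DP code paths: pairwise
costs come from a Floyd-Warshall relaxation over single-event edges, and
the ancestral-reconstruction optimum from a full product enumeration of
universe states over internal nodes.
"""

import itertools
import math

from archevo.model import (
    DEFAULT_ALPHABET,
    DEFAULT_CAPS,
    DEFAULT_COSTS,
    EventType,
    enumerate_events,
)


def induced_pair_costs(profiles, costs=DEFAULT_COSTS, caps=DEFAULT_CAPS,
                       alphabet=DEFAULT_ALPHABET, max_cost=12.0):
    """All-pairs shortest-path costs over the event graph induced on ``profiles``."""
    idx = {p: i for i, p in enumerate(profiles)}
    n = len(profiles)
    cost_table = dict(costs.items)
    allow_gain = math.isfinite(cost_table[EventType.GENE_GAIN])
    gain_pool = sorted({g for p in profiles for g in p.genes}) if allow_gain else None
    D = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        D[i][i] = 0.0
    for i, p in enumerate(profiles):
        for event, neighbor in enumerate_events(
            p, caps, allow_gain=allow_gain, gain_pool=gain_pool, alphabet=alphabet
        ):
            j = idx.get(neighbor)
            if j is not None:
                D[i][j] = min(D[i][j], cost_table[event.type])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    for i in range(n):
        for j in range(n):
            if D[i][j] > max_cost:
                D[i][j] = math.inf
    return D


def exhaustive_min_cost(tree, tips, profiles, D, root_constraint=None):
    """Minimum total cost over every ancestral assignment (brute product)."""
    idx = {p: i for i, p in enumerate(profiles)}
    internal = [n for n in tree.nodes() if not n.is_tip]
    fixed = {n.id: idx[tips[n.name]] for n in tree.tips()}
    best = math.inf
    options = []
    for node in internal:
        if node is tree.root and root_constraint is not None:
            options.append([idx[root_constraint]])
        else:
            options.append(range(len(profiles)))
    for combo in itertools.product(*options):
        assign = dict(fixed)
        for node, state in zip(internal, combo):
            assign[node.id] = state
        total = 0.0
        for node in tree.nodes():
            if node.parent is None:
                continue
            total += D[assign[node.parent.id]][assign[node.id]]
            if total >= best:
                break
        best = min(best, total)
    return best
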