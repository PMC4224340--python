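"""Stated per-branch event histories: play them forward, check them, count them.

A :class:`Scenario` is a narrative reconstruction — a root profile plus an
ordered list of events placed on branches (addressed by the child node's
name, so tips use taxon names and internal events use clade labels).
``play_scenario`` propagates the root state down the tree applying each
branch's events in order; ``validate_scenario`` compares the implied tip
profiles with the observed ones; ``summarize_scenario`` classifies every
placement with the grammar's pure classifier and reports per-type counts
(with the fission total) and the total cost under a cost model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .model import (
    DEFAULT_CAPS,
    DEFAULT_COSTS,
    ApplicationError,
    CostModel,
    Event,
    EventType,
    Profile,
    StateCaps,
    apply_event,
    classify_event,
)
from .treeio import Phylogeny, TreeError


class ScenarioError(ValueError):
    """A scenario inconsistent with its tree or the event grammar."""


@dataclass(frozen=True)
class Scenario:
    root_state: Profile
    placements: tuple[tuple[str, Event], ...]  # (child-node name, event), ordered
    label: str = ""


@dataclass
class ScenarioReport:
    """Per-tip match/mismatch plus grammar validity of a scenario."""

    valid: bool
    tip_mismatches: list[tuple[str, str, str]]  # (taxon, implied text, observed text)
    grammar_errors: list[str]
    implied_tips: dict[str, Profile]


def _events_by_branch(tree: Phylogeny, scenario: Scenario) -> dict[int, list[Event]]:
    by_branch: dict[int, list[Event]] = {}
    for child_name, event in scenario.placements:
        try:
            node = tree.node_by_name(child_name)
        except TreeError as exc:
            raise ScenarioError(str(exc)) from exc
        if node is tree.root:
            raise ScenarioError(f"cannot place an event above the root ({child_name!r})")
        by_branch.setdefault(node.id, []).append(event)
    return by_branch


def play_scenario(
    tree: Phylogeny, scenario: Scenario, caps: StateCaps = DEFAULT_CAPS
) -> dict[int, Profile]:
    """Implied profile at every node; raises on a grammar-violating placement."""
    by_branch = _events_by_branch(tree, scenario)
    states: dict[int, Profile] = {tree.root.id: scenario.root_state}
    for node in tree.preorder():
        if node is tree.root:
            continue
        state = states[node.parent.id]  # type: ignore[union-attr]
        for event in by_branch.get(node.id, ()):
            try:
                state = apply_event(state, event, caps)
            except ApplicationError as exc:
                raise ScenarioError(
                    f"event {event.describe()!r} on branch to "
                    f"{node.name or node.id}: {exc}"
                ) from exc
        states[node.id] = state
    return states


def validate_scenario(
    tree: Phylogeny,
    scenario: Scenario,
    observed_tips: Mapping[str, Profile],
    caps: StateCaps = DEFAULT_CAPS,
) -> ScenarioReport:
    """Report — never raise — on tip reproduction and grammar validity."""
    grammar_errors: list[str] = []
    try:
        states = play_scenario(tree, scenario, caps)
    except ScenarioError as exc:
        return ScenarioReport(False, [], [str(exc)], {})
    implied = {node.name: states[node.id] for node in tree.tips()}  # type: ignore[misc]
    mismatches: list[tuple[str, str, str]] = []
    for taxon, profile in sorted(implied.items()):
        observed = observed_tips.get(taxon)
        if observed is None:
            grammar_errors.append(f"tip {taxon!r} has no observed profile")
        elif observed != profile:
            mismatches.append((taxon, profile.text, observed.text))
    valid = not mismatches and not grammar_errors
    return ScenarioReport(valid, mismatches, grammar_errors, implied)


@dataclass
class ScenarioSummary:
    counts: dict[str, int]  # per event type, plus fissions_total
    total_cost: float
    n_events: int


def summarize_scenario(
    tree: Phylogeny,
    scenario: Scenario,
    costs: CostModel = DEFAULT_COSTS,
    caps: StateCaps = DEFAULT_CAPS,
) -> ScenarioSummary:
    """Classify and count the scenario's events; cost = sum of per-type costs.

    Counts are computed by running each placement through
    :func:`classify_event`, never read off stored labels.  A scenario that
    violates the grammar is refused — run :func:`validate_scenario` for a
    diagnostic report.
    """
    try:
        play_scenario(tree, scenario, caps)  # grammar check
    except ScenarioError as exc:
        raise ScenarioError(
            f"scenario is not grammar-valid ({exc}); see validate_scenario"
        ) from exc
    counts = {t.value: 0 for t in EventType}
    total_cost = 0.0
    table = dict(costs.items)
    for _branch, event in scenario.placements:
        parent = event.inputs[0] if event.inputs else None
        etype = classify_event(parent, event)
        counts[etype.value] += 1
        total_cost += table[etype]
    counts["fissions_total"] = (
        counts[EventType.FISSION_SEPARATION.value]
        + counts[EventType.FISSION_DOMAIN_LOSS.value]
    )
    return ScenarioSummary(counts, total_cost, len(scenario.placements))
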