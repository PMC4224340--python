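"""Plain-text formats: profile tables, scenario tables, cost/rate configs.

Profiles travel as two-column TSV (``taxon``, ``profile``; extra columns
such as provenance notes are preserved but ignored).  Scenarios are TSV
with columns ``child_node  event_type  inputs  outputs  detail``; the root
state is a special first row with ``child_node = (root)`` and
``event_type = root_state``.  Cost and rate overrides are flat
``key = value`` files keyed by event-type name; unknown keys are hard
errors, because a silently ignored typo would corrupt an inference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .model import (
    DEFAULT_ALPHABET,
    Alphabet,
    Architecture,
    CostModel,
    Event,
    EventType,
    Profile,
    parse_architecture,
    parse_profile,
)
from .scenario import Scenario, ScenarioError
from .simulate import RateModel

PathLike = Union[str, Path]

ROOT_ROW = "(root)"

#: Operational spellings accepted in scenario files.  Deletions are written
#: as plain ``deletion`` and classified by the grammar (fission by domain
#: loss vs domain contraction) from the acted-on gene.
_EVENT_ALIASES = {
    "fusion": "fusion",
    "separation": "separation",
    "fission_separation": "separation",
    "deletion": "deletion",
    "fission_domain_loss": "deletion",
    "domain_contraction": "deletion",
    "duplication": "duplication",
    "domain_duplication": "duplication",
    "loss": "loss",
    "gene_loss": "loss",
    "gain": "gain",
    "gene_gain": "gain",
}


def read_profiles(path: PathLike, alphabet: Alphabet = DEFAULT_ALPHABET) -> dict[str, Profile]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "taxon" not in df.columns or "profile" not in df.columns:
        raise ValueError(f"{path}: profile table needs 'taxon' and 'profile' columns")
    out: dict[str, Profile] = {}
    for _, row in df.iterrows():
        taxon = row["taxon"].strip()
        if taxon in out:
            raise ValueError(f"{path}: duplicate taxon {taxon!r}")
        out[taxon] = parse_profile(row["profile"], alphabet)
    return out


def write_profiles(profiles: Mapping[str, Profile], path: PathLike) -> None:
    df = pd.DataFrame(
        {"taxon": list(profiles), "profile": [p.text for p in profiles.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_span(detail: str) -> tuple[int, int]:
    start, stop = detail.split(":")
    return int(start), int(stop)


def _row_event(event_type: str, inputs: str, outputs: str, detail: str, alphabet: Alphabet) -> Event:
    kind = _EVENT_ALIASES.get(event_type.strip().lower())
    if kind is None:
        raise ScenarioError(f"unknown event type {event_type!r}")
    in_archs = (
        [parse_architecture(s, alphabet) for s in inputs.split(";")] if inputs.strip() else []
    )
    if kind == "fusion":
        if len(in_archs) != 2:
            raise ScenarioError("fusion needs two input genes")
        event = Event.fusion(in_archs[0], in_archs[1])
    elif kind == "separation":
        event = Event.separation(in_archs[0], int(detail))
    elif kind == "deletion":
        event = Event.deletion(in_archs[0], *_parse_span(detail))
    elif kind == "duplication":
        event = Event.duplication(in_archs[0], *_parse_span(detail))
    elif kind == "loss":
        event = Event.loss(in_archs[0])
    else:  # gain
        event = Event.gain(parse_architecture(outputs, alphabet))
    if outputs.strip() and kind != "gain":
        stated = parse_profile(outputs, alphabet)
        produced = Profile.of(event.outputs)
        if stated != produced:
            raise ScenarioError(
                f"stated outputs {stated.text!r} disagree with grammar result "
                f"{produced.text!r} for {event.describe()}"
            )
    return event


def read_scenario(
    path: PathLike, alphabet: Alphabet = DEFAULT_ALPHABET, label: str = ""
) -> Scenario:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    needed = {"child_node", "event_type", "inputs", "outputs", "detail"}
    if not needed <= set(df.columns):
        raise ScenarioError(f"{path}: scenario table needs columns {sorted(needed)}")
    root_state: Optional[Profile] = None
    placements: list[tuple[str, Event]] = []
    for _, row in df.iterrows():
        child = row["child_node"].strip()
        if child == ROOT_ROW or row["event_type"].strip() == "root_state":
            if root_state is not None:
                raise ScenarioError(f"{path}: multiple root_state rows")
            root_state = parse_profile(row["outputs"], alphabet)
            continue
        placements.append(
            (child, _row_event(row["event_type"], row["inputs"], row["outputs"], row["detail"], alphabet))
        )
    if root_state is None:
        raise ScenarioError(f"{path}: missing '(root)' root_state row")
    return Scenario(root_state, tuple(placements), label or str(path))


def write_scenario(scenario: Scenario, path: PathLike) -> None:
    rows = [
        {
            "child_node": ROOT_ROW,
            "event_type": "root_state",
            "inputs": "",
            "outputs": scenario.root_state.text,
            "detail": "",
        }
    ]
    for child, event in scenario.placements:
        if event.type is EventType.FISSION_SEPARATION:
            detail = str(event.detail[0])
        elif event.detail:
            detail = f"{event.detail[0]}:{event.detail[1]}"
        else:
            detail = ""
        rows.append(
            {
                "child_node": child,
                "event_type": event.type.value,
                "inputs": ";".join(g.text for g in event.inputs),
                "outputs": ";".join(g.text for g in event.outputs) or ".",
                "detail": detail,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_keyvalue(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = val
    return out


def read_costs(path: PathLike) -> CostModel:
    valid = {t.value for t in EventType}
    mapping = {}
    for key, val in _read_keyvalue(path).items():
        if key not in valid:
            raise ValueError(f"{path}: unknown cost key {key!r} (valid: {sorted(valid)})")
        mapping[EventType(key)] = float(val)
    return CostModel.from_mapping(mapping)


def read_rates(path: PathLike, alphabet: Alphabet = DEFAULT_ALPHABET) -> RateModel:
    valid = {t.value for t in EventType}
    mapping: dict[EventType, float] = {}
    gain_pool: tuple[Architecture, ...] = ()
    for key, val in _read_keyvalue(path).items():
        if key == "gain_pool":
            gain_pool = tuple(parse_architecture(s, alphabet) for s in val.split(";"))
        elif key in valid:
            mapping[EventType(key)] = float(val)
        else:
            raise ValueError(
                f"{path}: unknown rate key {key!r} (valid: {sorted(valid | {'gain_pool'})})"
            )
    return RateModel.from_mapping(mapping, gain_pool)
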