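"""Core types for multi-domain gene architectures and the event grammar.

A *gene architecture* is the ordered N->C string of protein domains encoded
by one gene (e.g. ``B-K-P`` for a folB-folK-folP triple fusion).  A *genome
profile* is the multiset of pathway gene architectures present in one
genome; an empty profile means the pathway is absent.  Profiles evolve by a
small closed grammar of events: fusion of two genes, fission of a gene
(either by open-reading-frame separation or by loss of a component domain),
tandem duplication of a domain run, contraction of a single-domain-type
gene, whole-gene loss, and whole-gene gain (the high-cost move used to
model horizontal acquisition).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence


class ArchitectureError(ValueError):
    """Malformed architecture or profile text."""


class AlphabetError(ArchitectureError):
    """A domain token outside the registered alphabet."""


class ApplicationError(ValueError):
    """An event whose inputs are not applicable to a profile."""


class CapError(ApplicationError):
    """An event whose result violates the state caps."""


@dataclass(frozen=True)
class Alphabet:
    """Registered set of domain tokens architectures may use."""

    tokens: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("alphabet must contain at least one token")
        for tok in self.tokens:
            if not tok or not tok.isupper():
                raise ValueError(f"alphabet tokens must be nonempty uppercase, got {tok!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    def sorted_tokens(self) -> tuple[str, ...]:
        return tuple(sorted(self.tokens))


#: Default alphabet: the folB (DHNA), folK (HPPK) and folP (DHPS) domains of
#: the pterin branch of folate biosynthesis.
DEFAULT_ALPHABET = Alphabet(frozenset({"B", "K", "P"}))


@dataclass(frozen=True, order=True)
class Architecture:
    """One gene's ordered N->C domain string."""

    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.domains) < 1:
            raise ArchitectureError("architecture must contain at least one domain")

    @property
    def text(self) -> str:
        return "-".join(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def distinct_types(self) -> frozenset[str]:
        return frozenset(self.domains)

    def token_counts(self) -> Counter:
        return Counter(self.domains)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_architecture(text: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> Architecture:
    """Parse a hyphen-joined token string such as ``"B-K-P"``.

    Whitespace at field boundaries is ignored.  Raises
    :class:`ArchitectureError` on empty input and :class:`AlphabetError`
    naming the first unknown token.
    """
    text = text.strip()
    if not text:
        raise ArchitectureError("empty architecture string")
    tokens = tuple(tok.strip() for tok in text.split("-"))
    for tok in tokens:
        if not tok:
            raise ArchitectureError(f"empty domain token in {text!r}")
        if tok not in alphabet:
            raise AlphabetError(f"unknown domain token {tok!r} (alphabet: {sorted(alphabet.tokens)})")
    return Architecture(tokens)


@dataclass(frozen=True, order=True)
class Profile:
    """Multiset of gene architectures for one genome (canonically sorted).

    The canonical text form joins architecture strings with ``";"``; the
    empty profile prints as ``"."``.
    """

    genes: tuple[Architecture, ...] = ()

    @staticmethod
    def of(genes: Iterable[Architecture]) -> "Profile":
        return Profile(tuple(sorted(genes)))

    def __post_init__(self) -> None:
        if tuple(sorted(self.genes)) != self.genes:
            raise ArchitectureError("Profile genes must be canonically sorted; use Profile.of()")

    @property
    def text(self) -> str:
        return ";".join(g.text for g in self.genes) if self.genes else "."

    def __len__(self) -> int:
        return len(self.genes)

    def counts(self) -> Counter:
        return Counter(self.genes)

    def contains(self, genes: Sequence[Architecture]) -> bool:
        need = Counter(genes)
        have = self.counts()
        return all(have[g] >= n for g, n in need.items())

    def remove(self, *genes: Architecture) -> "Profile":
        have = self.counts()
        for g in genes:
            if have[g] <= 0:
                raise ApplicationError(f"gene {g.text!r} not present in profile {self.text!r}")
            have[g] -= 1
        return Profile.of(have.elements())

    def add(self, *genes: Architecture) -> "Profile":
        return Profile.of(tuple(self.genes) + tuple(genes))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


EMPTY_PROFILE = Profile()


def parse_profile(text: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> Profile:
    """Parse a ``";"``-joined profile string; ``"."`` is the empty profile."""
    text = text.strip()
    if not text:
        raise ArchitectureError("empty profile string (use '.' for an empty profile)")
    if text == ".":
        return EMPTY_PROFILE
    return Profile.of(parse_architecture(part, alphabet) for part in text.split(";"))


class EventType(str, Enum):
    FUSION = "fusion"
    FISSION_SEPARATION = "fission_separation"
    FISSION_DOMAIN_LOSS = "fission_domain_loss"
    DOMAIN_CONTRACTION = "domain_contraction"
    DOMAIN_DUPLICATION = "domain_duplication"
    GENE_LOSS = "gene_loss"
    GENE_GAIN = "gene_gain"


#: Event types that count toward the fission total.
FISSION_TYPES = (EventType.FISSION_SEPARATION, EventType.FISSION_DOMAIN_LOSS)

_ARITY = {
    EventType.FUSION: (2, 1),
    EventType.FISSION_SEPARATION: (1, 2),
    EventType.FISSION_DOMAIN_LOSS: (1, 1),
    EventType.DOMAIN_CONTRACTION: (1, 1),
    EventType.DOMAIN_DUPLICATION: (1, 1),
    EventType.GENE_LOSS: (1, 0),
    EventType.GENE_GAIN: (0, 1),
}


@dataclass(frozen=True)
class Event:
    """One grammar transition; outputs are derived from inputs + detail.

    ``detail`` holds event-specific indices: the split boundary for a
    separation, the half-open deleted/duplicated run ``(i, j)`` for
    deletions and duplications, and nothing for the other types.
    """

    type: EventType
    inputs: tuple[Architecture, ...]
    outputs: tuple[Architecture, ...]
    detail: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n_in, n_out = _ARITY[self.type]
        if len(self.inputs) != n_in or len(self.outputs) != n_out:
            raise ApplicationError(
                f"{self.type.value} event has arity {n_in}->{n_out}, "
                f"got {len(self.inputs)}->{len(self.outputs)}"
            )

    # -- constructors -------------------------------------------------

    @staticmethod
    def fusion(g1: Architecture, g2: Architecture) -> "Event":
        """Concatenate two genes N->C in the stated order (g1 then g2)."""
        return Event(EventType.FUSION, (g1, g2), (Architecture(g1.domains + g2.domains),))

    @staticmethod
    def separation(g: Architecture, boundary: int) -> "Event":
        """Break one gene into prefix ``g[:boundary]`` and suffix ``g[boundary:]``."""
        if not 1 <= boundary <= len(g) - 1:
            raise ApplicationError(f"separation boundary {boundary} out of range for {g.text!r}")
        return Event(
            EventType.FISSION_SEPARATION,
            (g,),
            (Architecture(g.domains[:boundary]), Architecture(g.domains[boundary:])),
            (boundary,),
        )

    @staticmethod
    def deletion(g: Architecture, start: int, stop: int) -> "Event":
        """Delete the contiguous run ``g[start:stop]`` (must leave a nonempty gene).

        The event is classified at construction: a deletion from a gene with
        at least two distinct domain types is a fission by domain loss; from
        a single-type gene it is a domain contraction (not a fission).
        """
        if not (0 <= start < stop <= len(g)):
            raise ApplicationError(f"deletion run ({start},{stop}) out of range for {g.text!r}")
        remaining = g.domains[:start] + g.domains[stop:]
        if not remaining:
            raise ApplicationError(
                "deletion may not empty a gene; total removal is gene_loss"
            )
        etype = (
            EventType.FISSION_DOMAIN_LOSS
            if len(g.distinct_types()) >= 2
            else EventType.DOMAIN_CONTRACTION
        )
        return Event(etype, (g,), (Architecture(remaining),), (start, stop))

    @staticmethod
    def duplication(g: Architecture, start: int, stop: int) -> "Event":
        """Insert a tandem copy of the run ``g[start:stop]`` adjacent to itself."""
        if not (0 <= start < stop <= len(g)):
            raise ApplicationError(f"duplication run ({start},{stop}) out of range for {g.text!r}")
        run = g.domains[start:stop]
        return Event(
            EventType.DOMAIN_DUPLICATION,
            (g,),
            (Architecture(g.domains[:stop] + run + g.domains[stop:]),),
            (start, stop),
        )

    @staticmethod
    def loss(g: Architecture) -> "Event":
        return Event(EventType.GENE_LOSS, (g,), ())

    @staticmethod
    def gain(g: Architecture) -> "Event":
        return Event(EventType.GENE_GAIN, (), (g,))

    # -- misc ----------------------------------------------------------

    def sort_key(self) -> tuple:
        return (
            self.type.value,
            tuple(g.text for g in self.inputs),
            self.detail,
            tuple(g.text for g in self.outputs),
        )

    def describe(self) -> str:
        ins = "+".join(g.text for g in self.inputs) or "(none)"
        outs = "+".join(g.text for g in self.outputs) or "(none)"
        return f"{self.type.value}: {ins} -> {outs}"


def classify_event(parent_gene: Optional[Architecture], event: Event) -> EventType:
    """Classify an event given the gene it acts on (pure, total).

    Deletion-like events are reclassified from the parent gene: at least
    two distinct domain types present means fission by domain loss, exactly
    one means domain contraction.  All other types classify as themselves.
    """
    if event.type in (EventType.FISSION_DOMAIN_LOSS, EventType.DOMAIN_CONTRACTION):
        if parent_gene is None:
            raise ApplicationError("deletion classification requires the parent gene")
        return (
            EventType.FISSION_DOMAIN_LOSS
            if len(parent_gene.distinct_types()) >= 2
            else EventType.DOMAIN_CONTRACTION
        )
    return event.type


@dataclass(frozen=True)
class StateCaps:
    """Bounds on the profile universe.

    ``max_copies_per_type_per_gene`` caps how many copies of one domain
    token a single gene may carry (default 2, matching the observed
    tandem-duplicated form).  ``max_genes_per_profile`` caps the multiset
    size of a profile (default 4).
    """

    max_copies_per_type_per_gene: int = 2
    max_genes_per_profile: int = 4

    def __post_init__(self) -> None:
        if self.max_copies_per_type_per_gene < 1 or self.max_genes_per_profile < 1:
            raise ValueError("state caps must be >= 1")

    def gene_ok(self, g: Architecture) -> bool:
        return all(n <= self.max_copies_per_type_per_gene for n in g.token_counts().values())

    def profile_ok(self, p: Profile) -> bool:
        return len(p) <= self.max_genes_per_profile and all(self.gene_ok(g) for g in p.genes)

    def check(self, p: Profile) -> None:
        if len(p) > self.max_genes_per_profile:
            raise CapError(
                f"profile {p.text!r} exceeds max_genes_per_profile={self.max_genes_per_profile}"
            )
        for g in p.genes:
            if not self.gene_ok(g):
                raise CapError(
                    f"gene {g.text!r} exceeds max_copies_per_type_per_gene="
                    f"{self.max_copies_per_type_per_gene}"
                )


DEFAULT_CAPS = StateCaps()


@dataclass(frozen=True)
class CostModel:
    """Nonnegative per-event-type costs for parsimony inference.

    Defaults are unit costs for all event types except gene gain, which is
    10.0: gains model horizontal acquisition and are deliberately expensive
    so that vertical-inheritance explanations are preferred.
    """

    items: tuple[tuple[EventType, float], ...] = field(
        default=tuple(
            (t, 10.0 if t is EventType.GENE_GAIN else 1.0) for t in EventType
        )
    )

    def __post_init__(self) -> None:
        seen = {t for t, _ in self.items}
        if seen != set(EventType):
            missing = sorted(t.value for t in set(EventType) - seen)
            raise ValueError(f"cost model missing event types: {missing}")
        for t, c in self.items:
            if not c >= 0:
                raise ValueError(f"negative cost for {t.value}: {c}")

    @staticmethod
    def default() -> "CostModel":
        return CostModel()

    @staticmethod
    def from_mapping(mapping: Mapping[EventType, float]) -> "CostModel":
        base = dict(CostModel().items)
        for key, val in mapping.items():
            if not isinstance(key, EventType):
                key = EventType(key)  # raises ValueError on unknown names
            base[key] = float(val)
        return CostModel(tuple(sorted(base.items(), key=lambda kv: kv[0].value)))

    def cost(self, t: EventType) -> float:
        return dict(self.items)[t]

    def as_dict(self) -> dict[str, float]:
        return {t.value: c for t, c in sorted(self.items, key=lambda kv: kv[0].value)}

    def path_cost(self, events: Iterable[Event]) -> float:
        table = dict(self.items)
        return float(sum(table[e.type] for e in events))


DEFAULT_COSTS = CostModel()


@lru_cache(maxsize=None)
def all_architectures(
    alphabet: Alphabet = DEFAULT_ALPHABET, caps: StateCaps = DEFAULT_CAPS
) -> tuple[Architecture, ...]:
    """Every architecture over ``alphabet`` respecting the per-gene copy cap."""
    tokens = alphabet.sorted_tokens()
    cap = caps.max_copies_per_type_per_gene
    out: list[Architecture] = []

    def extend(prefix: tuple[str, ...], counts: Counter) -> None:
        if prefix:
            out.append(Architecture(prefix))
        for tok in tokens:
            if counts[tok] < cap:
                counts[tok] += 1
                extend(prefix + (tok,), counts)
                counts[tok] -= 1

    extend((), Counter())
    return tuple(sorted(out))


def apply_event(profile: Profile, event: Event, caps: StateCaps = DEFAULT_CAPS) -> Profile:
    """Apply one event to a profile, enforcing input presence and state caps."""
    if not profile.contains(event.inputs):
        raise ApplicationError(
            f"event inputs {[g.text for g in event.inputs]} not present in {profile.text!r}"
        )
    result = profile.remove(*event.inputs).add(*event.outputs)
    caps.check(result)
    return result


def enumerate_event_instances(
    profile: Profile,
    caps: StateCaps = DEFAULT_CAPS,
    allow_gain: bool = False,
    gain_pool: Optional[Sequence[Architecture]] = None,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> list[tuple[Event, Profile, int]]:
    """All applicable event instances with multiplicities.

    Multiplicity counts distinct gene-copy choices producing the same
    (event, neighbour) pair: identical copies are interchangeable, so a
    gene present in ``c`` copies contributes ``c`` instances of each
    single-gene event, ordered pairs contribute ``c1*c2`` (or ``c*(c-1)``
    for self-fusion) fusion instances.  Instances whose result would break
    the caps are excluded entirely, which keeps simulation hazards
    well-defined.
    """
    counts = profile.counts()
    out: list[tuple[Event, Profile, int]] = []

    def emit(event: Event, mult: int) -> None:
        result = profile.remove(*event.inputs).add(*event.outputs)
        if caps.profile_ok(result):
            out.append((event, result, mult))

    distinct = sorted(counts)
    for g in distinct:
        c = counts[g]
        emit(Event.loss(g), c)
        for boundary in range(1, len(g)):
            emit(Event.separation(g, boundary), c)
        for start in range(len(g)):
            for stop in range(start + 1, len(g) + 1):
                if (start, stop) != (0, len(g)):
                    emit(Event.deletion(g, start, stop), c)
                emit(Event.duplication(g, start, stop), c)
    for g1 in distinct:
        for g2 in distinct:
            if g1 == g2:
                if counts[g1] >= 2:
                    emit(Event.fusion(g1, g2), counts[g1] * (counts[g1] - 1))
            else:
                emit(Event.fusion(g1, g2), counts[g1] * counts[g2])
    if allow_gain:
        pool = tuple(gain_pool) if gain_pool is not None else all_architectures(alphabet, caps)
        for g in sorted(set(pool)):
            emit(Event.gain(g), 1)
    out.sort(key=lambda item: (item[0].sort_key(), item[1].text))
    return out


def enumerate_events(
    profile: Profile,
    caps: StateCaps = DEFAULT_CAPS,
    allow_gain: bool = False,
    gain_pool: Optional[Sequence[Architecture]] = None,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> list[tuple[Event, Profile]]:
    """Neighbour generator: duplicate-free over (canonical neighbour, event type).

    Among instances collapsing to the same (neighbour, type) pair the event
    with the smallest sort key is kept, so the listing is deterministic.
    """
    seen: dict[tuple[str, EventType], tuple[Event, Profile]] = {}
    for event, result, _mult in enumerate_event_instances(
        profile, caps, allow_gain, gain_pool, alphabet
    ):
        key = (result.text, event.type)
        if key not in seen:
            seen[key] = (event, result)
    return sorted(seen.values(), key=lambda er: (er[0].sort_key(), er[1].text))


def count_fused_architectures(profiles: Iterable[Profile]) -> int:
    """Number of distinct architectures with >= 2 distinct domain types.

    Single-type genes (``B``, ``B-B``) are not fusions and are excluded.
    """
    fused = {
        g
        for p in profiles
        for g in p.genes
        if len(g.distinct_types()) >= 2
    }
    return len(fused)
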