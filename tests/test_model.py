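"""Unit and property tests for architectures, profiles and the event grammar."""

import pytest
from hypothesis import given, settings, strategies as st

from archevo import (
    AlphabetError,
    ApplicationError,
    ArchitectureError,
    CapError,
    CostModel,
    Event,
    EventType,
    Profile,
    StateCaps,
    apply_event,
    classify_event,
    count_fused_architectures,
    enumerate_events,
    parse_architecture,
    parse_profile,
)
from archevo.model import all_architectures, enumerate_event_instances


def arch(text):
    return parse_architecture(text)


# deterministic architecture/profile strategies over the default alphabet,
# respecting the default caps (<=2 copies per domain type per gene)
architectures = st.sampled_from(all_architectures())
profiles = st.lists(architectures, min_size=0, max_size=4).map(Profile.of)


class TestParsing:
    @pytest.mark.parametrize(
        "text,domains",
        [
            ("B-K-P", ("B", "K", "P")),
            ("B-B-K-P", ("B", "B", "K", "P")),
            (" B - K ", ("B", "K")),
            ("P", ("P",)),
        ],
    )
    def test_parse_architecture(self, text, domains):
        assert parse_architecture(text).domains == domains

    def test_unknown_token_names_the_offender(self):
        with pytest.raises(AlphabetError, match="'Q'"):
            parse_architecture("B-Q-P")

    def test_empty_inputs_rejected(self):
        with pytest.raises(ArchitectureError):
            parse_architecture("")
        with pytest.raises(ArchitectureError):
            parse_profile("")

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("B-B;K-P", ["B-B", "K-P"]),
            (".", []),
            ("K-P;K-P", ["K-P", "K-P"]),
            ("K-P;B-B", ["B-B", "K-P"]),  # canonical order imposed
        ],
    )
    def test_parse_profile(self, text, expected):
        assert [g.text for g in parse_profile(text).genes] == expected

    def test_multiset_semantics(self):
        p = parse_profile("K-P;K-P")
        assert p.counts()[arch("K-P")] == 2

    @settings(max_examples=200, derandomize=True)
    @given(profiles)
    def test_round_trip(self, p):
        assert parse_profile(p.text) == p
        for g in p.genes:
            assert parse_architecture(g.text) == g


class TestApplyEvent:
    def test_duplication_creates_tandem(self):
        p = parse_profile("B-K-P")
        out = apply_event(p, Event.duplication(arch("B-K-P"), 0, 1))
        assert out == parse_profile("B-B-K-P")

    def test_separation_splits_fusion(self):
        out = apply_event(parse_profile("B-B-K-P"), Event.separation(arch("B-B-K-P"), 2))
        assert out == parse_profile("B-B;K-P")

    def test_deletion_of_run(self):
        out = apply_event(parse_profile("B-B-K-P"), Event.deletion(arch("B-B-K-P"), 0, 2))
        assert out == parse_profile("K-P")

    def test_fusion_concatenates_in_order(self):
        out = apply_event(parse_profile("B;K-P"), Event.fusion(arch("B"), arch("K-P")))
        assert out == parse_profile("B-K-P")
        out2 = apply_event(parse_profile("B;K-P"), Event.fusion(arch("K-P"), arch("B")))
        assert out2 == parse_profile("K-P-B")

    def test_missing_input_rejected(self):
        with pytest.raises(ApplicationError):
            apply_event(parse_profile("K-P"), Event.loss(arch("B")))

    def test_emptying_deletion_must_be_gene_loss(self):
        with pytest.raises(ApplicationError, match="gene_loss"):
            Event.deletion(arch("B-B"), 0, 2)

    def test_cap_violation(self):
        with pytest.raises(CapError):
            apply_event(parse_profile("B-B;B-K-P"), Event.fusion(arch("B-B"), arch("B-K-P")))


class TestClassification:
    def test_deletion_from_multitype_gene_is_fission(self):
        e = Event.deletion(arch("B-B-K-P"), 0, 1)
        assert e.type is EventType.FISSION_DOMAIN_LOSS
        assert classify_event(arch("B-B-K-P"), e) is EventType.FISSION_DOMAIN_LOSS

    def test_deletion_from_single_type_gene_is_contraction(self):
        e = Event.deletion(arch("B-B"), 0, 1)
        assert e.type is EventType.DOMAIN_CONTRACTION
        assert classify_event(arch("B-B"), e) is EventType.DOMAIN_CONTRACTION

    def test_any_split_is_separation(self):
        for b in (1, 2, 3):
            assert Event.separation(arch("B-B-K-P"), b).type is EventType.FISSION_SEPARATION

    @settings(max_examples=100, derandomize=True)
    @given(profiles)
    def test_classification_total_and_consistent(self, p):
        for event, _n in enumerate_events(p, allow_gain=True):
            parent = event.inputs[0] if event.inputs else None
            assert classify_event(parent, event) is event.type


class TestEnumerate:
    def test_triple_fusion_neighborhood(self):
        # frozen from a direct enumeration of all grammar applications to
        # {B-K-P}: 2 separations, 5 distinct deletions, 6 duplications,
        # 1 gene loss, no fusions (single copy), gains disabled
        nbrs = enumerate_events(parse_profile("B-K-P"))
        assert len(nbrs) == 14
        results = {p.text for _e, p in nbrs}
        assert "B;K-P" in results and "B-K;P" in results

    def test_fusion_orders_both_generated(self):
        results = {
            p.text
            for e, p in enumerate_events(parse_profile("B;K-P"))
            if e.type is EventType.FUSION
        }
        assert results == {"B-K-P", "K-P-B"}

    def test_gain_only_when_enabled(self):
        p = parse_profile("K-P")
        assert all(e.type is not EventType.GENE_GAIN for e, _ in enumerate_events(p))
        gains = [e for e, _ in enumerate_events(p, allow_gain=True) if e.type is EventType.GENE_GAIN]
        assert gains

    @settings(max_examples=100, derandomize=True)
    @given(profiles)
    def test_apply_enumerate_consistency(self, p):
        listed = enumerate_events(p, allow_gain=True)
        keys = [(n.text, e.type) for e, n in listed]
        assert len(keys) == len(set(keys)), "duplicate (neighbor, type) pairs"
        for event, neighbor in listed:
            assert apply_event(p, event) == neighbor

    @settings(max_examples=60, derandomize=True)
    @given(profiles)
    def test_reversibility_pairing(self, p):
        """Every separation has an inverse fusion; every duplication an inverse deletion."""
        for event, neighbor in enumerate_events(p):
            if event.type is EventType.FISSION_SEPARATION:
                inverses = [
                    e
                    for e, back in enumerate_events(neighbor)
                    if e.type is EventType.FUSION and back == p
                ]
                assert inverses, f"no inverse fusion for {event.describe()} from {p.text}"
            elif event.type is EventType.DOMAIN_DUPLICATION:
                inverses = [
                    e
                    for e, back in enumerate_events(neighbor)
                    if e.type
                    in (EventType.FISSION_DOMAIN_LOSS, EventType.DOMAIN_CONTRACTION)
                    and back == p
                ]
                assert inverses, f"no inverse deletion for {event.describe()} from {p.text}"

    def test_multiplicities_scale_with_copies(self):
        single = enumerate_event_instances(parse_profile("K-P"))
        double = enumerate_event_instances(parse_profile("K-P;K-P"))
        loss_mult = {e.sort_key(): m for e, _r, m in double if e.type is EventType.GENE_LOSS}
        assert list(loss_mult.values()) == [2]
        fusions = [m for e, _r, m in double if e.type is EventType.FUSION]
        assert fusions == [2]  # ordered pairs of the two identical copies
        assert all(m == 1 for e, _r, m in single if e.type is EventType.GENE_LOSS)


class TestCounting:
    def test_no_profiles(self):
        assert count_fused_architectures([]) == 0

    def test_single_type_genes_excluded(self):
        assert count_fused_architectures([parse_profile("B-B"), parse_profile("B")]) == 0

    def test_distinct_fused_architectures(self):
        profs = [parse_profile(t) for t in ["B-K-P;K-P", "B-B-K-P", "K-P", "B-B"]]
        assert count_fused_architectures(profs) == 3


class TestCostModel:
    def test_defaults(self):
        cm = CostModel.default()
        assert cm.cost(EventType.GENE_GAIN) == 10.0
        assert cm.cost(EventType.FUSION) == 1.0

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            CostModel.from_mapping({"not_an_event": 1.0})

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            CostModel.from_mapping({EventType.FUSION: -1.0})

    def test_caps_validate(self):
        with pytest.raises(ValueError):
            StateCaps(0, 4)
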