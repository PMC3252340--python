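"""Tests for the BP / Cre / Flp recombination engine."""

import random

import pytest

from grimkit import resources
from grimkit.errors import (
    InsufficientSitesError,
    MultiSiteError,
    PartnerSpecificityError,
    SiteTopologyError,
)
from grimkit.recombine import (
    RecombinationSiteDef,
    bp_recombine,
    cre_recombine,
    flp_recombine,
    locate_sites,
)
from grimkit.seqcore import SeqRecord, reverse_complement


def _canonical_rotation(seq: str) -> str:
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def _rand(rng, n):
    return "".join(rng.choice("ACG") for _ in range(n))


class TestLocateSites:
    def test_destination_fixture_sites(self, fixture_set):
        matches = locate_sites(fixture_set.destination)
        found = {(m.name, m.orientation) for m in matches}
        assert found == {("FRT", "+"), ("loxP", "+"), ("attP1", "+"), ("attP2", "+")}

    def test_reverse_complemented_loxp_is_minus(self):
        rec = SeqRecord("r", "GGCC" + reverse_complement(resources.LOXP) + "TTAA")
        matches = locate_sites(rec, names=("loxP",))
        assert [m.orientation for m in matches] == ["-"]

    def test_no_sites_is_empty_list(self):
        assert locate_sites(SeqRecord("r", "ACGT" * 30)) == []

    def test_hybrid_att_sites_located_on_bp_product(self, fixture_set):
        names = {m.name for m in locate_sites(fixture_set.grim_off())}
        assert {"attL1", "attL2", "loxP", "FRT"} <= names
        assert not {"attP1", "attP2", "attB1", "attB2"} & names


def _toy_catalog():
    """Miniature site definitions for hand-checkable BP arithmetic."""
    return {
        "attB1": RecombinationSiteDef("attB1", "AAGGCTAA", (2, 5), ("attP1",)),
        "attP1": RecombinationSiteDef("attP1", "CCGGCTCC", (2, 5), ("attB1",)),
        "attB2": RecombinationSiteDef("attB2", "TTCAGTT", (2, 5), ("attP2",)),
        "attP2": RecombinationSiteDef("attP2", "GGCAGGG", (2, 5), ("attB2",)),
    }


class TestToyBP:
    def test_product_matches_hand_construction(self):
        cat = _toy_catalog()
        b1, b2 = cat["attB1"].seq, cat["attB2"].seq
        p1, p2 = cat["attP1"].seq, cat["attP2"].seq
        payload = "ACACACACAC"
        donor = SeqRecord("toy_donor", "GG" + b1 + payload + b2 + "CC")
        cassette = "GTGTGTGTGTGTGTGT"
        backbone = "AGAGAGAGAGAGAGAGAGAGAG"
        dest = SeqRecord("toy_dest", p1 + cassette + p2 + backbone, "circular")
        event = bp_recombine(donor, dest, cat)
        product, byproduct = event.products
        # crossover at the 5' core boundary (offset 2 in every toy site):
        # product = P1[:2]+B1[2:] + payload + B2[:2]+P2[2:] + backbone
        expected_product = (
            p1[:2] + b1[2:] + payload + b2[:2] + p2[2:] + backbone
        )
        expected_byproduct = (
            "GG" + b1[:2] + p1[2:] + cassette + p2[:2] + b2[2:] + "CC"
        )
        assert _canonical_rotation(product.seq) == _canonical_rotation(expected_product)
        assert byproduct.seq == expected_byproduct
        assert byproduct.topology == "linear" and product.topology == "circular"
        assert len(product.seq) + len(byproduct.seq) == len(donor.seq) + len(dest.seq)


class TestBPOnFixtures:
    def test_attl1_feature_is_118_bp(self, fixture_set):
        off = fixture_set.grim_off()
        attl1 = off.features_of_kind("attL1")
        assert len(attl1) == 1
        assert attl1[0].length(len(off.seq)) == 118
        assert off.feature_seq(attl1[0]) == resources.ATTL1

    def test_base_count_conserved(self, fixture_set):
        event = fixture_set.bp_event()
        assert sum(len(p.seq) for p in event.products) == sum(
            len(r.seq) for r in event.inputs
        )

    def test_byproduct_carries_cassette_and_attr_sites(self, fixture_set):
        byproduct = fixture_set.bp_event().products[1]
        kinds = {f.kind for f in byproduct.features}
        assert {"attR1", "attR2", "cassette"} <= kinds

    def test_donor_lacking_attb2_is_topology_error(self, fixture_set):
        donor = fixture_set.donor.record
        truncated = SeqRecord("trunc", donor.seq[:-25])
        with pytest.raises(SiteTopologyError):
            bp_recombine(truncated, fixture_set.destination)

    def test_b1_offered_to_p2_is_partner_error(self, fixture_set):
        dest = fixture_set.destination
        p1 = dest.features_of_kind("attP1")[0]
        # ablate attP1 so only attP2 remains on the destination
        mangled = SeqRecord(
            "noP1", dest.seq[: p1.start] + "A" * (p1.end - p1.start) + dest.seq[p1.end :],
            "circular",
        )
        with pytest.raises(PartnerSpecificityError):
            bp_recombine(fixture_set.donor.record, mangled)

    def test_circular_donor_rejected(self, fixture_set):
        donor = fixture_set.donor.record
        with pytest.raises(SiteTopologyError):
            bp_recombine(SeqRecord(donor.id, donor.seq, "circular"), fixture_set.destination)


class TestCre:
    def test_off_fixture_excision_removes_175(self, fixture_set):
        event = fixture_set.cre_event()
        assert event.removed_length == 175
        assert len(event.inputs[0].seq) - len(event.products[0].seq) == 175

    def test_one_loxp_retained_upstream_of_hairpin(self, fixture_set):
        on = fixture_set.grim_on()
        loxp = on.features_of_kind("loxP")
        arm5 = on.features_of_kind("scaffold_arm_5p")
        assert len(loxp) == 1 and len(arm5) == 1
        assert loxp[0].end == arm5[0].start  # retained loxP abuts the hairpin

    def test_excised_circle_carries_the_other_loxp(self, fixture_set):
        excised = fixture_set.cre_event().products[1]
        assert excised.topology == "circular"
        assert len(excised.seq) == 175
        assert len(locate_sites(excised, names=("loxP",))) == 1

    def test_second_application_is_idempotence_error(self, fixture_set):
        with pytest.raises(InsufficientSitesError):
            cre_recombine(fixture_set.grim_on())

    def test_fewer_than_two_sites(self):
        with pytest.raises(InsufficientSitesError):
            cre_recombine(SeqRecord("r", "AA" + resources.LOXP + "TT", "circular"))

    def test_three_sites_need_explicit_pair(self):
        rng = random.Random(0)
        seq = "".join(
            _rand(rng, 30) + resources.LOXP for _ in range(3)
        ) + _rand(rng, 30)
        rec = SeqRecord("r", seq, "circular")
        with pytest.raises(MultiSiteError):
            cre_recombine(rec)
        event = cre_recombine(rec, pair=(0, 1))
        assert event.removed_length == 30 + 34


class TestInversion:
    def _inverted_circle(self):
        rng = random.Random(5)
        prefix, mid, suffix = _rand(rng, 21), _rand(rng, 33), _rand(rng, 26)
        seq = prefix + resources.LOXP + mid + reverse_complement(resources.LOXP) + suffix
        return SeqRecord("inv", seq, "circular"), prefix, mid, suffix

    def test_inversion_matches_hand_construction(self):
        rec, prefix, mid, suffix = self._inverted_circle()
        event = cre_recombine(rec)
        expected = (
            prefix + resources.LOXP + reverse_complement(mid)
            + reverse_complement(resources.LOXP) + suffix
        )
        assert event.products[0].seq == expected
        assert event.removed_length == 0

    def test_double_inversion_restores_original(self):
        rec, *_ = self._inverted_circle()
        once = cre_recombine(rec).products[0]
        twice = cre_recombine(once).products[0]
        assert twice.seq == rec.seq


class TestFlp:
    def test_on_fixture_shutdown(self, fixture_set):
        event = fixture_set.flp_event()
        retained, excised = event.products
        excised_kinds = {f.kind for f in excised.features}
        assert {"promoter", "loxP", "scaffold_arm_5p", "sense", "loop", "guide",
                "scaffold_arm_3p", "terminator"} <= excised_kinds
        retained_kinds = {f.kind for f in retained.features}
        assert "FRT" in retained_kinds
        assert not retained_kinds & {"sense", "guide", "promoter"}
        assert len(retained.features_of_kind("FRT")) == 1

    def test_single_frt_is_insufficient(self):
        with pytest.raises(InsufficientSitesError):
            flp_recombine(SeqRecord("r", "AA" + resources.FRT + "GG", "circular"))

    def test_conservation(self, fixture_set):
        event = fixture_set.flp_event()
        assert sum(len(p.seq) for p in event.products) == len(event.inputs[0].seq)


class TestRandomizedConservation:
    @pytest.mark.parametrize("site_seq", [resources.LOXP, resources.FRT])
    def test_excision_and_inversion_conserve_bases(self, site_seq):
        rng = random.Random(99)
        recombinase = cre_recombine if site_seq == resources.LOXP else flp_recombine
        for trial in range(100):
            spans = [rng.randrange(10, 120) for _ in range(3)]
            inverted = rng.random() < 0.5
            second = reverse_complement(site_seq) if inverted else site_seq
            seq = (
                _rand(rng, spans[0]) + site_seq + _rand(rng, spans[1])
                + second + _rand(rng, spans[2])
            )
            rec = SeqRecord("r", seq, "circular" if rng.random() < 0.5 else "linear")
            event = recombinase(rec)
            assert sum(len(p.seq) for p in event.products) == len(seq)

    def test_full_lifecycle_ends_without_hairpin(self, fixture_set):
        dead = fixture_set.flp_dead()
        assert not dead.features_of_kind(*[
            "scaffold_arm_5p", "sense", "loop", "guide", "scaffold_arm_3p",
        ])
        from grimkit.errors import MissingFeatureError
        from grimkit.grimqc import predict_u6_transcript

        with pytest.raises(MissingFeatureError):
            predict_u6_transcript(dead)
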