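"""Unit and property tests for sequence records, motif search, digestion, I/O."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from grimkit import resources
from grimkit.errors import AlphabetError, ParseError
from grimkit.seqcore import (
    ECORI,
    Enzyme,
    Feature,
    SeqRecord,
    digest,
    find_motif,
    read_record,
    read_records,
    reverse_complement,
    transcribe,
    write_record,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GAATTC", "GAATTC"),  # palindrome maps to itself
            ("CGTTTGGACCCCGAGCCAAACT", "AGTTTGGCTCGGGGTCCAAACG"),
            ("ACGTN", "NACGT"),
        ],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @pytest.mark.parametrize("bad", ["", "ACGU", "ACGX", "A CGT"])
    def test_rejects_non_dna(self, bad):
        with pytest.raises(AlphabetError):
            reverse_complement(bad)

    @settings(derandomize=True, max_examples=200)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    @settings(derandomize=True, max_examples=100)
    @given(dna)
    def test_agrees_with_biopython(self, seq):
        from Bio.Seq import Seq

        assert reverse_complement(seq) == str(Seq(seq).reverse_complement())


class TestTranscribe:
    def test_examples(self):
        assert transcribe("TTTTTT") == "UUUUUU"
        assert transcribe("ACGT") == "ACGU"

    def test_rejects_rna_input(self):
        with pytest.raises(AlphabetError):
            transcribe("ACGU")


def _naive_motif_scan(record: SeqRecord, motif: str, both_strands: bool):
    """Independent oracle: scan the doubled sequence character by character."""
    n, m = len(record.seq), len(motif)
    text = record.seq + (record.seq[: m - 1] if record.is_circular else "")
    probes = [(motif, "+")]
    if both_strands:
        probes.append((reverse_complement(motif), "-"))
    found = {}
    for probe, strand in probes:
        for i in range(len(text) - m + 1):
            w = text[i : i + m]
            if "N" not in w and "N" not in probe and w == probe:
                found.setdefault(i % n, strand)
    return sorted(found.items())


class TestFindMotif:
    def test_palindromic_motif_deduplicated(self):
        rec = SeqRecord("r", "ATAGAATTCGGGATCGATCA")
        assert find_motif(rec, "GAATTC", both_strands=True) == [(3, "+")]

    def test_minus_strand_orientation(self):
        rec = SeqRecord("r", "GG" + reverse_complement(resources.LOXP) + "CC")
        assert find_motif(rec, resources.LOXP, both_strands=True) == [(2, "-")]

    def test_wrap_spanning_hit_found_once(self):
        motif = "GCATTGCAGT"
        rng = random.Random(7)
        body = "".join(rng.choice("ACG") for _ in range(290))
        seq = motif[4:] + body + motif[:4]  # motif spans the origin
        rec = SeqRecord("r", seq, "circular")
        hits = find_motif(rec, motif)
        assert hits == [(len(seq) - 4, "+")]

    def test_n_never_matches(self):
        rec = SeqRecord("r", "AANTTC")
        assert find_motif(rec, "ANT") == []
        assert find_motif(rec, "AAN") == []

    @settings(derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="ACGT", min_size=8, max_size=80),
        st.text(alphabet="ACGT", min_size=2, max_size=6),
        st.booleans(),
        st.booleans(),
    )
    def test_agrees_with_naive_oracle(self, seq, motif, circular, both):
        rec = SeqRecord("r", seq, "circular" if circular else "linear")
        assert find_motif(rec, motif, both) == _naive_motif_scan(rec, motif, both)


def _rotation_digest_oracle(record: SeqRecord, enzyme: Enzyme):
    """Independent circular-digest oracle: rotate the plasmid to each cut."""
    hits = _naive_motif_scan(record, enzyme.recognition, True)
    cuts = sorted(
        {
            (s + (enzyme.cut_offset if strand == "+" else len(enzyme.recognition) - enzyme.cut_offset))
            % len(record.seq)
            for s, strand in hits
        }
    )
    if not cuts:
        return sorted([len(record.seq)], reverse=True)
    lengths = []
    for a, b in zip(cuts, cuts[1:] + [cuts[0] + len(record.seq)]):
        lengths.append(b - a)
    return sorted(lengths, reverse=True)


class TestDigest:
    def test_single_cut_linearizes_circle(self):
        rec = SeqRecord("r", "GAATTC" + "A" * 94, "circular")
        frags = digest(rec, ECORI)
        assert frags.fragment_lengths == [100]
        assert not frags.uncut
        # fragment starts at the cut, not the site start
        assert frags.fragment_seqs[0].startswith("AATTC")

    def test_linear_no_site(self):
        rec = SeqRecord("r", "A" * 50)
        frags = digest(rec, ECORI)
        assert frags.fragment_lengths == [50]

    def test_uncut_circle_flagged(self):
        frags = digest(SeqRecord("r", "A" * 30, "circular"), ECORI)
        assert frags.uncut and frags.fragment_lengths == [30]

    def test_three_planted_sites_match_rotation_oracle(self):
        rng = random.Random(11)
        filler = lambda n: "".join(rng.choice("ACG") for _ in range(n))
        seq = filler(50) + "GAATTC" + filler(120) + "GAATTC" + filler(30) + "GAATTC" + filler(188)
        rec = SeqRecord("r", seq, "circular")
        frags = digest(rec, ECORI)
        assert len(frags.fragment_lengths) == 3
        assert frags.fragment_lengths == _rotation_digest_oracle(rec, ECORI)

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=300), st.booleans())
    def test_base_count_conserved(self, seq, circular):
        rec = SeqRecord("r", seq, "circular" if circular else "linear")
        frags = digest(rec, ECORI)
        assert sum(frags.fragment_lengths) == len(seq)
        assert sum(map(len, frags.fragment_seqs)) == len(seq)

    def test_linear_fragment_count(self):
        rec = SeqRecord("r", "AAGAATTCTTGAATTCAA")
        frags = digest(rec, ECORI)
        assert len(frags.fragment_lengths) == 3  # k+1 for k cuts


class TestIO:
    def test_genbank_round_trip_preserves_features(self, tmp_path, fixture_set):
        path = tmp_path / "dest.gb"
        write_record(fixture_set.destination, path, "genbank")
        back = read_record(path, "genbank")
        assert back.seq == fixture_set.destination.seq
        assert back.topology == "circular"
        original = [(f.kind, f.start, f.end, f.strand) for f in fixture_set.destination.features]
        round_tripped = [(f.kind, f.start, f.end, f.strand) for f in back.features]
        assert round_tripped == original

    def test_wraparound_feature_round_trip(self, tmp_path):
        rec = SeqRecord(
            "r", "ATGC" * 25, "circular",
            [Feature("ori-span", "other", 90, 10)],
        )
        path = tmp_path / "wrap.gb"
        write_record(rec, path, "genbank")
        back = read_record(path, "genbank")
        assert [(f.start, f.end) for f in back.features] == [(90, 10)]

    def test_fasta_normalizes_case_and_wrapping(self, tmp_path):
        path = tmp_path / "q.fasta"
        path.write_text(">q test\nacgtac\ngtACGT\n")
        rec = read_record(path, "fasta")
        assert rec.seq == "ACGTACGTACGT"

    def test_fasta_wraps_at_60_columns(self, tmp_path):
        path = tmp_path / "long.fasta"
        write_record(SeqRecord("r", "A" * 130), path, "fasta")
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 10]

    def test_illegal_character_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">bad\nACGTXXACGT\n")
        with pytest.raises(ParseError):
            read_record(path, "fasta")

    def test_multi_record_fasta(self, tmp_path):
        path = tmp_path / "multi.fasta"
        path.write_text(">a\nACGT\n>b\nGGCC\n")
        assert [r.id for r in read_records(path, "fasta")] == ["a", "b"]
        with pytest.raises(ParseError):
            read_record(path, "fasta")


class TestRecordInvariants:
    def test_empty_sequence_rejected(self):
        with pytest.raises(AlphabetError):
            SeqRecord("r", "")

    def test_feature_outside_record_rejected(self):
        with pytest.raises(ValueError):
            SeqRecord("r", "ACGT", features=[Feature("f", "other", 2, 9)])

    def test_wrap_feature_on_linear_rejected(self):
        with pytest.raises(ValueError):
            SeqRecord("r", "ACGTACGT", "linear", [Feature("f", "other", 6, 2)])

    def test_unknown_feature_kind_rejected(self):
        with pytest.raises(ValueError):
            Feature("f", "mystery", 0, 4)
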