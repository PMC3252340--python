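"""Core sequence records, feature annotation, I/O, and restriction digestion.

This module is the substrate layer for the whole toolkit: plasmids, linear
donors and transcripts are all :class:`SeqRecord` objects — a deliberately
small container (sequence text, linear/circular topology, typed features)
with file I/O delegated to Biopython.

Coordinates are 0-based half-open internally.  On circular records a feature
whose ``end`` is smaller than its ``start`` wraps across the origin.
User-facing reports are 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import AlphabetError, ParseError

DNA_ALPHABET = frozenset("ACGTN")

#: Closed vocabulary of feature kinds used throughout the toolkit.
FEATURE_KINDS = frozenset({
    "promoter", "loxP", "FRT",
    "attB1", "attB2", "attP1", "attP2",
    "attL1", "attL2", "attR1", "attR2",
    "scaffold_arm_5p", "sense", "loop", "guide", "scaffold_arm_3p",
    "terminator", "cassette", "spacer", "other",
})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_dna(seq: str, *, allow_empty: bool = False) -> str:
    s = seq.upper()
    if not s and not allow_empty:
        raise AlphabetError("empty sequence is not a valid DNA input")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"non-nucleotide character(s) {sorted(bad)} in sequence"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Antiparallel complement of a DNA string (involution: rc(rc(s)) == s)."""
    s = _validate_dna(seq)
    return s.translate(_COMPLEMENT)[::-1]


def transcribe(dna: str) -> str:
    """Plus-strand transcription: T becomes U, nothing else changes."""
    return _validate_dna(dna).replace("T", "U")


@dataclass
class Feature:
    """A typed, stranded interval on a record.

    ``kind`` is drawn from :data:`FEATURE_KINDS`.  The interval is 0-based
    half-open; on circular records ``end < start`` denotes a feature that
    wraps across the origin.
    """

    label: str
    kind: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start == self.end:
            raise ValueError(f"zero-length feature {self.label!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, parent_length: int) -> int:
        if self.wraps:
            return parent_length - self.start + self.end
        return self.end - self.start


@dataclass
class SeqRecord:
    """A nucleotide sequence with topology and typed features."""

    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = _validate_dna(self.seq)
        if self.topology not in {"linear", "circular"}:
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: Feature) -> None:
        n = len(self.seq)
        if not (0 <= f.start < n) or not (0 <= f.end <= n):
            raise ValueError(
                f"feature {f.label!r} [{f.start},{f.end}) outside record of length {n}"
            )
        if f.wraps and self.topology != "linear":
            return
        if f.wraps:
            raise ValueError(
                f"wrap-around feature {f.label!r} on linear record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def feature_seq(self, f: Feature) -> str:
        raw = (self.seq[f.start:] + self.seq[: f.end]) if f.wraps else self.seq[f.start : f.end]
        return reverse_complement(raw) if f.strand == "-" else raw

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def rotated(self, offset: int) -> "SeqRecord":
        """Return the circular record with its origin moved to ``offset``."""
        if not self.is_circular:
            raise ValueError("only circular records can be rotated")
        n = len(self.seq)
        offset %= n
        feats = [
            replace(f, start=(f.start - offset) % n, end=(f.end - offset) % n or n)
            for f in self.features
        ]
        return SeqRecord(self.id, self.seq[offset:] + self.seq[:offset], "circular", feats)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease defined by its recognition site.

    ``cut_offset`` is the top-strand cut position within the recognition
    sequence (EcoRI = GAATTC, offset 1: G^AATTC).
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _validate_dna(self.recognition))
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")
        is_pal = self.recognition == reverse_complement(self.recognition)
        if self.palindromic and not is_pal:
            raise ValueError(
                f"{self.name}: recognition {self.recognition} is not palindromic; "
                "pass palindromic=False explicitly"
            )


ECORI = Enzyme("EcoRI", "GAATTC", 1)


@dataclass
class FragmentSet:
    """Digestion products, canonicalized by descending length then sequence."""

    fragment_lengths: list[int]
    fragment_seqs: list[str]
    uncut: bool = False

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.fragment_seqs)),
            key=lambda i: (-self.fragment_lengths[i], self.fragment_seqs[i]),
        )
        self.fragment_lengths = [self.fragment_lengths[i] for i in order]
        self.fragment_seqs = [self.fragment_seqs[i] for i in order]

    def to_tsv(self) -> str:
        lines = ["fragment_index\tlength\tsequence"]
        for i, (n, s) in enumerate(zip(self.fragment_lengths, self.fragment_seqs), 1):
            lines.append(f"{i}\t{n}\t{s}")
        return "\n".join(lines) + "\n"


def find_motif(record: SeqRecord, motif: str, both_strands: bool = False) -> list[tuple[int, str]]:
    """All exact occurrences of ``motif``, as (0-based start, strand) pairs.

    Circular records are searched across the origin and wrap-spanning hits are
    reported once, with start < len(record).  ``N`` never matches, on either
    side.  A palindromic motif found on both strands at one position is
    reported once, on the plus strand.
    """
    motif = _validate_dna(motif)
    seq = record.seq
    n, m = len(seq), len(motif)
    search = seq + seq[: m - 1] if record.is_circular and m > 1 else seq
    targets = [(motif, "+")]
    if both_strands:
        targets.append((reverse_complement(motif), "-"))
    hits: dict[int, str] = {}
    for probe, strand in targets:
        if "N" in probe:
            continue  # N never matches
        for i in range(len(search) - m + 1):
            window = search[i : i + m]
            if "N" in window or window != probe:
                continue
            start = i % n
            if start not in hits:
                hits[start] = strand
    return sorted(hits.items())


def digest(record: SeqRecord, enzyme: Enzyme) -> FragmentSet:
    """Cut a record at every recognition site and return the fragments.

    A linear parent with k cut sites yields k+1 fragments; a circular parent
    with k >= 1 sites yields k; a circular parent with no site yields one
    fragment flagged ``uncut``.
    """
    n = len(record.seq)
    cuts: set[int] = set()
    for start, strand in find_motif(record, enzyme.recognition, both_strands=True):
        if strand == "+":
            cuts.add((start + enzyme.cut_offset) % n)
        else:
            cuts.add((start + len(enzyme.recognition) - enzyme.cut_offset) % n)
    positions = sorted(cuts)
    if record.is_circular:
        if not positions:
            return FragmentSet([n], [record.seq], uncut=True)
        doubled = record.seq + record.seq
        seqs = [
            doubled[p : q if q > p else q + n]
            for p, q in zip(positions, positions[1:] + positions[:1])
        ]
        if len(positions) == 1:
            seqs = [doubled[positions[0] : positions[0] + n]]
    else:
        bounds = [0] + positions + [n]
        seqs = [record.seq[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]
        if not positions:
            seqs = [record.seq]
    return FragmentSet([len(s) for s in seqs], seqs)


# ---------------------------------------------------------------------------
# Standard-format I/O (Biopython-backed)

_KIND_TO_GBTYPE = {
    "promoter": "promoter",
    "terminator": "terminator",
    "loxP": "misc_recomb",
    "FRT": "misc_recomb",
    "attB1": "misc_recomb",
    "attB2": "misc_recomb",
    "attP1": "misc_recomb",
    "attP2": "misc_recomb",
    "attL1": "misc_recomb",
    "attL2": "misc_recomb",
    "attR1": "misc_recomb",
    "attR2": "misc_recomb",
}
# everything else round-trips as misc_feature with the kind in a note


def _to_bio(record: SeqRecord) -> BioSeqRecord:
    bio = BioSeqRecord(Seq(record.seq), id=record.id, name=record.id[:16] or "record",
                       description="")
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = record.topology
    n = len(record.seq)
    for f in record.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start, n, strand),
                SimpleLocation(0, f.end, strand),
            ])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        gbtype = _KIND_TO_GBTYPE.get(f.kind, "misc_feature")
        qualifiers = {"label": [f.label], "note": [f"kind:{f.kind}"]}
        bio.features.append(SeqFeature(loc, type=gbtype, qualifiers=qualifiers))
    return bio


def _from_bio(bio: BioSeqRecord, path: str) -> SeqRecord:
    try:
        seq = _validate_dna(str(bio.seq))
    except AlphabetError as exc:
        raise ParseError(f"{path}: record {bio.id!r}: {exc}") from exc
    topology = bio.annotations.get("topology", "linear")
    if topology not in {"linear", "circular"}:
        topology = "linear"
    feats: list[Feature] = []
    n = len(seq)
    for sf in bio.features:
        if sf.type == "source":
            continue
        label = (sf.qualifiers.get("label") or sf.qualifiers.get("gene") or [sf.type])[0]
        kind = None
        for note in sf.qualifiers.get("note", []):
            if note.startswith("kind:") and note[5:] in FEATURE_KINDS:
                kind = note[5:]
                break
        if kind is None:
            kind = sf.type if sf.type in FEATURE_KINDS else "other"
        strand = "-" if sf.location.strand == -1 else "+"
        parts = getattr(sf.location, "parts", [sf.location])
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start), int(parts[1].end)  # origin-wrapping
        else:
            start, end = int(sf.location.start), int(sf.location.end)
        feats.append(Feature(label, kind, start, end, strand))
    return SeqRecord(bio.id, seq, topology, feats)


_FORMATS = {"fasta": "fasta", "genbank": "genbank", "gb": "genbank"}


def _norm_format(fmt: str) -> str:
    try:
        return _FORMATS[fmt.lower()]
    except KeyError:
        raise ParseError(f"unsupported format {fmt!r} (use fasta or genbank)") from None


def read_records(path: str | os.PathLike, fmt: str) -> list[SeqRecord]:
    """Read all records from a FASTA or GenBank file."""
    fmt = _norm_format(fmt)
    try:
        bios = list(SeqIO.parse(os.fspath(path), fmt))
    except (ValueError, KeyError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not bios:
        raise ParseError(f"{path}: no records found")
    return [_from_bio(b, os.fspath(path)) for b in bios]


def read_record(path: str | os.PathLike, fmt: str) -> SeqRecord:
    """Read a single record; raises :class:`ParseError` for malformed files."""
    records = read_records(path, fmt)
    if len(records) != 1:
        raise ParseError(f"{path}: expected one record, found {len(records)}")
    return records[0]


def write_record(record: SeqRecord | list[SeqRecord], path: str | os.PathLike, fmt: str) -> None:
    """Write record(s) as FASTA (60-column wrap) or annotated GenBank."""
    fmt = _norm_format(fmt)
    records = record if isinstance(record, list) else [record]
    SeqIO.write([_to_bio(r) for r in records], os.fspath(path), fmt)
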