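"""Four-oligo overlap-extension assembly of the 219-bp linear miRNA donor.

A donor is extended from four primers: two packaged *common* primers that
carry the Gateway attB ends, the loxP and (optional) FRT recombination
sites and the outermost scaffold stubs, and the two miRNA-specific primers
produced by the designer.  Adjacent primers share exact complementary 3'
overlaps (14/19/16 nt for the default layout), so a polymerase can fill the
gaps to one full-length duplex:

    attB1 - spacer - loxP - [miR-30a hairpin + terminator] - FRT - attB2

Assembly here is exact-match only; mispriming and partial extension
products are represented solely by the error paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from . import resources
from .design import Candidate, DEFAULT_SCAFFOLD, ScaffoldDefinition
from .errors import AmbiguousAssemblyError, AnnotationError, AssemblyError, ConfigurationError
from .seqcore import Feature, SeqRecord, reverse_complement


@dataclass(frozen=True)
class Oligo:
    name: str
    seq: str
    strand_role: str  # "plus" | "minus"

    def __post_init__(self) -> None:
        if not self.seq or set(self.seq.upper()) - set("ACGT"):
            raise ConfigurationError(f"oligo {self.name!r} must be non-empty ACGT DNA")
        if self.strand_role not in {"plus", "minus"}:
            raise ConfigurationError("strand_role must be 'plus' or 'minus'")

    @property
    def plus_seq(self) -> str:
        """The oligo written on the plus strand of the final duplex."""
        return self.seq if self.strand_role == "plus" else reverse_complement(self.seq)


@dataclass(frozen=True)
class CommonPrimerSet:
    """The two universal outside primers (77 and 78 nt with defaults).

    Common primer 1 (plus): attB1 + 3-bp junction spacer + loxP + the first
    15 nt of the miR-30a 5' lower stem.  Common primer 2 (minus): the
    reverse complement of 3' lower stem + TTTTTT terminator + optional FRT +
    attB2.
    """

    common1_plus: str
    common2_minus: str
    include_frt: bool = True

    def as_oligos(self) -> tuple[Oligo, Oligo]:
        return (
            Oligo("common primer 1", self.common1_plus, "plus"),
            Oligo("common primer 2", self.common2_minus, "minus"),
        )


def build_common_primers(
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD, include_frt: bool = True
) -> CommonPrimerSet:
    """Assemble the packaged common primers from the resource constants."""
    for name in ("ATTB1", "ATTB2", "LOXP", "FRT", "JUNCTION_SPACER"):
        if not getattr(resources, name, None):
            raise ConfigurationError(f"missing packaged resource constant {name}")
    common1 = resources.ATTB1 + resources.JUNCTION_SPACER + resources.LOXP + scaffold.arm5[:15]
    frt = resources.FRT if include_frt else ""
    common2 = reverse_complement(
        scaffold.arm3 + scaffold.terminator + frt + resources.ATTB2
    )
    return CommonPrimerSet(common1, common2, include_frt)


@dataclass
class AssembledDonor:
    record: SeqRecord
    overlap_map: list[tuple[str, str, int]]


def _overlap_lengths(a: str, b: str, min_overlap: int) -> list[int]:
    limit = min(len(a), len(b))
    return [k for k in range(min_overlap, limit) if a[-k:] == b[:k]]


def simulate_overlap_extension(
    oligos: list[Oligo], min_overlap: int = 13
) -> AssembledDonor:
    """Merge oligos into the unique full-length duplex they encode.

    The chain must alternate plus/minus strand roles, and each adjacent pair
    must share exactly one exact-match overlap of >= ``min_overlap`` nt.
    Input order is irrelevant: the canonical chain is recovered by search.
    """
    if len(oligos) < 2:
        raise AssemblyError("need at least two oligos to assemble")
    successes: list[tuple[str, list[tuple[str, str, int]]]] = []
    best_partial: dict[tuple[str, str], int] = {}
    for perm in permutations(oligos):
        if any(a.strand_role == b.strand_role for a, b in zip(perm, perm[1:])):
            continue
        seq = perm[0].plus_seq
        overlaps: list[tuple[str, str, int]] = []
        ok = True
        for a, b in zip(perm, perm[1:]):
            ks = _overlap_lengths(seq, b.plus_seq, min_overlap)
            if not ks:
                probe = _overlap_lengths(a.plus_seq, b.plus_seq, 1)
                best_partial[(a.name, b.name)] = max(
                    best_partial.get((a.name, b.name), 0), max(probe, default=0)
                )
                ok = False
                break
            if len(ks) > 1:
                raise AmbiguousAssemblyError(
                    f"junction {a.name} -> {b.name} admits {len(ks)} overlap "
                    f"placements >= {min_overlap} nt: {ks}"
                )
            k = ks[0]
            overlaps.append((a.name, b.name, k))
            seq = seq + b.plus_seq[k:]
        if ok:
            successes.append((seq, overlaps))
    if not successes:
        partials = ", ".join(
            f"{a}->{b}: {k} nt" for (a, b), k in sorted(best_partial.items())
        ) or "none"
        raise AssemblyError(
            f"no valid overlap chain (min_overlap={min_overlap}); "
            f"best partial overlaps: {partials}"
        )
    seqs = {s for s, _ in successes}
    if len(seqs) > 1:
        raise AmbiguousAssemblyError(
            f"{len(seqs)} distinct assemblies satisfy the overlap constraints"
        )
    seq, overlaps = successes[0]
    record = SeqRecord("miRNA_donor", seq, "linear")
    return AssembledDonor(record, overlaps)


def _expected_layout(
    candidate: Candidate | None,
    scaffold: ScaffoldDefinition,
    include_frt: bool,
) -> list[tuple[str, str, str | int]]:
    """(label, kind, expected-seq-or-length) tuples in donor order."""
    site_len = 20 + len(scaffold.guide_tail)
    sense = candidate.duplex.sense_dna if candidate else site_len
    guide = candidate.duplex.guide_dna if candidate else site_len
    layout: list[tuple[str, str, str | int]] = [
        ("attB1", "attB1", resources.ATTB1),
        ("junction spacer", "spacer", resources.JUNCTION_SPACER),
        ("loxP", "loxP", resources.LOXP),
        ("5p arm", "scaffold_arm_5p", scaffold.arm5),
        ("sense", "sense", sense),
        ("loop", "loop", scaffold.loop),
        ("guide", "guide", guide),
        ("3p arm", "scaffold_arm_3p", scaffold.arm3),
        ("pol III terminator", "terminator", scaffold.terminator),
    ]
    if include_frt:
        layout.append(("FRT", "FRT", resources.FRT))
    layout.append(("attB2", "attB2", resources.ATTB2))
    return layout


def annotate_donor(
    record: SeqRecord,
    candidate: Candidate | None = None,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
    include_frt: bool = True,
) -> SeqRecord:
    """Attach the full contiguous feature layout to an assembled donor.

    Constant segments are verified against the packaged resources at their
    expected offsets; the variable sense/guide segments are verified against
    the candidate when one is given, else accepted by length after checking
    guide = rc(sense[1..20]) + tail.
    """
    layout = _expected_layout(candidate, scaffold, include_frt)
    feats: list[Feature] = []
    pos = 0
    segs: dict[str, str] = {}
    for label, kind, expected in layout:
        length = expected if isinstance(expected, int) else len(expected)
        seg = record.seq[pos : pos + length]
        if len(seg) != length:
            raise AnnotationError(
                f"donor truncated at offset {pos}: expected {label} ({length} nt)"
            )
        if isinstance(expected, str) and seg != expected:
            raise AnnotationError(
                f"unrecognized segment at offset {pos}: expected {label}"
            )
        segs[kind] = seg
        feats.append(Feature(label, kind, pos, pos + length))
        pos += length
    if pos != len(record.seq):
        raise AnnotationError(
            f"unrecognized trailing sequence at offset {pos} of the donor"
        )
    tail = scaffold.guide_tail
    if segs["guide"] != reverse_complement(segs["sense"][: len(segs["sense"]) - len(tail)]) + tail:
        raise AnnotationError(
            "guide segment is not rc(sense minus tail) + tail; "
            "not a valid shuttle layout"
        )
    return SeqRecord(record.id, record.seq, "linear", feats)


def donor_oligos(
    candidate: Candidate,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
    include_frt: bool = True,
) -> list[Oligo]:
    """All four construction oligos for one designed candidate."""
    common = build_common_primers(scaffold, include_frt)
    c1, c2 = common.as_oligos()
    return [
        c1,
        Oligo("miRNA primer 1", candidate.primers.primer1_minus, "minus"),
        Oligo("miRNA primer 2", candidate.primers.primer2_plus, "plus"),
        c2,
    ]


def build_donor(
    candidate: Candidate,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
    include_frt: bool = True,
    min_overlap: int = 13,
) -> AssembledDonor:
    """Design-to-donor convenience: oligos, assembly, annotation."""
    assembled = simulate_overlap_extension(
        donor_oligos(candidate, scaffold, include_frt), min_overlap
    )
    assembled.record = annotate_donor(
        assembled.record, candidate, scaffold, include_frt
    )
    return assembled


def oligo_sheet_tsv(oligos: list[Oligo]) -> str:
    lines = ["name\tlength\tsequence"]
    lines += [f"{o.name}\t{len(o.seq)}\t{o.seq}" for o in oligos]
    return "\n".join(lines) + "\n"
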