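"""Artificial-miRNA design: target-site scanning, duplex and hairpin
assembly on the miR-30a scaffold, and construction-oligo derivation.

The designer slides a 22-nt window along the query mRNA/CDS (plus strand
only) and keeps windows whose *guide* strand satisfies two published-rule
style heuristics:

1. **GC content** — the 22-nt mature guide must be <= 60% G+C, so the
   duplex is not too stable to unwind.
2. **Terminal asymmetry** — the guide must have strictly more G+C among its
   last ``asymmetry_window`` bases than its first, biasing RISC to load the
   guide (the complex prefers the thermodynamically weaker 5' end).

An additional filter, on by default, rejects candidates whose hairpin would
carry a run of >= 4 T upstream of the terminal terminator: such a run is a
pol III termination signal and would truncate the primary transcript.

The guide is the reverse complement of the first 20 site bases plus a
constant 2-nt ``AG`` tail; the tail leaves the engineered mismatch two bases
upstream of the Drosha cut site that proper processing requires.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import resources
from .errors import InputTooShortError, ParameterError
from .seqcore import Feature, reverse_complement, transcribe


@dataclass(frozen=True)
class ScaffoldDefinition:
    """Constant miR-30a-derived segments wrapping a designed duplex.

    Defaults: 18-nt 5' arm, 17-nt loop, 13-nt 3' arm, 2-nt guide tail, and a
    6-T pol III terminator — a 98-nt primary-miRNA unit around a 22-nt site.
    """

    arm5: str = resources.ARM5
    loop: str = resources.LOOP
    arm3: str = resources.ARM3
    guide_tail: str = resources.GUIDE_TAIL
    terminator: str = resources.TERMINATOR

    def __post_init__(self) -> None:
        for name in ("arm5", "loop", "arm3", "guide_tail", "terminator"):
            value = getattr(self, name)
            if not value or set(value) - set("ACGT"):
                raise ParameterError(f"scaffold segment {name} must be non-empty DNA")

    @property
    def hairpin_length(self) -> int:
        # arm5 + site + loop + guide + arm3 + terminator
        site = 20 + len(self.guide_tail)
        return len(self.arm5) + 2 * site + len(self.loop) + len(self.arm3) + len(self.terminator)


DEFAULT_SCAFFOLD = ScaffoldDefinition()


@dataclass(frozen=True)
class DesignParameters:
    """Tunable selection rules for target-site scanning."""

    paired_span: int = 20
    gc_max_percent: float = 60.0
    asymmetry_window: int = 4
    forbid_internal_terminator: bool = True
    min_t_run: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.asymmetry_window <= 4:
            raise ParameterError("asymmetry_window must be in 1..4")
        if not 0 < self.gc_max_percent <= 100:
            raise ParameterError("gc_max_percent must be in (0, 100]")
        if self.min_t_run < 1:
            raise ParameterError("min_t_run must be >= 1")

    def site_length(self, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD) -> int:
        return self.paired_span + len(scaffold.guide_tail)


DEFAULT_PARAMETERS = DesignParameters()


@dataclass(frozen=True)
class TargetSite:
    """A 22-nt plus-strand window of the query (1-based inclusive coords)."""

    query_id: str
    start_1based: int
    end_1based: int
    site_seq: str

    def __post_init__(self) -> None:
        if self.end_1based - self.start_1based + 1 != len(self.site_seq):
            raise ParameterError("site coordinates do not match sequence length")
        if set(self.site_seq) - set("ACGT"):
            raise ParameterError("target site must be unambiguous ACGT")


@dataclass(frozen=True)
class RuleReport:
    """Per-site rule evaluation, computed on the guide strand."""

    gc_percent_guide: float
    gc5: int
    gc3: int
    passes_gc: bool
    passes_asymmetry: bool
    internal_terminator: bool

    @property
    def passes(self) -> bool:
        return self.passes_gc and self.passes_asymmetry


@dataclass(frozen=True)
class MatureDuplex:
    """The designed sense/guide RNA pair (20 paired columns, 2-nt tails)."""

    sense_rna: str
    guide_rna: str
    paired_columns: int
    mismatch_note: str

    @property
    def sense_dna(self) -> str:
        return self.sense_rna.replace("U", "T")

    @property
    def guide_dna(self) -> str:
        return self.guide_rna.replace("U", "T")


@dataclass(frozen=True)
class Hairpin:
    """The full primary-miRNA unit (98 nt with the default scaffold)."""

    rna: str
    dna: str
    segments: tuple[Feature, ...]


@dataclass(frozen=True)
class MirnaPrimerPair:
    """The two miRNA-specific construction oligos (56/57-mers by default)."""

    primer1_minus: str
    primer2_plus: str


@dataclass(frozen=True)
class Candidate:
    site: TargetSite
    report: RuleReport
    duplex: MatureDuplex
    hairpin: Hairpin
    primers: MirnaPrimerPair


@dataclass
class DesignResult:
    query_id: str
    query_length: int
    candidates: list[Candidate] = field(default_factory=list)
    skipped_windows: int = 0


def _gc_count(seq: str) -> int:
    return sum(1 for c in seq.upper() if c in "GC")


def _guide_dna(site_seq: str, params: DesignParameters, scaffold: ScaffoldDefinition) -> str:
    return reverse_complement(site_seq[: params.paired_span]) + scaffold.guide_tail


def evaluate_rules(
    site: TargetSite,
    params: DesignParameters = DEFAULT_PARAMETERS,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
) -> RuleReport:
    """Apply the GC-content and terminal-asymmetry rules to one site.

    Both rules are evaluated on the 22-nt guide (constant tail included);
    the internal-terminator flag is computed on the hairpin coding DNA
    upstream of the terminal terminator.
    """
    guide = _guide_dna(site.site_seq, params, scaffold)
    gc_percent = 100.0 * _gc_count(guide) / len(guide)
    w = params.asymmetry_window
    gc5, gc3 = _gc_count(guide[:w]), _gc_count(guide[-w:])
    pre_terminator = (
        scaffold.arm5 + site.site_seq + scaffold.loop + guide + scaffold.arm3
    )
    internal = bool(re.search(f"T{{{params.min_t_run},}}", pre_terminator))
    return RuleReport(
        gc_percent_guide=gc_percent,
        gc5=gc5,
        gc3=gc3,
        passes_gc=gc_percent <= params.gc_max_percent,
        passes_asymmetry=gc3 > gc5,
        internal_terminator=internal,
    )


def build_duplex(
    site: TargetSite,
    params: DesignParameters = DEFAULT_PARAMETERS,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
) -> MatureDuplex:
    """Sense = transcribed site; guide = rc(site[1..20]) + constant tail."""
    sense = transcribe(site.site_seq)
    guide_dna = _guide_dna(site.site_seq, params, scaffold)
    guide = transcribe(guide_dna)
    span = params.paired_span
    paired = sum(
        1
        for j in range(min(span, len(sense), len(guide)))
        if _watson_crick(sense[j], guide[span - 1 - j])
    )
    tail = scaffold.guide_tail
    note = (
        f"guide 3' tail {tail!r} is a scaffold constant; it preserves the "
        "mismatch 2 nt upstream of the Drosha cut site required for processing"
    )
    return MatureDuplex(sense, guide, paired, note)


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _watson_crick(a: str, b: str) -> bool:
    return (a, b) in _WC


def assemble_hairpin(
    duplex: MatureDuplex, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD
) -> Hairpin:
    """Concatenate arm5 + sense + loop + guide + arm3 + terminator."""
    parts = [
        ("5p arm", "scaffold_arm_5p", scaffold.arm5),
        ("sense", "sense", duplex.sense_dna),
        ("loop", "loop", scaffold.loop),
        ("guide", "guide", duplex.guide_dna),
        ("3p arm", "scaffold_arm_3p", scaffold.arm3),
        ("pol III terminator", "terminator", scaffold.terminator),
    ]
    dna = "".join(p[2] for p in parts)
    feats = []
    pos = 0
    for label, kind, seg in parts:
        feats.append(Feature(label, kind, pos, pos + len(seg)))
        pos += len(seg)
    return Hairpin(rna=transcribe(dna), dna=dna, segments=tuple(feats))


def derive_mirna_primers(
    hairpin: Hairpin, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD
) -> MirnaPrimerPair:
    """Derive the two miRNA-specific oligos from a hairpin.

    Primer 1 (minus strand) reads back from the loop through the sense
    strand into all but the first base of the 5' arm; primer 2 (plus strand)
    runs from the last two sense bases through the loop, guide and 3' arm
    into a 3-T stub of the terminator.  The two overlap across the loop.
    """
    segs = {f.kind: f for f in hairpin.segments}
    sense = hairpin.dna[segs["sense"].start : segs["sense"].end]
    guide = hairpin.dna[segs["guide"].start : segs["guide"].end]
    primer1 = reverse_complement(scaffold.arm5[1:] + sense + scaffold.loop)
    primer2 = (
        sense[len(sense) - len(scaffold.guide_tail):]
        + scaffold.loop
        + guide
        + scaffold.arm3
        + scaffold.terminator[:3]
    )
    return MirnaPrimerPair(primer1_minus=primer1, primer2_plus=primer2)


def candidate_from_site(
    site_seq: str,
    start_1based: int = 1,
    query_id: str = "query",
    params: DesignParameters = DEFAULT_PARAMETERS,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
) -> Candidate:
    """Build a full candidate directly from a user-supplied site sequence."""
    site_seq = site_seq.upper().replace("U", "T")
    site = TargetSite(
        query_id, start_1based, start_1based + len(site_seq) - 1, site_seq
    )
    report = evaluate_rules(site, params, scaffold)
    duplex = build_duplex(site, params, scaffold)
    hairpin = assemble_hairpin(duplex, scaffold)
    primers = derive_mirna_primers(hairpin, scaffold)
    return Candidate(site, report, duplex, hairpin, primers)


def scan_targets(
    query: str,
    params: DesignParameters = DEFAULT_PARAMETERS,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
    query_id: str = "query",
) -> DesignResult:
    """Evaluate every 22-nt window of the query and keep rule-passing sites.

    Windows containing ambiguous bases are skipped (and tallied).  Output is
    deterministic and ordered by ascending position; no ranking is applied
    beyond pass/fail.
    """
    q = query.upper().replace("U", "T").replace(" ", "").replace("\n", "")
    site_len = params.site_length(scaffold)
    if len(q) < site_len:
        raise InputTooShortError(
            f"query of {len(q)} nt is shorter than one {site_len}-nt window"
        )
    result = DesignResult(query_id=query_id, query_length=len(q))
    acgt = set("ACGT")
    for i in range(len(q) - site_len + 1):
        window = q[i : i + site_len]
        if set(window) - acgt:
            result.skipped_windows += 1
            continue
        site = TargetSite(query_id, i + 1, i + site_len, window)
        report = evaluate_rules(site, params, scaffold)
        if not (report.passes_gc and report.passes_asymmetry):
            continue
        if params.forbid_internal_terminator and report.internal_terminator:
            continue
        duplex = build_duplex(site, params, scaffold)
        hairpin = assemble_hairpin(duplex, scaffold)
        primers = derive_mirna_primers(hairpin, scaffold)
        result.candidates.append(Candidate(site, report, duplex, hairpin, primers))
    return result


# ---------------------------------------------------------------------------
# Report formatting


def render_candidate(candidate: Candidate, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD) -> str:
    """One candidate block of the plain-text design report (byte-stable)."""
    from .grimqc import render_duplex  # late import; grimqc depends on seqcore only

    lines = [
        f"miRNA position: {candidate.site.start_1based}-{candidate.site.end_1based}",
        "Mature Duplex:",
        render_duplex(candidate.duplex, tail=len(scaffold.guide_tail)),
        "Full length GRIM.miRNA sequence:",
        f"5' {candidate.hairpin.rna} 3'",
        f"miRNA primer 1: 5' {candidate.primers.primer1_minus} 3'",
        f"miRNA primer 2: 5' {candidate.primers.primer2_plus} 3'",
    ]
    return "\n".join(lines)


def format_report(result: DesignResult, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD) -> str:
    """Full plain-text design report: header line, rule, candidate blocks."""
    blocks = [f"Query sequence: {result.query_length} nt", "-" * 22]
    for cand in result.candidates:
        blocks.append(render_candidate(cand, scaffold))
    return "\n".join(blocks) + "\n"


def candidates_tsv(result: DesignResult) -> str:
    header = "start_1based\tend_1based\tsite\tguide\tgc_percent\tgc5\tgc3"
    rows = [header]
    for c in result.candidates:
        rows.append(
            "\t".join([
                str(c.site.start_1based),
                str(c.site.end_1based),
                c.site.site_seq,
                c.duplex.guide_dna,
                f"{c.report.gc_percent_guide:.2f}",
                str(c.report.gc5),
                str(c.report.gc3),
            ])
        )
    return "\n".join(rows) + "\n"
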