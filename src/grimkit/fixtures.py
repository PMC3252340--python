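"""Synthetic, constraint-calibrated vector fixtures and query generation.

The true destination-vector and plasmid backbone sequences behind this
cloning system were never published; what is on record is a set of hard
numeric constraints the lifecycle must satisfy:

* the assembled linear donor is 219 bp,
* the BP junction upstream of the miRNA (attL1) is a 118-bp hybrid,
* Cre excision removes exactly 175 bp from the OFF plasmid,
* the ON transcript is 34 nt (one loxP) longer than a conventionally
  cloned U6 transcript of the same miRNA.

This module builds fully synthetic plasmids that satisfy all four
constraints simultaneously: real element sequences (loxP, FRT, attB,
scaffold) embedded in seeded, TTTT-free random filler.  The free geometry
is solved once — a 20-bp linker between the destination loxP and attP1 and
a 3-bp spacer between attB1 and loxP on the donor give an inter-loxP span
of 20 + 118 + 3 + 34 = 175 on the BP product.  The filler is TTTT-free so
pol III terminator logic is exercised only by intended elements, and
EcoRI-free so digestion screens see only deliberately placed sites.

An optional *banded* mode additionally solves backbone and cassette
lengths so that EcoRI digestion reproduces the diagnostic band pattern of
the real screening protocol: 3,501 + 2,170 + 805 bp for the empty
destination vector, 3,501 + 900 bp for the OFF plasmid and 3,501 + 725 bp
after Cre excision.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import resources
from .design import (
    Candidate,
    DEFAULT_SCAFFOLD,
    ScaffoldDefinition,
    candidate_from_site,
)
from .donor import AssembledDonor, build_donor
from .errors import ConstraintError, ParameterError
from .grimqc import scan_pol3_terminators
from .recombine import RecombinationEvent, bp_recombine, cre_recombine, flp_recombine
from .seqcore import ECORI, Feature, SeqRecord, find_motif

#: 22-nt example target site (the shuttle worked through this package's docs);
#: passes both selection rules and reproduces the reference design output.
EXAMPLE_SITE = "CGTTTGGACCCCGAGCCAAACT"

_OFF_BAND = 900          # EcoRI band spanning the miRNA cassette, OFF state
_BACKBONE_BAND = 3501    # invariant backbone band
_DEST_BANDS = (2170, 805)  # cassette-region bands of the empty destination


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry of the synthetic fixture set.

    The reference-length constraints (donor 219, attL1 118, Cre removal 175,
    transcript delta 34) are fixed; ``dest_linker_length`` and the 3-bp donor
    spacer are the documented default solution making them mutually
    consistent.  Filler lengths are free.
    """

    backbone_length: int = 3000
    seed: int = 42
    u6_length: int = 300
    cassette_length: int = 1500
    dest_linker_length: int = 20
    include_frt: bool = True
    banded: bool = False

    donor_constraint: int = 219
    attl1_constraint: int = 118
    cre_removal_constraint: int = 175
    transcript_delta_constraint: int = 34


def validate_constraints(
    config: FixtureConfig, scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD
) -> None:
    """Assert the reference-length constraints against the packaged geometry.

    This is pure arithmetic on element lengths — deliberately independent of
    the recombination engine, so a geometry regression is caught even if the
    engine were wrong in a compensating way.
    """
    r = resources
    spacer = len(r.JUNCTION_SPACER)
    donor_sum = (
        len(r.ATTB1) + spacer + len(r.LOXP)
        + scaffold.hairpin_length
        + len(r.FRT) + len(r.ATTB2)
    )
    if donor_sum != config.donor_constraint:
        raise ConstraintError(
            f"donor element lengths sum to {donor_sum}, not {config.donor_constraint}"
        )
    attl1 = r.ATTP1_CORE[0] + len(r.ATTB1) - r.ATTB1_CORE[0]
    if attl1 != config.attl1_constraint:
        raise ConstraintError(
            f"attL1 hybrid is {r.ATTP1_CORE[0]} + {len(r.ATTB1) - r.ATTB1_CORE[0]} "
            f"= {attl1} bp, not {config.attl1_constraint}"
        )
    inter_loxp = config.dest_linker_length + attl1 + spacer
    removal = inter_loxp + len(r.LOXP)
    if removal != config.cre_removal_constraint:
        raise ConstraintError(
            f"Cre removal = linker {config.dest_linker_length} + attL1 {attl1} "
            f"+ spacer {spacer} + loxP {len(r.LOXP)} = {removal} bp, "
            f"not {config.cre_removal_constraint}"
        )
    if len(r.LOXP) != config.transcript_delta_constraint:
        raise ConstraintError(
            f"retained loxP is {len(r.LOXP)} nt; transcript delta constraint is "
            f"{config.transcript_delta_constraint}"
        )


def _filler(rng: random.Random, length: int) -> str:
    """Seeded random DNA with no TTTT run, no EcoRI site, and non-T edges."""
    if length <= 0:
        return ""
    out: list[str] = []
    while len(out) < length:
        c = rng.choice("ACGT")
        if c == "T" and (len(out) == 0 or len(out) == length - 1):
            continue
        trial = "".join(out[-5:]) + c
        if "TTTT" in trial or "GAATTC" in trial:
            continue
        out.append(c)
    return "".join(out)


def random_query(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Seeded random gene-like query with expected GC near ``gc_fraction``."""
    if length < 22:
        raise ParameterError(f"query length must be >= 22, got {length}")
    if not 0 <= gc_fraction <= 1:
        raise ParameterError("gc_fraction must be in [0, 1]")
    rng = random.Random(seed)
    bases = []
    for _ in range(length):
        if rng.random() < gc_fraction:
            bases.append(rng.choice("GC"))
        else:
            bases.append(rng.choice("AT"))
    return "".join(bases)


def _splice(seq: str, offset: int, insert: str) -> str:
    """Overwrite ``seq`` at ``offset`` with ``insert`` (length preserved)."""
    return seq[:offset] + insert + seq[offset + len(insert) :]


@dataclass
class FixtureSet:
    """Destination + conventional-U6 plasmids, the assembled donor, and the
    lifecycle records derived from them on demand."""

    config: FixtureConfig
    candidate: Candidate
    destination: SeqRecord
    conventional_u6: SeqRecord
    donor: AssembledDonor
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD
    _cache: dict = field(default_factory=dict, repr=False)

    def bp_event(self) -> RecombinationEvent:
        if "bp" not in self._cache:
            event = bp_recombine(self.donor.record, self.destination)
            event.products[0].id = "GRIM_miRNA_off"
            self._cache["bp"] = event
        return self._cache["bp"]

    def grim_off(self) -> SeqRecord:
        return self.bp_event().products[0]

    def cre_event(self) -> RecombinationEvent:
        if "cre" not in self._cache:
            event = cre_recombine(self.grim_off())
            event.products[0].id = "GRIM_miRNA_on"
            self._cache["cre"] = event
        return self._cache["cre"]

    def grim_on(self) -> SeqRecord:
        return self.cre_event().products[0]

    def flp_event(self) -> RecombinationEvent:
        if "flp" not in self._cache:
            event = flp_recombine(self.grim_on())
            event.products[0].id = "GRIM_miRNA_dead"
            self._cache["flp"] = event
        return self._cache["flp"]

    def flp_dead(self) -> SeqRecord:
        return self.flp_event().products[0]

    def lifecycle(self) -> dict:
        """Run design -> donor -> BP -> Cre -> Flp and return every stage."""
        return {
            "candidate": self.candidate,
            "donor": self.donor.record,
            "destination": self.destination,
            "grim_off": self.grim_off(),
            "grim_on": self.grim_on(),
            "flp_dead": self.flp_dead(),
            "events": [self.bp_event(), self.cre_event(), self.flp_event()],
        }


def _build_destination(config: FixtureConfig, rng: random.Random) -> SeqRecord:
    r = resources
    u6 = _filler(rng, config.u6_length)
    linker = _filler(rng, config.dest_linker_length)

    cassette_length = config.cassette_length
    backbone_length = config.backbone_length
    cassette_cut_rel = None
    backbone_cut_rels: tuple[int, int] | None = None
    if config.banded:
        # inner OFF-state region: FRT..attL2, everything the 900-bp band spans
        inner_off = (
            len(r.FRT) + config.u6_length + len(r.LOXP) + config.dest_linker_length
            + config.attl1_constraint + len(r.JUNCTION_SPACER) + len(r.LOXP)
            + DEFAULT_SCAFFOLD.hairpin_length + len(r.FRT) + len(r.ATTL2)
        )
        slack = _OFF_BAND - inner_off
        if slack < 2:
            raise ConstraintError(
                f"banded mode needs the {_OFF_BAND}-bp band to cover the "
                f"{inner_off}-bp cassette region plus margins"
            )
        x, y = slack // 2, slack - slack // 2
        backbone_length = _BACKBONE_BAND + slack
        pre = len(r.FRT) + config.u6_length + len(r.LOXP) + config.dest_linker_length
        cassette_length = (
            sum(_DEST_BANDS) - x - y - pre - len(r.ATTP1) - len(r.ATTP2)
        )
        if cassette_length < len(ECORI.recognition) + 2:
            raise ConstraintError("banded cassette length is unsatisfiable")
        cassette_cut_rel = _DEST_BANDS[0] - x - pre - len(r.ATTP1)
        if not 1 <= cassette_cut_rel <= cassette_length - len(ECORI.recognition):
            raise ConstraintError(
                f"cassette EcoRI site at relative cut {cassette_cut_rel} "
                f"falls outside the {cassette_length}-bp cassette"
            )
        backbone_cut_rels = (y, backbone_length - x)

    cassette = _filler(rng, cassette_length)
    backbone = _filler(rng, backbone_length)
    if config.banded:
        cassette = _splice(cassette, cassette_cut_rel - ECORI.cut_offset, ECORI.recognition)
        for cut in backbone_cut_rels:
            backbone = _splice(backbone, cut - ECORI.cut_offset, ECORI.recognition)

    parts = [
        ("FRT", "FRT", r.FRT),
        ("U6 promoter (synthetic placeholder)", "promoter", u6),
        ("loxP", "loxP", r.LOXP),
        ("linker", "spacer", linker),
        ("attP1", "attP1", r.ATTP1),
        ("Gateway cassette placeholder (ccdB/CmR)", "cassette", cassette),
        ("attP2", "attP2", r.ATTP2),
        ("backbone", "other", backbone),
    ]
    seq = "".join(p[2] for p in parts)
    feats = []
    pos = 0
    for label, kind, part in parts:
        feats.append(Feature(label, kind, pos, pos + len(part)))
        pos += len(part)
    return SeqRecord("GRIM_destination", seq, "circular", feats)


def _build_conventional(
    config: FixtureConfig, rng: random.Random, candidate: Candidate
) -> SeqRecord:
    u6 = _filler(rng, config.u6_length)
    backbone = _filler(rng, config.backbone_length)
    hairpin = candidate.hairpin
    seq = u6 + hairpin.dna + backbone
    feats = [Feature("U6 promoter (synthetic placeholder)", "promoter", 0, len(u6))]
    for f in hairpin.segments:
        feats.append(
            Feature(f.label, f.kind, f.start + len(u6), f.end + len(u6))
        )
    return SeqRecord("conventional_U6_miRNA", seq, "circular", feats)


def build_fixture_set(
    config: FixtureConfig | None = None,
    candidate: Candidate | None = None,
    scaffold: ScaffoldDefinition = DEFAULT_SCAFFOLD,
) -> FixtureSet:
    """Build the destination / conventional plasmids and the donor.

    Deterministic for a given ``config.seed``.  Raises
    :class:`~grimkit.errors.ConstraintError` when modified geometry cannot
    satisfy the reference-length constraints.
    """
    config = config or FixtureConfig()
    validate_constraints(config, scaffold)
    if candidate is None:
        candidate = candidate_from_site(EXAMPLE_SITE, start_1based=70)
    if not (candidate.report.passes and not candidate.report.internal_terminator):
        raise ParameterError("fixture candidate must pass all design rules")

    expected_ecori = 3 if config.banded else 0
    for attempt in range(25):
        rng = random.Random(config.seed * 1000003 + attempt)
        destination = _build_destination(config, rng)
        conventional = _build_conventional(config, rng, candidate)
        ecori_hits = len(find_motif(destination, ECORI.recognition, both_strands=True))
        runs = scan_pol3_terminators(destination.seq)
        if ecori_hits == expected_ecori and len(runs) == 3 and not find_motif(
            conventional, ECORI.recognition, both_strands=True
        ):
            break
    else:  # pragma: no cover - filler is constructed to avoid this
        raise ConstraintError("could not generate clean filler for the fixtures")

    donor = build_donor(candidate, scaffold, include_frt=config.include_frt)
    if config.include_frt and len(donor.record.seq) != config.donor_constraint:
        raise ConstraintError(
            f"assembled donor is {len(donor.record.seq)} bp, "
            f"expected {config.donor_constraint}"
        )
    return FixtureSet(config, candidate, destination, conventional, donor, scaffold)
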