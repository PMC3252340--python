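"""Site-specific recombination engine: Gateway BP, Cre/loxP and Flp/FRT.

All three reactions are modelled as deterministic cut-and-join operations
at the 5' boundary of each site's asymmetric crossover core:

* **BP** — double crossover between a linear donor (attB1...attB2) and a
  circular destination (attP1...attP2).  B1 pairs only with P1 and B2 only
  with P2.  The inter-attP cassette is replaced by the donor payload; the
  junctions become hybrid attL1/attL2 sites and the displaced cassette
  leaves as a linear attR-flanked byproduct.
* **Cre / Flp** — intramolecular events on two loxP / FRT sites.  Direct
  repeats excise the intervening segment plus one site (one site retained
  on each product); inverted repeats invert the intervening segment in
  place.  Site pairing is deterministic (coordinate order) for
  reproducibility; base count is conserved by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from . import resources
from .errors import (
    InsufficientSitesError,
    MultiSiteError,
    PartnerSpecificityError,
    SiteTopologyError,
)
from .seqcore import Feature, SeqRecord, find_motif, reverse_complement


@dataclass(frozen=True)
class RecombinationSiteDef:
    """A recombination site: sequence, crossover core, allowed partners."""

    name: str
    seq: str
    core: tuple[int, int]
    partners: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cs, ce = self.core
        if not 0 <= cs < ce <= len(self.seq):
            raise ValueError(f"{self.name}: core outside site")
        core_seq = self.seq[cs:ce]
        if core_seq == reverse_complement(core_seq):
            raise ValueError(f"{self.name}: crossover core must be asymmetric")

    @property
    def core_seq(self) -> str:
        return self.seq[self.core[0] : self.core[1]]

    @property
    def cut(self) -> int:
        """Offset of the crossover point (5' core boundary) within the site."""
        return self.core[0]


def default_catalog() -> dict[str, RecombinationSiteDef]:
    r = resources
    defs = [
        RecombinationSiteDef("attB1", r.ATTB1, r.ATTB1_CORE, ("attP1",)),
        RecombinationSiteDef("attB2", r.ATTB2, r.ATTB2_CORE, ("attP2",)),
        RecombinationSiteDef("attP1", r.ATTP1, r.ATTP1_CORE, ("attB1",)),
        RecombinationSiteDef("attP2", r.ATTP2, r.ATTP2_CORE, ("attB2",)),
        RecombinationSiteDef("loxP", r.LOXP, r.LOXP_CORE, ("loxP",)),
        RecombinationSiteDef("FRT", r.FRT, r.FRT_CORE, ("FRT",)),
        # hybrid products, for location/screening only
        RecombinationSiteDef("attL1", r.ATTL1, (r.ATTP1_CORE[0], r.ATTP1_CORE[0] + 7)),
        RecombinationSiteDef("attL2", r.ATTL2, (r.ATTB2_CORE[0], r.ATTB2_CORE[0] + 7)),
        RecombinationSiteDef("attR1", r.ATTR1, (r.ATTB1_CORE[0], r.ATTB1_CORE[0] + 7)),
        RecombinationSiteDef("attR2", r.ATTR2, (r.ATTP2_CORE[0], r.ATTP2_CORE[0] + 7)),
    ]
    return {d.name: d for d in defs}


DEFAULT_CATALOG = default_catalog()


@dataclass(frozen=True)
class SiteMatch:
    site: RecombinationSiteDef
    start: int
    end: int
    orientation: str  # "+" | "-"

    @property
    def name(self) -> str:
        return self.site.name


def locate_sites(
    record: SeqRecord,
    catalog: dict[str, RecombinationSiteDef] | None = None,
    names: tuple[str, ...] | None = None,
) -> list[SiteMatch]:
    """All catalog-site occurrences on a record, with core-derived orientation.

    When two matches overlap, the longer site wins (a hybrid att site
    subsumes the fragments of its parents); ties are resolved by position.
    """
    catalog = catalog if catalog is not None else DEFAULT_CATALOG
    raw: list[SiteMatch] = []
    for name, sd in catalog.items():
        if names is not None and name not in names:
            continue
        for start, strand in find_motif(record, sd.seq, both_strands=True):
            raw.append(SiteMatch(sd, start, start + len(sd.seq), strand))
    kept: list[SiteMatch] = []
    for m in sorted(raw, key=lambda m: (-(m.end - m.start), m.start)):
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: m.start)


@dataclass
class RecombinationEvent:
    kind: str  # "BP" | "Cre" | "Flp"
    inputs: list[SeqRecord]
    products: list[SeqRecord]
    removed_length: int
    report: str = ""
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "removed_length": self.removed_length,
                "products": [
                    {"id": p.id, "length": len(p.seq), "topology": p.topology}
                    for p in self.products
                ],
                "report": self.report,
                **self.details,
            },
            indent=2,
        )


def _features_within(
    record: SeqRecord, start: int, end: int, offset: int
) -> list[Feature]:
    """Features fully inside [start, end), shifted so ``start`` maps to ``offset``."""
    out = []
    for f in record.features:
        if f.wraps:
            continue
        if start <= f.start and f.end <= end:
            out.append(replace(f, start=f.start - start + offset, end=f.end - start + offset))
    return out


def _single_site(
    matches: list[SiteMatch], name: str, owner: str
) -> SiteMatch:
    found = [m for m in matches if m.name == name]
    if not found:
        raise SiteTopologyError(f"{owner} lacks an {name} site")
    if len(found) > 1:
        raise SiteTopologyError(f"{owner} carries {len(found)} {name} sites; expected one")
    m = found[0]
    if m.orientation != "+":
        raise SiteTopologyError(f"{owner}: {name} site is on the minus strand")
    return m


def bp_recombine(
    donor: SeqRecord,
    destination: SeqRecord,
    catalog: dict[str, RecombinationSiteDef] | None = None,
) -> RecombinationEvent:
    """BP reaction: replace the inter-attP cassette with the donor payload.

    Returns an event whose first product is the recombined circular vector
    (attL1/attL2 junctions) and second the linear attR-flanked byproduct.
    """
    catalog = catalog if catalog is not None else DEFAULT_CATALOG
    if donor.topology != "linear":
        raise SiteTopologyError("donor must be a linear record")
    if destination.topology != "circular":
        raise SiteTopologyError("destination must be a circular record")
    att_names = ("attB1", "attB2", "attP1", "attP2")
    donor_matches = locate_sites(donor, catalog, names=att_names)
    dest_matches = locate_sites(destination, catalog, names=att_names)
    donor_names = {m.name for m in donor_matches}
    dest_names = {m.name for m in dest_matches}
    for b, p in (("attB1", "attP1"), ("attB2", "attP2")):
        if b in donor_names and p not in dest_names and dest_names & {"attP1", "attP2"}:
            raise PartnerSpecificityError(
                f"{b} can only recombine with {p}; destination offers "
                f"{sorted(dest_names & {'attP1', 'attP2'})}"
            )
    b1 = _single_site(donor_matches, "attB1", "donor")
    b2 = _single_site(donor_matches, "attB2", "donor")
    if b1.start >= b2.start:
        raise SiteTopologyError("attB1 must precede attB2 on the donor")

    # normalize the circle: put attP1 at the origin so attP1-cut < attP2-cut
    p1_raw = _single_site(dest_matches, "attP1", "destination")
    dest = destination.rotated(p1_raw.start)
    dest_matches = locate_sites(dest, catalog, names=att_names)
    p1 = _single_site(dest_matches, "attP1", "destination")
    p2 = _single_site(dest_matches, "attP2", "destination")

    c1 = b1.start + catalog["attB1"].cut
    c2 = b2.start + catalog["attB2"].cut
    d1 = p1.start + catalog["attP1"].cut
    d2 = p2.start + catalog["attP2"].cut
    n = len(dest.seq)
    r = len(catalog["attP2"].seq) - catalog["attP2"].cut  # attP2 tail kept in product

    mid = donor.seq[c1:c2]
    kept_a, kept_b = dest.seq[d2:], dest.seq[:d1]
    product_seq = kept_a[r:] + kept_b + mid + kept_a[:r]
    off_b = n - d2 - r        # product offset where destination position 0 lands
    off_m = off_b + d1        # product offset where donor position c1 lands
    feats = (
        _features_within(dest, d2 + r, n, 0)
        + _features_within(dest, 0, d1, off_b)
        + _features_within(donor, c1, c2, off_m)
    )
    attl1_len = catalog["attP1"].cut + len(catalog["attB1"].seq) - catalog["attB1"].cut
    attl2_len = catalog["attB2"].cut + len(catalog["attP2"].seq) - catalog["attP2"].cut
    attl1_start = off_b + p1.start
    attl2_start = off_m + (b2.start - c1)  # attB2 head, then the attP2 tail
    feats.append(Feature("attL1", "attL1", attl1_start, attl1_start + attl1_len))
    feats.append(Feature("attL2", "attL2", attl2_start, attl2_start + attl2_len))
    product = SeqRecord(
        f"{destination.id}_x_{donor.id}", product_seq, "circular",
        sorted(feats, key=lambda f: f.start),
    )

    by_seq = donor.seq[:c1] + dest.seq[d1:d2] + donor.seq[c2:]
    by_feats = (
        _features_within(donor, 0, c1, 0)
        + _features_within(dest, d1, d2, c1)
        + _features_within(donor, c2, len(donor.seq), c1 + (d2 - d1))
    )
    attr1_len = catalog["attB1"].cut + len(catalog["attP1"].seq) - catalog["attP1"].cut
    attr2_len = catalog["attP2"].cut + len(catalog["attB2"].seq) - catalog["attB2"].cut
    by_feats.append(Feature("attR1", "attR1", b1.start, b1.start + attr1_len))
    by_feats.append(Feature("attR2", "attR2", len(by_seq) - attr2_len, len(by_seq)))
    byproduct = SeqRecord(
        "bp_byproduct", by_seq, "linear", sorted(by_feats, key=lambda f: f.start)
    )
    report = (
        f"BP: cassette of {d2 - d1} bp replaced by donor payload of {c2 - c1} bp; "
        f"attL1 junction {attl1_len} bp, attL2 junction {attl2_len} bp"
    )
    return RecombinationEvent(
        "BP", [donor, destination], [product, byproduct], 0, report,
        details={"attL1_length": attl1_len, "attL2_length": attl2_len},
    )


def _excise_or_invert(
    record: SeqRecord,
    kind: str,
    site_name: str,
    catalog: dict[str, RecombinationSiteDef],
    pair: tuple[int, int] | None,
) -> RecombinationEvent:
    matches = locate_sites(record, catalog, names=(site_name,))
    if len(matches) < 2:
        raise InsufficientSitesError(
            f"{kind} needs two {site_name} sites; found {len(matches)} on {record.id!r}"
        )
    if len(matches) > 2:
        if pair is None:
            raise MultiSiteError(
                f"{len(matches)} {site_name} sites on {record.id!r}; "
                "name the pair to recombine explicitly"
            )
        m1, m2 = matches[pair[0]], matches[pair[1]]
    else:
        m1, m2 = matches
    if m2.start < m1.start:
        m1, m2 = m2, m1
    seq = record.seq
    if m1.orientation == m2.orientation:  # direct repeats -> excision
        s1e, s2e = m1.end, m2.end
        retained = SeqRecord(
            f"{record.id}_floxed" if site_name == "loxP" else f"{record.id}_flipped_out",
            seq[:s1e] + seq[s2e:],
            record.topology,
            _features_within(record, 0, s1e, 0)
            + _features_within(record, s2e, len(seq), s1e),
        )
        excised = SeqRecord(
            f"{record.id}_excised",
            seq[s1e:s2e],
            "circular",
            _features_within(record, s1e, s2e, 0),
        )
        removed = s2e - s1e
        report = (
            f"{kind}: excised {removed} bp between direct-repeat {site_name} sites; "
            "one site retained on each product"
        )
        return RecombinationEvent(kind, [record], [retained, excised], removed, report)
    # inverted repeats -> inversion of the intervening segment
    a, b = m1.end, m2.start
    inner = reverse_complement(seq[a:b])
    # a feature at [s, e) inside [a, b) maps to [a + b - e, a + b - s), flipped
    flipped = [
        replace(
            f,
            start=b - f.end,
            end=b - f.start,
            strand="-" if f.strand == "+" else "+",
        )
        for f in _features_within(record, a, b, 0)
    ]
    product = SeqRecord(
        f"{record.id}_inverted",
        seq[:a] + inner + seq[b:],
        record.topology,
        _features_within(record, 0, a, 0)
        + flipped
        + _features_within(record, b, len(seq), b),
    )
    report = f"{kind}: inverted {b - a} bp between head-to-head {site_name} sites"
    return RecombinationEvent(kind, [record], [product], 0, report)


def cre_recombine(
    record: SeqRecord,
    catalog: dict[str, RecombinationSiteDef] | None = None,
    pair: tuple[int, int] | None = None,
) -> RecombinationEvent:
    """Cre/loxP: excision for direct repeats, inversion for inverted ones."""
    return _excise_or_invert(
        record, "Cre", "loxP", catalog if catalog is not None else DEFAULT_CATALOG, pair
    )


def flp_recombine(
    record: SeqRecord,
    catalog: dict[str, RecombinationSiteDef] | None = None,
    pair: tuple[int, int] | None = None,
) -> RecombinationEvent:
    """Flp/FRT: identical semantics to Cre, acting on FRT sites."""
    return _excise_or_invert(
        record, "Flp", "FRT", catalog if catalog is not None else DEFAULT_CATALOG, pair
    )
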