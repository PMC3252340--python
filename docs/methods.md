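# Methods

This note documents the models behind `grimkit`: what is simulated, which
parameters matter, which choices were genuinely open, and what the synthetic
fixtures do and do not establish about real vectors.

## Sequence substrate

Records are plain upper-case A/C/G/T/N strings with linear or circular
topology and typed features (closed kind vocabulary).  Coordinates are
0-based half-open internally and 1-based inclusive in all user-facing
reports.  On circular records a feature with `end < start` wraps the
origin; motif search and digestion operate on the doubled sequence with
deduplication, which is the simplest correct model for plasmids.  `N` never
matches in motif search and is rejected inside design windows.  File I/O is
delegated to Biopython; feature kinds round-trip through GenBank via a
`kind:` note qualifier, and unknown GenBank types come back as `other` with
their label preserved.

Restriction digestion cuts at `site_start + cut_offset` on the top strand
(EcoRI G^AATTC is the packaged enzyme).  A linear molecule with *k* sites
yields *k*+1 fragments, a circle *k* (one uncut-flagged pseudo-fragment for
*k* = 0).  Fragments are canonicalized by descending length, then sequence.

## Shuttle design

The designer slides a 22-nt window along the plus strand of the query (the
target is an mRNA/CDS; the reverse strand is deliberately not scanned).
Both published-rule heuristics are evaluated on the **guide** strand,
constant 2-nt tail included:

* GC(guide) ≤ `gc_max_percent` (default 60 %); the only worked reference
  design passes at 13/22 ≈ 59.1 %, consistent with this reading of "mature
  miRNA sequence".  Evaluating on the sense strand or the DNA site would
  shift the value by at most one base-equivalent; the guide was chosen
  because the guide is the mature, RISC-loaded species.
* Strict terminal asymmetry GC(3′ window) > GC(5′ window), window
  configurable between 3 and 4 (default 4).  Ties fail: equality gives the
  loading machinery no preference, so the site is not worth synthesizing.

The guide tail `AG` is treated as a scaffold constant rather than derived
from the target: it recreates the mismatch two bases upstream of the Drosha
site that processing requires, and the single available reference design is
consistent with a constant tail.  This is the main interpretive choice in
the module; a site-dependent tail cannot be ruled out from available
examples, and the tail is a `ScaffoldDefinition` field precisely so it can
be changed.

An internal-terminator filter (on by default, toggleable) rejects any
window whose hairpin coding DNA would contain a run of ≥ `min_t_run` (4) T
upstream of the terminal terminator.  This is not one of the two published
selection rules; it is an implication of the premature-termination model
below applied to the shuttle itself, and it is documented as such.

Candidates are reported in ascending position with no further ranking —
the source method defines pass/fail rules, not a score.  Output is
deterministic and byte-stable; reports print the query length header, the
1-based `miRNA position` line, the offset-aligned duplex with one pipe per
Watson–Crick column (20 for every default design), the 98-nt hairpin RNA
and both construction primers.

## Donor assembly

The four-oligo overlap-extension step is modelled as exact-match merging:
fragments must alternate strand roles and each junction must admit exactly
one suffix–prefix overlap ≥ `min_overlap`.  The default layout uses 14, 19
and 16-nt overlaps, so `min_overlap = 13` leaves one base of slack below
the smallest real junction.  No valid chain raises an assembly error
listing the best partial overlaps; two admissible placements at one
junction raise an ambiguity error.  Thermodynamics, mispriming and the
incompletely extended side products of a real extension reaction are out of
scope — those shorter products lack complete attB ends and cannot
participate in BP anyway.

Element-length bookkeeping: attB1 25 + spacer 3 + loxP 34 + hairpin 98 +
FRT 34 + attB2 25 = 219.  The element roles alone sum to 216; the donor
total of 219 bp therefore requires 3 bp not attributable to any named
element.  `grimkit` places this as a fixed TTTT-free `CAA` junction spacer
between attB1 and loxP — upstream of the post-Cre transcript, so it cannot
perturb the 34-nt transcript difference.  Its position and sequence are an
explicit calibration, not a derivation.

## Recombination model

Every site carries an asymmetric crossover core (8 bp for loxP/FRT, 7 bp
shared between attB/attP partners); the cut is placed at the core's 5′
boundary and hybrid sites are concatenations of the exchanged arms.  This
single convention gives:

* **BP** — attB1×attP1 and attB2×attP2 double crossover; partner
  specificity is enforced (B1 offered only P2 is an error).  The product
  carries attL1 = attP1 5′ arm + core + attB1 3′ arm; the synthetic attP1
  arm lengths are solved so attL1 is exactly 118 bp.  Canonical Gateway
  attL1 is ~100 bp; the 118-bp reference value is taken as authoritative for
  the packaged geometry, and which arms compose it is not derivable from
  public sequence, so the fixture treats 118 as a constraint.
* **Cre/Flp** — deterministic intramolecular events on the first site pair
  in coordinate order (real recombination is stochastic; determinism was
  chosen for reproducibility).  Direct repeats excise the intervening
  segment plus one site, leaving one site on each product; inverted repeats
  invert the segment in place, so a second application restores the
  original.  Intermolecular integration is out of scope, as are kinetics
  and efficiencies — the published 90 %/100 % figures are colony
  statistics, not molecular events.

Base count is conserved by construction in every event and property-tested
over randomized substrates.  Overlapping site matches are resolved in
favour of the longer site (a hybrid att subsumes fragments of its parents).

## Transcript logic

Pol III termination is modelled as the first maximal run of ≥ `min_run` T
(default 4; the run is included in the transcript — real U6 transcripts end
in a few U's, and comparisons only need one consistent convention) on the
coding strand downstream of the single promoter feature.  The +1 is defined
as the first base after the promoter feature; the exact +1 of the real
promoter is not specified anywhere usable, and every comparison made here
(OFF vs ON, ON vs conventional) is invariant to a constant offset.
Termination is scanned on the coding strand only, matching the T-run
framing of the underlying model; the packaged attL1 orientation is the one
presenting its three runs to the transcript.

A prediction is `premature` when termination occurs before the hairpin's
own terminator, and `mature_producible` when the complete hairpin feature
set lies inside the transcript.  On the OFF fixture the first run ≥ 4 T
after +1 sits 18 nt into attL1, so the transcript is a 76-nt stub
(loxP 34 + linker 20 + 22 nt of attL1); after Cre the transcript is loxP +
hairpin = 132 nt, exactly 34 nt longer than the 98-nt conventional-U6
transcript — and this delta holds for every designed candidate, not just
the packaged example, because it is the length of the retained loxP.

## Synthetic fixtures

The destination vector is circular
`FRT – U6 placeholder – loxP – linker(20) – attP1 – cassette – attP2 – backbone`,
with all filler seeded, TTTT-free and EcoRI-free, so terminator logic and
digestion screens are exercised only by intended elements.  The U6 promoter
is a labelled placeholder: only its feature boundary matters to the
simulation.  The cassette placeholder stands in for the ccdB/CmR selection
cassette, whose biology (lethality, antibiotic selection) is wet-lab logic
outside the model.  Geometry defaults (linker 20, spacer 3) are the
documented solution of {donor 219, attL1 118, removal 175, Δ 34}; the
constraint arithmetic is asserted at build time independently of the
recombination engine, and any modified geometry that breaks it fails fast
with the arithmetic in the message.

Banded mode additionally solves backbone and cassette lengths and EcoRI
placements so the three screening digests reproduce the published band
patterns exactly (destination 3,501/2,170/805; OFF 3,501/900; ON
3,501/725).  The default fixtures do not carry these sites — band geometry
is opt-in because it constrains total plasmid length.

What passing tests show: the design algebra, assembly, recombination
semantics and transcript logic are mutually consistent and reproduce every
reference length and sequence.  What they cannot show: behaviour on the real
(unpublished) plasmid sequences, RNA secondary structure (the steric
component of attL1 inhibition is not modelled — only the termination
component), Drosha/Dicer processing outcomes, or any quantitative silencing
efficacy.

## Numerical and degenerate-input choices

Problem sizes are deliberately small — plasmids of a few kb, hundreds to a
thousand randomized property cases — because every operation is exact
string algebra and larger inputs add no information.  Empty sequences are
rejected at record construction; design queries shorter than one window
raise a dedicated error; ambiguous bases skip their windows and are
tallied rather than failing the scan.  Determinism is end-to-end: a seed
fixes the fixtures, and identical inputs give byte-identical reports.
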