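"""Packaged sequence constants.

Two classes of constants live here and the distinction matters:

* **Canonical element sequences** — the miR-30a-derived scaffold segments,
  the 34-bp loxP and minimal FRT sites, and the 25-bp Gateway attB core
  sites.  These are the field-standard sequences; the loxP halves and the
  FRT prefix are the ones embedded in the published destination-vector
  stitching primers.

* **Synthetic stand-ins** — the attP1/attP2 sites and (downstream, in the
  fixture builder) all plasmid filler.  The true destination-vector attP
  regions are not published, so the attP constants here are synthetic arms
  built around the same asymmetric crossover cores as their attB partners,
  with their lengths solved so that the attB1 x attP1 hybrid (attL1) is
  exactly 118 bp and carries exactly three runs of >= 4 T — the geometry
  the recombination and transcript-logic modules are specified against.
"""

from __future__ import annotations

# --- miR-30a scaffold segments (see design.ScaffoldDefinition) -------------
ARM5 = "TGTTGGACAGTGAGCGAT"        # 18 nt lower-stem 5' arm
LOOP = "GTAAAGCCACAGATGGG"         # 17 nt loop
ARM3 = "CGCCTACTGTCAC"             # 13 nt lower-stem 3' arm
GUIDE_TAIL = "AG"                  # 2 nt constant guide 3' tail (-2 mismatch)
TERMINATOR = "TTTTTT"              # engineered pol III termination signal

# --- recombination sites ---------------------------------------------------
#: Canonical 34-bp Cre target; 13-bp palindromic arms around an 8-bp
#: asymmetric core (ATGTATGC) that defines site orientation.
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"
LOXP_CORE = (13, 21)

#: Minimal 34-bp Flp target, same arm/core geometry (core TCTAGAAA).
FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"
FRT_CORE = (13, 21)

#: 25-bp Gateway attB core sites.  The 7-bp crossover cores (attB1: TGTACAA,
#: attB2: GTACAAA) are what B1/P1 and B2/P2 partners share; their asymmetry
#: enforces directional, partner-specific recombination.
ATTB1 = "ACAAGTTTGTACAAAAAAGCAGGCT"
ATTB1_CORE = (7, 14)
ATTB2 = "ACCCAGCTTTCTTGTACAAAGTGGT"
ATTB2_CORE = (13, 20)

#: SYNTHETIC attP1 (150 bp): 100-bp 5' arm + TGTACAA core + 43-bp 3' arm.
#: The 5' arm carries exactly three poly-T stretches (4/5/4 T) so the attL1
#: hybrid presents three pol III terminator runs to the U6 transcript.
ATTP1 = (
    "GCTTCTCGTAAGAGTTAATTTTAGAACCTACCGACCATGCAATTTTTGGCCTACCCGG"
    "TAATGCGTGATTTTGATAACGCTCGAGAATTAATTCAAGCGC"
    "TGTACAA"
    "CCCGCACGACGAGAGGTACGTACGAGGTCACTGTGGAAAATCG"
)
ATTP1_CORE = (100, 107)

#: SYNTHETIC attP2 (120 bp): 60-bp 5' arm + GTACAAA core + 53-bp 3' arm.
ATTP2 = (
    "GGTCCTACTGAGATTACCCGATGTGACATTAGCAGGCAGTGGTCGCGGGGAATGCCTCCC"
    "GTACAAA"
    "ACTTAGCCGCCGTTTCTCACCCACTATAGGAACTGAGTTCAGAACACGATCGA"
)
ATTP2_CORE = (60, 67)

# --- donor geometry --------------------------------------------------------
#: 3-bp junction spacer between attB1 and loxP on the donor.  The element
#: roles alone sum to 216 bp; this documented constant (TTTT-free, arbitrary
#: sequence) brings the assembled donor to its full 219 bp.  It sits
#: upstream of loxP, outside the post-Cre transcript.
JUNCTION_SPACER = "CAA"

# Derived hybrid sites, for annotation and screening.
ATTL1 = ATTP1[: ATTP1_CORE[0]] + ATTB1[ATTB1_CORE[0] :]   # 118 bp
ATTL2 = ATTB2[: ATTB2_CORE[0]] + ATTP2[ATTP2_CORE[0] :]   # 73 bp
ATTR1 = ATTB1[: ATTB1_CORE[0]] + ATTP1[ATTP1_CORE[0] :]   # 57 bp
ATTR2 = ATTP2[: ATTP2_CORE[0]] + ATTB2[ATTB2_CORE[0] :]   # 72 bp

assert len(ATTP1) == 150 and len(ATTP2) == 120
assert len(ATTL1) == 118, len(ATTL1)
assert ATTP1[ATTP1_CORE[0] : ATTP1_CORE[1]] == ATTB1[ATTB1_CORE[0] : ATTB1_CORE[1]]
assert ATTP2[ATTP2_CORE[0] : ATTP2_CORE[1]] == ATTB2[ATTB2_CORE[0] : ATTB2_CORE[1]]
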