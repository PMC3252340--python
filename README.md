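# grimkit

In-silico construction and lifecycle simulation of **GRIM**
(Gateway-Ready Inducible MiRNA) expression vectors — a recombinase-based
cloning system for artificial miRNA shuttles.

`grimkit` is for molecular biologists and tool builders who work with
miR-30-based RNAi vectors and want the whole workflow — target-site
selection, construction-oligo design, donor assembly, Gateway BP cloning,
Cre induction and Flp shutdown — as deterministic, testable code.

## The system in brief

An **artificial miRNA shuttle** replaces the mature arms of human miR-30a
with a user-designed sense/guide pair targeting a gene of interest.  For a
22-nt plus-strand target site *s*, the designer builds

```
guide  = rc(s[1..20]) + AG          (22 nt; constant tail keeps the −2 mismatch)
hairpin = arm5 + s + loop + guide + arm3 + T6   (18+22+17+22+13+6 = 98 nt)
```

and keeps only sites whose guide satisfies two selection rules:

* **GC rule** — GC(guide) ≤ 60 %, and
* **terminal asymmetry** — GC(guide[last *w*]) > GC(guide[first *w*]),
  *w* ∈ {3, 4}, so RISC loads the guide from its thermodynamically weaker
  5′ end.

A third filter (on by default) rejects hairpins carrying an internal run of
≥ 4 T, which RNA polymerase III would read as a premature terminator.

The hairpin is encoded on a 219-bp linear **donor**
(attB1–spacer–loxP–hairpin–FRT–attB2) extended from four oligos, and cloned
by **BP recombination** (attB×attP → attL) into a destination vector.  The
resulting *OFF* plasmid carries a loxP-flanked 118-bp attL1 hybrid between
the U6 promoter and the hairpin; attL1 presents three pol III terminator
runs, so transcription stops before the miRNA.  **Cre** excises 175 bp
(linker + attL1 + spacer + one loxP), switching the vector *ON* — its
transcript is exactly 34 nt (one retained loxP) longer than a
conventionally cloned U6 transcript.  **Flp** removes the whole
FRT-flanked expression cassette, permanently shutting the vector down.

The true plasmid backbones were never published, so `grimkit` ships
*synthetic*, constraint-calibrated fixtures: real element sequences
(loxP, FRT, attB, scaffold) in seeded TTTT-free filler, with the free
geometry solved so that all four reference lengths (219 / 118 / 175 / 34)
hold simultaneously.  An optional *banded* mode also solves the EcoRI
screening pattern (3,501+2,170+805 → 3,501+900 → 3,501+725 bp).

## Worked example

Design shuttles for a 1,073-nt query (here a seeded synthetic gene with
the documented example site spliced in at position 70):

```python
from grimkit import scan_targets, format_report
from grimkit.fixtures import random_query, EXAMPLE_SITE

query = random_query(1073, 0.5, seed=21)
query = query[:69] + EXAMPLE_SITE + query[91:]
print(format_report(scan_targets(query)))
```

The report starts `Query sequence: 1073 nt` and contains, among the
passing candidates, the block for the site at 70–91:

```
miRNA position: 70-91
Mature Duplex:
5'   CGUUUGGACCCCGAGCCAAACU 3'
     ||||||||||||||||||||
3' GAGCAAACCUGGGGCUCGGUUU   5'
Full length GRIM.miRNA sequence:
5' UGUUGGACAGUGAGCGAUCGUUUGGACCCCGAGCCAAACUGUAAAGCCACAGAUGGGUUUGGCUCGGGGUCCAAACGAGCGCCUACUGUCACUUUUUU 3'
miRNA primer 1: 5' CCCATCTGTGGCTTTACAGTTTGGCTCGGGGTCCAAACGATCGCTCACTGTCCAAC 3'
miRNA primer 2: 5' CTGTAAAGCCACAGATGGGTTTGGCTCGGGGTCCAAACGAGCGCCTACTGTCACTTT 3'
```

The duplex shows 20 paired columns with 2-nt 3′ overhangs; the two 56/57-nt
miRNA primers overlap each other across the 17-nt loop and, together with
the packaged 77/78-nt common primers, extend into the 219-bp donor.

Run the whole lifecycle from the shell:

```console
$ grim lifecycle
donor: 219 bp
destination: 5158 bp
GRIM off: 3748 bp
Cre removed: 175 bp
GRIM on: 3573 bp
after Flp: 3107 bp
```

Other subcommands: `grim design`, `grim donor`, `grim bp`, `grim cre`,
`grim flp`, `grim transcript`, `grim terminators`, `grim digest`,
`grim fixtures` (see `grim <cmd> --help`).  Records are read and written
as FASTA/GenBank; tabular outputs are TSV, event reports JSON.

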