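"""Transcriptional logic and sequence quality metrics.

Models why an unFLOXed (OFF) vector is silent and its Cre-excised (ON)
derivative expresses: RNA polymerase III terminates at runs of >= 4 T on the
coding strand, and the attL1 hybrid left by BP recombination presents three
such runs between the U6 promoter and the miRNA hairpin.  Excising attL1
restores read-through; the retained loxP makes the ON transcript exactly
34 nt longer than a conventionally cloned U6 transcript of the same miRNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import MissingFeatureError, OrientationError, ParameterError
from .seqcore import SeqRecord, transcribe

if TYPE_CHECKING:  # pragma: no cover
    from .design import MatureDuplex

#: Feature kinds that together constitute a complete miRNA hairpin unit.
HAIRPIN_KINDS = (
    "scaffold_arm_5p", "sense", "loop", "guide", "scaffold_arm_3p", "terminator",
)


@dataclass(frozen=True)
class TerminatorRun:
    """A maximal run of >= min_run T on the coding strand (0-based start)."""

    start: int
    length: int
    strand: str = "+"


def scan_pol3_terminators(seq: str, min_run: int = 4) -> list[TerminatorRun]:
    """All maximal T-runs of length >= ``min_run``, left to right."""
    if min_run < 1:
        raise ParameterError(f"min_run must be >= 1, got {min_run}")
    s = seq.upper().replace("U", "T")
    return [
        TerminatorRun(m.start(), m.end() - m.start())
        for m in re.finditer(f"T{{{min_run},}}", s)
    ]


def terminator_tsv(runs: list[TerminatorRun]) -> str:
    lines = ["run_start\trun_length"]
    lines += [f"{r.start}\t{r.length}" for r in runs]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TranscriptPrediction:
    """The U6 transcript implied by a record.

    ``start`` is the +1 position (first base after the promoter feature) and
    ``end`` the first position after the terminating T-run, both absolute on
    the record; the run itself is part of the transcript.  ``premature``
    means transcription stopped before the hairpin's own terminator;
    ``mature_producible`` means the complete hairpin lies inside the
    transcript, so processing can release a mature miRNA.
    """

    start: int
    end: int
    rna: str
    premature: bool
    mature_producible: bool

    @property
    def length(self) -> int:
        return len(self.rna)


def predict_u6_transcript(record: SeqRecord, min_run: int = 4) -> TranscriptPrediction:
    """Predict the pol III transcript of the single promoter on a record.

    Transcription starts at the first base after the promoter feature and
    runs to the end of the first T-run of >= ``min_run`` on the coding
    strand (or to the end of the scanned region when no run exists).
    """
    promoters = record.features_of_kind("promoter")
    if not promoters:
        raise MissingFeatureError(f"record {record.id!r} has no promoter feature")
    if len(promoters) > 1:
        raise MissingFeatureError(
            f"record {record.id!r} has {len(promoters)} promoter features; expected one"
        )
    prom = promoters[0]
    if prom.strand != "+":
        raise OrientationError("minus-strand promoters are not supported")
    n = len(record.seq)
    start = prom.end % n
    if record.is_circular:
        downstream = record.seq[start:] + record.seq[: prom.start]
    else:
        downstream = record.seq[start:]
    runs = scan_pol3_terminators(downstream, min_run)
    t_end_rel = runs[0].start + runs[0].length if runs else len(downstream)
    rna = transcribe(downstream[:t_end_rel])
    end = (start + t_end_rel) % n if record.is_circular else start + t_end_rel

    def rel(pos: int) -> int:
        return (pos - start) % n if record.is_circular else pos - start

    present: dict[str, bool] = {}
    terminator_rel_end: int | None = None
    for kind in HAIRPIN_KINDS:
        feats = record.features_of_kind(kind)
        inside = False
        for f in feats:
            r0 = rel(f.start)
            r1 = r0 + f.length(n)
            if 0 <= r0 and r1 <= t_end_rel:
                inside = True
            if kind == "terminator" and r0 >= 0 and r0 < len(downstream):
                terminator_rel_end = r1 if terminator_rel_end is None else min(terminator_rel_end, r1)
        present[kind] = inside
    mature = all(present.values())
    premature = terminator_rel_end is not None and t_end_rel < terminator_rel_end
    if mature:
        premature = False
    return TranscriptPrediction(start, end, rna, premature, mature)


def gc_percent(seq: str) -> float:
    """100 * (G+C) / length, case-insensitive, DNA or RNA."""
    if not seq:
        raise ParameterError("gc_percent of an empty sequence is undefined")
    s = seq.upper()
    return 100.0 * sum(1 for c in s if c in "GC") / len(s)


def terminal_asymmetry(guide: str, window: int) -> tuple[int, int, bool]:
    """G+C counts over the first/last ``window`` bases; pass iff gc3 > gc5.

    The strict inequality encodes the RISC-loading heuristic: the guide's 5'
    terminus must be the thermodynamically weaker end.
    """
    if not 1 <= window <= len(guide) // 2:
        raise ParameterError(
            f"window {window} out of range for a {len(guide)}-nt guide"
        )
    gc = lambda s: sum(1 for c in s.upper() if c in "GC")
    gc5, gc3 = gc(guide[:window]), gc(guide[-window:])
    return gc5, gc3, gc3 > gc5


_RNA_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def render_duplex(duplex: "MatureDuplex", tail: int = 2) -> str:
    """Three-line text block: sense 5'->3', pipe row, guide 3'->5'.

    The strands are drawn with the physical ``tail``-nt 3' overhang offset;
    a pipe marks every Watson-Crick paired column (20 for a default design).
    """
    sense, guide = duplex.sense_rna, duplex.guide_rna
    rev_guide = guide[::-1]
    top = "5' " + " " * tail + sense + " 3'"
    bottom = "3' " + rev_guide + " " * tail + " 5'"
    pipes = []
    for i, base in enumerate(sense):
        j = len(guide) - 1 - tail - i  # guide index aligned under sense[i]
        paired = 0 <= j < len(guide) and (base, guide[j]) in _RNA_WC
        pipes.append("|" if paired else " ")
    mid = ("   " + " " * tail + "".join(pipes)).rstrip()
    return "\n".join([top, mid, bottom])


def parse_duplex_block(text: str) -> tuple[str, str]:
    """Recover (sense 5'->3', guide 5'->3') from a rendered duplex block."""
    lines = text.splitlines()
    top = lines[0].replace("5'", "").replace("3'", "").strip()
    bottom = lines[-1].replace("3'", "").replace("5'", "").strip()
    return top, bottom[::-1]
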