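"""Readthrough extension ORFs and dual-luciferase reporter inserts.

A readthrough event decodes the annotated stop codon as a sense codon
and continues in frame until the next stop.  The *extension region* is
the codons strictly between the two stops; the appended peptide is one
residue longer because the recoded stop itself is decoded (a 66-codon
between-stop region yields a 67-aa extension).  Reporter inserts take
6 nt of CDS upstream of the stop plus up to 12 nt downstream, truncated
to whole codons before any in-frame stop so the luciferase fusion stays
in frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from readthrough.annotation import STOP_CODONS, StopContext, TranscriptModel


@dataclass
class ExtensionORF:
    """The readthrough extension of one transcript."""

    transcript_id: str
    between_stops_codons: int
    peptide: str  # recoded-stop residue first, marked with `recoded_aa`
    terminated: bool
    second_stop: tuple[str, int] | None  # (codon, transcript coord), if found

    @property
    def extension_aa_length(self) -> int:
        """Residues appended on readthrough: recoded stop + downstream codons."""
        return 1 + self.between_stops_codons


@dataclass
class ReporterInsert:
    """Stop-codon context formatted for a dual-luciferase fusion."""

    transcript_id: str
    sequence: str  # upstream + stop + truncated downstream
    control_sequence: str  # same with the stop replaced by TGG
    upstream: str
    stop_codon: str
    downstream: str
    truncated_reason: str  # none | inframe_stop | short_utr

    @property
    def downstream_len(self) -> int:
        return len(self.downstream)


def find_extension(
    t: TranscriptModel,
    recoded_aa: str = "X",
) -> ExtensionORF:
    """Scan in frame past the annotated stop for the next stop codon.

    Translates the between-stop codons with the standard genetic code;
    the residue decoded at the recoded stop is rendered as ``recoded_aa``
    since the amino acid inserted there is not determined by sequence
    alone.  If the transcript ends before another in-frame stop the ORF
    is returned unterminated with the available codons translated.
    """
    utr = t.sequence[t.cds_end :]
    codons: list[str] = []
    second_stop: tuple[str, int] | None = None
    for i in range(0, len(utr) - 2, 3):
        codon = utr[i : i + 3].upper()
        if codon in STOP_CODONS:
            second_stop = (codon, t.cds_end + i)
            break
        codons.append(codon)
    peptide = recoded_aa + str(Seq("".join(codons)).translate())
    return ExtensionORF(
        transcript_id=t.transcript_id,
        between_stops_codons=len(codons),
        peptide=peptide,
        terminated=second_stop is not None,
        second_stop=second_stop,
    )


def design_reporter_insert(
    c: StopContext, up: int = 6, down: int = 12
) -> ReporterInsert:
    """Design the test insert (and its TGG sense-codon control) for a context.

    The downstream segment is truncated to end before the first in-frame
    stop codon within the window, keeping whole codons only; a downstream
    segment shorter than the window because the 3'UTR ran out is flagged
    ``short_utr``.  The control differs only by stop -> TGG, the variant
    used to measure 100% readthrough.
    """
    upstream = c.upstream[-up:] if up else ""
    window = c.downstream[:down]
    reason = "none" if len(window) == down else "short_utr"
    downstream = window
    for i in range(0, len(window) - 2, 3):
        codon = window[i : i + 3].upper()
        if codon in STOP_CODONS:
            downstream = window[:i]
            reason = "inframe_stop"
            break
    seq = upstream + c.stop_codon + downstream
    control = upstream + "TGG" + downstream
    return ReporterInsert(
        transcript_id=c.transcript_id,
        sequence=seq,
        control_sequence=control,
        upstream=upstream,
        stop_codon=c.stop_codon,
        downstream=downstream,
        truncated_reason=reason,
    )


def export_peptides(orfs: Iterable[ExtensionORF], path: str | Path) -> int:
    """Write extension peptides of terminated ORFs as FASTA; returns count."""
    n = 0
    with open(path, "w") as fh:
        for orf in orfs:
            if not orf.terminated:
                continue
            fh.write(f">{orf.transcript_id} extension_aa={orf.extension_aa_length}\n")
            fh.write(orf.peptide + "\n")
            n += 1
    return n


def orfs_to_tsv(orfs: Iterable[ExtensionORF], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tbetween_stops_codons\textension_aa_length\t"
            "terminated\tsecond_stop_codon\tsecond_stop_pos\n"
        )
        for o in orfs:
            codon, pos = o.second_stop if o.second_stop else ("", "")
            fh.write(
                f"{o.transcript_id}\t{o.between_stops_codons}\t"
                f"{o.extension_aa_length}\t{o.terminated}\t{codon}\t{pos}\n"
            )
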