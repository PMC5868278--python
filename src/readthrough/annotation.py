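"""Transcript models and stop-codon context extraction.

Reads a genome FASTA plus a GTF of transcript models, splices each
transcript, locates its annotated stop codon and extracts the flanking
context (6 nt upstream, up to 12 nt downstream by default) that is the
unit of the downstream motif census and reporter-insert design.

Coordinates are 0-based half-open in transcript space throughout;
``cds_end`` points just past the stop codon.  The GTF is read in the
GENCODE dialect by default (CDS features exclude the stop codon); pass
``stop_in_cds=True`` for annotations whose terminal CDS includes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class TranscriptModel:
    """A spliced transcript with its CDS span in transcript coordinates.

    ``exons`` are genomic 0-based half-open intervals listed in
    transcript (5'->3') order, so the first exon of a minus-strand
    transcript is the genomically rightmost one.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int  # exclusive; points just past the stop codon
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.cds_end - 3 : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript coordinate to a genomic coordinate (0-based)."""
        if tpos < 0 or tpos >= len(self.sequence):
            raise IndexError(f"transcript position {tpos} out of range")
        off = 0
        for gstart, gend in self.exons:
            length = gend - gstart
            if tpos < off + length:
                within = tpos - off
                if self.strand == "+":
                    return gstart + within
                return gend - 1 - within
            off += length
        raise IndexError(f"transcript position {tpos} beyond exon span")

    @property
    def stop_genomic_pos(self) -> int:
        """Genomic coordinate of the first nucleotide of the stop codon."""
        return self.transcript_to_genomic(self.cds_end - 3)

    @property
    def genomic_key(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.stop_genomic_pos)


@dataclass(frozen=True)
class StopContext:
    """Stop codon plus fixed flanks; the unit of the motif census."""

    transcript_id: str
    stop_codon: str
    upstream: str  # up to 6 nt of CDS immediately 5' of the stop
    downstream: str  # up to 12 nt of 3'UTR immediately 3' of the stop
    genomic_key: tuple[str, str, int]
    short_upstream: bool = False
    short_downstream: bool = False


def _read_genome(fasta: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}


def _splice(genome_seq: str, exons_asc: Sequence[tuple[int, int]], strand: str) -> str:
    chunks = [genome_seq[s:e] for s, e in exons_asc]
    seq = "".join(chunks)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def load_transcripts(
    fasta: str | Path,
    gtf: str | Path,
    stop_in_cds: bool = False,
) -> tuple[list[TranscriptModel], list[tuple[str, str]]]:
    """Load transcript models whose CDS ends in a valid stop codon.

    Parameters
    ----------
    fasta
        Genome FASTA; record ids are chromosome names referenced by the GTF.
    gtf
        Transcript models with ``exon`` and ``CDS`` features carrying
        ``transcript_id``/``gene_id`` attributes.
    stop_in_cds
        If True the annotated CDS already includes the stop codon
        (non-GENCODE dialect); otherwise the stop is the 3 nt following
        the last CDS base.

    Returns
    -------
    (models, skipped)
        Retained transcripts, and ``(transcript_id, reason)`` pairs for
        those excluded (reasons: ``missing_sequence``, ``no_cds``,
        ``truncated``, ``cds_length``, ``no_stop``).
    """
    genome = _read_genome(fasta)
    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_tx: dict[str, list] = {}
    cds_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for ftype, store in (("exon", exons_by_tx), ("CDS", cds_by_tx)):
        for f in db.features_of_type(ftype):
            tid = f.attributes["transcript_id"][0]
            store.setdefault(tid, []).append(f)
            gene = f.attributes.get("gene_id", [tid])[0]
            meta.setdefault(tid, (gene, f.seqid, f.strand))

    models: list[TranscriptModel] = []
    skipped: list[tuple[str, str]] = []
    for tid in sorted(meta):
        gene_id, chrom, strand = meta[tid]
        if chrom not in genome:
            skipped.append((tid, "missing_sequence"))
            continue
        if tid not in cds_by_tx:
            skipped.append((tid, "no_cds"))
            continue
        exon_feats = exons_by_tx.get(tid) or cds_by_tx[tid]
        exons_asc = sorted((f.start - 1, f.end) for f in exon_feats)
        seq = _splice(genome[chrom], exons_asc, strand)
        exons_tx_order = exons_asc if strand == "+" else exons_asc[::-1]

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            sequence=seq,
            cds_start=0,
            cds_end=0,
            chrom=chrom,
            strand=strand,
            exons=exons_tx_order,
        )
        # Map CDS genomic endpoints into transcript coordinates.
        gpos_to_tpos = {
            model.transcript_to_genomic(t): t for t in range(len(seq))
        }
        try:
            tpositions = [
                gpos_to_tpos[g]
                for f in cds_by_tx[tid]
                for g in (f.start - 1, f.end - 1)
            ]
        except KeyError:
            skipped.append((tid, "missing_sequence"))
            continue
        cds_start = min(tpositions)
        cds_end = max(tpositions) + 1
        if not stop_in_cds:
            cds_end += 3
        if cds_end > len(seq):
            skipped.append((tid, "truncated"))
            continue
        if (cds_end - cds_start) % 3 != 0:
            skipped.append((tid, "cds_length"))
            continue
        model.cds_start = cds_start
        model.cds_end = cds_end
        if model.stop_codon not in STOP_CODONS:
            skipped.append((tid, "no_stop"))
            continue
        models.append(model)

    for tid, reason in skipped:
        logger.warning("skipping transcript %s: %s", tid, reason)
    return models, skipped


def extract_stop_context(t: TranscriptModel, up: int = 6, down: int = 12) -> StopContext:
    """Extract the stop codon and its flanks from a retained transcript.

    The upstream flank is confined to the CDS (a CDS shorter than
    ``up + 3`` nt yields a shortened, flagged upstream) and the
    downstream flank is truncated at the transcript end.
    """
    stop_start = t.cds_end - 3
    upstream = t.sequence[max(t.cds_start, stop_start - up) : stop_start]
    downstream = t.sequence[t.cds_end : t.cds_end + down]
    return StopContext(
        transcript_id=t.transcript_id,
        stop_codon=t.stop_codon,
        upstream=upstream,
        downstream=downstream,
        genomic_key=t.genomic_key,
        short_upstream=len(upstream) < up,
        short_downstream=len(downstream) < down,
    )


def dedupe_stops(contexts: Iterable[StopContext]) -> list[StopContext]:
    """Keep one context per genomic stop-codon position (first seen wins)."""
    seen: dict[tuple[str, str, int], StopContext] = {}
    n_dup = 0
    for c in contexts:
        if c.genomic_key in seen:
            n_dup += 1
        else:
            seen[c.genomic_key] = c
    if n_dup:
        logger.info("dedupe_stops: dropped %d duplicate contexts", n_dup)
    return list(seen.values())


def contexts_to_tsv(contexts: Iterable[StopContext], path: str | Path) -> None:
    """Write contexts as a TSV (one row per context)."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tstop_codon\tupstream\tdownstream\t"
            "chrom\tstrand\tstop_genomic_pos\n"
        )
        for c in contexts:
            chrom, strand, pos = c.genomic_key
            fh.write(
                f"{c.transcript_id}\t{c.stop_codon}\t{c.upstream}\t"
                f"{c.downstream}\t{chrom}\t{strand}\t{pos}\n"
            )
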