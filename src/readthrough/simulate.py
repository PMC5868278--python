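"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the real data the pipeline consumes:

* :func:`gen_transcriptome` — a single-isoform transcriptome (genome
  FASTA + GTF) with controllable stop-codon usage, post-stop nucleotide
  frequencies, and a planted multiplicative depletion/enrichment factor
  for a 4-nt motif after UGA stops;
* :func:`simulate_codon_alignment` — codon alignments evolved down a
  phylogeny under a coding or noncoding substitution model, with
  optional indels of length 1–3 nt (so frameshifting events occur);
* :func:`gen_plate` — dual-luciferase plates with a known true
  readthrough efficiency and multiplicative lognormal noise;
* :func:`gen_dose_response` — 4-parameter-logistic dose–response tables
  with known EC50s.

All randomness in a call flows from one ``numpy`` generator seeded by
the spec's integer seed, so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from readthrough.annotation import STOP_CODONS, StopContext, TranscriptModel
from readthrough.phylo import CodonAlignment, CodonModel

NUCS = "ACGT"
_WORDS4 = ["".join(w) for w in itertools.product(NUCS, repeat=4)]


# ---------------------------------------------------------------------------
# Transcriptome


@dataclass
class TranscriptomeSpec:
    """Parameters of the synthetic transcriptome.

    ``post_stop_freqs`` gives the per-position nucleotide frequency
    vectors (ACGT order) for the 4 nt immediately after the stop codon;
    ``motif_factor`` multiplies the joint probability of ``motif`` after
    UGA stops (``<1`` plants a depletion, ``>1`` an enrichment).
    """

    n_transcripts: int = 500
    utr3_length_range: tuple[int, int] = (30, 200)
    stop_codon_mix: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.47, "TAG": 0.24, "TGA": 0.29}
    )
    post_stop_freqs: np.ndarray = field(
        default_factory=lambda: np.full((4, 4), 0.25)
    )
    motif: str = "CTAG"
    motif_factor: float = 1.0
    cds_codon_range: tuple[int, int] = (20, 100)
    utr5_length_range: tuple[int, int] = (10, 50)
    seed: int = 0

    def __post_init__(self):
        self.post_stop_freqs = np.asarray(self.post_stop_freqs, dtype=float)
        if self.post_stop_freqs.shape != (4, 4):
            raise ValueError("post_stop_freqs must be 4 vectors of 4")
        if not np.allclose(self.post_stop_freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each post-stop frequency vector must sum to 1")
        mix = np.array([self.stop_codon_mix.get(s, 0.0) for s in sorted(STOP_CODONS)])
        if not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("stop_codon_mix must sum to 1 over TAA/TAG/TGA")
        if self.motif_factor < 0:
            raise ValueError("motif_factor must be non-negative")
        if len(self.motif) != 4 or any(n not in NUCS for n in self.motif):
            raise ValueError("motif must be a 4-nt DNA string")
        if self.motif_factor * self._motif_p0() > 1.0 + 1e-12:
            raise ValueError("adjusted joint motif probability exceeds 1")
        if self.utr3_length_range[0] < 4:
            raise ValueError("3'UTR must be at least 4 nt for the motif window")

    def _motif_p0(self) -> float:
        return float(
            np.prod(
                [self.post_stop_freqs[i, NUCS.index(n)] for i, n in enumerate(self.motif)]
            )
        )

    def word_probs(self, adjusted: bool) -> np.ndarray:
        """Joint probabilities of all 4-mers after the stop.

        ``adjusted=True`` applies ``motif_factor`` to the planted motif
        (used after UGA stops) and rescales the other words so the
        distribution still sums to 1.
        """
        p = np.array(
            [
                np.prod([self.post_stop_freqs[i, NUCS.index(n)] for i, n in enumerate(w)])
                for w in _WORDS4
            ]
        )
        if not adjusted or self.motif_factor == 1.0:
            return p
        m = _WORDS4.index(self.motif)
        pm = min(self.motif_factor * p[m], 1.0)
        if p[m] < 1.0:
            p *= (1.0 - pm) / (1.0 - p[m])
        p[m] = pm
        return p / p.sum()


@dataclass
class SyntheticTranscriptome:
    """Generated genome + transcript models, with writers for FASTA/GTF."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    gtf_text: str

    @property
    def fasta_text(self) -> str:
        out = []
        for chrom, seq in self.genome.items():
            out.append(f">{chrom}")
            out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    def write(self, fasta: str | Path, gtf: str | Path) -> None:
        Path(fasta).write_text(self.fasta_text)
        Path(gtf).write_text(self.gtf_text)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NUCS), size=n)) if n else ""


def _rand_sense_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        c = _rand_seq(rng, 3)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


def _tx_interval_to_genomic(exons_tx_order, strand, start, end):
    """Map a transcript-space interval to genomic intervals, exon by exon."""
    out = []
    off = 0
    for gstart, gend in exons_tx_order:
        length = gend - gstart
        s, e = max(start, off), min(end, off + length)
        if s < e:
            if strand == "+":
                out.append((gstart + (s - off), gstart + (e - off)))
            else:
                out.append((gend - (e - off), gend - (s - off)))
        off += length
    return sorted(out)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def gen_transcriptome(spec: TranscriptomeSpec) -> SyntheticTranscriptome:
    """Generate a transcriptome with a planted post-UGA motif factor.

    Each transcript is a single isoform with 1–3 exons on a random
    strand of one synthetic chromosome.  The CDS ends in a stop drawn
    from ``stop_codon_mix``; the first 4 nt of the 3'UTR are drawn from
    ``post_stop_freqs`` — jointly adjusted by ``motif_factor`` when the
    stop is TGA — and the rest of the UTRs are uniform random sequence.
    The GTF uses the GENCODE dialect (CDS excludes the stop codon).
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chrS"
    p_plain = spec.word_probs(adjusted=False)
    p_uga = spec.word_probs(adjusted=True)
    stops = sorted(spec.stop_codon_mix)
    stop_p = np.array([spec.stop_codon_mix[s] for s in stops])

    genome_parts: list[str] = []
    gpos = 0
    gtf_lines: list[str] = []
    transcripts: list[TranscriptModel] = []

    for i in range(spec.n_transcripts):
        tid = f"TX{i:05d}"
        gid = f"G{i:05d}"
        utr5 = _rand_seq(rng, int(rng.integers(*spec.utr5_length_range)))
        n_cds = int(rng.integers(*spec.cds_codon_range))
        cds_body = _rand_sense_codons(rng, n_cds)
        stop = stops[rng.choice(len(stops), p=stop_p)]
        utr3_len = int(rng.integers(*spec.utr3_length_range))
        probs = p_uga if stop == "TGA" else p_plain
        head = _WORDS4[rng.choice(len(_WORDS4), p=probs)]
        utr3 = head + _rand_seq(rng, utr3_len - 4)
        seq = utr5 + cds_body + stop + utr3

        cds_start = len(utr5)
        cds_end = cds_start + len(cds_body) + 3  # past the stop
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), len(seq)]
        exon_lens = [bounds[k + 1] - bounds[k] for k in range(n_exons)]
        intron_lens = [int(rng.integers(30, 80)) for _ in range(n_exons - 1)]

        # Build the genomic locus in transcript orientation, then flip
        # the whole segment for minus-strand genes.
        pieces = []
        exon_local: list[tuple[int, int]] = []  # within-locus, tx orientation
        off = 0
        for k in range(n_exons):
            exon_seq = seq[bounds[k] : bounds[k + 1]]
            exon_local.append((off, off + exon_lens[k]))
            pieces.append(exon_seq)
            off += exon_lens[k]
            if k < n_exons - 1:
                pieces.append(_rand_seq(rng, intron_lens[k]))
                off += intron_lens[k]
        locus = "".join(pieces)
        if strand == "-":
            locus = locus[::-1].translate(_COMPLEMENT)
            exon_local = [(len(locus) - e, len(locus) - s) for s, e in exon_local]
        exons_tx_order = [(gpos + s, gpos + e) for s, e in exon_local]
        genome_parts.append(locus)
        genome_parts.append(_rand_seq(rng, 50))
        gpos += len(locus) + 50

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            sequence=seq,
            cds_start=cds_start,
            cds_end=cds_end,
            chrom=chrom,
            strand=strand,
            exons=exons_tx_order,
        )
        transcripts.append(model)

        exons_asc = sorted(exons_tx_order)
        feats = [("exon", s, e) for s, e in exons_asc]
        cds_giv = _tx_interval_to_genomic(
            exons_tx_order, strand, cds_start, cds_end - 3
        )
        feats += [("CDS", s, e) for s, e in cds_giv]
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        for ftype, s, e in sorted(feats, key=lambda f: (f[1], f[0])):
            gtf_lines.append(
                f"{chrom}\tsynth\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )

    genome = {chrom: "".join(genome_parts)}
    return SyntheticTranscriptome(genome, transcripts, "\n".join(gtf_lines) + "\n")


def gen_stop_contexts(spec: TranscriptomeSpec) -> list[StopContext]:
    """Generate stop contexts directly, without genome/GTF plumbing.

    Draws from the same distributions as :func:`gen_transcriptome`
    (stop-codon mix, post-stop word probabilities with the motif factor
    applied after TGA stops) but emits :class:`StopContext` objects with
    unique synthetic genomic keys.  Useful for census-scale statistical
    experiments where splicing and file round-trips are irrelevant.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    p_plain = spec.word_probs(adjusted=False)
    p_uga = spec.word_probs(adjusted=True)
    stops = sorted(spec.stop_codon_mix)
    stop_p = np.array([spec.stop_codon_mix[s] for s in stops])

    stop_idx = rng.choice(len(stops), size=n, p=stop_p)
    word_idx = rng.choice(len(_WORDS4), size=n, p=p_plain)
    uga = np.array([stops[i] == "TGA" for i in stop_idx])
    if uga.any():
        word_idx[uga] = rng.choice(len(_WORDS4), size=int(uga.sum()), p=p_uga)
    nucs = np.array(list(NUCS))
    tails = nucs[rng.integers(0, 4, size=(n, 8))]
    ups = nucs[rng.integers(0, 4, size=(n, 6))]
    return [
        StopContext(
            transcript_id=f"TX{i:05d}",
            stop_codon=stops[stop_idx[i]],
            upstream="".join(ups[i]),
            downstream=_WORDS4[word_idx[i]] + "".join(tails[i]),
            genomic_key=("chrS", "+", 1000 * i),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class AlignmentSimSpec:
    """Parameters of a codon-alignment simulation down a tree."""

    tree: dendropy.Tree
    n_codons: int
    regime: str  # "coding" | "noncoding"
    indel_rate: float = 0.0  # events per codon per unit branch length
    ref_name: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.regime not in ("coding", "noncoding"):
            raise ValueError(f"unknown regime {self.regime!r}")


def _sample_rows(P: np.ndarray, states: np.ndarray, rng: np.random.Generator):
    """Sample next states given transition matrix rows for current states."""
    P = np.clip(P, 0.0, None)
    out = np.empty_like(states)
    u = rng.random(states.size)
    for k, s in enumerate(states):
        row = P[s]
        c = np.cumsum(row / row.sum())
        out[k] = np.searchsorted(c, u[k])
    return out


def simulate_codon_alignment(
    spec: AlignmentSimSpec, model: CodonModel
) -> CodonAlignment:
    """Evolve codons down the tree; overlay indel events as alignment gaps.

    The root is drawn from the model's stationary distribution and each
    branch applies the model's transition probabilities per codon.
    Indel events occur on each branch with Poisson rate
    ``indel_rate * n_codons * branch_length``; each is a deletion or an
    insertion (1–3 nt, uniform) placed uniformly, inherited by the whole
    descendant clade.  Substitutions are simulated on the root codon
    lattice, so indels do not feed back into the substitution process.
    """
    if spec.regime != model.regime:
        raise ValueError(
            f"spec regime {spec.regime!r} != model regime {model.regime!r}"
        )
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    n = spec.n_codons
    L = 3 * n

    from readthrough.phylo import CODONS  # local import to avoid cycle at load

    root_states = rng.choice(64, size=n, p=model.pi)
    node_states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    # Indel bookkeeping: deletions as root-coordinate position sets per
    # node path; insertions as (anchor, seq, clade) events.
    node_dels: dict[int, set[int]] = {id(tree.seed_node): set()}
    insertions: list[tuple[int, str, set[str]]] = []

    def clade_leaves(node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        t = node.edge.length if node.edge.length is not None else 0.0
        if t < 0:
            raise ValueError("tree has a negative branch length")
        P = model.transition_matrix(t)
        node_states[id(node)] = _sample_rows(P, node_states[id(parent)], rng)
        dels = set(node_dels[id(parent)])
        n_events = rng.poisson(spec.indel_rate * n * t)
        for _ in range(n_events):
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                start = int(rng.integers(0, L))
                dels.update(range(start, min(start + length, L)))
            else:
                anchor = int(rng.integers(0, L + 1))
                insertions.append((anchor, _rand_seq(rng, length), clade_leaves(node)))
        node_dels[id(node)] = dels

    leaves = list(tree.leaf_node_iter())
    names = [lf.taxon.label for lf in leaves]
    rows: dict[str, list[str]] = {name: [] for name in names}
    ins_by_anchor: dict[int, list[tuple[str, set[str]]]] = {}
    for anchor, seq, clade in insertions:
        ins_by_anchor.setdefault(anchor, []).append((seq, clade))

    leaf_seq = {
        lf.taxon.label: "".join(CODONS[s] for s in node_states[id(lf)])
        for lf in leaves
    }
    leaf_dels = {lf.taxon.label: node_dels[id(lf)] for lf in leaves}
    for pos in range(L + 1):
        for seq, clade in ins_by_anchor.get(pos, []):
            for name in names:
                rows[name].append(seq if name in clade else "-" * len(seq))
        if pos < L:
            for name in names:
                rows[name].append(
                    "-" if pos in leaf_dels[name] else leaf_seq[name][pos]
                )
    ref = spec.ref_name or names[0]
    return CodonAlignment({n_: "".join(r) for n_, r in rows.items()}, ref)


# ---------------------------------------------------------------------------
# Luciferase plates


@dataclass
class PlateSimSpec:
    """Parameters of a simulated dual-luciferase readthrough plate."""

    true_efficiency: float = 0.067
    n_replicates: int = 12
    cv: float = 0.1  # coefficient of variation of lognormal reading noise
    construct: str = "construct1"
    batch: str = "plate1"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.true_efficiency <= 1.0:
            raise ValueError("true_efficiency must be in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


_BASE_FIREFLY = 5.0e5
_BASE_RENILLA = 1.0e6


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)  # median 1


def gen_plate(spec: PlateSimSpec) -> pd.DataFrame:
    """Simulate paired TGA (test) and TGG (control) luciferase wells.

    The TGA well's firefly signal is the control's scaled by the true
    readthrough efficiency; every reading carries independent
    multiplicative lognormal noise with the requested CV (median 1, so
    the per-replicate efficiency is median-unbiased).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for variant in ("TGA", "TGG"):
        f_base = _BASE_FIREFLY * (
            spec.true_efficiency if variant == "TGA" else 1.0
        )
        fnoise = _lognoise(rng, spec.cv, spec.n_replicates)
        rnoise = _lognoise(rng, spec.cv, spec.n_replicates)
        for r in range(spec.n_replicates):
            rows.append(
                {
                    "batch": spec.batch,
                    "construct": spec.construct,
                    "variant": variant,
                    "treatment": "none",
                    "dose": 0.0,
                    "replicate": r + 1,
                    "firefly": f_base * fnoise[r],
                    "renilla": _BASE_RENILLA * rnoise[r],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose-response curves


def gen_dose_response(
    ec50s: dict[str, float],
    hill: float = 1.0,
    fold_range: float = 6.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_doses: int = 12,
    dose_range: tuple[float, float] = (1e-12, 1e-6),
    n_replicates: int = 3,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Simulate 4-parameter-logistic responses on a log-spaced dose grid.

    ``ec50s`` maps construct name to its EC50 (same units as
    ``dose_range``); the response spans ``floor`` to ``floor *
    fold_range``.  Multiplicative lognormal noise (median 1) is applied
    per reading.
    """
    if not all(e > 0 for e in ec50s.values()):
        raise ValueError("every EC50 must be positive")
    if not (math.isfinite(hill) and hill > 0):
        raise ValueError("hill slope must be finite and positive")
    if fold_range <= 1:
        raise ValueError("fold_range must exceed 1")
    rng = np.random.default_rng(seed)
    doses = np.logspace(
        math.log10(dose_range[0]), math.log10(dose_range[1]), n_doses
    )
    span = floor * (fold_range - 1.0)
    rows = []
    for construct, ec50 in ec50s.items():
        for d in doses:
            mu = floor + span / (1.0 + (ec50 / d) ** hill)
            noise = _lognoise(rng, noise_cv, n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "construct": construct,
                        "dose": d,
                        "replicate": r + 1,
                        "response": mu * noise[r],
                    }
                )
    return pd.DataFrame(rows)
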