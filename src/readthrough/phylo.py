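"""Phylogenetic coding-potential scoring of codon alignments.

Scores a reference-framed codon alignment for protein-coding
evolutionary signature with a likelihood ratio between two reversible
64-state codon substitution models evaluated by Felsenstein pruning:

* **coding** — a GY94-style model: single-nucleotide exchanges between
  sense codons at rate proportional to the target codon's stationary
  frequency, multiplied by kappa for transitions and omega for
  nonsynonymous changes; stop codons carry zero stationary mass and no
  flow.
* **noncoding** — three independent HKY nucleotide processes composed
  onto the codon space (stops included), i.e. evolution with no reading
  frame.

The score is reported in decibans, ``10 * log10`` of the
coding/noncoding likelihood ratio, the convention used by
comparative-genomics coding-potential scores; positive values favour
protein-coding evolution.  The scorer is a self-contained simplified
model with documented parameters, not a reimplementation of any
empirically trained codon model, so published scores on real alignments
are comparison points rather than expected outputs.

Rate matrices are scaled so one unit of branch length equals 3 expected
substitutions per codon (one per nucleotide site), matching trees whose
branch lengths are in nucleotide substitutions per site.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCS = "ACGT"
_NUC_IDX = {n: i for i, n in enumerate(NUCS)}
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_IDX = {c: i for i, c in enumerate(CODONS)}
STOPS = ("TAA", "TAG", "TGA")
STOP_IDX = frozenset(CODON_IDX[s] for s in STOPS)
AA = [str(Seq(c).translate()) for c in CODONS]
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


# ---------------------------------------------------------------------------
# Codon substitution models


@dataclass
class CodonModel:
    """A reversible 64-state codon rate matrix with cached spectral form."""

    regime: str  # "coding" | "noncoding"
    Q: np.ndarray  # (64, 64), rows sum to 0
    pi: np.ndarray  # stationary distribution, sums to 1
    kappa: float
    omega: float | None
    nuc_freqs: np.ndarray  # (3, 4) per-codon-position nucleotide frequencies
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def _spectral(self):
        # Symmetric-form eigendecomposition restricted to states with mass.
        if self._eig is None:
            support = np.flatnonzero(self.pi > 0)
            d = np.sqrt(self.pi[support])
            S = (d[:, None] * self.Q[np.ix_(support, support)]) / d[None, :]
            S = 0.5 * (S + S.T)
            w, U = np.linalg.eigh(S)
            self._eig = (support, d, w, U)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); identity on zero-mass (stop, coding) states."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        support, d, w, U = self._spectral()
        E = U @ (np.exp(w * t)[:, None] * U.T)
        Ps = (E / d[:, None]) * d[None, :]
        P = np.eye(64)
        P[np.ix_(support, support)] = Ps
        return P


def _hky_q(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """HKY85 4x4 rate matrix, normalized to 1 substitution/site/unit time."""
    Q = np.empty((4, 4))
    for i, a in enumerate(NUCS):
        for j, b in enumerate(NUCS):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (a, b) in _TRANSITIONS else 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(freqs, np.diag(Q)))
    return Q / rate


def _as_position_freqs(nuc_freqs) -> np.ndarray:
    f = np.asarray(nuc_freqs, dtype=float)
    if f.ndim == 1:
        f = np.tile(f, (3, 1))
    if f.shape != (3, 4):
        raise ValueError("nuc_freqs must be 4 frequencies or a (3, 4) array")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each nucleotide frequency vector must sum to 1")
    if np.any(f <= 0):
        raise ValueError("nucleotide frequencies must be strictly positive")
    return f


def build_model(
    regime: str,
    kappa: float = 2.5,
    omega: float | None = 0.2,
    nuc_freqs=(0.25, 0.25, 0.25, 0.25),
) -> CodonModel:
    """Build the coding (GY94-style) or noncoding (composed-HKY) model.

    Parameters
    ----------
    regime
        ``"coding"`` or ``"noncoding"``.
    kappa
        Transition/transversion rate ratio (> 0).
    omega
        Nonsynonymous/synonymous rate ratio; required and > 0 for the
        coding regime, ignored for noncoding.
    nuc_freqs
        One frequency vector over ACGT shared by all codon positions, or
        a (3, 4) array of per-position vectors (F3x4 style).
    """
    if regime not in ("coding", "noncoding"):
        raise ValueError(f"unknown regime {regime!r}")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    f = _as_position_freqs(nuc_freqs)

    if regime == "noncoding":
        qs = [_hky_q(f[p], kappa) for p in range(3)]
        I4 = np.eye(4)
        Q = (
            np.kron(np.kron(qs[0], I4), I4)
            + np.kron(np.kron(I4, qs[1]), I4)
            + np.kron(np.kron(I4, I4), qs[2])
        )
        pi = np.kron(np.kron(f[0], f[1]), f[2])
        return CodonModel("noncoding", Q, pi, kappa, None, f)

    if omega is None or omega <= 0:
        raise ValueError("coding regime requires omega > 0")
    pi = np.array(
        [f[0][_NUC_IDX[c[0]]] * f[1][_NUC_IDX[c[1]]] * f[2][_NUC_IDX[c[2]]]
         for c in CODONS]
    )
    pi[list(STOP_IDX)] = 0.0
    pi /= pi.sum()
    Q = np.zeros((64, 64))
    for i, ci in enumerate(CODONS):
        if i in STOP_IDX:
            continue
        for j, cj in enumerate(CODONS):
            if i == j or j in STOP_IDX:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if diffs[0] in _TRANSITIONS:
                rate *= kappa
            if AA[i] != AA[j]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(Q)))
    Q *= 3.0 / rate  # 3 substitutions per codon per unit branch length
    return CodonModel("coding", Q, pi, kappa, omega, f)


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class CodonAlignment:
    """A gapped multi-sequence alignment framed by a reference row."""

    rows: dict[str, str]
    ref_name: str
    frame_offset: int = 0

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.ref_name not in self.rows:
            raise ValueError(f"reference row {self.ref_name!r} not in alignment")

    @property
    def ncol(self) -> int:
        return len(self.rows[self.ref_name])

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ref_positions(self) -> list[int]:
        """Alignment columns at which the reference row has a base."""
        ref = self.rows[self.ref_name]
        return [i for i in range(self.frame_offset, len(ref)) if ref[i] != "-"]

    def ref_codon_columns(self) -> list[tuple[int, int, int]]:
        """Column-index triples of the reference-frame codons."""
        pos = self.ref_positions()
        n = len(pos) // 3
        return [tuple(pos[3 * c : 3 * c + 3]) for c in range(n)]


def read_alignment(
    path: str | Path, ref_name: str | None = None, frame_offset: int = 0
) -> CodonAlignment:
    """Read a gapped multi-FASTA alignment; the first record is the
    reference unless ``ref_name`` is given."""
    rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"empty alignment file {path}")
    if ref_name is None:
        ref_name = next(iter(rows))
    return CodonAlignment(rows, ref_name, frame_offset)


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in aln.rows:
            fh.write(f">{name}\n{aln.rows[name]}\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def f3x4_freqs(aln: CodonAlignment, pseudocount: float = 1.0) -> np.ndarray:
    """Position-specific nucleotide frequencies from reference-frame codons."""
    counts = np.full((3, 4), pseudocount, dtype=float)
    cols = aln.ref_codon_columns()
    for seq in aln.rows.values():
        for triple in cols:
            for p, col in enumerate(triple):
                nuc = seq[col]
                if nuc in _NUC_IDX:
                    counts[p, _NUC_IDX[nuc]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Likelihood


def _leaf_states(
    aln: CodonAlignment, model: CodonModel, mask_stops: bool = False
) -> dict[str, np.ndarray]:
    """Per-species codon state indices per reference codon; -1 = missing.

    A codon containing a gap or ambiguity, or one the model assigns zero
    stationary mass, is treated as missing data.  ``mask_stops``
    additionally treats every stop codon as missing regardless of the
    model — used when comparing coding and noncoding likelihoods, so
    both are computed on the same observations.
    """
    cols = aln.ref_codon_columns()
    out: dict[str, np.ndarray] = {}
    for name, seq in aln.rows.items():
        states = np.full(len(cols), -1, dtype=int)
        for c, triple in enumerate(cols):
            codon = "".join(seq[i] for i in triple)
            idx = CODON_IDX.get(codon)
            if idx is None:
                continue
            if model.pi[idx] <= 0:
                continue
            if mask_stops and idx in STOP_IDX:
                continue
            states[c] = idx
        out[name] = states
    return out


def _prepare_tree(tree: dendropy.Tree, species: Sequence[str]) -> dendropy.Tree:
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(species) - leaf_labels)
    if missing:
        raise ValueError(f"alignment species absent from tree: {missing}")
    work = tree.clone(depth=1)
    if leaf_labels - set(species):
        work.retain_taxa_with_labels(list(species))
    return work

def felsenstein_loglik(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    model: CodonModel,
    mask_stops: bool = False,
) -> float:
    """Log-likelihood (nats) of the alignment under the model by pruning.

    Codon columns are treated as independent; partial likelihoods are
    rescaled per column to avoid underflow.  A column impossible under
    the model (e.g. two different codons joined by zero-length branches)
    contributes a hard-zero column likelihood: the result is ``-inf`` or
    an astronomically negative finite value (spectral round-off leaves
    transition entries of order 1e-15), never an exception.
    """
    cols = aln.ref_codon_columns()
    if not cols:
        raise ValueError("alignment has no complete reference-frame codon")
    states = _leaf_states(aln, model, mask_stops)
    work = _prepare_tree(tree, aln.species)
    ncod = len(cols)

    log_scale = np.zeros(ncod)
    partials: dict[int, np.ndarray] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            st = states[node.taxon.label]
            part = np.zeros((64, ncod))
            missing = st < 0
            part[:, missing] = 1.0
            obs = np.flatnonzero(~missing)
            part[st[obs], obs] = 1.0
        else:
            part = np.ones((64, ncod))
            for child in node.child_nodes():
                t = child.edge.length if child.edge.length is not None else 0.0
                P = model.transition_matrix(t)
                part = part * (P @ partials.pop(id(child)))
            cmax = part.max(axis=0)
            nz = cmax > 0
            part[:, nz] /= cmax[nz]
            with np.errstate(divide="ignore"):
                log_scale += np.where(nz, np.log(np.where(nz, cmax, 1.0)), -np.inf)
        partials[id(node)] = part

    root = partials[id(work.seed_node)]
    site_lik = model.pi @ root
    with np.errstate(divide="ignore"):
        logl = np.log(site_lik) + log_scale
    return float(np.sum(logl))


LOG10_FACTOR = 10.0 / math.log(10.0)


@dataclass
class ScoreResult:
    """Coding-potential likelihood-ratio score in decibans."""

    score: float
    logL_coding: float
    logL_noncoding: float
    n_codons: int
    species_used: list[str]
    masked_ref_stops: list[int] = field(default_factory=list)


def csf_score(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    coding: CodonModel,
    noncoding: CodonModel,
) -> ScoreResult:
    """Score an alignment region: 10*log10 of the coding/noncoding ratio.

    The caller supplies the region with its bounding stop codons already
    excluded.  Any stop codons remaining inside the region are masked
    (treated as missing) under *both* models — the coding model assigns
    them zero probability, so keeping them under only one model would
    make the likelihoods incomparable; those found in the reference row
    are reported in ``masked_ref_stops`` (1-based codon indices).
    """
    cols = aln.ref_codon_columns()
    if not cols:
        raise ValueError("empty scoring region")
    ref = aln.rows[aln.ref_name]
    masked = [
        c + 1
        for c, triple in enumerate(cols)
        if "".join(ref[i] for i in triple) in STOPS
    ]
    logc = felsenstein_loglik(aln, tree, coding, mask_stops=True)
    logn = felsenstein_loglik(aln, tree, noncoding, mask_stops=True)
    return ScoreResult(
        score=LOG10_FACTOR * (logc - logn),
        logL_coding=logc,
        logL_noncoding=logn,
        n_codons=len(cols),
        species_used=aln.species,
        masked_ref_stops=masked,
    )


def clade_subset(
    aln: CodonAlignment,
    species: Sequence[str],
    tree: dendropy.Tree | None = None,
) -> tuple[CodonAlignment, dendropy.Tree | None]:
    """Restrict an alignment (and optionally its tree) to a species subset.

    Species absent from the alignment are logged and skipped; columns
    gapped in every retained row are dropped; the pruned tree keeps path
    lengths between retained leaves.
    """
    present = [s for s in species if s in aln.rows]
    missing = [s for s in species if s not in aln.rows]
    if missing:
        logger.warning("clade_subset: species not in alignment: %s", missing)
    if aln.ref_name not in present:
        present = [aln.ref_name] + present
    if len(present) < 2:
        raise ValueError("fewer than 2 species remain after subsetting")
    keep_cols = [
        j
        for j in range(aln.ncol)
        if any(aln.rows[s][j] != "-" for s in present)
    ]
    rows = {s: "".join(aln.rows[s][j] for j in keep_cols) for s in present}
    new_offset = sum(1 for j in keep_cols if j < aln.frame_offset)
    sub = CodonAlignment(rows, aln.ref_name, new_offset)
    pruned = None
    if tree is not None:
        pruned = tree.clone(depth=1)
        pruned.retain_taxa_with_labels(present)
    return sub, pruned


def background_percentile(score: float, background: Sequence[float]) -> float:
    """Fraction of background scores strictly below the query score."""
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background is empty")
    return float(np.mean(bg < score))


# ---------------------------------------------------------------------------
# Frame-integrity event calling


@dataclass(frozen=True)
class FrameEvent:
    """A per-species disruption of the putative extended reading frame."""

    species: str
    kind: str  # frameshift_indel | premature_stop | second_stop_loss
    codon_index: int  # 1-based position in the reference frame
    detail: str  # indel length or observed codon


def frame_integrity(
    aln: CodonAlignment, second_stop_codon_index: int
) -> list[FrameEvent]:
    """Call frame-disrupting events per species against the reference frame.

    The reference row defines the codon frame; codons 1..
    ``second_stop_codon_index`` (the bounding second stop) are examined.
    Per non-reference species, three event kinds are called:

    * ``frameshift_indel`` — an indel run (species gaps against
      reference bases, or species bases against reference gaps) after
      which the cumulative indel length within the region is no longer a
      multiple of 3, reported at the codon where frame is first lost; a
      later compensating indel restores frame and re-arms the caller.
    * ``premature_stop`` — a complete species codon that is a stop,
      before the reference second stop (reference stop positions are
      skipped and reported under the reference's own name).
    * ``second_stop_loss`` — a complete species codon at the reference
      second-stop position that is not a stop.
    """
    cols = aln.ref_codon_columns()
    idx = second_stop_codon_index
    if idx < 1 or idx > len(cols):
        raise ValueError("second_stop_codon_index outside reference frame")
    ref = aln.rows[aln.ref_name]

    region_start = cols[0][0]
    region_end = cols[idx - 1][2]  # inclusive
    # Map each alignment column in the region to a 1-based codon index;
    # insertion columns (reference gaps) belong to the following codon,
    # where their frame effect first shows.
    col_codon = {}
    for c, triple in enumerate(cols[:idx], start=1):
        for j in triple:
            col_codon[j] = c
    codon_of_col = [0] * (region_end - region_start + 1)
    current = idx
    for off in range(region_end - region_start, -1, -1):
        j = region_start + off
        if j in col_codon:
            current = col_codon[j]
        codon_of_col[off] = current

    def species_codon(seq: str, c: int) -> str:
        return "".join(seq[j] for j in cols[c - 1])

    events: list[FrameEvent] = []
    ref_internal = [
        c for c in range(1, idx) if species_codon(ref, c) in STOPS
    ]
    for c in ref_internal:
        events.append(
            FrameEvent(aln.ref_name, "premature_stop", c, species_codon(ref, c))
        )
    if species_codon(ref, idx) not in STOPS:
        logger.warning(
            "reference codon %d is %s, not a stop codon",
            idx,
            species_codon(ref, idx),
        )

    for name, seq in aln.rows.items():
        if name == aln.ref_name:
            continue
        # (a) frameshifting indel runs
        cum = 0
        frame_lost = False
        run_len = 0
        run_kind = None
        run_codon = 1
        def flush():
            nonlocal cum, frame_lost, run_len, run_kind
            if run_len == 0:
                return
            cum += run_len
            if cum % 3 != 0 and not frame_lost:
                events.append(
                    FrameEvent(name, "frameshift_indel", run_codon, str(run_len))
                )
                frame_lost = True
            elif cum % 3 == 0 and frame_lost:
                frame_lost = False
            run_len = 0
            run_kind = None

        for off, j in enumerate(range(region_start, region_end + 1)):
            rgap = ref[j] == "-"
            sgap = seq[j] == "-"
            kind = None
            if rgap and not sgap:
                kind = "ins"
            elif sgap and not rgap:
                kind = "del"
            if kind is None:
                flush()
                continue
            if kind != run_kind:
                flush()
                run_kind = kind
                run_codon = codon_of_col[off]
            run_len += 1
        flush()

        # (b) premature stops from substitutions
        for c in range(1, idx):
            if c in ref_internal:
                continue
            codon = species_codon(seq, c)
            if codon in STOPS:
                events.append(FrameEvent(name, "premature_stop", c, codon))

        # (c) loss of the bounding second stop
        codon = species_codon(seq, idx)
        if all(b in _NUC_IDX for b in codon) and codon not in STOPS:
            events.append(FrameEvent(name, "second_stop_loss", idx, codon))

    return events
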