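"""Stop-context motif census with a binomial depletion/enrichment test.

Counts how often a 3' tetranucleotide (default CTAG, i.e. the UGA_CUAG
readthrough motif in RNA space) immediately follows a given stop codon
across deduplicated stop contexts, computes the expected count under an
independence null built from the per-position nucleotide frequencies of
the same contexts, and tests the observed count against that null with a
one-sided exact binomial or Poisson-limit tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from readthrough.annotation import StopContext

NUCS = "ACGT"
_NUC_IDX = {n: i for i, n in enumerate(NUCS)}


def _norm(s: str) -> str:
    return s.upper().replace("U", "T")


@dataclass
class CensusResult:
    """Result of the motif depletion/enrichment test."""

    motif: tuple[str, str]  # (stop codon, downstream 4-mer), DNA space
    n_trials: int
    observed: int
    expected: float
    p_motif: float
    p_value: float
    direction: str  # "depletion" or "enrichment"
    mode: str
    position_freqs: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {
            "motif": f"{self.motif[0]}:{self.motif[1]}",
            "n_trials": self.n_trials,
            "observed": self.observed,
            "expected": self.expected,
            "p_motif": self.p_motif,
            "p_value": self.p_value,
            "direction": self.direction,
            "mode": self.mode,
        }
        if self.position_freqs is not None:
            d["position_freqs"] = self.position_freqs.tolist()
        return d


def scan_motif(
    contexts: Iterable[StopContext],
    motif: tuple[str, str] = ("TGA", "CTAG"),
) -> tuple[list[StopContext], list[StopContext], int]:
    """Scan contexts for a stop-codon + downstream-4-mer motif.

    A context is a *trial* if its stop codon matches the motif's stop and
    it has at least 4 unambiguous downstream nucleotides; a trial is a
    *hit* if its downstream sequence begins with the motif 4-mer.
    Matching is case-insensitive and accepts RNA (U) spelling.

    Returns ``(hits, trials, n_short)`` where ``n_short`` counts contexts
    with the right stop codon but fewer than 4 usable downstream nt.
    """
    stop, ext = _norm(motif[0]), _norm(motif[1])
    if len(ext) != 4:
        raise ValueError("motif downstream pattern must be 4 nt")
    hits: list[StopContext] = []
    trials: list[StopContext] = []
    n_short = 0
    for c in contexts:
        if _norm(c.stop_codon) != stop:
            continue
        down4 = _norm(c.downstream[:4])
        if len(down4) < 4 or any(n not in _NUC_IDX for n in down4):
            n_short += 1
            continue
        trials.append(c)
        if down4 == ext:
            hits.append(c)
    return hits, trials, n_short


def position_freqs(contexts: Sequence[StopContext], stop: str = "TGA") -> np.ndarray:
    """Per-position nucleotide frequencies of the 4 nt after a given stop.

    Restricted to contexts with the requested stop codon and at least 4
    unambiguous downstream nucleotides.  Returns a (4, 4) array indexed
    (position, nucleotide ACGT); each row sums to 1.
    """
    stop = _norm(stop)
    counts = np.zeros((4, 4), dtype=float)
    for c in contexts:
        if _norm(c.stop_codon) != stop:
            continue
        down4 = _norm(c.downstream[:4])
        if len(down4) < 4 or any(n not in _NUC_IDX for n in down4):
            continue
        for pos, nuc in enumerate(down4):
            counts[pos, _NUC_IDX[nuc]] += 1
    total = counts.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("no eligible contexts for position frequencies")
    return counts / total[:, None]


def motif_probability(freqs: np.ndarray, ext: str) -> float:
    """Joint probability of a 4-mer under the independence null."""
    ext = _norm(ext)
    return float(np.prod([freqs[i, _NUC_IDX[n]] for i, n in enumerate(ext)]))


def depletion_test(
    observed: int,
    n_trials: int,
    p_motif: float,
    mode: str = "exact_binomial",
    motif: tuple[str, str] = ("TGA", "CTAG"),
    position_freqs: np.ndarray | None = None,
) -> CensusResult:
    """One-sided tail test of an observed motif count against its null.

    The test side is chosen by comparing the observed count with the
    expectation ``n_trials * p_motif``: the lower tail P(X <= observed)
    when observed falls below it (depletion), the upper tail
    P(X >= observed) otherwise (enrichment).  ``poisson_limit`` mode uses
    a Poisson tail with mean ``n_trials * p_motif`` instead of the exact
    binomial.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= p_motif <= 1.0:
        raise ValueError("p_motif must be a probability")
    if mode not in ("exact_binomial", "poisson_limit"):
        raise ValueError(f"unknown mode {mode!r}")
    expected = n_trials * p_motif
    depleted = observed < expected
    if mode == "exact_binomial":
        dist = stats.binom(n_trials, p_motif)
    else:
        dist = stats.poisson(expected)
    if depleted:
        p = float(dist.cdf(observed))
    else:
        p = float(dist.sf(observed - 1))
    return CensusResult(
        motif=motif,
        n_trials=n_trials,
        observed=observed,
        expected=expected,
        p_motif=p_motif,
        p_value=min(p, 1.0),
        direction="depletion" if depleted else "enrichment",
        mode=mode,
        position_freqs=position_freqs,
    )


def run_census(
    contexts: Sequence[StopContext],
    motif: tuple[str, str] = ("TGA", "CTAG"),
    mode: str = "exact_binomial",
) -> CensusResult:
    """Scan, build the positional null and test, in one call."""
    hits, trials, _ = scan_motif(contexts, motif)
    if not trials:
        raise ValueError(f"no eligible {motif[0]}-stop contexts to census")
    freqs = position_freqs(trials, stop=motif[0])
    p = motif_probability(freqs, motif[1])
    return depletion_test(
        len(hits), len(trials), p, mode=mode, motif=motif, position_freqs=freqs
    )
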