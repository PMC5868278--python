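# Methods

## Stop-context census and depletion test

The unit of the census is the *stop context*: the annotated stop codon
of a transcript plus 6 nt of CDS upstream and up to 12 nt of 3′UTR
downstream, deduplicated by the genomic coordinate of the stop codon's
first nucleotide so that isoforms sharing a stop contribute once.
Contexts with fewer than 4 unambiguous downstream nucleotides are
excluded from both the hit count and the frequency denominators, keeping
observed and expected on the same sample; they are tallied separately.

The null model for a stop+4-mer motif (default TGA followed by CTAG) is
independence across the four downstream positions: the motif probability
is the product of the empirical per-position nucleotide frequencies of
the eligible contexts, and the expected count is E = N·p.  The test is
one-sided, with the side chosen by comparing the observed count with E
(lower tail for depletion, upper tail for enrichment) and recorded in
the result.  Two modes are provided: the exact Binomial(N, p) tail and
the Poisson limit with mean N·p.  The two agree to within a few percent
for moderate means (they diverge in the far tail as the mean grows —
the deliberate grid check uses observations at 80% of the mean).

Coordinates are 0-based half-open in transcript space, with `cds_end`
pointing just past the stop codon.  GTFs are read in the GENCODE dialect
(CDS features exclude the stop codon) by default; `stop_in_cds=True`
handles annotations that include it.  Sequences are handled in DNA space
(T, not U) because FASTA/GTF inputs are DNA; motif matching accepts RNA
spelling.

## Extension ORFs and reporter inserts

The readthrough extension region is the run of codons strictly between
the annotated stop and the next in-frame stop.  The appended peptide has
`1 + between_stops_codons` residues because the recoded stop itself is
decoded; both counts are reported so either convention can be compared.
The residue inserted at the recoded stop is not determined by the
sequence, so it is rendered as a configurable placeholder (default `X`).
Transcripts whose 3′UTR ends before another in-frame stop yield an
unterminated ORF covering the available whole codons.

Reporter inserts follow the dual-luciferase design rule: 6 nt of CDS,
the stop, and up to 12 nt of 3′UTR truncated to end *before* the first
in-frame stop within the window, keeping whole codons only so the
luciferase fusion stays in frame (an in-frame stop at downstream codon 4
leaves 9 nt).  A control with the stop replaced by TGG — the variant
measuring 100% readthrough — is emitted with every insert.

## Phylogenetic coding-potential score

The score asks whether an alignment region evolves like protein-coding
sequence.  Two reversible 64-state codon models are compared:

* **coding** — GY94-style: only single-nucleotide exchanges between
  sense codons have nonzero rate, q_ij = π_j·κ^[transition]·ω^[nonsyn],
  with codon stationary frequencies π from position-specific nucleotide
  frequencies (F3×4) renormalized over sense codons; stop codons carry
  zero stationary mass and no flow.  Defaults: κ = 2.5, ω = 0.2 —
  conventional values for a transition/transversion ratio and for
  purifying selection on a functional protein.
* **noncoding** — three independent HKY85 nucleotide processes composed
  onto the codon space (the codon rate matrix is the Kronecker sum of
  three 4×4 HKY matrices, stationary distribution the outer product),
  i.e. evolution with no reading frame; stops included.

Both matrices are scaled so one unit of branch length equals 3 expected
substitutions per codon (one per nucleotide site), matching trees in
nucleotide substitutions per site.  Likelihoods are computed by
Felsenstein pruning over reference-frame codon columns, treated as
independent; the score is 10·log₁₀(L_coding/L_noncoding) decibans.

This scorer is a self-contained surrogate with documented parameters,
*not* a reimplementation of empirically trained codon-frequency models
such as PhyloCSF's; published scores from those tools on real alignments
are comparison points, never expected outputs of this implementation.
What the package reproduces is the *construction*: score a query region,
score the same-sized post-stop regions of other transcripts as a
background, and report the fraction of background scores strictly below
the query.

### Missing data and stop codons

A codon containing a gap or ambiguity is treated as missing (all-ones
partial likelihood).  Stop codons inside the scored region are masked as
missing under **both** models: the coding model assigns them zero
probability, so scoring them under only the noncoding model would
inflate the coding likelihood by silently dropping observations and make
the two log-likelihoods incomparable.  Masked reference-row stops are
reported (1-based codon indices).  Gap-containing codons are excluded
from likelihoods but drive the frame-integrity caller, separating signal
estimation from indel calling.

### Numerical choices

Transition matrices come from a symmetric-form eigendecomposition of the
reversible rate matrix restricted to states with stationary mass
(D^{1/2} Q D^{-1/2} is symmetric), embedded back with identity on
zero-mass states; rows of exp(Qt) are stochastic to ~1e-10.  Pruning
rescales partials per column by their maximum to avoid underflow.  An
impossible configuration (e.g. two different codons joined by zero-length
branches) produces a hard-zero column likelihood: the log-likelihood is
−inf or an astronomically negative finite value (spectral round-off
leaves transition entries of order 1e-15); it never raises.

### Frame-integrity events

With the reference row defining the frame and the bounding second stop
at a known codon index, each other species is scanned for:

* `frameshift_indel` — maximal indel runs (species gaps against
  reference bases, or bases against reference gaps) after which the
  cumulative indel length in the region is not a multiple of 3; reported
  at the codon where frame is first lost (insertions localize to the
  following reference codon), with later compensating indels restoring
  frame and re-arming the caller;
* `premature_stop` — a complete species codon that is a stop before the
  second-stop position (reference-row internal stops are reported under
  the reference's own name and skipped for other species);
* `second_stop_loss` — a complete non-stop species codon aligned at the
  reference second stop.

Because deletions appear as alignment gaps, downstream columns remain
aligned to the reference frame; premature stops therefore arise from
substitutions, not from rereading a shifted sequence.

## Dual-luciferase quantification

Per-replicate readthrough efficiency is 100·(F/R of a TGA test well)
divided by the **mean** F/R of the TGG control wells of the same batch;
a paired mode dividing by the same-numbered control replicate is also
provided.  The batch-mean default is robust to unequal replicate counts.
Box summaries use type-7 (linear-interpolation) quantiles — the default
of common statistical software — with whiskers at the most extreme
values within 1.5·IQR of the box and values beyond returned as outliers.

Transactivation fold-change is the ratio of mean relative activities,
stimulated over vehicle, with a standard error combining the two arms'
relative dispersions.  Dose-response curves are fit by least squares to
a 4-parameter logistic on log₁₀ dose, with multi-start initialization
from the dose quartiles (tolerances 1e-8); the dose shift between two
curves is the ratio of fitted EC50s, cross-checked by a fit-free
horizontal interpolation at each curve's half-maximal mean response,
which is flagged unavailable when a curve never crosses half-maximum.

## Synthetic-data generators

All generators draw every random quantity from a single seeded NumPy
generator per call, so identical specs give byte-identical outputs.

* **Transcriptome** — single-isoform transcripts (1–3 exons, random
  strand) on one synthetic chromosome; CDS of 20–100 random sense codons
  ending in a stop drawn from a TAA/TAG/TGA mix (0.47/0.24/0.29,
  approximating human stop usage); 3′UTRs of 30–200 nt whose first 4 nt
  follow configurable per-position frequencies (uniform by default),
  with the joint probability of the planted motif multiplied by
  `motif_factor` after TGA stops and the other 4-mers rescaled.  A
  context-level fast path (`gen_stop_contexts`) draws from the same
  distributions without genome/GTF plumbing for census-scale
  experiments.  Not emulated: alternative isoforms sharing stops,
  biased human 3′UTR composition, selenoprotein UGA recoding — so
  passing tests show the census machinery is correct, not that any
  particular genome is depleted.
* **Codon alignments** — the root is drawn from the model's stationary
  distribution and each branch applies exp(Qt) per codon.  Indel events
  occur per branch at `indel_rate`·codons·length, each a deletion or
  insertion of 1–3 nt (uniform — so frameshifting, non-multiple-of-3
  events occur) placed uniformly and inherited by the descendant clade.
  Substitutions are simulated on the root codon lattice; indels are
  overlaid as alignment events and do not feed back into the
  substitution process, and insertions-into-insertions are not modelled.
  This is sufficient for testing the likelihood machinery and the
  frame-integrity caller; it is not a realistic long-indel evolution
  model.
* **Plates** — TGA wells carry the control firefly signal scaled by the
  true efficiency; every reading gets independent multiplicative
  lognormal noise with the requested CV and median 1 (luminescence is
  positive and its noise scales with signal; the median-1 convention
  makes the per-replicate efficiency median-unbiased).
* **Dose-response** — 4PL responses on a 12-point log-spaced dose grid
  (10⁻¹² – 10⁻⁶ by default) spanning `floor` to `floor·fold_range`, with
  the same lognormal noise model.

## Problem sizes in the test suite

The statistical checks run at desk scale, chosen to make the assertions
sharp while the whole suite stays fast: regime separation uses 200
coding + 200 noncoding alignments of 66 codons over 8 taxa; the
percentile construction ranks 100 coding queries against the 200-score
noncoding background; efficiency recovery uses 100 seeds per truth at
12 replicates; pruning is checked against exhaustive ancestral-state
enumeration on 50 random cases of ≤4 taxa and ≤5 codons.  The census
power check plants a 0.3× motif factor over ~5,000 UGA contexts, where
the exact test's detection probability at α = 0.01 is high; milder
depletions at this sample size are genuinely underpowered (a 0.6× factor
yields only ~25–30% power) and are not asserted.

## Known limitations

* The coding/noncoding scorer uses fixed κ and ω rather than empirical
  codon frequencies or branch-specific rates; its absolute scores are
  not comparable with trained tools, only its sign/rank behavior.
* Branch lengths are taken as given; no branch-length or parameter
  estimation is performed.
* The GTF reader handles single-isoform-per-transcript models with exon
  and CDS features; genome-space scanning without transcript models is
  out of scope.
* Frame-integrity calling is relative to the extant reference row; it
  does not attempt ancestral-frame reconstruction.
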