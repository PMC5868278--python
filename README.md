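# readthrough

Analysis toolkit for **stop-codon readthrough**: the decoding of a stop
codon (UGA/UAG/UAA) by a near-cognate tRNA so that translation continues
in frame and appends a C-terminal extension to the protein.  The package
is aimed at computational biologists studying readthrough candidates such
as the extended vitamin D receptor proteoform produced by readthrough of
the *VDR* stop codon, and covers the four computational stages such a
study needs:

1. **Stop-context motif census** (`readthrough.census`) — count how often
   a 3′ tetranucleotide (default CTAG, i.e. the UGA_CUAG readthrough
   motif) follows a given stop codon across deduplicated transcript stop
   contexts, and test the observed count *k* against its expectation
   under an independence null, E = N·∏ᵢ fᵢ(mᵢ), built from the
   per-position nucleotide frequencies fᵢ of the same contexts.  The
   one-sided tail P(X ≤ k) (depletion) or P(X ≥ k) (enrichment) is
   computed exactly under Binomial(N, p) or in the Poisson limit.
2. **Extension ORFs and reporter design** (`readthrough.extension`) —
   scan in frame past the annotated stop to the next in-frame stop; the
   extension appends 1 + (between-stop codons) residues, because the
   recoded stop itself is decoded (a 66-codon region → a 67-aa
   extension).  Dual-luciferase inserts take 6 nt of CDS + stop + up to
   12 nt of 3′UTR, truncated to whole codons before any in-frame stop,
   with a TGG sense-codon control emitted alongside.
3. **Phylogenetic coding potential** (`readthrough.phylo`) — a
   likelihood ratio between a GY94-style codon model (transition bias κ,
   selection ω, stop codons excluded) and a composed-HKY noncoding model,
   evaluated by Felsenstein pruning over a phylogeny and reported in
   decibans, 10·log₁₀(L_coding/L_noncoding); plus per-species
   frame-integrity calls (frameshifting indels, premature stops, loss of
   the bounding second stop) and percentile ranking against an empirical
   background of other transcripts' post-stop regions.
4. **Dual-luciferase quantification** (`readthrough.assay`) — percent
   readthrough as 100·(F/R of the TGA construct)/(F/R of its TGG
   control), R-convention box statistics, transactivation fold-changes,
   and EC50 dose-shift estimation from 4-parameter-logistic fits.

Every stage runs on synthetic data with known ground truth
(`readthrough.simulate`), so the whole pipeline is testable without any
genome downloads.

## Worked example

```python
import dendropy
from readthrough import simulate, annotation, census, phylo, assay

# 1. synthetic transcriptome with a planted 0.5x depletion of CTAG after TGA
spec = simulate.TranscriptomeSpec(n_transcripts=12000, motif_factor=0.5, seed=42)
contexts = annotation.dedupe_stops(simulate.gen_stop_contexts(spec))
result = census.run_census(contexts, motif=("TGA", "CTAG"), mode="exact_binomial")
print(f"UGA-stop contexts: {result.n_trials}")
print(f"TGA_CTAG observed: {result.observed}  expected: {result.expected:.1f}")
print(f"one-sided {result.direction} p = {result.p_value:.4f}")

# 2. coding-potential score of a coding-simulated 66-codon alignment
tree = dendropy.Tree.get(
    data="(((A:0.08,B:0.08):0.04,(C:0.08,D:0.08):0.04):0.04,"
         "((E:0.08,F:0.08):0.04,(G:0.08,H:0.08):0.04):0.04);",
    schema="newick")
coding = phylo.build_model("coding", kappa=2.5, omega=0.2)
noncoding = phylo.build_model("noncoding", kappa=2.5)
aln = simulate.simulate_codon_alignment(
    simulate.AlignmentSimSpec(tree=tree, n_codons=66, regime="coding", seed=42),
    coding)
score = phylo.csf_score(aln, tree, coding, noncoding)
print(f"coding-potential score: {score.score:.1f} decibans over {score.n_codons} codons")

# 3. readthrough efficiency from a simulated dual-luciferase plate
plate = simulate.gen_plate(simulate.PlateSimSpec(true_efficiency=0.067, cv=0.1, seed=42))
eff = assay.readthrough_efficiency(plate[plate.variant == "TGA"],
                                   plate[plate.variant == "TGG"])
print(f"median readthrough: {eff.median:.1f}% (IQR {eff.box.q25:.1f}-{eff.box.q75:.1f}%)")
```

Output:

```
UGA-stop contexts: 3426
TGA_CTAG observed: 3  expected: 13.4
one-sided depletion p = 0.0008
coding-potential score: 288.9 decibans over 66 codons
median readthrough: 6.4% (IQR 6.3-6.7%)
```

The census finds the planted depletion (3 observed where the positional
null expects 13.4; small tail probability); the coding-simulated
alignment scores strongly positive, i.e. its substitution pattern looks
protein-coding; and the plate analysis recovers the planted 6.7%
readthrough efficiency up to the simulated 10% measurement noise.

A command-line interface mirrors these stages
(`readthrough simulate | census | extend | score | frame-check |
efficiency | transactivation | doseshift | all`); see
`readthrough --help`.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generators and what they do and do not emulate, numerical choices, and
known limitations.
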