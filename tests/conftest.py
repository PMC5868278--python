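import dendropy
import numpy as np
import pytest

from readthrough import annotation, phylo, simulate


def make_transcript(
    utr5: str,
    cds_body: str,
    stop: str,
    utr3: str,
    tid: str = "toy1",
    chrom: str = "chrT",
    strand: str = "+",
    offset: int = 0,
) -> annotation.TranscriptModel:
    """Single-exon toy transcript; genomic coords = transcript coords + offset."""
    seq = utr5 + cds_body + stop + utr3
    return annotation.TranscriptModel(
        transcript_id=tid,
        gene_id=tid,
        sequence=seq,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds_body) + 3,
        chrom=chrom,
        strand=strand,
        exons=[(offset, offset + len(seq))],
    )


def exhaustive_loglik(
    aln: phylo.CodonAlignment,
    tree: dendropy.Tree,
    model: phylo.CodonModel,
    mask_stops: bool = False,
) -> float:
    """Likelihood by explicit summation over all ancestral-state assignments.

    Builds the full joint tensor over internal-node codon states (one
    64-long axis per internal node) and sums it — independent of the
    pruning recursion it cross-checks.  Only feasible for tiny trees.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    k = len(internals)
    axis = {id(n): i for i, n in enumerate(internals)}
    states = phylo._leaf_states(aln, model, mask_stops)
    ncod = len(aln.ref_codon_columns())

    def expand(arr: np.ndarray, axes: list[int]) -> np.ndarray:
        """Broadcast a 1- or 2-axis factor onto the k-axis joint shape."""
        shape = [1] * k
        for a in axes:
            shape[a] = 64
        if arr.ndim == 1:
            return arr.reshape(shape)
        full = np.zeros(shape)
        moved = np.moveaxis(full, axes, [0, 1])
        moved[...] = arr.reshape(64, 64, *[1] * (k - 2))
        return full

    total = 0.0
    for c in range(ncod):
        joint = expand(model.pi, [axis[id(tree.seed_node)]]).copy()
        joint = np.broadcast_to(joint, (64,) * k).copy()
        for node in internals:
            for child in node.child_nodes():
                P = model.transition_matrix(child.edge.length or 0.0)
                if child.is_leaf():
                    s = states[child.taxon.label][c]
                    vec = np.ones(64) if s < 0 else P[:, s]
                    joint = joint * expand(vec, [axis[id(node)]])
                else:
                    joint = joint * expand(P, [axis[id(node)], axis[id(child)]])
        lik = float(joint.sum())
        total += np.log(lik) if lik > 0 else -np.inf
    return total


@pytest.fixture(scope="session")
def tree4() -> dendropy.Tree:
    return dendropy.Tree.get(
        data="((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.05);", schema="newick"
    )


@pytest.fixture(scope="session")
def tree8() -> dendropy.Tree:
    return dendropy.Tree.get(
        data=(
            "(((A:0.08,B:0.08):0.04,(C:0.08,D:0.08):0.04):0.04,"
            "((E:0.08,F:0.08):0.04,(G:0.08,H:0.08):0.04):0.04);"
        ),
        schema="newick",
    )


@pytest.fixture(scope="session")
def coding_model() -> phylo.CodonModel:
    return phylo.build_model("coding")


@pytest.fixture(scope="session")
def noncoding_model() -> phylo.CodonModel:
    return phylo.build_model("noncoding")


@pytest.fixture(scope="session")
def small_transcriptome(tmp_path_factory):
    """A 40-transcript synthetic transcriptome written to disk."""
    spec = simulate.TranscriptomeSpec(n_transcripts=40, seed=11)
    tx = simulate.gen_transcriptome(spec)
    d = tmp_path_factory.mktemp("synthtx")
    fasta, gtf = d / "transcripts.fa", d / "models.gtf"
    tx.write(fasta, gtf)
    return spec, tx, fasta, gtf


@pytest.fixture(scope="session")
def loaded_models(small_transcriptome):
    _, _, fasta, gtf = small_transcriptome
    models, skipped = annotation.load_transcripts(fasta, gtf)
    return models, skipped
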