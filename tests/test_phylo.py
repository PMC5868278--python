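"""Codon models, pruning likelihoods, scores, and frame-event calling."""

import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from readthrough import phylo, simulate
from tests.conftest import exhaustive_loglik


def make_aln(rows, ref=None):
    return phylo.CodonAlignment(dict(rows), ref or next(iter(dict(rows))))


def random_tree(rng, n_taxa):
    """Random bifurcating tree over s0..s{n-1} with uniform branch lengths."""
    nodes = [f"s{i}" for i in range(n_taxa)]
    newicks = {n: f"{n}:{rng.uniform(0.01, 0.5):.4f}" for n in nodes}
    items = nodes.copy()
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[j], items[i]
        items = [x for x in items if x not in (a, b)]
        merged = f"({newicks.pop(a)},{newicks.pop(b)}):{rng.uniform(0.01, 0.5):.4f}"
        key = f"anc{len(items)}"
        items.append(key)
        newicks[key] = merged
    # strip the dangling root edge so the top merge is the root node
    data = newicks[items[0]].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=data, schema="newick")


class TestBuildModel:
    def test_detailed_balance_coding(self, coding_model):
        m = coding_model
        lhs = m.pi[:, None] * m.Q
        assert np.allclose(lhs, lhs.T, atol=1e-10)

    def test_stationarity(self, coding_model, noncoding_model):
        for m in (coding_model, noncoding_model):
            assert np.allclose(m.pi @ m.Q, 0.0, atol=1e-8)
            assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-10)

    def test_coding_rate_normalized_to_three_per_codon(self, coding_model):
        assert -float(coding_model.pi @ np.diag(coding_model.Q)) == pytest.approx(3.0)

    def test_stops_have_no_mass_or_flow_in_coding(self, coding_model):
        for s in phylo.STOP_IDX:
            assert coding_model.pi[s] == 0.0
            assert np.all(coding_model.Q[s] == 0.0)
            assert np.all(coding_model.Q[:, s] == 0.0)

    def test_noncoding_transition_matrix_is_hky_tensor_product(self):
        freqs = np.array(
            [[0.3, 0.2, 0.2, 0.3], [0.25, 0.25, 0.25, 0.25], [0.1, 0.4, 0.3, 0.2]]
        )
        m = phylo.build_model("noncoding", kappa=3.0, nuc_freqs=freqs)
        t = 0.37
        P64 = m.transition_matrix(t)
        hkys = [expm(phylo._hky_q(freqs[p], 3.0) * t) for p in range(3)]
        composed = np.kron(np.kron(hkys[0], hkys[1]), hkys[2])
        assert np.allclose(P64, composed, atol=1e-8)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_transition_rows_stochastic(self, coding_model, noncoding_model, t):
        for m in (coding_model, noncoding_model):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            phylo.build_model("coding", kappa=-1)
        with pytest.raises(ValueError):
            phylo.build_model("coding", omega=0.0)
        with pytest.raises(ValueError):
            phylo.build_model("noncoding", nuc_freqs=(1.0, 0.0, 0.0, 0.0))


class TestFelsenstein:
    def test_single_leaf_is_log_stationary(self, coding_model):
        tree = dendropy.Tree.get(data="(A:0.0);", schema="newick")
        aln = make_aln({"A": "ATGGCC"})
        ll = phylo.felsenstein_loglik(aln, tree, coding_model)
        expected = sum(
            math.log(coding_model.pi[phylo.CODON_IDX[c]]) for c in ("ATG", "GCC")
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration_on_seeded_cases(
        self, coding_model, noncoding_model
    ):
        rng = np.random.default_rng(42)
        for case in range(12):
            n_taxa = int(rng.integers(2, 5))
            tree = random_tree(rng, n_taxa)
            n_cod = int(rng.integers(1, 6))
            model = coding_model if case % 2 else noncoding_model
            rows = {}
            for leaf in tree.taxon_namespace:
                sense = np.flatnonzero(model.pi > 0)
                codons = rng.choice(sense, size=n_cod)
                seq = "".join(phylo.CODONS[c] for c in codons)
                if rng.random() < 0.3:  # plant a gap codon
                    k = int(rng.integers(0, n_cod))
                    if leaf.label != "s0":
                        seq = seq[: 3 * k] + "---" + seq[3 * k + 3 :]
                rows[leaf.label] = seq
            aln = make_aln(rows, ref="s0")
            ll = phylo.felsenstein_loglik(aln, tree, model)
            oracle = exhaustive_loglik(aln, tree, model)
            assert ll == pytest.approx(oracle, abs=1e-9)

    def test_long_branches_decouple_into_stationary_product(self, noncoding_model):
        tree = dendropy.Tree.get(
            data="((A:50,B:50):50,(C:50,D:50):50);", schema="newick"
        )
        aln = make_aln(
            {"A": "ATGGCC", "B": "TTTAAA", "C": "CCGCGG", "D": "ATGTGA"}
        )
        ll = phylo.felsenstein_loglik(aln, tree, noncoding_model)
        expected = sum(
            math.log(noncoding_model.pi[phylo.CODON_IDX[row[i : i + 3]]])
            for row in aln.rows.values()
            for i in (0, 3)
        )
        assert ll == pytest.approx(expected, abs=1e-3)

    def test_impossible_column_hard_zero_not_crash(self, coding_model):
        # mismatched leaves under a zero-length cherry: the column
        # likelihood collapses to (numerical) zero without raising
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        aln = make_aln({"A": "ATG", "B": "GCC"})
        ll = phylo.felsenstein_loglik(aln, tree, coding_model)
        assert not math.isnan(ll)
        assert ll < -30.0  # column probability below ~1e-14

    def test_unknown_species_error_lists_names(self, coding_model, tree4):
        aln = make_aln({"A": "ATG", "Z": "ATG"})
        with pytest.raises(ValueError, match="Z"):
            phylo.felsenstein_loglik(aln, tree4, coding_model)


class TestCsfScore:
    def test_collapsed_tree_scores_single_sequence_ratio(
        self, coding_model, noncoding_model
    ):
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        aln = make_aln({"A": "ATGGCC", "B": "ATGGCC"})
        res = phylo.csf_score(aln, tree, coding_model, noncoding_model)
        lc = sum(
            math.log(coding_model.pi[phylo.CODON_IDX[c]]) for c in ("ATG", "GCC")
        )
        ln = sum(
            math.log(noncoding_model.pi[phylo.CODON_IDX[c]]) for c in ("ATG", "GCC")
        )
        assert res.score == pytest.approx(10 / math.log(10) * (lc - ln), abs=1e-8)
        assert res.score == pytest.approx(
            phylo.LOG10_FACTOR * (res.logL_coding - res.logL_noncoding)
        )

    def test_score_additive_over_codon_blocks(
        self, tree4, coding_model, noncoding_model
    ):
        rows = {
            "A": "ATGGCCTTT",
            "B": "ATGGCATTC",
            "C": "ACGGCCTTT",
            "D": "ATGGACTTT",
        }
        aln = make_aln(rows)
        whole = phylo.csf_score(aln, tree4, coding_model, noncoding_model).score
        parts = 0.0
        for k in (0, 3, 6):
            block = make_aln({s: r[k : k + 3] for s, r in rows.items()})
            parts += phylo.csf_score(block, tree4, coding_model, noncoding_model).score
        assert whole == pytest.approx(parts, abs=1e-8)

    def test_internal_reference_stops_masked_and_reported(
        self, tree4, coding_model, noncoding_model
    ):
        aln = make_aln(
            {"A": "ATGTGAGCC", "B": "ATGTGAGCC", "C": "ATGTGAGCC", "D": "ATGTGAGCC"}
        )
        res = phylo.csf_score(aln, tree4, coding_model, noncoding_model)
        assert res.masked_ref_stops == [2]
        assert math.isfinite(res.score)

    def test_empty_region_errors(self, tree4, coding_model, noncoding_model):
        aln = make_aln({"A": "--", "B": "AT", "C": "AT", "D": "AT"})
        with pytest.raises(ValueError, match="empty"):
            phylo.csf_score(aln, tree4, coding_model, noncoding_model)

    def test_regime_discrimination_at_desk_scale(
        self, tree8, coding_model, noncoding_model
    ):
        correct = 0
        n = 25
        for seed in range(n):
            ac = simulate.simulate_codon_alignment(
                simulate.AlignmentSimSpec(
                    tree=tree8, n_codons=66, regime="coding", seed=seed
                ),
                coding_model,
            )
            an = simulate.simulate_codon_alignment(
                simulate.AlignmentSimSpec(
                    tree=tree8, n_codons=66, regime="noncoding", seed=10_000 + seed
                ),
                noncoding_model,
            )
            correct += phylo.csf_score(ac, tree8, coding_model, noncoding_model).score > 0
            correct += phylo.csf_score(an, tree8, coding_model, noncoding_model).score < 0
        assert correct / (2 * n) >= 0.9


class TestCladeSubset:
    def test_subset_to_all_is_identity(self, tree8, coding_model):
        aln = simulate.simulate_codon_alignment(
            simulate.AlignmentSimSpec(tree=tree8, n_codons=10, regime="coding", seed=1),
            coding_model,
        )
        sub, pruned = phylo.clade_subset(aln, list(aln.rows), tree8)
        assert sub.rows == aln.rows
        assert {l.taxon.label for l in pruned.leaf_node_iter()} == set(aln.rows)

    def test_all_gap_columns_purged(self):
        aln = make_aln(
            {"A": "ATG---GCC", "B": "ATGAAAGCC", "C": "ATG---GCC"}, ref="A"
        )
        sub, _ = phylo.clade_subset(aln, ["A", "C"])
        assert sub.rows == {"A": "ATGGCC", "C": "ATGGCC"}

    def test_pruned_tree_leaves_match_and_paths_preserved(self, tree8):
        aln = make_aln({s: "ATG" for s in "ABCDEFGH"}, ref="A")
        sub, pruned = phylo.clade_subset(aln, ["A", "B", "E"], tree8)
        assert {l.taxon.label for l in pruned.leaf_node_iter()} == {"A", "B", "E"}
        pdm_full = tree8.phylogenetic_distance_matrix()
        pdm_sub = pruned.phylogenetic_distance_matrix()
        tfull = {t.label: t for t in tree8.taxon_namespace}
        tsub = {t.label: t for t in pruned.taxon_namespace}
        for x, y in (("A", "B"), ("A", "E")):
            assert pdm_sub.patristic_distance(
                tsub[x], tsub[y]
            ) == pytest.approx(pdm_full.patristic_distance(tfull[x], tfull[y]))

    def test_too_few_species_errors(self):
        aln = make_aln({"A": "ATG", "B": "ATG"})
        with pytest.raises(ValueError, match="fewer than 2"):
            phylo.clade_subset(aln, [])


class TestBackgroundPercentile:
    def test_above_all_is_one_and_at_min_is_zero(self):
        bg = [1.0, 2.0, 3.0]
        assert phylo.background_percentile(10.0, bg) == 1.0
        assert phylo.background_percentile(1.0, bg) == 0.0  # strict inequality
        assert phylo.background_percentile(2.5, bg) == pytest.approx(2 / 3)
        assert phylo.background_percentile(-5.0, bg) == 0.0

    def test_matches_counting_oracle_and_order_invariant(self):
        rng = np.random.default_rng(8)
        bg = list(rng.normal(size=200))
        score = float(rng.normal())
        frac = phylo.background_percentile(score, bg)
        assert frac == sum(b < score for b in bg) / len(bg)
        rng.shuffle(bg)
        assert phylo.background_percentile(score, bg) == frac

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            phylo.background_percentile(0.0, [])


class TestFrameIntegrity:
    def make_clean(self, n_codons=50, seed=0):
        rng = np.random.default_rng(seed)
        sense = [c for c in phylo.CODONS if c not in phylo.STOPS]
        body = "".join(rng.choice(sense, size=n_codons - 1))
        return body + "TGA"  # second stop at codon n_codons

    def test_identical_row_has_no_events(self):
        ref = self.make_clean()
        aln = make_aln({"human": ref, "rhesus": ref}, ref="human")
        assert phylo.frame_integrity(aln, 50) == []

    def test_one_base_deletion_in_codon_45(self):
        ref = self.make_clean()
        col = 3 * 44 + 1  # middle base of codon 45
        other = ref[:col] + "-" + ref[col + 1 :]
        aln = make_aln({"human": ref, "gibbon": other}, ref="human")
        events = phylo.frame_integrity(aln, 50)
        fs = [e for e in events if e.kind == "frameshift_indel"]
        assert len(fs) == 1
        assert fs[0].species == "gibbon"
        assert fs[0].codon_index == 45

    def test_compensating_indels_restore_frame(self):
        ref = self.make_clean()
        # delete 1 nt in codon 10 and 2 nt in codon 20: net 3, frame restored
        row = list(ref)
        row[3 * 9] = "-"
        row[3 * 19] = "-"
        row[3 * 19 + 1] = "-"
        aln = make_aln({"human": ref, "sp": "".join(row)}, ref="human")
        fs = [
            e
            for e in phylo.frame_integrity(aln, 50)
            if e.kind == "frameshift_indel"
        ]
        assert len(fs) == 1
        assert fs[0].codon_index == 10

    def test_codon_length_deletion_is_not_frameshift(self):
        ref = self.make_clean()
        other = ref[:30] + "---" + ref[33:]
        aln = make_aln({"human": ref, "sp": other}, ref="human")
        assert phylo.frame_integrity(aln, 50) == []

    def test_substitution_to_stop_called_premature(self):
        ref = self.make_clean()
        other = ref[:30] + "TAA" + ref[33:]
        aln = make_aln({"human": ref, "marmoset": other}, ref="human")
        events = phylo.frame_integrity(aln, 50)
        assert [e.kind for e in events] == ["premature_stop"]
        assert events[0].codon_index == 11

    def test_second_stop_substitution_called_loss(self):
        ref = self.make_clean()
        other = ref[:-3] + "CGA"
        aln = make_aln({"human": ref, "marmoset": other}, ref="human")
        events = phylo.frame_integrity(aln, 50)
        assert [e.kind for e in events] == ["second_stop_loss"]
        assert events[0].codon_index == 50
        assert events[0].detail == "CGA"

    def test_insertion_shifts_frame_too(self):
        ref = self.make_clean()
        col = 3 * 10
        ref_g = ref[:col] + "-" + ref[col:]
        other = ref[:col] + "A" + ref[col:]
        aln = make_aln({"human": ref_g, "sp": other}, ref="human")
        fs = [
            e
            for e in phylo.frame_integrity(aln, 50)
            if e.kind == "frameshift_indel"
        ]
        assert len(fs) == 1 and fs[0].codon_index == 11

    def test_matches_cumulative_gap_walk_oracle(self):
        rng = np.random.default_rng(77)
        sense = [c for c in phylo.CODONS if c not in phylo.STOPS]
        for _ in range(50):
            n = 30
            ref = "".join(rng.choice(sense, size=n - 1)) + "TAA"
            row = list(ref)
            # plant 1-3 deletions of length 1-3 in distinct codons
            for _ in range(int(rng.integers(1, 4))):
                c = int(rng.integers(0, n - 1))
                length = int(rng.integers(1, 4))
                for k in range(length):
                    if 3 * c + k < len(row):
                        row[3 * c + k] = "-"
            aln = make_aln({"r": ref, "q": "".join(row)}, ref="r")
            events = phylo.frame_integrity(aln, n)
            fs = [e for e in events if e.kind == "frameshift_indel"]
            # oracle: walk columns, track cumulative gap length transitions
            oracle = []
            cum, lost, run, run_codon = 0, False, 0, None
            for j, (rb, qb) in enumerate(zip(ref, "".join(row))):
                gap = qb == "-" and rb != "-"
                if gap:
                    if run == 0:
                        run_codon = j // 3 + 1
                    run += 1
                elif run:
                    cum += run
                    if cum % 3 and not lost:
                        oracle.append(run_codon)
                        lost = True
                    elif cum % 3 == 0 and lost:
                        lost = False
                    run = 0
            if run:
                cum += run
                if cum % 3 and not lost:
                    oracle.append(run_codon)
            assert [e.codon_index for e in fs] == oracle
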