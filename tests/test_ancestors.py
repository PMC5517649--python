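import itertools

import numpy as np
import pytest

from trefoilforge import ancestors as anc
from trefoilforge import synthetic as syn
from trefoilforge.structio import SequenceRecord


@pytest.fixture(scope="module")
def model():
    return anc.SubstitutionModel.blosum62()


def brute_force_site_likelihood(column, branch_lengths, model):
    """Independent oracle: explicit sum over all 20 root states."""
    total = 0.0
    Ps = [model.transition_matrix(bl) for bl in branch_lengths]
    for a in range(20):
        p = model.pi[a]
        for aa, P in zip(column, Ps):
            if aa in anc.AA_INDEX:
                p *= P[a, anc.AA_INDEX[aa]]
        total += p
    return total


def brute_force_root_posterior(column, branch_lengths, model):
    probs = np.zeros(20)
    Ps = [model.transition_matrix(bl) for bl in branch_lengths]
    for a in range(20):
        p = model.pi[a]
        for aa, P in zip(column, Ps):
            if aa in anc.AA_INDEX:
                p *= P[a, anc.AA_INDEX[aa]]
        probs[a] = p
    return probs / probs.sum()


class TestSubstitutionModel:
    def test_stationarity_and_normalisation(self, model):
        assert np.abs(model.pi @ model.Q).max() < 1e-10
        assert np.abs(model.Q.sum(axis=1)).max() < 1e-10
        assert abs(-np.dot(model.pi, np.diag(model.Q)) - 1.0) < 1e-10
        off = model.Q[~np.eye(20, dtype=bool)]
        assert (off >= 0).all()

    def test_transition_matrix_properties(self, model):
        P = model.transition_matrix(0.7)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12
        assert (P >= 0).all()
        np.testing.assert_allclose(model.transition_matrix(0.0), np.eye(20), atol=1e-10)
        # Chapman-Kolmogorov: P(s+t) = P(s)P(t)
        np.testing.assert_allclose(
            model.transition_matrix(0.9),
            model.transition_matrix(0.4) @ model.transition_matrix(0.5),
            atol=1e-10,
        )

    def test_detailed_balance(self, model):
        P = model.transition_matrix(0.5)
        flux = model.pi[:, None] * P
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_paml_round_trip(self, model, tmp_path):
        # serialise the exchangeabilities to PAML layout and re-load
        S = np.zeros((20, 20))
        # reconstruct S from Q: S_ij = Q_ij / pi_j
        S = model.Q / model.pi[None, :]
        lines = []
        for i in range(1, 20):
            lines.append(" ".join(f"{S[i, j]:.8f}" for j in range(i)))
        lines.append(" ".join(f"{f:.8f}" for f in model.pi))
        p = tmp_path / "model.dat"
        p.write_text("\n".join(lines) + "\n")
        m2 = anc.SubstitutionModel.from_paml(p)
        np.testing.assert_allclose(m2.Q, model.Q, atol=1e-6)


class TestAlignRepeats:
    def test_identical_sequences_gap_free(self):
        seqs = [SequenceRecord(id=c, residues="MKTAYIAKQR") for c in "ABC"]
        aln = anc.align_repeats(seqs)
        assert all(r.residues == "MKTAYIAKQR" for r in aln.records)

    def test_guide_pairing_followed_exactly(self):
        seqs = [SequenceRecord(id=c, residues="ACDEF") for c in "ABC"]
        guide = [(i, i, i) for i in range(5)]
        aln = anc.align_repeats(seqs, guide_pairing=guide)
        assert aln.n_sites == 5
        assert all("-" not in r.residues for r in aln.records)

    def test_guide_places_gap_at_unpaired_position(self):
        seqs = [
            SequenceRecord(id="A", residues="ACDEF"),
            SequenceRecord(id="B", residues="ACEF"),  # D deleted
            SequenceRecord(id="C", residues="ACDEF"),
        ]
        guide = [(0, 0, 0), (1, 1, 1), (2, None, 2), (3, 2, 3), (4, 3, 4)]
        aln = anc.align_repeats(seqs, guide_pairing=guide)
        assert aln.records[1].residues == "AC-EF"
        assert aln.records[0].residues == "ACDEF"

    def test_unguided_alignment_recovers_internal_deletion(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        seqs = [
            SequenceRecord(id="A", residues=base),
            SequenceRecord(id="B", residues=base[:15] + base[18:]),
            SequenceRecord(id="C", residues=base),
        ]
        aln = anc.align_repeats(seqs)
        assert aln.n_sites == len(base)
        assert aln.records[1].residues.count("-") == 3

    def test_inconsistent_guide_rejected(self):
        seqs = [SequenceRecord(id=c, residues="ACDEF") for c in "ABC"]
        guide = [(1, 1, 1), (0, 0, 0)]  # order violation
        with pytest.raises(ValueError):
            anc.align_repeats(seqs, guide_pairing=guide)


class TestPruningLoglik:
    def test_zero_branches_identical_leaves_closed_form(self, model):
        aln = anc.Alignment([SequenceRecord(id=c, residues="H") for c in "ABC"])
        tree = anc.PhyloTree(["A", "B", "C"], np.zeros(3))
        _, per_site = anc.pruning_loglik(aln, tree, model)
        assert abs(per_site[0] - np.log(model.pi[anc.AA_INDEX["H"]])) < 1e-12

    def test_matches_brute_force_enumeration(self, model):
        lengths = np.array([0.2, 0.5, 1.1])
        tree = anc.PhyloTree(["A", "B", "C"], lengths)
        for cols in [("HD", "HE", "DD"), ("AC", "AC", "AC"), ("WY", "YW", "WW")]:
            aln = anc.Alignment(
                [SequenceRecord(id=c, residues=s) for c, s in zip("ABC", cols)]
            )
            total, per_site = anc.pruning_loglik(aln, tree, model)
            for s in range(aln.n_sites):
                expected = np.log(
                    brute_force_site_likelihood(aln.column(s), lengths, model)
                )
                assert abs(per_site[s] - expected) < 1e-10
            assert abs(total - per_site.sum()) < 1e-12

    def test_gaps_are_missing_data(self, model):
        tree = anc.PhyloTree(["A", "B", "C"], np.array([0.3, 0.3, 0.3]))
        with_gap = anc.Alignment(
            [SequenceRecord(id="A", residues="H"),
             SequenceRecord(id="B", residues="-"),
             SequenceRecord(id="C", residues="D")]
        )
        two_leaf_equiv = brute_force_site_likelihood(["H", "-", "D"], tree.branch_lengths, model)
        _, per_site = anc.pruning_loglik(with_gap, tree, model)
        assert abs(per_site[0] - np.log(two_leaf_equiv)) < 1e-12

    def test_invariant_under_leaf_permutation(self, model):
        tree_names = ["A", "B", "C"]
        lengths = np.array([0.1, 0.4, 0.9])
        records = {
            "A": SequenceRecord(id="A", residues="HKW"),
            "B": SequenceRecord(id="B", residues="HRW"),
            "C": SequenceRecord(id="C", residues="DKY"),
        }
        base = None
        for perm in itertools.permutations("ABC"):
            aln = anc.Alignment([records[c] for c in perm])
            tree = anc.PhyloTree(tree_names, lengths)
            ll, _ = anc.pruning_loglik(aln, tree, model)
            if base is None:
                base = ll
            assert abs(ll - base) < 1e-12


class TestInferTree:
    def test_identical_sequences_zero_branches(self, model):
        aln = anc.Alignment([SequenceRecord(id=c, residues="MKTAYIAKQR" * 3) for c in "ABC"])
        tree = anc.infer_tree(aln, model)
        assert np.abs(tree.branch_lengths).max() < 1e-4

    def test_branch_length_recovery_from_simulation(self, model):
        true = 0.3
        tree = anc.PhyloTree(["A", "B", "C"], np.full(3, true))
        estimates = []
        for seed in range(6):
            root = syn.random_root(200, model, seed=100 + seed)
            leaves, _ = syn.evolve(syn.EvolutionScenario(root, tree, model, seed=100 + seed))
            est = anc.infer_tree(anc.Alignment(leaves), model)
            estimates.extend(est.branch_lengths)
        mean = np.mean(estimates)
        assert abs(mean - true) / true < 0.3

    def test_divergent_leaf_gets_largest_branch(self, model):
        seq = "MKTAYIAKQRQISFVKSHFS"
        other = "WWPPGGHHEEDDNNQQRRKK"
        aln = anc.Alignment(
            [SequenceRecord(id="A", residues=seq),
             SequenceRecord(id="B", residues=seq),
             SequenceRecord(id="C", residues=other)]
        )
        tree = anc.infer_tree(aln, model)
        assert tree.branch_lengths[2] > tree.branch_lengths[0]
        assert tree.branch_lengths[2] > tree.branch_lengths[1]

    def test_newick_round_trip(self):
        tree = anc.PhyloTree(["A", "B", "C"], np.array([0.1, 0.2, 0.3]))
        again = anc.PhyloTree.from_newick(tree.to_newick())
        assert again.leaf_names == tree.leaf_names
        np.testing.assert_allclose(again.branch_lengths, tree.branch_lengths, atol=1e-6)


class TestMarginalPosterior:
    def test_short_branches_concentrate_on_observed_state(self, model):
        aln = anc.Alignment([SequenceRecord(id=c, residues="H") for c in "ABC"])
        tree = anc.PhyloTree(["A", "B", "C"], np.full(3, 1e-8))
        post = anc.marginal_posterior(aln, tree, model)
        assert post.probabilities[0, anc.AA_INDEX["H"]] > 1.0 - 1e-6

    def test_matches_brute_force_bayes(self, model):
        aln = anc.Alignment(
            [SequenceRecord(id="A", residues="H"),
             SequenceRecord(id="B", residues="H"),
             SequenceRecord(id="C", residues="D")]
        )
        lengths = np.full(3, 0.5)
        tree = anc.PhyloTree(["A", "B", "C"], lengths)
        post = anc.marginal_posterior(aln, tree, model)
        expected = brute_force_root_posterior(["H", "H", "D"], lengths, model)
        np.testing.assert_allclose(post.probabilities[0], expected, atol=1e-12)

    def test_rows_are_probability_vectors(self, model):
        tree = anc.PhyloTree(["A", "B", "C"], np.array([0.2, 0.3, 0.4]))
        root = syn.random_root(50, model, seed=5)
        leaves, _ = syn.evolve(syn.EvolutionScenario(root, tree, model, seed=5))
        post = anc.marginal_posterior(anc.Alignment(leaves), tree, model)
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert (post.probabilities >= 0).all()

    def test_entropy_non_decreasing_in_branch_scale(self, model):
        aln = anc.Alignment(
            [SequenceRecord(id="A", residues="HKWDY"),
             SequenceRecord(id="B", residues="HRWDY"),
             SequenceRecord(id="C", residues="DKYEY")]
        )
        base = np.array([0.2, 0.2, 0.2])
        entropies = []
        for scale in [0.25, 0.5, 1.0, 2.0, 4.0]:
            tree = anc.PhyloTree(["A", "B", "C"], base * scale)
            post = anc.marginal_posterior(aln, tree, model)
            entropies.append(post.entropy().mean())
        assert all(b >= a - 1e-9 for a, b in zip(entropies, entropies[1:]))


class TestSampleCandidates:
    def _point_posterior(self, seq):
        p = np.zeros((len(seq), 20))
        for i, aa in enumerate(seq):
            p[i, anc.AA_INDEX[aa]] = 1.0
        return anc.AncestralPosterior(p)

    def test_degenerate_posterior_gives_map_everywhere(self):
        post = self._point_posterior("MKTAY")
        out = anc.sample_candidates(post, n=5, seed=1)
        assert len(out) == 5
        assert all(c.sequence == "MKTAY" for c in out)
        assert sum(1 for c in out if c.provenance == "MAP") == 1

    def test_requested_pool_size_2000(self):
        post = self._point_posterior("MKTAYIAKQR")
        out = anc.sample_candidates(post, n=2000, seed=1)
        assert len(out) == 2000

    def test_site_frequencies_within_3_sigma_of_binomial(self):
        p = np.zeros((1, 20))
        p[0, anc.AA_INDEX["A"]] = 0.7
        p[0, anc.AA_INDEX["V"]] = 0.3
        post = anc.AncestralPosterior(p)
        n = 10000
        out = anc.sample_candidates(post, n=n, seed=7, include_map=False)
        n_a = sum(1 for c in out if c.sequence == "A")
        sigma = np.sqrt(n * 0.7 * 0.3)
        assert abs(n_a - 0.7 * n) <= 3 * sigma

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(20), size=8)
        post = anc.AncestralPosterior(p)
        a = anc.sample_candidates(post, n=20, seed=3)
        b = anc.sample_candidates(post, n=20, seed=3)
        assert [c.sequence for c in a] == [c.sequence for c in b]

    def test_map_has_maximal_per_site_probability(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(20), size=10)
        post = anc.AncestralPosterior(p)
        out = anc.sample_candidates(post, n=50, seed=2)
        map_logp = out.candidates[0].log_posterior
        assert all(c.log_posterior <= map_logp + 1e-12 for c in out)

    def test_invalid_n_rejected(self):
        post = self._point_posterior("M")
        with pytest.raises(ValueError):
            anc.sample_candidates(post, n=0)


def test_map_reconstruction_recovers_known_ancestor(model):
    """On repeats evolved at branch length 0.2, the MAP root sequence
    recovers >= 90% of the true ancestor (averaged over 20 seeds)."""
    tree = anc.PhyloTree(["A", "B", "C"], np.full(3, 0.2))
    idents = []
    for seed in range(20):
        root = syn.random_root(120, model, seed=seed)
        leaves, _ = syn.evolve(syn.EvolutionScenario(root, tree, model, seed=seed))
        aln = anc.Alignment(leaves)
        fitted = anc.infer_tree(aln, model)
        post = anc.marginal_posterior(aln, fitted, model)
        mapseq = post.map_sequence()
        idents.append(np.mean([a == b for a, b in zip(mapseq, root)]))
    assert np.mean(idents) >= 0.90
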