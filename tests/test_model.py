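"""Rate matrix construction, pruning likelihood, fitting and the LRT."""

import numpy as np
import pytest

from codonsel import (
    CodonAlignment,
    CodonModel,
    SimulationConfig,
    SpeciesTree,
    build_rate_matrix,
    estimate_f3x4,
    lrt,
    simulate_alignment,
    uniform_codon_freqs,
)
from codonsel.genetics import CODON_INDEX, CODONS, STOP_CODONS


class TestRateMatrix:
    def test_rows_sum_to_zero_and_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = build_rate_matrix(3.1, 0.7, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_neutral_symmetric_case_equal_offdiagonals(self):
        # omega = kappa = 1, uniform pi: every allowed change has one rate
        Q = build_rate_matrix(1.0, 1.0, uniform_codon_freqs())
        off = Q[~np.eye(61, dtype=bool)]
        rates = np.unique(np.round(off[off > 0], 12))
        assert len(rates) == 1

    def test_transition_and_omega_scaling_of_single_entries(self):
        # TTT->TTC is a synonymous transition (rate ∝ kappa);
        # TTT->TTA is a nonsynonymous transversion (rate ∝ omega)
        Q = build_rate_matrix(2.0, 0.5, uniform_codon_freqs())
        i, j_ts, j_tv = CODON_INDEX["TTT"], CODON_INDEX["TTC"], CODON_INDEX["TTA"]
        assert Q[i, j_ts] / Q[i, j_tv] == pytest.approx(2.0 / 0.5)

    def test_multi_nucleotide_changes_forbidden(self):
        Q = build_rate_matrix(2.0, 0.5, uniform_codon_freqs())
        assert Q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0
        assert Q[CODON_INDEX["AAA"], CODON_INDEX["CCC"]] == 0.0

    def test_mean_rate_scaled_to_one(self):
        pi = np.random.default_rng(1).dirichlet(np.ones(61))
        Q = build_rate_matrix(5.0, 2.0, pi)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_degenerate_pi_rejected(self):
        pi = uniform_codon_freqs()
        pi[0] = 0.0
        pi[1] += 1.0 / 61
        with pytest.raises(ValueError, match="degenerate"):
            build_rate_matrix(2.0, 0.5, pi)


class TestF3x4:
    def test_sums_to_one_with_no_stop_mass(self):
        aln = CodonAlignment(["a", "b"], {"a": "ATGAAA", "b": "ATGCGC"})
        pi = estimate_f3x4(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert pi.shape == (61,)
        assert all(c not in STOP_CODONS for c in CODONS)

    def test_uniform_codon_usage_recovers_analytic_f3x4(self, eight_taxon_tree):
        # under uniform usage of the 61 sense codons, the positional
        # nucleotide marginals are the sense-codon counts / 61 (stop-codon
        # exclusion skews them); F3x4 should converge to their product
        counts = np.zeros((3, 4))
        for c in CODONS:
            for pos, n in enumerate(c):
                counts[pos, "ACGT".index(n)] += 1
        marg = counts / 61.0
        expected = np.array(
            [
                marg[0, "ACGT".index(c[0])]
                * marg[1, "ACGT".index(c[1])]
                * marg[2, "ACGT".index(c[2])]
                for c in CODONS
            ]
        )
        expected /= expected.sum()
        cfg = SimulationConfig(tree=eight_taxon_tree, n_codons=4000, seed=5)
        pi = estimate_f3x4(simulate_alignment(cfg))
        assert np.abs(pi - expected).max() < 0.15 / 61

    def test_all_gap_alignment_rejected(self):
        aln = CodonAlignment(["a", "b"], {"a": "---", "b": "---"})
        with pytest.raises(ValueError, match="resolved"):
            estimate_f3x4(aln)


class TestLikelihood:
    def test_single_taxon_loglik_is_log_pi_sum(self):
        aln = CodonAlignment(["a", "b", "c"], {"a": "ATGAAA", "b": "ATGAAA", "c": "ATGAAA"})
        tree = SpeciesTree.from_newick("(a:0.0,b:0.0,c:0.0):0.0;")
        m = CodonModel(aln, tree, freq="uniform")
        lnL = m.loglik("M0", {"kappa": 2.0, "omega": 0.5})
        # zero branch lengths: likelihood is just pi over observed codons
        expected = 2 * np.log(1.0 / 61)
        assert lnL == pytest.approx(expected, abs=1e-10)

    def test_duplicating_columns_doubles_loglik(self, quartet_tree):
        cfg = SimulationConfig(tree=quartet_tree, n_codons=20, seed=3)
        aln = simulate_alignment(cfg)
        doubled = CodonAlignment(
            aln.taxa, {t: s + s for t, s in aln.sequences.items()}
        )
        m1 = CodonModel(aln, quartet_tree, freq="uniform")
        m2 = CodonModel(doubled, quartet_tree, freq="uniform")
        p = {"kappa": 2.0, "omega": 0.4}
        assert m2.loglik("M0", p) == pytest.approx(2 * m1.loglik("M0", p), rel=1e-12)

    def test_loglik_invariant_under_taxon_reordering(self, quartet_tree):
        cfg = SimulationConfig(tree=quartet_tree, n_codons=30, seed=9)
        aln = simulate_alignment(cfg)
        rev = CodonAlignment(list(reversed(aln.taxa)), dict(aln.sequences))
        p = {"kappa": 1.7, "omega": 0.6}
        a = CodonModel(aln, quartet_tree, freq="uniform").loglik("M0", p)
        b = CodonModel(rev, quartet_tree, freq="uniform").loglik("M0", p)
        assert a == pytest.approx(b, abs=1e-9)

    def test_loglik_invariant_under_rerooting(self, quartet_tree):
        # same unrooted topology, root slid along the internal edge:
        # a reversible model must give the identical likelihood
        cfg = SimulationConfig(tree=quartet_tree, n_codons=40, seed=19)
        aln = simulate_alignment(cfg)
        rerooted = SpeciesTree.from_newick(
            "((a:0.2,b:0.15):0.03,(c:0.3,d:0.05):0.14):0.0;"
        )
        p = {"kappa": 2.1, "omega": 0.5}
        a = CodonModel(aln, quartet_tree, freq="uniform").loglik("M0", p)
        b = CodonModel(aln, rerooted, freq="uniform").loglik("M0", p)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("n_codons,seed", [(2, 7), (3, 21)])
    def test_pruning_matches_brute_force_m0(self, brute_force, quartet_tree, n_codons, seed):
        cfg = SimulationConfig(tree=quartet_tree, n_codons=n_codons, seed=seed)
        aln = simulate_alignment(cfg)
        m = CodonModel(aln, quartet_tree, freq="uniform")
        lnL = m.loglik("M0", {"kappa": 2.3, "omega": 0.4})
        bf = brute_force(m, {False: 0.4, True: 0.4}, 2.3)
        assert lnL == pytest.approx(bf, abs=1e-8)

    def test_pruning_matches_brute_force_with_missing_data(self, brute_force, quartet_tree):
        cfg = SimulationConfig(tree=quartet_tree, n_codons=2, seed=13)
        aln = simulate_alignment(cfg)
        seqs = dict(aln.sequences)
        seqs["b"] = "---" + seqs["b"][3:]  # one missing codon
        aln = CodonAlignment(aln.taxa, seqs)
        m = CodonModel(aln, quartet_tree, freq="uniform")
        lnL = m.loglik("branch", {"kappa": 1.8, "omega_background": 0.3,
                                  "omega_foreground": 2.0})
        bf = brute_force(m, {False: 0.3, True: 2.0}, 1.8)
        assert lnL == pytest.approx(bf, abs=1e-8)


class TestFit:
    def test_m0_recovers_simulated_omega(self, quartet_tree):
        cfg = SimulationConfig(
            tree=quartet_tree, n_codons=2000, omega_background=0.2,
            omega_foreground=0.2, seed=42,
        )
        aln = simulate_alignment(cfg)
        res = CodonModel(aln, quartet_tree).fit("M0", starts=1)
        assert res.converged
        assert 0.15 <= res.params["omega"] <= 0.25

    def test_nested_model_loglik_monotone(self, quartet_tree, small_alignment):
        m = CodonModel(small_alignment, quartet_tree)
        l0 = m.fit("M0", starts=1).lnL
        l2 = m.fit("branch", starts=1).lnL
        assert l2 >= l0 - 1e-6

    def test_branch_site_null_fixes_omega2(self, quartet_tree, small_alignment):
        m = CodonModel(small_alignment, quartet_tree)
        res = m.fit("branch-site-null", starts=1)
        assert res.params["omega2"] == 1.0
        assert res.n_free_params == 4

    def test_branch_model_requires_foreground(self, small_alignment):
        tree = SpeciesTree.from_newick(
            "((a:0.2,b:0.15):0.1,(c:0.3,d:0.05):0.07):0.0;"
        )
        m = CodonModel(small_alignment, tree)
        with pytest.raises(ValueError, match="foreground"):
            m.fit("branch")

    def test_summary_reports_fit(self, quartet_tree, small_alignment):
        res = CodonModel(small_alignment, quartet_tree).fit("M0", starts=1)
        text = res.summary()
        assert "M0" in text and "log-likelihood" in text and "omega" in text


class TestSitePosteriors:
    def test_posteriors_in_unit_interval(self, quartet_tree, small_alignment):
        m = CodonModel(small_alignment, quartet_tree)
        res = m.fit("branch-site", starts=1)
        post = res.site_posteriors()
        assert len(post) == small_alignment.n_codons
        assert post["posterior"].between(0, 1).all()
        assert (post["flavor"] == "NEB").all()

    def test_posteriors_refused_for_non_branch_site_fit(self, quartet_tree, small_alignment):
        res = CodonModel(small_alignment, quartet_tree).fit("M0", starts=1)
        with pytest.raises(ValueError, match="branch-site"):
            res.site_posteriors()

    def test_invariant_column_posterior_not_above_class_prior(self, quartet_tree):
        # a column identical in every taxon carries no selection signal
        cfg = SimulationConfig(tree=quartet_tree, n_codons=120, seed=2,
                               omega_foreground=3.0)
        aln = simulate_alignment(cfg)
        seqs = {t: "ATG" + s[3:] for t, s in aln.sequences.items()}
        aln = CodonAlignment(aln.taxa, seqs)
        m = CodonModel(aln, quartet_tree)
        res = m.fit("branch-site", starts=2)
        prior = (1 - res.params["p0"] - res.params["p1"])
        post = res.site_posteriors()["posterior"].iloc[0]
        assert post <= prior + 1e-6


class TestLRT:
    def test_equal_logliks_give_p_one(self):
        r = lrt(-100.0, -100.0, df=1)
        assert r.stat == 0.0 and r.p == 1.0

    def test_worse_alternative_clamped_to_zero(self):
        assert lrt(-100.0, -101.0).stat == 0.0

    def test_p_decreases_with_stat(self):
        ps = [lrt(-100.0, -100.0 + d).p for d in (0.5, 1.0, 2.0, 4.0)]
        assert ps == sorted(ps, reverse=True)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            lrt(float("nan"), -1.0)
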