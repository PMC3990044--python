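"""Latent-genotype likelihood: exact enumeration, EM fitting, model choice."""

import itertools

import numpy as np
import pytest
from scipy import stats

import gxglink as gx
from gxglink.likelihood_inference import (
    ENUMERATION_GUARD,
    FunctionalModelHypothesis,
    fit_model,
    log_likelihood_exact,
)

from conftest import make_table


def bruteforce_loglik(table, hyp):
    """Independent oracle: plain double sum over every joint assignment of
    latent genotypes to all isolates, products of binomial pmfs."""
    A = hyp.matrix()
    eps = hyp.epsilon
    pi = A * (1 - 2 * eps) + eps
    G, H, R = table.counts.shape
    t = table.design.trials_per_cell
    total = 0.0
    for zh in itertools.product(range(hyp.K), repeat=G):
        for zp in itertools.product(range(hyp.K), repeat=H):
            prob = np.prod([hyp.host_freqs[i] for i in zh])
            prob *= np.prod([hyp.parasite_freqs[j] for j in zp])
            for gi in range(G):
                for hj in range(H):
                    for r in range(R):
                        prob *= stats.binom.pmf(
                            table.counts[gi, hj, r], t, pi[zh[gi], zp[hj]]
                        )
            total += prob
    return np.log(total) if total > 0 else float("-inf")


class TestExactLikelihood:
    def test_single_cell_single_genotype(self):
        design = gx.ExperimentDesign(
            n_isolates_host=1, n_isolates_parasite=1, trials_per_cell=5,
            replicates=1,
        )
        tab = gx.CrossInfectionTable(np.zeros((1, 1, 1), int), design)
        hyp = FunctionalModelHypothesis("IMA", 1, [1.0], [1.0], epsilon=0.01)
        # alpha entry 0, eps=0.01: P(no infection in 5 trials) = 0.99**5
        assert log_likelihood_exact(tab, hyp) == pytest.approx(5 * np.log(0.99))

    def test_k1_reduces_to_iid_binomial(self):
        tab = make_table("MA", 2, seed=4)
        hyp = FunctionalModelHypothesis("MA", 1, [1.0], [1.0], epsilon=0.05)
        pi = 1.0 * (1 - 0.1) + 0.05
        expected = stats.binom.logpmf(tab.counts, 5, pi).sum()
        assert log_likelihood_exact(tab, hyp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "model,K,f,g,seed",
        [
            ("MA", 2, (0.5, 0.5), (0.5, 0.5), 0),
            ("MA", 2, (0.8, 0.2), (0.3, 0.7), 1),
            ("GFG", 3, (1 / 3,) * 3, (1 / 3,) * 3, 2),
            ("IMA", 2, (0.6, 0.4), (0.6, 0.4), 3),
        ],
    )
    def test_matches_bruteforce_enumeration(self, model, K, f, g, seed):
        tab = make_table(model, K, f=f[:K], g=g[:K], seed=seed)
        hyp = FunctionalModelHypothesis(model, K, f, g, epsilon=0.05)
        assert log_likelihood_exact(tab, hyp) == pytest.approx(
            bruteforce_loglik(tab, hyp), abs=1e-9
        )

    def test_guard_triggers_for_large_instances(self):
        design = gx.ExperimentDesign(error_rate=0.01)  # 30 x 30 isolates
        tab = make_table("MA", 3, f=(1 / 3,) * 3, g=(1 / 3,) * 3, design=design)
        hyp = FunctionalModelHypothesis("MA", 3, (1 / 3,) * 3, (1 / 3,) * 3)
        with pytest.raises(ValueError, match="fit_model"):
            log_likelihood_exact(tab, hyp)

    def test_epsilon_zero_contradictory_data_is_minus_inf(self):
        design = gx.ExperimentDesign(
            n_isolates_host=1, n_isolates_parasite=1, replicates=2,
        )
        # one "infection" observed although alpha = 0 everywhere and eps = 0
        tab = gx.CrossInfectionTable(np.array([[[1, 0]]]), design)
        hyp = FunctionalModelHypothesis("IMA", 1, [1.0], [1.0], epsilon=0.0)
        with pytest.warns(UserWarning, match="impossible"):
            assert log_likelihood_exact(tab, hyp) == float("-inf")

    def test_invariance_under_isolate_permutation(self, rng):
        tab = make_table("MA", 2, seed=6)
        hyp = FunctionalModelHypothesis("MA", 2, [0.6, 0.4], [0.5, 0.5], 0.03)
        base = log_likelihood_exact(tab, hyp)
        perm = rng.permutation(tab.n_host_isolates)
        shuffled = gx.CrossInfectionTable(tab.counts[perm], tab.design)
        assert log_likelihood_exact(shuffled, hyp) == pytest.approx(base)

    def test_invariance_under_matrix_preserving_relabeling(self):
        # swapping both genotypes maps the MA matrix to itself
        tab = make_table("MA", 2, seed=7)
        h1 = FunctionalModelHypothesis("MA", 2, [0.7, 0.3], [0.4, 0.6], 0.05)
        h2 = FunctionalModelHypothesis("MA", 2, [0.3, 0.7], [0.6, 0.4], 0.05)
        assert log_likelihood_exact(tab, h1) == pytest.approx(
            log_likelihood_exact(tab, h2)
        )


class TestFitModel:
    def test_monotone_and_at_least_uniform_start(self):
        tab = make_table("MA", 2, seed=8)
        fit = fit_model(tab, "MA", 2, epsilon=0.05, seed=0)
        uniform = FunctionalModelHypothesis("MA", 2, [0.5, 0.5], [0.5, 0.5], 0.05)
        assert fit.exact
        assert fit.log_likelihood >= log_likelihood_exact(tab, uniform) - 1e-9

    def test_matches_profile_maximum_from_grid_search(self):
        """On an instance small enough to enumerate, the fitted likelihood
        reaches the global profile maximum located by grid search + local
        refinement of the exact objective."""
        tab = make_table("MA", 2, f=(0.7, 0.3), g=(0.4, 0.6), seed=9)
        fit = fit_model(tab, "MA", 2, epsilon=0.05, seed=0)
        grid = np.arange(0.01, 1.0, 0.01)
        best = -np.inf
        for x in grid:
            for y in grid:
                hyp = FunctionalModelHypothesis("MA", 2, [x, 1 - x], [y, 1 - y], 0.05)
                best = max(best, log_likelihood_exact(tab, hyp))
        # the fit must not fall below the grid optimum (grid is coarser than
        # the optimizer, so it cannot legitimately exceed the fit by much)
        assert fit.log_likelihood >= best - 1e-6
        assert fit.log_likelihood <= best + 0.05

    def test_recovers_generating_frequencies(self):
        errs = []
        for seed in range(8):
            design = gx.ExperimentDesign(
                n_isolates_host=20, n_isolates_parasite=20, error_rate=0.02
            )
            tab = make_table("MA", 2, f=(0.7, 0.3), g=(0.7, 0.3), design=design,
                             seed=100 + seed)
            fit = fit_model(tab, "MA", 2, epsilon=0.02, seed=seed)
            f = fit.hypothesis.host_freqs
            g = fit.hypothesis.parasite_freqs
            # MA is invariant under the simultaneous genotype swap; recovery
            # error = mean absolute error over both frequency vectors
            errs.append(
                min(
                    0.5 * (abs(f[0] - 0.7) + abs(g[0] - 0.7)),
                    0.5 * (abs(f[1] - 0.7) + abs(g[1] - 0.7)),
                )
            )
        assert np.mean(errs) < 0.1

    def test_const_closed_form(self):
        tab = make_table("CONST", 2, seed=10, matrix_params={"c": 0.5})
        fit = fit_model(tab, "CONST", 2, epsilon=0.01)
        phat = tab.counts.mean() / tab.design.trials_per_cell
        c = (phat - 0.01) / 0.98
        assert fit.hypothesis.matrix_params["c"] == pytest.approx(c)
        assert fit.n_params == 1
        assert fit.exact

    def test_estimate_epsilon_improves_misspecified_error(self):
        design = gx.ExperimentDesign(
            n_isolates_host=12, n_isolates_parasite=12, error_rate=0.15
        )
        tab = make_table("MA", 2, f=(0.5, 0.5), g=(0.5, 0.5), design=design, seed=11)
        fixed = fit_model(tab, "MA", 2, epsilon=0.01, seed=0)
        free = fit_model(tab, "MA", 2, epsilon=0.01, estimate_epsilon=True, seed=0)
        assert free.hypothesis.epsilon > 0.05  # moved toward the truth
        assert free.elbo > fixed.elbo
        assert free.n_params == fixed.n_params + 1


class TestCompareModels:
    def test_const_data_prefers_const(self):
        wins = 0
        for seed in range(6):
            design = gx.ExperimentDesign(
                n_isolates_host=15, n_isolates_parasite=15, error_rate=0.01
            )
            tab = make_table("CONST", 3, f=(1 / 3,) * 3, g=(1 / 3,) * 3,
                             design=design, seed=300 + seed,
                             matrix_params={"c": 0.5})
            res = gx.compare_models(
                tab, [("MA", 3), ("CONST", 3)], epsilon=0.01, n_restarts=5, seed=seed
            )
            wins += res.selected == "CONST"
        assert wins >= 4

    def test_identical_hypotheses_tie_broken_stably(self):
        tab = make_table("MA", 2, seed=12)
        res = gx.compare_models(
            tab, [("MA", 2), ("MA", 2)], epsilon=0.05, n_restarts=3, seed=0
        )
        assert res.table.log_likelihood.iloc[0] == pytest.approx(
            res.table.log_likelihood.iloc[1]
        )
        assert res.selected_index == 0

    def test_needs_two_hypotheses(self):
        tab = make_table("MA", 2, seed=13)
        with pytest.raises(ValueError, match="two hypotheses"):
            gx.compare_models(tab, [("MA", 2)])

    def test_aic_definition_and_report(self, tmp_path):
        tab = make_table("MA", 2, seed=14)
        res = gx.compare_models(tab, [("MA", 2), ("CONST", 2)], epsilon=0.05,
                                n_restarts=3, seed=0)
        for fit in res.fits:
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        payload = res.to_json_dict()
        assert payload["selected"] in {"MA", "CONST"}
        assert len(payload["models"]) == 2
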