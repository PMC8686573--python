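import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

import chronokit as ck
from chronokit.population_model import (
    CostEngine,
    Hyperparameters,
    ModelParameters,
    kernel_weights,
    penalty_gene_mean_grad,
    penalty_growth_rate_grad,
    penalty_guide_efficacy_grad,
    penalty_kernel_grad,
    penalty_rho_grad,
)
from chronokit.inference import initialize, project_constraints

from conftest import make_toy_screen


def _toy_params(n_lines=2, n_genes=3, guides_per_gene=2, seed=0):
    genes = [f"G{i}" for i in range(n_genes)]
    guides = [f"{g}_sg{k}" for g in genes for k in range(guides_per_gene)]
    lines = [f"L{i}" for i in range(n_lines)]
    rng = np.random.default_rng(seed)
    return ModelParameters(
        rho=pd.DataFrame(0.0, index=["b0"], columns=guides),
        guide_efficacy=pd.Series(1.0, index=guides),
        cell_efficacy=pd.Series(1.0, index=lines),
        growth_rate=pd.Series(1.0, index=lines),
        gene_mean=pd.Series(rng.normal(0, 0.5, n_genes), index=genes),
        delta=pd.DataFrame(
            rng.normal(0, 0.2, (n_lines, n_genes)), index=lines, columns=genes
        ),
        guide_map=pd.Series([g.rsplit("_sg", 1)[0] for g in guides], index=guides),
    )


class TestNB2:
    def test_zero_when_observation_equals_mean(self):
        for alpha in (1e-3, 0.05, 1.0):
            assert ck.nb2_negative_log_likelihood(100.0, 100.0, alpha) == 0.0

    def test_matches_log_gamma_oracle_on_random_triples(self):
        rng = np.random.default_rng(42)
        N = rng.integers(0, 5000, 1000).astype(float)
        mu = rng.uniform(0.5, 5000.0, 1000)
        alpha = rng.uniform(1e-3, 1.0, 1000)
        ours = ck.nb2_negative_log_likelihood(N, mu, alpha)
        n = 1.0 / alpha
        oracle = -(nbinom.logpmf(N, n, n / (n + mu)) - nbinom.logpmf(N, n, n / (n + N)))
        np.testing.assert_allclose(ours, oracle, atol=1e-8)
        assert (ours >= -1e-12).all()

    def test_poisson_deviance_limit(self):
        N, mu = 137.0, 88.0
        limit = ck.nb2_negative_log_likelihood(N, mu, 1e-8)
        deviance = N * np.log(N / mu) - (N - mu)
        assert abs(limit - deviance) < 1e-4

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            ck.nb2_negative_log_likelihood(10.0, 0.0, 0.1)


class TestInitialAbundance:
    def test_zero_rho_returns_pdna_medians(self, toy_screen):
        med = ck.initial_abundance(toy_screen)
        # median across the two pDNA rows' relative abundances
        rel = toy_screen.counts.loc[["pdna_a", "pdna_b"]]
        rel = rel.div(rel.sum(axis=1), axis=0)
        np.testing.assert_allclose(med.loc["b0"], rel.median(axis=0), rtol=1e-12)

    def test_rho_recentered_per_gene(self, toy_screen):
        rho = pd.DataFrame(
            0.3, index=["b0"], columns=toy_screen.counts.columns
        )  # constant offset within every gene -> recentered away entirely
        with_rho = ck.initial_abundance(toy_screen, rho)
        without = ck.initial_abundance(toy_screen)
        pd.testing.assert_frame_equal(with_rho, without)

    def test_antisymmetric_rho_survives_centering(self, toy_screen):
        rho = pd.DataFrame(0.0, index=["b0"], columns=toy_screen.counts.columns)
        rho.loc["b0", "G0_sg0"] = 0.2
        rho.loc["b0", "G0_sg1"] = -0.2
        out = ck.initial_abundance(toy_screen, rho)
        base = ck.initial_abundance(toy_screen)
        assert out.loc["b0", "G0_sg0"] == pytest.approx(
            base.loc["b0", "G0_sg0"] * np.exp(0.2)
        )

    def test_zero_pdna_abundance_rejected(self, toy_screen):
        counts = toy_screen.counts.copy()
        counts.loc[["pdna_a", "pdna_b"], "G0_sg0"] = 0.0
        data = ck.ScreenData(
            counts=counts,
            sequence_map=toy_screen.sequence_map,
            guide_map=toy_screen.guide_map,
        )
        with pytest.raises(ValueError, match="G0_sg0"):
            ck.initial_abundance(data)


class TestPredictedAbundance:
    def test_before_delay_equals_normalized_nu0(self):
        params = _toy_params()
        params.d_g = 3.0
        nu0 = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.1],
                        index=params.guide_efficacy.index)
        pred = ck.predicted_abundance(params, nu0, [0.0, 2.9])
        expected = np.tile((nu0 / nu0.sum()).to_numpy(), (2, 1))
        for t in range(2):
            np.testing.assert_allclose(pred.nu[t], expected, rtol=1e-12)

    def test_null_effects_are_time_constant(self):
        params = _toy_params()
        params.gene_mean[:] = 0.0
        params.delta.iloc[:, :] = 0.0
        nu0 = pd.Series(np.full(6, 1 / 6), index=params.guide_efficacy.index)
        pred = ck.predicted_abundance(params, nu0, [0.0, 10.0, 30.0])
        for t in (1, 2):
            np.testing.assert_allclose(pred.nu[t], pred.nu[0], rtol=1e-12)

    def test_two_guide_closed_form(self):
        """One depleting (r=-1) and one neutral guide, p=1, R=1, d_g=0:
        nu_depleting(t) = e^-t / (1 + e^-t)."""
        genes = ["dep", "neu"]
        guides = ["dep_sg0", "neu_sg0"]
        params = ModelParameters(
            rho=pd.DataFrame(0.0, index=["b0"], columns=guides),
            guide_efficacy=pd.Series(1.0, index=guides),
            cell_efficacy=pd.Series(1.0, index=["L0"]),
            growth_rate=pd.Series(1.0, index=["L0"]),
            gene_mean=pd.Series([-1.0, 0.0], index=genes),
            delta=pd.DataFrame(0.0, index=["L0"], columns=genes),
            guide_map=pd.Series(genes, index=guides),
            d_g=0.0,
        )
        nu0 = pd.Series([0.5, 0.5], index=guides)
        days = np.linspace(0.0, 30.0, 61)
        pred = ck.predicted_abundance(params, nu0, days)
        expected = np.exp(-days) / (1.0 + np.exp(-days))
        np.testing.assert_allclose(pred.nu[:, 0, 0], expected, atol=1e-10)

    def test_rows_sum_to_one(self):
        params = _toy_params(seed=3)
        nu0 = pd.Series(np.full(6, 1 / 6), index=params.guide_efficacy.index)
        pred = ck.predicted_abundance(params, nu0, [5.0, 12.0])
        np.testing.assert_allclose(pred.nu.sum(axis=2), 1.0, atol=1e-10)


class TestPenalties:
    def test_zero_rho_gives_zero_penalty(self):
        params = _toy_params()
        assert ck.penalty_rho(params, Hyperparameters()) == 0.0

    def test_guide_efficacy_each_gene_contributes_two_reciprocals(self):
        params = _toy_params(n_genes=4, guides_per_gene=4)
        params.guide_efficacy[:] = 1.0
        hp = Hyperparameters()
        # every gene contributes 1/1 + 1/1 = 2 before chi_p and gene-averaging
        assert ck.penalty_guide_efficacy(params, hp) == pytest.approx(hp.chi_p * 2.0)

    def test_unit_growth_rates_and_flat_profiles_give_zero(self):
        params = _toy_params()
        assert ck.penalty_growth_rate(params, Hyperparameters()) == 0.0
        params.delta.iloc[:, :] = 0.0  # r_cg equal across lines per gene
        hp = Hyperparameters(chi_k=1e-12)  # isolate the delta (own-mean) term
        assert ck.penalty_kernel(params, hp) == pytest.approx(0.0, abs=1e-12)

    def test_gene_mean_penalty_is_squared_global_mean(self):
        params = _toy_params(seed=1)
        hp = Hyperparameters()
        r = params.gene_effect.to_numpy()
        assert ck.penalty_gene_mean(params, hp) == pytest.approx(
            hp.chi_r1 * r.mean() ** 2
        )

    def test_kernel_matches_hand_computed_toy(self):
        """3 genes, sigma=5: direct triple-loop evaluation of the truncated
        Gaussian kernel is reproduced by the vectorized implementation."""
        params = _toy_params(n_lines=2, n_genes=3, seed=2)
        hp = Hyperparameters()
        r = params.gene_effect.to_numpy()
        rbar = r.mean(axis=0)
        order = np.argsort(rbar, kind="stable")
        ranks = np.empty(3, dtype=int)
        ranks[order] = np.arange(3)
        width = int(3 * hp.sigma)
        b = sum(np.exp(-(d**2) / (2 * hp.sigma**2)) for d in range(-width, width + 1))
        total, count = 0.0, 0
        for c in range(2):
            for g in range(3):
                for h in range(3):
                    d = ranks[g] - ranks[h]
                    if abs(d) > width:
                        continue
                    kappa = hp.chi_h * (g == h) + hp.chi_k * np.exp(
                        -(d**2) / (2 * hp.sigma**2)
                    ) / b
                    total += kappa * (r[c, g] - rbar[h]) ** 2
                    count += 1
        assert ck.penalty_kernel(params, hp) == pytest.approx(total / count, rel=1e-12)

    def test_kernel_weights_truncated_at_three_sigma(self):
        means = pd.Series(np.linspace(-1, 0, 40), index=[f"G{i}" for i in range(40)])
        hp = Hyperparameters()
        W = kernel_weights(means, hp)
        assert W[0, 15] > 0
        assert W[0, 16] == 0.0


class TestCoreCost:
    def test_perfect_predictions_cost_zero(self, noise_free_sim):
        """Noise-free counts from perfect reagents: the truth parameters give
        exactly the observed proportions, so the shifted NB2 cost vanishes."""
        data, truth = noise_free_sim
        genes = pd.Index(sorted(truth.gene_effect.columns))
        lines = truth.gene_effect.index
        guides = data.counts.columns
        params = ModelParameters(
            rho=pd.DataFrame(0.0, index=["batch0"], columns=guides),
            guide_efficacy=truth.guide_efficacy.reindex(guides),
            cell_efficacy=pd.Series(
                truth.cell_efficacy.to_numpy(),
                index=pd.MultiIndex.from_product(
                    [lines, ["default"]], names=["cell_line_name", "library"]
                ),
            ),
            growth_rate=pd.Series(
                truth.growth_rate.to_numpy(),
                index=pd.MultiIndex.from_product(
                    [lines, ["default"]], names=["cell_line_name", "library"]
                ),
            ),
            gene_mean=pd.Series(0.0, index=genes),
            delta=truth.gene_effect.reindex(columns=genes),
            guide_map=data.guide_genes(),
        )
        cost = ck.core_cost(data, params)
        assert cost == pytest.approx(0.0, abs=1e-4)

    def test_rpm_invariance_under_count_doubling(self, toy_screen):
        hp = Hyperparameters()
        params = initialize(toy_screen, hp, seed=0)
        params.cell_efficacy = pd.Series(
            0.9, index=params.cell_efficacy.index
        )
        c1 = ck.core_cost(toy_screen, params)
        doubled = toy_screen.copy()
        doubled.counts.loc["rep1"] *= 2.0
        c2 = ck.core_cost(doubled, params)
        assert c1 == pytest.approx(c2, rel=1e-10)

    def test_matches_term_by_term_oracle(self):
        """Single replicate, two guides: sum the shifted NB2 terms by hand."""
        guides = ["g1_sg0", "g2_sg0"]
        counts = pd.DataFrame(
            [[40.0, 60.0], [70.0, 30.0]], index=["pdna", "rep"], columns=guides
        )
        data = ck.ScreenData(
            counts=counts,
            sequence_map=pd.DataFrame(
                {
                    "sequence_ID": ["pdna", "rep"],
                    "cell_line_name": ["pDNA", "lineA"],
                    "pDNA_batch": ["b", "b"],
                    "days": [0.0, 10.0],
                }
            ),
            guide_map=pd.DataFrame({"sgrna": guides, "gene": ["g1", "g2"]}),
        )
        params = ModelParameters(
            rho=pd.DataFrame(0.0, index=["b"], columns=guides),
            guide_efficacy=pd.Series([0.9, 0.8], index=guides),
            cell_efficacy=pd.Series(
                [0.85],
                index=pd.MultiIndex.from_tuples(
                    [("lineA", "default")], names=["cell_line_name", "library"]
                ),
            ),
            growth_rate=pd.Series(
                [1.0],
                index=pd.MultiIndex.from_tuples(
                    [("lineA", "default")], names=["cell_line_name", "library"]
                ),
            ),
            gene_mean=pd.Series([-0.5, 0.1], index=["g1", "g2"]),
            delta=pd.DataFrame(0.0, index=["lineA"], columns=["g1", "g2"]),
            guide_map=pd.Series(["g1", "g2"], index=guides),
            alpha=0.05,
        )
        # oracle: explicit forward pass
        nu0 = np.array([0.4, 0.6])
        tau = 10.0 - 3.0
        Z = nu0 * (
            1.0
            + 0.85 * np.array([0.9, 0.8]) * (np.exp(np.array([-0.5, 0.1]) * tau) - 1.0)
        )
        mu = 1e6 * Z / Z.sum()
        N = 1e6 * np.array([0.7, 0.3])
        expected = sum(
            ck.nb2_negative_log_likelihood(N[j], mu[j], 0.05) for j in range(2)
        )
        assert ck.core_cost(data, params) == pytest.approx(expected, rel=1e-10)


class TestTotalCostAndGradients:
    def test_total_cost_is_sum_of_parts(self, toy_screen):
        hp = Hyperparameters()
        params = initialize(toy_screen, hp, seed=1)
        params.cell_efficacy = pd.Series(0.9, index=params.cell_efficacy.index)
        total = ck.total_cost(toy_screen, params, hp, rescale=0.5)
        parts = (
            0.5 * ck.core_cost(toy_screen, params)
            + ck.penalty_rho(params, hp)
            + ck.penalty_guide_efficacy(params, hp)
            + ck.penalty_growth_rate(params, hp)
            + ck.penalty_gene_mean(params, hp)
            + ck.penalty_kernel(params, hp)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_analytic_gradients_match_finite_differences(self, toy_screen):
        """Every gradient of the total cost agrees with central differences on
        a 2-line x 4-gene problem to relative error < 1e-4."""
        hp = Hyperparameters()
        params = initialize(toy_screen, hp, seed=2)
        params.cell_efficacy = pd.Series(0.85, index=params.cell_efficacy.index)
        rng = np.random.default_rng(0)
        params.gene_mean += rng.normal(0, 0.3, len(params.gene_mean))
        params.delta += rng.normal(0, 0.2, params.delta.shape)
        params.rho += rng.normal(0, 0.1, params.rho.shape)
        params.guide_efficacy = pd.Series(
            rng.uniform(0.5, 0.95, len(params.guide_efficacy)),
            index=params.guide_efficacy.index,
        )
        project_constraints(params)
        engine = CostEngine(toy_screen, d_g=hp.d_g)
        state = engine.forward(params)
        grads = engine.gradients(params, state)
        grads["gene_effect"] = (
            grads["gene_effect"]
            + penalty_gene_mean_grad(params, hp)
            + penalty_kernel_grad(params, hp)
        )
        grads["rho"] = grads["rho"] + penalty_rho_grad(params, hp)
        grads["guide_efficacy"] = grads["guide_efficacy"] + penalty_guide_efficacy_grad(
            params, hp
        )
        grads["growth_rate"] = grads["growth_rate"] + penalty_growth_rate_grad(
            params, hp
        )

        def cost():
            return (
                engine.core_cost(params)
                + ck.penalty_rho(params, hp)
                + ck.penalty_guide_efficacy(params, hp)
                + ck.penalty_growth_rate(params, hp)
                + ck.penalty_gene_mean(params, hp)
                + ck.penalty_kernel(params, hp)
            )

        eps = 1e-6

        def check(name, get, set_):
            base = get().copy()
            analytic = grads[name]
            numeric = np.zeros_like(base, dtype=float)
            it = np.nditer(base, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                pert = base.copy()
                pert[i] += eps
                set_(pert)
                up = cost()
                pert[i] -= 2 * eps
                set_(pert)
                down = cost()
                set_(base)
                numeric[i] = (up - down) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-10)
            assert np.abs(numeric - analytic).max() / scale < 1e-4, name

        check(
            "gene_effect",
            lambda: params.gene_effect.to_numpy(),
            lambda v: setattr(
                params,
                "delta",
                pd.DataFrame(
                    v - params.gene_mean.to_numpy(),
                    index=params.delta.index,
                    columns=params.delta.columns,
                ),
            ),
        )
        check(
            "guide_efficacy",
            lambda: params.guide_efficacy.to_numpy(),
            lambda v: setattr(
                params,
                "guide_efficacy",
                pd.Series(v, index=params.guide_efficacy.index),
            ),
        )
        check(
            "growth_rate",
            lambda: params.growth_rate.to_numpy(),
            lambda v: setattr(
                params, "growth_rate", pd.Series(v, index=params.growth_rate.index)
            ),
        )
        check(
            "rho",
            lambda: params.rho.to_numpy(),
            lambda v: setattr(
                params,
                "rho",
                pd.DataFrame(v, index=params.rho.index, columns=params.rho.columns),
            ),
        )

    def test_cost_decreases_toward_observed_proportions(self, toy_screen):
        """Moving predictions along the line toward the observed proportions
        lowers the NB2 cost (spot-check of convexity in the nu direction)."""
        engine = CostEngine(toy_screen, d_g=3.0)
        hp = Hyperparameters()
        params = initialize(toy_screen, hp, seed=0)
        params.cell_efficacy = pd.Series(0.9, index=params.cell_efficacy.index)
        rng = np.random.default_rng(1)
        params.gene_mean += rng.normal(0, 0.4, len(params.gene_mean))
        state = engine.forward(params)
        observed = np.where(engine.observed, engine.N, state["mu"])
        costs = []
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            mu = (1 - lam) * state["mu"] + lam * observed
            terms = ck.nb2_negative_log_likelihood(observed, mu, 0.05)
            costs.append(float(np.where(engine.observed, terms, 0.0).sum()))
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))


class TestCellEfficacy:
    def test_no_depletion_floors_at_p_min(self):
        lfc = pd.DataFrame(
            np.zeros((1, 200)), index=["rep"], columns=[f"sg{i}" for i in range(200)]
        )
        sm = pd.DataFrame(
            {"sequence_ID": ["rep"], "cell_line_name": ["L"], "days": [14.0]}
        )
        pc = ck.estimate_cell_efficacy(lfc, sm)
        assert pc.iloc[0] == 0.01

    def test_complete_dropout_gives_full_efficacy(self):
        values = np.zeros(200)
        values[:10] = -30.0  # effectively -inf fold change
        lfc = pd.DataFrame(
            values[None, :], index=["rep"], columns=[f"sg{i}" for i in range(200)]
        )
        sm = pd.DataFrame(
            {"sequence_ID": ["rep"], "cell_line_name": ["L"], "days": [14.0]}
        )
        pc = ck.estimate_cell_efficacy(lfc, sm)
        assert pc.iloc[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("true_pc", [0.6, 0.8, 1.0])
    def test_simulated_screen_recovery(self, true_pc):
        sc = ck.SimulationScenario(
            n_lines=2, n_genes=150, guides_per_gene=4, n_replicates=2,
            time_points=(14.0, 21.0), depth=500.0, seed=int(true_pc * 10),
            cell_efficacy_range=(true_pc, true_pc),
        )
        data, truth = ck.simulate_screen(sc)
        lfc = ck.compute_lfc(data)
        pc = ck.estimate_cell_efficacy(lfc, data.sequence_map)
        assert np.abs(pc.to_numpy() - true_pc).max() < 0.1
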