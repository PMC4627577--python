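"""Technical-noise model: coefficients, per-cell estimation, model fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikevar as sv
from spikevar.technical import technical_coefficients

from conftest import GAMMA_MOMENTS, THETA_MOMENTS


class TestCoefficients:
    def test_pure_poisson_limit(self):
        # deterministic full capture, constant sequencing: x ~ Poisson(m*g)
        derived = technical_coefficients(1.0, 0.0, 2.0, 0.0)
        assert derived["A"] == pytest.approx(2.0)
        assert derived["B"] == pytest.approx(0.0)
        assert derived["mu_eta"] == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mu_t=st.floats(0.01, 1.0),
        var_t=st.floats(0, 0.05),
        mu_g=st.floats(0.05, 5.0),
        var_g=st.floats(0, 1.0),
    )
    def test_moment_identity(self, mu_t, var_t, mu_g, var_g):
        """r2_theta * r2_gamma = B + mu_eta^2 holds for any valid moments."""
        d = technical_coefficients(mu_t, var_t, mu_g, var_g)
        assert d["r2_theta"] * d["r2_gamma"] == pytest.approx(
            d["B"] + d["mu_eta"] ** 2, rel=1e-12
        )

    def test_variance_formula_matches_brute_force_draws(self, rng):
        mu_t, var_t = THETA_MOMENTS
        mu_g, var_g = GAMMA_MOMENTS
        d = technical_coefficients(mu_t, var_t, mu_g, var_g)
        mu_m = 50
        n = 200_000
        theta = rng.beta(
            mu_t * (mu_t * (1 - mu_t) / var_t - 1),
            (1 - mu_t) * (mu_t * (1 - mu_t) / var_t - 1),
            n,
        )
        gamma = rng.gamma(mu_g**2 / var_g, var_g / mu_g, n)
        x = rng.poisson(rng.binomial(mu_m, theta) * gamma)
        expected = mu_m * d["A"] + mu_m**2 * d["B"]
        s2 = x.var(ddof=1)
        m4 = ((x - x.mean()) ** 4).mean()
        se = np.sqrt((m4 - s2**2 * (n - 3) / (n - 1)) / n)
        assert abs(s2 - expected) < 3 * se


class TestCellEfficiencies:
    def test_exact_counts_give_unit_eta(self):
        n_s = pd.Series(np.geomspace(1, 1000, 20), index=[f"s{i}" for i in range(20)])
        counts = pd.DataFrame(
            {"c0": n_s, "c1": n_s}, index=n_s.index
        )
        est = sv.estimate_cell_efficiencies(counts, n_s)
        assert est["eta_hat"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_noise_free_cell_flagged_degenerate(self):
        n_s = pd.Series(
            np.geomspace(10, 1000, 15), index=[f"s{i}" for i in range(15)]
        )
        counts = pd.DataFrame({"c0": 0.1 * n_s}, index=n_s.index)
        est = sv.estimate_cell_efficiencies(counts, n_s, gamma_floor=0.01)
        assert bool(est["degenerate"].iloc[0])
        assert est["gamma_hat"].iloc[0] >= 0.01
        assert est["w_hat"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_cell_errors(self):
        n_s = pd.Series([1.0, 10.0], index=["a", "b"])
        counts = pd.DataFrame({"c0": [0, 0]}, index=n_s.index)
        with pytest.raises(ValueError, match="zero spike-in"):
            sv.estimate_cell_efficiencies(counts, n_s)

    def test_mean_eta_recovery_from_simulation(self):
        exp = sv.generate_synthetic_experiment(
            sv.SyntheticConfig(
                n_cells=200,
                genes_per_condition=0,
                n_background_genes=1,
                n_null_alleles=0,
                n_imprinted=0,
                n_stochastic=0,
            ),
            seed=7,
        )
        est = sv.estimate_cell_efficiencies(
            exp.matrix.spikeins(), exp.reference.n_s
        )
        true_eta = THETA_MOMENTS[0] * GAMMA_MOMENTS[0]
        se = est["eta_hat"].std(ddof=1) / np.sqrt(len(est))
        assert abs(est["eta_hat"].mean() - true_eta) < 3 * se + 0.002


class TestModelFit:
    def test_fitted_identity_holds_exactly(self, fitted_model):
        m = fitted_model
        assert m.r2_theta_ * m.r2_gamma_ == pytest.approx(
            m.B_ + m.mu_eta_**2, rel=1e-12
        )
        assert m.mu_eta_ == pytest.approx(m.mu_theta_ * m.mu_gamma_, rel=1e-12)
        assert 0 < m.mu_theta_ <= 1
        assert m.mu_gamma_ > 0
        assert m.var_theta_ >= 0 and m.var_gamma_ >= 0
        assert m.A_ > 0 and m.B_ >= 0

    def test_requires_three_cells_and_spikes(self, experiment):
        two = experiment.matrix.subset_cells(experiment.matrix.cell_ids[:2])
        with pytest.raises(ValueError, match="3 cells"):
            sv.TechnicalNoiseModel().fit(two, experiment.reference)
        endo_only = sv.CountMatrix(
            counts=experiment.matrix.endogenous().iloc[:5],
            gene_role=pd.Series(
                "endogenous", index=experiment.matrix.endogenous().index[:5]
            ),
        )
        with pytest.raises(ValueError, match="no spike-in"):
            sv.TechnicalNoiseModel().fit(endo_only, experiment.reference)

    def test_moment_and_direct_regression_ab_agree(self, fitted_model):
        """The fitted (A, B) and an independent quadratic regression of
        per-spike variances on (n_s, n_s^2) are two routes to the same
        quantities; they must agree within estimation error."""
        direct = fitted_model.direct_fit_
        assert direct["A"] == pytest.approx(fitted_model.A_, rel=0.2)
        assert direct["B"] == pytest.approx(fitted_model.B_, rel=0.2)

    def test_technical_variance_contract(self, fitted_model):
        assert fitted_model.technical_variance(0.0) == 0.0
        grid = np.array([0.5, 1, 5, 10, 100, 1000.0])
        v = fitted_model.technical_variance(grid)
        assert np.all(np.diff(v) > 0), "V_tech must increase with abundance"
        with pytest.raises(ValueError, match="nonnegative"):
            fitted_model.technical_variance(-1.0)

    def test_serialization_roundtrip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.save(path)
        again = sv.TechnicalNoiseModel.load(path)
        for attr in ("mu_theta_", "var_theta_", "mu_gamma_", "var_gamma_", "A_", "B_"):
            assert getattr(again, attr) == getattr(fitted_model, attr)
        assert again.technical_variance(50.0) == fitted_model.technical_variance(50.0)
        pd.testing.assert_frame_equal(
            again.cell_estimates_.reset_index(drop=True),
            fitted_model.cell_estimates_.reset_index(drop=True),
        )

    def test_fit_is_deterministic(self, experiment):
        a = sv.TechnicalNoiseModel(random_state=3).fit(
            experiment.matrix, experiment.reference
        )
        b = sv.TechnicalNoiseModel(random_state=3).fit(
            experiment.matrix, experiment.reference
        )
        assert a.mu_theta_ == b.mu_theta_
        assert a.var_gamma_ == b.var_gamma_

    def test_sample_moments_method(self, experiment):
        m = sv.TechnicalNoiseModel(fit_method="sample_moments").fit(
            experiment.matrix, experiment.reference
        )
        est = m.cell_estimates_
        assert m.mu_theta_ == pytest.approx(est["theta_hat"].mean())
        assert m.var_gamma_ == pytest.approx(est["gamma_hat"].var(ddof=1))

    def test_parameter_recovery_single_replicate(self, fitted_model):
        """Means of the efficiency laws recover within a loose band on one
        synthetic experiment (tight multi-replicate recovery is exercised by
        the acceptance suite)."""
        assert fitted_model.mu_theta_ == pytest.approx(THETA_MOMENTS[0], rel=0.3)
        assert fitted_model.mu_gamma_ == pytest.approx(GAMMA_MOMENTS[0], rel=0.3)
        assert fitted_model.mu_eta_ == pytest.approx(
            THETA_MOMENTS[0] * GAMMA_MOMENTS[0], rel=0.1
        )


class TestSpikeinCv2Table:
    def test_predicted_cv2_limits(self, fitted_model):
        m = fitted_model
        # large-abundance floor: CV^2 -> B/mu_eta^2
        big = 1e9
        cv2 = m.technical_variance(big) / (big * m.mu_eta_) ** 2
        assert cv2 == pytest.approx(m.B_ / m.mu_eta_**2, rel=1e-3)

    def test_validation_table_calibration(self, experiment, fitted_model, rng):
        """Observed spike CV^2 falls inside the simulated pointwise 95% band
        of the fitted mean-variance relationship for >= 90% of spikes."""
        table = fitted_model.predicted_spikein_cv2(
            experiment.matrix, experiment.reference
        )
        n_cells = experiment.matrix.n_cells
        n_rep = 200
        est = fitted_model.cell_estimates_
        inside = []
        for spike_id, row in table.iterrows():
            if row["obs_mean"] <= 0:
                continue
            idx = rng.integers(0, len(est), size=(n_rep, n_cells))
            theta = est["theta_hat"].to_numpy()[idx]
            gamma = est["gamma_hat"].to_numpy()[idx]
            m = sv.stochastic_round(
                np.full((n_rep, n_cells), row["n_s"]), rng
            )
            x = rng.poisson(rng.binomial(m, theta) * gamma)
            mean = x.mean(axis=1)
            var = x.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv2 = np.where(mean > 0, var / mean**2, np.nan)
            lo, hi = np.nanpercentile(cv2, [2.5, 97.5])
            inside.append(lo <= row["obs_cv2"] <= hi)
        assert np.mean(inside) >= 0.9
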