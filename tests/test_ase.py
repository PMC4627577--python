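"""Allelic-ratio statistics and the stochastic-ASE test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikevar as sv


def _table(units: dict[str, tuple[np.ndarray, np.ndarray]], gene_map=None):
    rows = []
    for snp, (mat, pat) in units.items():
        gene = gene_map.get(snp, f"gene_{snp}") if gene_map else f"gene_{snp}"
        for c, (m, p) in enumerate(zip(mat, pat)):
            rows.append(
                {
                    "snp_id": snp,
                    "gene_id": gene,
                    "cell_id": f"c{c}",
                    "maternal": float(m),
                    "paternal": float(p),
                }
            )
    return sv.AlleleCountTable(records=pd.DataFrame(rows))


class TestAllelicRatio:
    @pytest.mark.parametrize(
        "mat,pat,expected",
        [(5, 5, 0.5), (0, 7, 1.0), (3, 1, 0.75), (7, 0, 1.0)],
    )
    def test_worked_examples(self, mat, pat, expected):
        assert sv.allelic_ratio(mat, pat) == expected

    def test_double_zero_undefined(self):
        assert np.isnan(sv.allelic_ratio(0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mat=st.floats(0, 1e6),
        pat=st.floats(0, 1e6),
        k=st.floats(1e-3, 1e3),
    )
    def test_swap_symmetry_and_scale_invariance(self, mat, pat, k):
        r = sv.allelic_ratio(mat, pat)
        r_swap = sv.allelic_ratio(pat, mat)
        r_scaled = sv.allelic_ratio(mat * k, pat * k)
        if np.isnan(r):
            assert np.isnan(r_swap)
        else:
            assert 0.5 <= r <= 1.0
            assert r == r_swap
            assert r_scaled == pytest.approx(r, rel=1e-9)


class TestMeanAllelicRatio:
    def test_worked_example(self):
        r, n = sv.mean_allelic_ratio([10, 0, 5], [0, 10, 5])
        assert n == 3
        assert r == pytest.approx(5 / 6)

    def test_all_zero_undefined(self):
        r, n = sv.mean_allelic_ratio([0, 0], [0, 0])
        assert n == 0 and np.isnan(r)

    def test_per_cell_scaling_invariance(self, rng):
        mat = rng.integers(0, 20, 30).astype(float)
        pat = rng.integers(0, 20, 30).astype(float)
        r0, _ = sv.mean_allelic_ratio(mat, pat)
        scale = rng.uniform(0.1, 10, 30)
        r1, _ = sv.mean_allelic_ratio(mat * scale, pat * scale)
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_min_cells_threshold(self):
        r, n = sv.mean_allelic_ratio([3, 0], [0, 0], min_cells=2)
        assert n == 1 and np.isnan(r)


class TestStochasticASETest:
    def test_extreme_ratio_beats_all_null_draws(self, fitted_model):
        # a unit where every cell expresses one allele completely and at
        # high level: observed r_bar = 1 > essentially every null draw
        n_cells = 54
        rng = np.random.default_rng(0)
        pick = rng.random(n_cells) < 0.5
        mat = np.where(pick, 40.0, 0.0)
        pat = np.where(pick, 0.0, 40.0)
        table = _table({"s1": (mat, pat)})
        res = sv.test_stochastic_ase(
            table, fitted_model, n_sim=2000, seed=1
        )
        assert res["p_emp"].iloc[0] <= 2 / 2001
        assert res["p_emp"].iloc[0] > 0
        assert bool(res["significant"].iloc[0])

    def test_balanced_unit_not_called(self, fitted_model):
        mat = np.full(54, 20.0)
        pat = np.full(54, 20.0)
        table = _table({"s1": (mat, pat)})
        res = sv.test_stochastic_ase(table, fitted_model, n_sim=500, seed=2)
        assert res["p_emp"].iloc[0] > 0.5

    def test_results_bit_reproducible(self, fitted_model, rng):
        mat = rng.poisson(3, 54).astype(float)
        pat = rng.poisson(3, 54).astype(float)
        table = _table({"s1": (mat, pat), "s2": (pat, mat)})
        a = sv.test_stochastic_ase(table, fitted_model, n_sim=400, seed=7)
        b = sv.test_stochastic_ase(table, fitted_model, n_sim=400, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_min_cells_skip(self, fitted_model):
        table = _table({"s1": (np.zeros(10), np.zeros(10))})
        res = sv.test_stochastic_ase(table, fitted_model, n_sim=100, seed=0)
        assert res["skipped_reason"].iloc[0] == "min_cells"
        assert np.isnan(res["p_emp"].iloc[0])

    def test_gene_level_uses_most_expressed_snp(self, fitted_model):
        strong = (np.full(20, 30.0), np.full(20, 30.0))
        weak = (np.full(20, 1.0), np.full(20, 1.0))
        table = _table(
            {"s_strong": strong, "s_weak": weak},
            gene_map={"s_strong": "geneX", "s_weak": "geneX"},
        )
        res = sv.test_stochastic_ase(
            table, fitted_model, n_sim=50, seed=0, level="gene"
        )
        assert list(res.index) == ["geneX"]
        # the reduction keeps the strong SNP's expression level; means are
        # divided by the simulator-consistent mean per-cell efficiency
        eta_bar = fitted_model.cell_estimates_["eta_hat"].mean()
        assert res["mu_mat_hat"].iloc[0] == pytest.approx(30.0 / eta_bar, rel=1e-6)


class TestMonoallelicSummary:
    def test_balanced_cells_fraction_zero(self):
        table = _table({"s1": (np.ones(10), np.ones(10))})
        out = sv.monoallelic_summary(table)
        assert out["frac_informative_cell_pairs_above"] == 0.0
        assert out["frac_units_flagged"] == 0.0

    def test_single_monoallelic_cell_flags_unit(self):
        mat = np.array([20.0, 5, 5, 5])
        pat = np.array([0.0, 5, 5, 5])
        out = sv.monoallelic_summary(_table({"s1": (mat, pat)}))
        assert out["frac_units_flagged"] == 1.0
        assert out["frac_informative_cell_pairs_above"] == pytest.approx(0.25)

    def test_cutoff_validation(self):
        table = _table({"s1": (np.ones(2), np.ones(2))})
        with pytest.raises(ValueError, match="cutoff"):
            sv.monoallelic_summary(table, cutoff=0.4)

    def test_flagging_increases_as_expression_drops(self, fitted_model):
        """Technical noise alone makes lowly expressed balanced units look
        monoallelic: flagged fraction rises monotonically as mu falls."""
        rng = np.random.default_rng(5)
        fracs = {}
        for mu in (100.0, 10.0, 1.0):
            units = {}
            for u in range(60):
                spec = sv.SimulationSpec(
                    mode="T",
                    n_cells=54,
                    mu=np.array([mu / 2, mu / 2]),
                    seed=int(rng.integers(2**31)),
                )
                sim = sv.simulate_pseudo_cells(fitted_model, spec)
                units[f"s{u}"] = (
                    sim.counts.to_numpy()[0].astype(float),
                    sim.counts.to_numpy()[1].astype(float),
                )
            fracs[mu] = sv.monoallelic_summary(_table(units))[
                "frac_informative_cell_pairs_above"
            ]
        assert fracs[1.0] > fracs[10.0] > fracs[100.0]


class TestRatioProfile:
    def test_profile_shape_and_empty_bins(self, fitted_model, rng):
        units = {}
        for u, mu in enumerate(np.geomspace(1, 500, 40)):
            spec = sv.SimulationSpec(
                mode="T",
                n_cells=54,
                mu=np.array([mu / 2, mu / 2]),
                seed=int(rng.integers(2**31)),
            )
            sim = sv.simulate_pseudo_cells(fitted_model, spec)
            units[f"s{u}"] = (
                sim.counts.to_numpy()[0].astype(float),
                sim.counts.to_numpy()[1].astype(float),
            )
        table = _table(units)
        bins = np.array([0.1, 3, 30, 300, 3000.0])
        prof = sv.ratio_profile(table, fitted_model, bins=bins, n_boot=50, seed=0)
        assert len(prof) == 4
        filled = prof.dropna(subset=["mean_ratio"])
        assert (filled["mean_ratio"] >= 0.5).all()
        assert (filled["ci_lo"] <= filled["mean_ratio"]).all()
        assert (filled["ci_hi"] >= filled["mean_ratio"]).all()


class TestAlleleCorrelation:
    def test_identical_alleles_maximal_correlation(self, fitted_model, rng):
        x = rng.poisson(20, 30).astype(float) + 1
        table = _table({"s1": (x, x)})
        res = sv.test_allele_correlation(table, fitted_model, n_sim=200, seed=0)
        assert res["spearman_rho"].iloc[0] == pytest.approx(1.0)
        assert res["p_emp"].iloc[0] <= 2 / 201

    def test_degenerate_unit_skipped(self, fitted_model):
        table = _table({"s1": (np.full(10, 5.0), np.full(10, 3.0))})
        res = sv.test_allele_correlation(table, fitted_model, n_sim=50, seed=0)
        assert res["skipped_reason"].iloc[0] == "degenerate"

    def test_shared_extrinsic_factor_detected(self, fitted_model, rng):
        """A per-cell factor multiplying both alleles' true counts creates
        detectable positive correlation."""
        n_cells = 54
        hits = 0
        n_units = 30
        for u in range(n_units):
            # strong extrinsic component: unit-mean lognormal-like factor
            factor = rng.gamma(1.0, 1.0, n_cells)
            theta, gamma = (
                fitted_model.cell_estimates_["theta_hat"].to_numpy(),
                fitted_model.cell_estimates_["gamma_hat"].to_numpy(),
            )
            idx = rng.integers(0, len(theta), n_cells)
            mat = sv.simulate_observation(
                rng.poisson(100 * factor), theta[idx], gamma[idx], rng
            ).astype(float)
            pat = sv.simulate_observation(
                rng.poisson(100 * factor), theta[idx], gamma[idx], rng
            ).astype(float)
            res = sv.test_allele_correlation(
                _table({"s": (mat, pat)}), fitted_model, n_sim=200, seed=u
            )
            if res["p_emp"].iloc[0] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_units
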