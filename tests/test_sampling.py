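"""Ensemble sampling, stability classification, correlations and PSW sweeps."""

import numpy as np
import pytest
import scipy.linalg

from genmod import (
    ConfigurationError,
    ParameterRanges,
    build_jacobian,
    fixture,
    leading_eigenvalue,
    proportion_stable_sweep,
    sample_ensemble,
    stability_correlation,
    stability_indicator,
)
from genmod.errors import NumericError


class TestLeadingEigenvalue:
    def test_one_d_closed_form(self):
        # lambda = alpha (g_x - l_x) with alpha=1, g=0.5, l=2
        assert leading_eigenvalue(np.array([[0.5 - 2.0]])) == -1.5

    def test_rotation_matrix_tie_broken_to_positive_imaginary(self):
        lam = leading_eigenvalue(np.array([[0.0, -1.0], [1.0, 0.0]]))
        assert lam == pytest.approx(1j)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(5, 5))
            lam = leading_eigenvalue(a)
            oracle = max(scipy.linalg.eigvals(a), key=lambda z: z.real)
            assert lam.real == pytest.approx(oracle.real, abs=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(NumericError):
            leading_eigenvalue(np.ones((2, 3)))
        with pytest.raises(NumericError):
            leading_eigenvalue(np.array([[np.nan]]))


class TestStabilityIndicator:
    @pytest.mark.parametrize(
        "lam, expected",
        [(-1.5 + 0j, 1), (0.3 + 2j, 0), (0j, 0), (1e-300 + 5j, 0)],
    )
    def test_strict_negative_real_part(self, lam, expected):
        # the boundary Re = 0 counts as unstable (strict inequality)
        assert stability_indicator(lam) == expected


class TestEnsemble:
    def test_determinism_bitwise(self, one_d_jac):
        r = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})
        a = sample_ensemble(one_d_jac, r, 500, seed=42)
        b = sample_ensemble(one_d_jac, r, 500, seed=42)
        assert (a.samples.values == b.samples.values).all()
        assert (a.lead == b.lead).all()
        assert (a.stable == b.stable).all()

    def test_point_mass_single_sample(self, one_d_jac):
        r = ParameterRanges({"g_x": (0.5, 0.5), "l_x": (2.0, 2.0)})
        ens = sample_ensemble(one_d_jac, r, 1, seed=0)
        assert ens.lead[0] == -1.5 and ens.stable[0] == 1

    def test_classification_agrees_with_closed_form_condition(self, one_d_jac):
        # 1-D stability law: stable iff g_x < l_x, on every sample exactly.
        r = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})
        ens = sample_ensemble(one_d_jac, r, 5000, seed=5)
        expected = (ens.samples["g_x"] < ens.samples["l_x"]).astype(int)
        assert (ens.stable == expected.to_numpy()).all()

    def test_stable_fraction_matches_analytic_probability(self, one_d_jac):
        # g ~ U(0,1), l ~ U(0,2): P(g < l) = 3/4 (brute-force integral).
        r = ParameterRanges({"g_x": (0, 1), "l_x": (0, 2)})
        m = 40_000
        ens = sample_ensemble(one_d_jac, r, m, seed=11)
        se = np.sqrt(0.75 * 0.25 / m)
        assert abs(ens.psw - 0.75) < 3 * se

    def test_uncovered_symbol_rejected(self, one_d_jac):
        with pytest.raises(ConfigurationError):
            sample_ensemble(one_d_jac, ParameterRanges({"g_x": (0, 2)}), 10, seed=0)

    def test_branching_weights_on_simplex(self, predator_prey_jac):
        r = ParameterRanges(
            {n: (0, 2) for n in ("s_x", "f_x", "f_y", "l_x", "g_x", "g_y", "m_y")}
        ) .with_overrides(alpha_y=(0.1, 10))
        ens = sample_ensemble(predator_prey_jac, r, 2000, seed=9)
        rho = ens.samples["sigma_f"].to_numpy()
        assert ((rho > 0) & (rho < 1)).all()


class TestStabilityCorrelation:
    def test_perfect_stabilizer_and_destabilizer(self, one_d_jac):
        r = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})
        ens = sample_ensemble(one_d_jac, r, 2000, seed=1)
        doctored = ens.samples.copy()
        doctored["g_x"] = ens.stable.astype(float)
        doctored["l_x"] = 1.0 - ens.stable.astype(float)
        from genmod.sampling import EnsembleResult

        rigged = EnsembleResult(doctored, ens.lead, ens.stable, ens.seed)
        corr = stability_correlation(rigged)
        assert corr["g_x"] == pytest.approx(1.0)
        assert corr["l_x"] == pytest.approx(-1.0)

    def test_threshold_rule_gives_point_biserial_value(self):
        # s = 1{p < 1/2}, p ~ U(0,1): corr(p, s) -> -sqrt(3)/2 ~ -0.866.
        from genmod.sampling import EnsembleResult
        import pandas as pd

        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100_000)
        s = (p < 0.5).astype(int)
        ens = EnsembleResult(pd.DataFrame({"p": p}), np.zeros(len(p), complex), s, 4)
        corr = stability_correlation(ens)["p"]
        assert corr == pytest.approx(-np.sqrt(3) / 2, abs=0.01)

    def test_constant_indicator_yields_nan_with_warning(self, one_d_jac):
        r = ParameterRanges({"g_x": (0.1, 0.2), "l_x": (1.5, 2.0)})  # always stable
        ens = sample_ensemble(one_d_jac, r, 100, seed=2)
        with pytest.warns(UserWarning):
            corr = stability_correlation(ens)
        assert corr.isna().all()

    def test_raw_covariance_option(self, one_d_jac):
        r = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})
        ens = sample_ensemble(one_d_jac, r, 2000, seed=1)
        cov = stability_correlation(ens, normalized=False)
        corr = stability_correlation(ens)
        # same signs, different scale
        assert np.sign(cov["l_x"]) == np.sign(corr["l_x"]) == 1

    def test_correlations_bounded(self, predator_prey_jac):
        r = ParameterRanges(
            {n: (0, 2) for n in ("s_x", "f_x", "f_y", "l_x", "g_x", "g_y", "m_y")}
        ).with_overrides(alpha_y=(0.1, 10))
        ens = sample_ensemble(predator_prey_jac, r, 3000, seed=13)
        corr = stability_correlation(ens).dropna()
        assert ((corr >= -1) & (corr <= 1)).all()


class TestSweep:
    def test_one_d_psw_tracks_analytic_line(self, one_d_jac):
        # g ~ U(0,2) clamped l: PSW = P(g < l) = l/2.
        r = ParameterRanges({"g_x": (0, 2)})
        grid = [0.5, 1.0, 1.5, 2.0]
        sw = proportion_stable_sweep(one_d_jac, r, {"l_x": grid}, 5000, seed=3)
        for _, row in sw.table.iterrows():
            expected = row["l_x"] / 2
            se = np.sqrt(max(expected * (1 - expected), 1e-4) / 5000)
            assert abs(row["psw"] - expected) <= 4 * se

    def test_unknown_swept_parameter_rejected(self, one_d_jac):
        r = ParameterRanges({"g_x": (0, 2), "l_x": (0, 2)})
        with pytest.raises(ConfigurationError):
            proportion_stable_sweep(one_d_jac, r, {"zz": [1.0]}, 10, seed=0)

    def test_two_parameter_sweep_bounded_and_consistent(self, predator_prey_jac):
        r = ParameterRanges(
            {n: (0, 2) for n in ("s_x", "f_x", "f_y", "l_x", "g_x", "g_y", "m_y")}
        )
        sw = proportion_stable_sweep(
            predator_prey_jac, r,
            {"alpha_y": [0.2, 1.0, 5.0], "sigma_f": [0.2, 0.8]},
            800, seed=6,
        )
        assert len(sw.table) == 6
        assert ((sw.table["psw"] >= 0) & (sw.table["psw"] <= 1)).all()
        # a sweep cell equals an independent clamped ensemble up to MC error
        cell = sw.table.iloc[0]
        ens = sample_ensemble(
            predator_prey_jac, r, 800, seed=99,
            _clamp={"alpha_y": cell["alpha_y"], "sigma_f": cell["sigma_f"]},
        )
        assert abs(ens.psw - cell["psw"]) < 4 * np.sqrt(0.25 / 800) * 2
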