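import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import approx_fprime

from twinpath import (
    ContractError,
    MeansParameters,
    ModelFamily,
    ModelSpec,
    PathParameters,
    ValidationError,
    expected_covariance,
    fit_model,
    fit_saturated,
    minus2_loglik,
    simulate_twin_dataset,
    standardize,
)
from twinpath.model import FittedModel, PairStats, _Packing, _objective, canonicalize
from conftest import (
    make_dataset,
    random_ip_params,
    univariate_config,
    univariate_params,
)
from twinpath.simulate import SimulationConfig, diastolic_like_config


def dense_minus2_loglik(params, spec, dataset):
    """Independent oracle: per-pair Gaussian -2 log-likelihood via explicit
    matrix inversion and determinant."""
    y, ages, sexes, zyg = dataset.arrays(spec.traits)
    p = spec.n_traits
    total = 0.0
    for k in range(dataset.n_pairs):
        sigma = expected_covariance(params, spec, zyg[k])
        mu = np.concatenate(
            [
                params.means.intercept
                + params.means.beta_age * ages[k, t]
                + params.means.beta_sex * sexes[k, t]
                for t in (0, 1)
            ]
        )
        r = np.concatenate([y[k, 0], y[k, 1]]) - mu
        sign, logdet = np.linalg.slogdet(sigma)
        assert sign > 0
        total += 2 * p * math.log(2 * math.pi) + logdet + r @ np.linalg.inv(sigma) @ r
    return total


class TestExpectedCovariance:
    def test_e_only_has_no_familial_sharing(self):
        spec = ModelSpec.univariate("y", sources=("E",))
        params = univariate_params(e=1.0, sources=("E",))
        for z in ("MZ", "DZ"):
            np.testing.assert_allclose(expected_covariance(params, spec, z), np.eye(2))

    def test_unit_ace_paths(self):
        spec = ModelSpec.univariate("y")
        params = univariate_params(a=1.0, c=1.0, e=1.0)
        np.testing.assert_allclose(
            expected_covariance(params, spec, "MZ"), [[3, 2], [2, 3]]
        )
        np.testing.assert_allclose(
            expected_covariance(params, spec, "DZ"), [[3, 1.5], [1.5, 3]]
        )

    def test_dominance_quarter_coefficient(self):
        spec = ModelSpec.univariate("y", sources=("A", "D", "E"))
        params = univariate_params(a=0.0, d=2.0, e=1.0, sources=("A", "D", "E"))
        np.testing.assert_allclose(
            expected_covariance(params, spec, "DZ"), [[5, 1.0], [1.0, 5]]
        )

    def test_psd_and_loewner_order_on_random_parameters(self):
        rng = np.random.default_rng(123)
        spec = ModelSpec.independent_pathway(("a", "b", "c", "d"))
        for _ in range(50):
            params = random_ip_params(rng, 4)
            mz = expected_covariance(params, spec, "MZ")
            dz = expected_covariance(params, spec, "DZ")
            for m in (mz, dz):
                np.testing.assert_allclose(m, m.T)
                assert np.linalg.eigvalsh(m).min() >= -1e-10
            # without D, MZ cross-twin sharing dominates DZ (Loewner order)
            p = 4
            diff = mz[:p, p:] - dz[:p, p:]
            assert np.linalg.eigvalsh(diff).min() >= -1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        paths=st.lists(
            st.floats(-2.0, 2.0, allow_nan=False), min_size=18, max_size=18
        )
    )
    def test_psd_for_any_real_paths(self, paths):
        # squared-path parameterization guarantees PSD for arbitrary reals
        vals = np.array(paths).reshape(6, 3)
        params = PathParameters(
            loadings={S: vals[i] for i, S in enumerate("ACE")},
            specifics={S: vals[i + 3] for i, S in enumerate("ACE")},
            means=MeansParameters(np.zeros(3), np.zeros(3), np.zeros(3)),
        )
        spec = ModelSpec.independent_pathway(("a", "b", "c"))
        for z in ("MZ", "DZ"):
            m = expected_covariance(params, spec, z)
            assert np.linalg.eigvalsh(m).min() >= -1e-10

    def test_ip_cross_twin_block_is_common_plus_specific_structure(self):
        spec = ModelSpec.independent_pathway(("a", "b", "c"), sources=("A", "E"))
        lam = np.array([1.0, 0.5, 0.5])
        params = PathParameters(
            loadings={"A": lam, "E": np.zeros(3)},
            specifics={"A": np.zeros(3), "E": np.ones(3)},
            means=MeansParameters(np.zeros(3), np.zeros(3), np.zeros(3)),
        )
        mz = expected_covariance(params, spec, "MZ")
        np.testing.assert_allclose(mz[:3, 3:], np.outer(lam, lam))

    def test_shape_mismatch_is_contract_error(self):
        spec = ModelSpec.independent_pathway(("a", "b", "c"))
        params = univariate_params()
        with pytest.raises(ContractError):
            expected_covariance(params, spec, "MZ")


class TestSpecValidation:
    def test_c_and_d_jointly_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec.univariate("y", sources=("A", "C", "D", "E"))

    def test_e_always_required(self):
        with pytest.raises(ValidationError):
            ModelSpec.univariate("y", sources=("A", "C"))

    def test_common_factor_needs_three_traits(self):
        with pytest.raises(ValidationError):
            ModelSpec.independent_pathway(("a", "b"))

    def test_json_round_trip(self):
        spec = ModelSpec.independent_pathway(("a", "b", "c")).drop_common("C")
        spec = spec.drop_specific("A", 1)
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_nesting(self):
        full = ModelSpec.independent_pathway(("a", "b", "c"))
        sub = full.drop_common("C").drop_specific("E", 0)
        assert sub.is_nested_in(full)
        assert not full.is_nested_in(sub)
        assert full.is_nested_in(ModelSpec.saturated(("a", "b", "c")))


class TestLikelihood:
    def test_single_standard_normal_pair(self):
        ds = make_dataset(
            "pair_id,zygosity,age_1,age_2,sex_1,sex_2,y_1,y_2\np,MZ,0,0,0,0,0,0"
        )
        spec = ModelSpec.univariate("y", sources=("E",), adjust_age=False, adjust_sex=False)
        params = univariate_params(e=1.0, sources=("E",))
        assert minus2_loglik(params, spec, ds) == pytest.approx(
            2 * math.log(2 * math.pi), rel=1e-12
        )

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        config = SimulationConfig(
            n_mz=10, n_dz=10, trait_names=("u", "v"),
            params=random_ip_params(rng, 2, with_means=True), seed=11,
        )
        ds = simulate_twin_dataset(config)
        # two traits: specifics only (a common factor needs >= 3 traits)
        spec = ModelSpec(
            family=ModelFamily.INDEPENDENT_PATHWAY,
            traits=("u", "v"),
            sources=("A", "C", "E"),
            common_free={},
            specific_free={S: (True, True) for S in "ACE"},
        )
        for _ in range(3):
            params = random_ip_params(rng, 2, with_means=True)
            got = minus2_loglik(params, spec, ds)
            want = dense_minus2_loglik(params, spec, ds)
            assert got == pytest.approx(want, rel=1e-8)

    def test_invariant_to_pair_order_and_twin_swap(self):
        config = univariate_config(0.4, 0.2, 0.4, n_mz=15, n_dz=15, seed=2)
        ds = simulate_twin_dataset(config)
        spec = ModelSpec.univariate("y")
        params = univariate_params(a=0.6, c=0.4, e=0.7, intercept=0.1,
                                   beta_age=0.01, beta_sex=0.2)
        base = minus2_loglik(params, spec, ds)
        shuffled = ds.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert minus2_loglik(params, spec, type(ds)(shuffled, ds.trait_names)) == base
        swapped = ds.table.copy()
        swapped[["y_1", "y_2"]] = swapped[["y_2", "y_1"]].to_numpy()
        assert minus2_loglik(params, spec, type(ds)(swapped, ds.trait_names)) == base

    def test_gradient_matches_finite_differences(self):
        config = diastolic_like_config(n_mz=60, n_dz=50, seed=4)
        ds = simulate_twin_dataset(config)
        spec = ModelSpec.independent_pathway(config.trait_names)
        stats = PairStats(ds, spec.traits)
        pk = _Packing(spec, stats.age_center, stats.sex_center)
        rng = np.random.default_rng(0)
        for _ in range(3):
            x = rng.normal(0.4, 0.2, pk.n_free)
            _, grad = _objective(x, pk, stats)
            numeric = approx_fprime(x, lambda z: _objective(z, pk, stats)[0], 1e-6)
            np.testing.assert_allclose(grad, numeric, rtol=2e-3, atol=2e-3)


class TestFitting:
    def test_fit_is_deterministic(self):
        config = univariate_config(0.5, 0.2, 0.3, n_mz=120, n_dz=100, seed=6)
        ds = simulate_twin_dataset(config)
        spec = ModelSpec.univariate("y")
        a = fit_model(ds, spec, seed=3)
        b = fit_model(ds, spec, seed=3)
        assert a.minus2ll == b.minus2ll
        np.testing.assert_array_equal(a.params.specifics["A"], b.params.specifics["A"])

    def test_aic_identity_and_sign_convention(self):
        config = diastolic_like_config(n_mz=150, n_dz=120, seed=8)
        ds = simulate_twin_dataset(config)
        fitted = fit_model(ds, ModelSpec.independent_pathway(config.trait_names), seed=1)
        assert fitted.aic == pytest.approx(fitted.minus2ll + 2 * fitted.n_free_params)
        for S in ("A", "C", "E"):
            assert fitted.params.loadings[S][0] >= 0
            assert (fitted.params.specifics[S] >= 0).all()

    def test_saturated_matches_closed_form_gaussian_mle(self):
        config = SimulationConfig(
            n_mz=12, n_dz=11, trait_names=("u", "v"),
            params=random_ip_params(np.random.default_rng(3), 2, with_means=True),
            seed=21,
        )
        ds = simulate_twin_dataset(config)
        fitted = fit_saturated(ds, ("u", "v"), adjust_age=False, adjust_sex=False)
        y, _, _, zyg = ds.arrays()
        expected = 0.0
        for group in ("MZ", "DZ"):
            Y = np.concatenate([y[zyg == group, 0], y[zyg == group, 1]], axis=1)
            n, d = Y.shape
            resid = Y - Y.mean(axis=0)
            S = resid.T @ resid / n
            expected += n * (d * math.log(2 * math.pi) + np.linalg.slogdet(S)[1] + d)
            np.testing.assert_allclose(
                fitted.params.mean_by_zygosity[group], Y.mean(axis=0), atol=1e-8
            )
        assert fitted.minus2ll == pytest.approx(expected, rel=1e-6)

    def test_saturated_is_likelihood_ceiling(self):
        config = diastolic_like_config(n_mz=120, n_dz=100, seed=13)
        ds = simulate_twin_dataset(config)
        sat = fit_saturated(ds, config.trait_names)
        structured = fit_model(ds, ModelSpec.independent_pathway(config.trait_names), seed=2)
        assert sat.minus2ll <= structured.minus2ll + 1e-6

    def test_saturated_equal_groups_give_equal_covariances(self):
        config = univariate_config(0.5, 0.2, 0.3, n_mz=25, n_dz=0, seed=30)
        mz = simulate_twin_dataset(config).table
        dz = mz.copy()
        dz["zygosity"] = "DZ"
        dz["pair_id"] = [f"d{k}" for k in range(len(dz))]
        import pandas as pd

        from twinpath import TwinDataset

        both = TwinDataset(pd.concat([mz, dz], ignore_index=True), ("y",))
        fitted = fit_saturated(both, ("y",), adjust_age=False, adjust_sex=False)
        np.testing.assert_allclose(
            fitted.params.covariance_by_zygosity["MZ"],
            fitted.params.covariance_by_zygosity["DZ"],
            rtol=1e-8,
        )


class TestStandardize:
    def test_equal_paths_split_evenly(self):
        spec = ModelSpec.univariate("y", sources=("A", "E"))
        params = univariate_params(a=1.0, e=1.0, sources=("A", "E"))
        fitted = FittedModel(spec, params, 0.0, 5, 10.0, True)
        dec = standardize(fitted)
        assert dec.overall("A")[0] == pytest.approx(0.5)
        assert dec.overall("E")[0] == pytest.approx(0.5)

    def test_shares_sum_to_one_on_random_draws(self):
        rng = np.random.default_rng(99)
        spec = ModelSpec.independent_pathway(("a", "b", "c", "d"))
        for _ in range(200):
            params = random_ip_params(rng, 4)
            fitted = FittedModel(spec, params, 0.0, spec.n_free_params, 0.0, True)
            dec = standardize(fitted)
            np.testing.assert_allclose(dec.share_sum(), 1.0, atol=1e-9)
            for S in dec.sources:
                assert (dec.common[S] >= 0).all() and (dec.specific[S] >= 0).all()

    def test_zero_variance_trait_errors(self):
        spec = ModelSpec.univariate("y")
        params = univariate_params(a=0.0, c=0.0, e=0.0)
        fitted = FittedModel(spec, params, 0.0, 5, 10.0, True)
        with pytest.raises(Exception, match="y"):
            standardize(fitted)
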