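"""Node-wise fitting, the bias-corrected covariance, and the partial
correlation estimator (including prior incorporation)."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from pcgii import (
    PartialCorrelationEstimator,
    PriorEdgeSet,
    bias_corrected_covariance,
    default_penalty,
    estimate_partial_correlations,
    fit_all_nodewise,
)
from pcgii.ggm import precision_model_from_omega
from pcgii.nodewise import NodewiseFit
from pcgii.simulate import generate_block_sigma, sample_expression


class TestDefaultPenalty:
    def test_closed_form(self):
        assert default_penalty(math.e, 4) == pytest.approx(1.0)
        assert default_penalty(100, 80) == pytest.approx(
            2.0 * math.sqrt(math.log(100) / 80)
        )

    def test_scaling_law(self):
        assert default_penalty(50, 200) == pytest.approx(
            default_penalty(50, 100) / math.sqrt(2)
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            default_penalty(0, 10)
        with pytest.raises(ValueError):
            default_penalty(10, 0)


def test_empty_prior_gives_identical_coefficient_matrices(rng):
    Y = rng.standard_normal((40, 6))
    fit = fit_all_nodewise(Y)
    assert np.array_equal(fit.alpha_full, fit.alpha_info)
    assert np.all(np.diag(fit.alpha_full) == -1.0)


def test_residuals_match_their_definition(rng):
    Y = rng.standard_normal((30, 5)) * 2.0 + 1.0
    for standardize in (False, True):
        fit = fit_all_nodewise(Y, standardize=standardize)
        Z = Y / fit.scale if standardize else Y
        for j in range(5):
            others = [k for k in range(5) if k != j]
            pred = fit.intercepts_full[j] + Z[:, others] @ fit.alpha_full[j, others]
            assert np.allclose(fit.residuals_full[:, j], Z[:, j] - pred, atol=1e-10)


def test_prior_edge_coefficient_closer_to_restricted_ols(rng):
    """Unpenalized prior coefficients should sit nearer the no-penalty fit
    than the shrunk lasso coefficients do."""
    omega = np.array(
        [[1.0, 0.45, 0.0, 0.0],
         [0.45, 1.0, 0.0, 0.0],
         [0.0, 0.0, 1.0, 0.0],
         [0.0, 0.0, 0.0, 1.0]]
    )
    model = precision_model_from_omega(omega)
    Y = sample_expression(model, 120, rng=np.random.default_rng(7)).values
    lam = 0.5
    fit = fit_all_nodewise(Y, prior=[(0, 1)], lam=lam)
    fit0 = fit_all_nodewise(Y, lam=0.0)  # unpenalized oracle
    target = fit0.alpha_full[0, 1]
    assert abs(fit.alpha_info[0, 1] - target) < abs(fit.alpha_full[0, 1] - target)


def test_bias_corrected_covariance_hand_oracle():
    """n=4, p=3 with fixed residuals/coefficients: direct arithmetic over
    the three terms of the de-biasing formula."""
    xi = np.array(
        [[0.5, -0.2, 0.1],
         [-0.3, 0.4, 0.0],
         [0.1, 0.1, -0.2],
         [-0.3, -0.3, 0.1]]
    )
    A = np.array(
        [[-1.0, 0.3, 0.0],
         [0.2, -1.0, -0.4],
         [0.0, 0.1, -1.0]]
    )
    fit = NodewiseFit(
        alpha_full=A, alpha_info=A,
        intercepts_full=np.zeros(3), intercepts_info=np.zeros(3),
        residuals_full=xi, lambda_used=np.zeros(3), prior=PriorEdgeSet.empty(),
    )
    v = bias_corrected_covariance(fit)
    n = 4
    for j1 in range(3):
        for j2 in range(3):
            expected = -np.mean(
                xi[:, j1] * xi[:, j2]
                + A[j1, j2] * xi[:, j2] ** 2
                + A[j2, j1] * xi[:, j1] ** 2
            )
            assert v[j1, j2] == pytest.approx(expected, abs=1e-14)
    # diagonal collapses to the residual sample variance, exactly
    assert np.array_equal(np.diag(v), (xi**2).sum(axis=0) / n)
    assert np.array_equal(v, v.T)


def test_zero_cross_coefficients_reduce_to_residual_cross_moment(rng):
    xi = rng.standard_normal((20, 2))
    A = -np.eye(2)
    fit = NodewiseFit(
        alpha_full=A, alpha_info=A,
        intercepts_full=np.zeros(2), intercepts_info=np.zeros(2),
        residuals_full=xi, lambda_used=np.zeros(2), prior=PriorEdgeSet.empty(),
    )
    v = bias_corrected_covariance(fit)
    assert v[0, 1] == pytest.approx(-np.mean(xi[:, 0] * xi[:, 1]), abs=1e-14)


def test_estimator_is_consistent_on_block_model():
    model = generate_block_sigma(10, 5, np.random.default_rng(3))
    Y = sample_expression(model, 2000, rng=np.random.default_rng(4)).values
    est = estimate_partial_correlations(Y)
    err = np.abs(est.rho_hat - model.rho)
    np.fill_diagonal(err, 0.0)
    assert err.max() < 0.1


def test_rmse_decreases_when_n_doubles():
    """Over seeded replicates at p=10, doubling n shrinks the estimation
    error of the partial correlations."""
    model = generate_block_sigma(10, 5, np.random.default_rng(3))
    off = ~np.eye(10, dtype=bool)

    def rmse(n, n_reps=50):
        errs = []
        for rep in range(n_reps):
            Y = sample_expression(model, n, rng=np.random.default_rng([rep, n])).values
            est = estimate_partial_correlations(Y)
            errs.append(np.sqrt(np.mean((est.rho_hat - model.rho)[off] ** 2)))
        return np.mean(errs)

    assert rmse(2000) < rmse(1000)


def test_duplicating_samples_leaves_estimate_unchanged(rng):
    Y = rng.standard_normal((25, 6))
    lam = 0.3
    a = estimate_partial_correlations(Y, lam=lam)
    b = estimate_partial_correlations(np.vstack([Y, Y]), lam=lam)
    assert np.allclose(a.rho_hat, b.rho_hat, atol=1e-12)


def test_independent_genes_have_small_partial_correlations():
    model = precision_model_from_omega(np.eye(10))
    Y = sample_expression(model, 500, rng=np.random.default_rng(5)).values
    est = estimate_partial_correlations(Y)
    off = np.abs(est.rho_hat[~np.eye(10, dtype=bool)])
    assert off.mean() < 0.1


def test_empty_prior_bit_identical_to_no_prior(rng):
    Y = rng.standard_normal((50, 8))
    a = estimate_partial_correlations(Y, prior=None)
    b = estimate_partial_correlations(Y, prior=PriorEdgeSet.empty())
    c = estimate_partial_correlations(Y, prior=[])
    assert np.array_equal(a.rho_hat, b.rho_hat)
    assert np.array_equal(a.rho_hat, c.rho_hat)
    assert not a.used_prior and not b.used_prior


def test_constant_gene_flagged_and_zeroed(rng):
    Y = rng.standard_normal((40, 4))
    Y[:, 1] = 7.0
    est = estimate_partial_correlations(Y)
    assert est.degenerate[1]
    assert np.all(est.rho_hat[1, [0, 2, 3]] == 0.0)
    assert np.all(est.rho_hat[[0, 2, 3], 1] == 0.0)


def test_too_few_genes_rejected(rng):
    with pytest.raises(ValueError):
        fit_all_nodewise(rng.standard_normal((20, 1)))


def test_sklearn_estimator_contract(rng):
    Y = rng.standard_normal((40, 6))
    est = PartialCorrelationEstimator(lam=0.3, prior=[(0, 1)])
    cloned = clone(est)
    assert cloned.get_params()["lam"] == 0.3
    est.fit(Y)
    assert est.rho_.shape == (6, 6)
    assert est.n_features_in_ == 6
    assert est.statistics_.shape == (6, 6)
    est.set_params(lam="auto")
    assert est.get_params()["lam"] == "auto"
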