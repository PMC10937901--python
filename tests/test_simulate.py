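"""The simulation engine: network structures, sampling, priors."""

import numpy as np
import pytest

from pcgii.ggm import validate_spd
from pcgii.prior import PriorEdgeSet
from pcgii.simulate import (
    PriorSpec,
    SimulationConfig,
    finalize_precision,
    generate_block_sigma,
    generate_model,
    generate_prior_set,
    generate_random_precision,
    generate_scalefree_precision,
    sample_expression,
)


class TestBlockStructure:
    def test_edge_count_and_block_zeros(self):
        model = generate_block_sigma(8, 4, np.random.default_rng(0))
        assert len(model.support) == 2 * (4 * 3 // 2)
        # inversion of the full covariance keeps cross-block zeros
        omega = np.linalg.inv(model.sigma)
        assert np.abs(omega[:4, 4:]).max() < 1e-10
        model.validate()

    @pytest.mark.parametrize("seed", range(5))
    def test_always_spd(self, seed):
        model = generate_block_sigma(12, 4, np.random.default_rng(seed))
        validate_spd(model.omega)
        validate_spd(model.sigma)

    def test_indivisible_block_size_rejected(self):
        with pytest.raises(ValueError):
            generate_block_sigma(10, 4, np.random.default_rng(0))


class TestRandomStructure:
    def test_eta_zero_gives_diagonal(self):
        model = generate_random_precision(20, 0.0, np.random.default_rng(1))
        assert model.support == frozenset()
        assert np.allclose(model.rho, np.eye(20))

    def test_mean_edge_count_binomial(self):
        counts = [
            len(generate_random_precision(100, 0.02, np.random.default_rng(s)).support)
            for s in range(50)
        ]
        total_pairs = 100 * 99 // 2
        expected = 0.02 * total_pairs
        sd = np.sqrt(total_pairs * 0.02 * 0.98)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(50)

    def test_spd_across_seeds(self):
        for s in range(100):
            model = generate_random_precision(30, 0.05, np.random.default_rng(s))
            validate_spd(model.omega)


class TestScaleFreeStructure:
    def test_tree_when_one_edge_per_step(self):
        model = generate_scalefree_precision(50, 1, np.random.default_rng(2))
        assert len(model.support) == 49

    def test_edge_count_formula(self):
        model = generate_scalefree_precision(100, 2, np.random.default_rng(2))
        assert len(model.support) == 2 * (100 - 2)

    def test_degree_distribution_right_skewed(self):
        ratios = []
        for s in range(20):
            model = generate_scalefree_precision(200, 1, np.random.default_rng(s))
            deg = np.zeros(200)
            for a, b in model.support:
                deg[a] += 1
                deg[b] += 1
            ratios.append(deg.max() / max(np.median(deg), 1))
        assert np.mean(ratios) > 3.0


class TestFinalizePrecision:
    def test_empty_support(self):
        model = finalize_precision(set(), 5, np.random.default_rng(0))
        assert np.allclose(model.omega, 0.1 * np.eye(5))

    def test_single_edge_diagonal_and_rho(self):
        class FixedRng:
            def uniform(self, lo, hi):
                return 0.4

            def random(self):
                return 0.9  # sign coin -> negative

        model = finalize_precision({(0, 1)}, 3, FixedRng())
        assert model.omega[0, 1] == pytest.approx(-0.4)
        assert np.allclose(np.diag(model.omega), [0.5, 0.5, 0.1])
        assert model.rho[0, 1] == pytest.approx(0.8)

    def test_gershgorin_margin(self):
        for s in range(20):
            model = generate_random_precision(40, 0.05, np.random.default_rng(s))
            assert np.linalg.eigvalsh(model.omega)[0] >= 0.1 - 1e-9

    def test_magnitudes_in_stated_band(self):
        model = generate_random_precision(50, 0.05, np.random.default_rng(3))
        off = model.omega[np.triu_indices(50, k=1)]
        nz = np.abs(off[off != 0])
        assert np.all((nz >= 0.2) & (nz <= 0.5))


class TestSampleExpression:
    def test_count_mode_nonnegative_integers(self):
        model = generate_block_sigma(8, 4, np.random.default_rng(0))
        X = sample_expression(
            model, 50, data_type="count", count_mean=10.0,
            rng=np.random.default_rng(1),
        )
        assert np.all(X.values >= 0)
        assert np.array_equal(X.values, np.rint(X.values))

    def test_sample_covariance_converges(self):
        model = generate_block_sigma(5, 5, np.random.default_rng(4))
        X = sample_expression(model, 5000, rng=np.random.default_rng(5))
        S = np.cov(X.values, rowvar=False, bias=True)
        assert np.abs(S - model.sigma).max() < 0.1

    def test_seed_reproducibility(self):
        model = generate_block_sigma(6, 3, np.random.default_rng(0))
        a = sample_expression(model, 20, rng=np.random.default_rng(9)).values
        b = sample_expression(model, 20, rng=np.random.default_rng(9)).values
        assert np.array_equal(a, b)


class TestPriorSet:
    truth = [(i, i + 1) for i in range(40)]  # m1 = 40 over p = 41

    def test_accurate_prior_counts(self):
        prior = generate_prior_set(
            self.truth, PriorSpec(pis=0.3, pa=1.0), 41, np.random.default_rng(0)
        )
        assert len(prior) == 12
        assert all(e in set(self.truth) for e in prior)

    def test_inaccurate_prior_counts(self):
        prior = generate_prior_set(
            self.truth, PriorSpec(pis=0.3, pa=0.5), 41, np.random.default_rng(0)
        )
        true_edges = [e for e in prior if e in set(self.truth)]
        assert len(prior) == 24
        assert len(true_edges) == 12

    def test_zero_pis_gives_empty_prior(self):
        prior = generate_prior_set(
            self.truth, PriorSpec(pis=0.0, pa=1.0), 41, np.random.default_rng(0)
        )
        assert len(prior) == 0

    def test_impossible_false_count_rejected(self):
        truth = [(0, 1), (0, 2), (1, 2)]  # complete graph on 3 of 3 nodes
        with pytest.raises(ValueError):
            generate_prior_set(
                truth, PriorSpec(pis=1.0, pa=0.1), 3, np.random.default_rng(0)
            )


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(structure="block", p=10, k=4)
        with pytest.raises(ValueError):
            SimulationConfig(structure="nope")
        with pytest.raises(ValueError):
            SimulationConfig(data_type="poisson")

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(structure="random", p=30, n=20, eta=0.05, seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    def test_model_fixed_given_seed(self):
        cfg = SimulationConfig(structure="scalefree", p=30, e=1, seed=5)
        m1 = generate_model(cfg, np.random.default_rng([5, 2**20]))
        m2 = generate_model(cfg, np.random.default_rng([5, 2**20]))
        assert np.array_equal(m1.omega, m2.omega)


def test_every_model_passes_validation_and_rho_in_range():
    for maker in (
        lambda r: generate_block_sigma(12, 4, r),
        lambda r: generate_random_precision(20, 0.08, r),
        lambda r: generate_scalefree_precision(20, 2, r),
    ):
        model = maker(np.random.default_rng(11))
        model.validate()
        off = model.rho[~np.eye(model.p, dtype=bool)]
        assert np.all(np.abs(off) < 1.0)


def test_prior_edge_set_basics():
    s = PriorEdgeSet([(3, 1), (1, 3), (0, 2)], p=5)
    assert len(s) == 2
    assert (1, 3) in s and (3, 1) in s
    assert s.neighbors(3) == {1}
    mask = s.mask(5)
    assert mask[1, 3] and mask[3, 1] and mask[0, 2]
    with pytest.raises(ValueError):
        PriorEdgeSet([(2, 2)])
    with pytest.raises(ValueError):
        PriorEdgeSet([(0, 9)], p=5)
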