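"""Weight-matrix generation: prescribed density, balance, symmetry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnndyn import weights
from rnndyn.weights import (WeightConfig, GenerationError, connection_counts,
                            desymmetrize_by_swaps, generate_weight_matrix,
                            measure_balance, measure_density,
                            measure_symmetry, sample_magnitudes)


class TestSampleMagnitudes:
    def test_zero_scale_degenerates_to_exp_loc(self, rng):
        vals = sample_magnitudes(5, loc=0.0, scale=0.0, rng=rng)
        assert np.all(vals == 1.0)

    def test_median_matches_lognormal_closed_form(self, rng):
        vals = sample_magnitudes(100_000, loc=0.0, scale=1.0, rng=rng)
        assert np.all(vals > 0)
        assert abs(np.median(vals) - 1.0) < 0.02

    def test_empty_and_invalid_arguments(self, rng):
        assert sample_magnitudes(0, 0.0, 1.0, rng).size == 0
        with pytest.raises(ValueError):
            sample_magnitudes(-1, 0.0, 1.0, rng)
        with pytest.raises(ValueError):
            sample_magnitudes(5, 0.0, -0.1, rng)

    def test_log_values_are_normal(self, rng):
        vals = sample_magnitudes(50_000, loc=0.5, scale=2.0, rng=rng)
        logs = np.log(vals)
        assert abs(logs.mean() - 0.5) < 0.05
        assert abs(logs.std() - 2.0) < 0.05


class TestMeasures:
    def test_density_counts_offdiagonal_support(self):
        W = np.zeros((3, 3))
        assert measure_density(W) == 0.0
        W[0, 1] = 1.0
        W[1, 2] = -2.0
        W[2, 0] = 0.5
        assert measure_density(W) == pytest.approx(0.5)
        W = np.ones((4, 4)) - np.eye(4)
        assert measure_density(W) == 1.0

    def test_balance_signed_count_excess(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[0, 2] = W[1, 2] = 1.0
        W[3, 0] = -1.0
        assert measure_balance(W) == pytest.approx(0.5)
        assert measure_balance(np.abs(W)) == 1.0
        assert measure_balance(-np.abs(W)) == -1.0

    def test_symmetry_requires_exact_mirror_equality(self):
        W = np.zeros((3, 3))
        a, b = 1.7, -0.3
        W[0, 1] = W[1, 0] = a
        W[0, 2] = b
        assert measure_symmetry(W) == pytest.approx(2 / 3)
        # strictly upper-triangular support has no reverse partners
        U = np.triu(np.ones((4, 4)), k=1)
        assert measure_symmetry(U) == 0.0

    def test_undefined_statistics_on_empty_matrix(self):
        W = np.zeros((3, 3))
        with pytest.raises(ValueError):
            measure_balance(W)
        with pytest.raises(ValueError):
            measure_symmetry(W)


class TestGenerate:
    def test_fully_excitatory_dense_matrix(self):
        cfg = WeightConfig(n=100, density=1.0, balance=1.0, symmetry=0.0, seed=1)
        W = generate_weight_matrix(cfg)
        assert np.all(np.diagonal(W) == 0)
        off = W[~np.eye(100, dtype=bool)]
        assert off.size == 9900 and np.all(off > 0)
        assert measure_balance(W) == 1.0

    def test_exact_counting_rules_at_half_density(self):
        cfg = WeightConfig(n=100, density=0.5, balance=0.0, symmetry=0.0, seed=2)
        W = generate_weight_matrix(cfg)
        m, m_plus, m_minus, _ = connection_counts(W)
        assert m == 4950
        assert m_plus == m_minus == 2475

    def test_fully_symmetric_inhibitory_matrix(self):
        cfg = WeightConfig(n=4, density=1.0, balance=-1.0, symmetry=1.0, seed=3)
        W = generate_weight_matrix(cfg)
        assert np.array_equal(W, W.T)
        off = W[~np.eye(4, dtype=bool)]
        assert np.all(off < 0)

    def test_same_seed_bit_identical_different_seed_differs(self):
        cfg = WeightConfig(n=50, density=0.3, balance=0.2, symmetry=0.4, seed=11)
        W1 = generate_weight_matrix(cfg)
        W2 = generate_weight_matrix(cfg)
        assert np.array_equal(W1, W2)
        W3 = generate_weight_matrix(
            WeightConfig(n=50, density=0.3, balance=0.2, symmetry=0.4, seed=12))
        assert not np.array_equal(W1, W3)

    def test_infeasible_density_raises(self):
        with pytest.raises(GenerationError):
            generate_weight_matrix(
                WeightConfig(n=10, density=0.001, balance=0.0, symmetry=0.0,
                             seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WeightConfig(n=1, density=0.5, balance=0.0, symmetry=0.0)
        with pytest.raises(ValueError):
            WeightConfig(n=10, density=1.5, balance=0.0, symmetry=0.0)
        with pytest.raises(ValueError):
            WeightConfig(n=10, density=0.5, balance=-2.0, symmetry=0.0)
        with pytest.raises(ValueError):
            WeightConfig(n=10, density=0.5, balance=0.0, symmetry=1.1)

    def test_round_trip_tolerances_over_random_configs(self):
        """100 random prescriptions land within the counting tolerances."""
        rng = np.random.default_rng(777)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            d = float(rng.uniform(0.1, 1.0))
            b = float(rng.uniform(-1.0, 1.0))
            s = float(rng.uniform(0.0, 1.0))
            cfg = WeightConfig(n=n, density=d, balance=b, symmetry=s,
                               seed=int(rng.integers(2**31)))
            W = generate_weight_matrix(cfg)
            m = connection_counts(W)[0]
            if m < 20:
                continue
            assert np.all(np.diagonal(W) == 0)
            assert abs(measure_density(W) - d) <= 1.0 / (n * (n - 1))
            assert abs(measure_balance(W) - b) <= 2.0 / m
            assert abs(measure_symmetry(W) - s) <= 4.0 / m

    def test_full_symmetry_is_bitwise_transpose_equality(self):
        cfg = WeightConfig(n=30, density=0.4, balance=0.1, symmetry=1.0, seed=5)
        W = generate_weight_matrix(cfg)
        assert np.array_equal(W, W.T)
        assert measure_symmetry(W) == 1.0


class TestDesymmetrize:
    @pytest.fixture
    def symmetric(self):
        cfg = WeightConfig(n=40, density=0.6, balance=0.0, symmetry=1.0, seed=9)
        return generate_weight_matrix(cfg)

    def test_target_one_returns_input_unchanged(self, symmetric, rng):
        out = desymmetrize_by_swaps(symmetric, 1.0, rng)
        assert np.array_equal(out, symmetric)
        assert np.array_equal(out, out.T)

    def test_target_zero_reached_within_tolerance(self, symmetric, rng):
        out = desymmetrize_by_swaps(symmetric, 0.0, rng)
        m = connection_counts(out)[0]
        assert measure_symmetry(out) <= 4.0 / m

    @pytest.mark.parametrize("s_target", [0.0, 0.25, 0.7])
    def test_swaps_preserve_value_multiset_and_counts(self, symmetric, rng,
                                                      s_target):
        before = connection_counts(symmetric)
        lower_before = np.sort(symmetric[np.tril_indices_from(symmetric, -1)])
        out = desymmetrize_by_swaps(symmetric, s_target, rng)
        m, mp, mm, _ = connection_counts(out)
        assert (m, mp, mm) == before[:3]
        lower_after = np.sort(out[np.tril_indices_from(out, -1)])
        assert np.array_equal(lower_before, lower_after)
        # upper triangle untouched
        iu = np.triu_indices_from(out, 1)
        assert np.array_equal(out[iu], symmetric[iu])

    def test_rejects_non_symmetric_input(self, rng):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        with pytest.raises(ValueError):
            desymmetrize_by_swaps(W, 0.5, rng)


class TestMatrixIO:
    def test_matrixmarket_round_trip(self, tmp_path):
        cfg = WeightConfig(n=25, density=0.3, balance=-0.4, symmetry=0.5,
                           seed=21)
        W = generate_weight_matrix(cfg)
        path = tmp_path / "net.mtx"
        weights.save_matrix(W, path, metadata={"config": cfg.to_dict()})
        W2 = weights.load_matrix(path)
        assert np.array_equal(W, W2)
        assert (tmp_path / "net.json").exists()

    def test_load_rejects_nonzero_diagonal(self, tmp_path):
        import scipy.io
        import scipy.sparse
        bad = np.eye(3)
        scipy.io.mmwrite(str(tmp_path / "bad.mtx"), scipy.sparse.coo_matrix(bad))
        with pytest.raises(ValueError):
            weights.load_matrix(tmp_path / "bad.mtx")


@given(st.integers(5, 40), st.floats(0.2, 1.0), st.floats(-1.0, 1.0),
       st.integers(0, 2**31 - 1))
def test_property_diagonal_zero_and_balance_tolerance(n, d, b, seed):
    cfg = WeightConfig(n=n, density=d, balance=b, symmetry=0.0, seed=seed)
    W = generate_weight_matrix(cfg)
    assert np.all(np.diagonal(W) == 0)
    m = connection_counts(W)[0]
    assert abs(measure_density(W) - d) <= 1.0 / (n * (n - 1))
    assert abs(measure_balance(W) - b) <= 2.0 / m
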