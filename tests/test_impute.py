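import numpy as np
import pytest

import acimpute as ac
from helpers import align_truth, count_matrix, normalized_matrix, random_transition


def powers(values, lo=1.0, hi=3.0):
    return ac.PowerMatrix(p=np.asarray(values, dtype=float), lo=lo, hi=hi)


class TestConstrainedSmooth:
    def test_exponent_one_reduces_to_plain_diffusion(self):
        tm = random_transition(10, seed=0)
        xn = normalized_matrix(np.random.default_rng(1).random((6, 10)) * 5)
        out = ac.constrained_smooth(xn, tm, powers(np.ones((6, 10))))
        assert np.allclose(out, xn.xn @ tm.m.T, atol=1e-12)

    def test_identity_chain_returns_input_for_any_exponent(self):
        n = 8
        tm = ac.TransitionMatrix(np.eye(n), 1, [0.0], [f"c{j}" for j in range(n)])
        xn = normalized_matrix(np.random.default_rng(2).random((5, n)))
        p = powers(np.random.default_rng(3).uniform(1, 3, (5, n)))
        out = ac.constrained_smooth(xn, tm, p)
        assert np.allclose(out, xn.xn, atol=1e-12)

    def test_hand_example_exponent_concentrates_weight(self):
        m = np.array([[0.75, 0.25], [0.5, 0.5]])
        tm = ac.TransitionMatrix(m, 1, [0.0], ["c0", "c1"])
        xn = normalized_matrix([[0.0, 4.0]])
        out2 = ac.constrained_smooth(xn, tm, powers([[2.0, 1.0]]))
        out1 = ac.constrained_smooth(xn, tm, powers([[1.0, 1.0]]))
        # weights for cell 0 at p=2: (0.5625, 0.0625)/0.625 = (0.9, 0.1)
        assert out2[0, 0] == pytest.approx(0.4, abs=1e-12)
        assert out1[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_entry_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        genes, cells = 25, 10
        tm = random_transition(cells, seed=5)
        xn = normalized_matrix(rng.random((genes, cells)) * 10)
        p = powers(rng.uniform(1, 3, (genes, cells)))
        got = ac.constrained_smooth(xn, tm, p)
        expected = np.zeros((genes, cells))
        for g in range(genes):
            for c in range(cells):
                w = np.array([tm.m[c, k] ** p.p[g, c] for k in range(cells)])
                w = w / w.sum()
                expected[g, c] = sum(w[k] * xn.xn[g, k] for k in range(cells))
        assert np.allclose(got, expected, atol=1e-10)

    def test_output_is_a_convex_combination_per_gene(self):
        rng = np.random.default_rng(6)
        tm = random_transition(12, seed=7)
        xn = normalized_matrix(rng.random((8, 12)) * 3)
        p = powers(rng.uniform(1, 3, (8, 12)))
        out = ac.constrained_smooth(xn, tm, p)
        lo = xn.xn.min(axis=1, keepdims=True)
        hi = xn.xn.max(axis=1, keepdims=True)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestRescaleAndDenormalize:
    def test_gene_max_mode_matches_normalized_maxima(self):
        rng = np.random.default_rng(8)
        counts = count_matrix(rng.integers(0, 20, (15, 10)))
        xn = ac.normalize(counts)
        xhat = rng.random((15, 10)) * 0.4
        out = ac.rescale_and_denormalize(xhat, xn, rescale="gene-max")
        renorm = out * xn.median_factor / xn.size_factors[None, :]
        assert np.allclose(renorm.max(axis=1), xn.xn.max(axis=1), rtol=1e-9)

    def test_none_mode_inverts_normalization_exactly(self):
        counts = count_matrix(np.random.default_rng(9).integers(0, 30, (20, 12)))
        xn = ac.normalize(counts)
        back = ac.rescale_and_denormalize(xn.xn, xn, rescale="none")
        assert np.allclose(back, counts.values, rtol=1e-9)

    def test_all_zero_gene_row_stays_zero(self):
        counts = count_matrix(np.vstack([np.zeros(16), np.ones(16) * 4, np.arange(16) + 1]))
        xn = ac.normalize(counts)
        xhat = xn.xn.copy()
        xhat[0] = 0.0
        for mode in ("gene-max", "none"):
            out = ac.rescale_and_denormalize(xhat, xn, rescale=mode)
            assert np.all(out[0] == 0.0)

    def test_unknown_mode_is_an_error(self):
        counts = count_matrix(np.ones((2, 3)))
        xn = ac.normalize(counts)
        with pytest.raises(ValueError, match="rescale"):
            ac.rescale_and_denormalize(xn.xn, xn, rescale="percentile")


class TestMergeWithObserved:
    def test_no_zeros_returns_observed_exactly(self):
        obs = count_matrix([[2.0, 1.0], [3.0, 5.0]])
        out = ac.merge_with_observed(obs, np.array([[9.0, 9.0], [9.0, 9.0]]))
        assert np.array_equal(out.final, obs.values)

    def test_all_zeros_returns_imputed(self):
        obs = count_matrix(np.zeros((2, 2)))
        xbar = np.array([[1.5, 0.5], [0.25, 4.0]])
        out = ac.merge_with_observed(obs, xbar)
        assert np.array_equal(out.final, xbar)

    def test_elementwise_mix(self):
        obs = count_matrix([[2.0, 0.0], [0.0, 5.0]])
        xbar = np.array([[1.9, 0.7], [0.3, 4.8]])
        out = ac.merge_with_observed(obs, xbar)
        assert np.array_equal(out.final, [[2.0, 0.7], [0.3, 5.0]])

    def test_shape_mismatch_is_an_error(self):
        obs = count_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="shape"):
            ac.merge_with_observed(obs, np.ones((3, 2)))


class TestRunPipeline:
    def test_deterministic_under_fixed_seed(self, small_dataset):
        a = ac.run_pipeline(small_dataset.observed, ac.ImputeConfig(seed=11))
        b = ac.run_pipeline(small_dataset.observed, ac.ImputeConfig(seed=11))
        assert np.array_equal(a.imputed.final, b.imputed.final)
        assert a.t == b.t and a.n_neighbors == b.n_neighbors

    def test_observed_nonzeros_survive_bit_exactly(self, small_result):
        obs = small_result.filtered.values
        final = small_result.imputed.final
        mask = obs != 0
        assert np.array_equal(final[mask], obs[mask])
        # and the nonzero pattern only ever grows
        assert np.all(final[mask] != 0)

    def test_report_records_data_driven_choices(self, small_result):
        rep = small_result.report()
        assert rep["t"] >= 2
        assert 1 <= rep["n_neighbors"] <= rep["n_cells_kept"] - 1
        assert rep["n_hvg"] >= 1
        assert len(rep["r2_trace"]) == rep["t"]

    def test_recovery_beats_observed_data(self, small_dataset, small_result):
        """Imputation moves cells closer to the dropout-free truth."""
        truth = align_truth(small_dataset.truth, small_result.filtered)
        final = small_result.imputed.final
        obs = small_result.filtered.values

        def median_cell_corr(mat):
            lm, lt = np.log1p(mat), np.log1p(truth)
            return np.median(
                [np.corrcoef(lm[:, c], lt[:, c])[0, 1] for c in range(mat.shape[1])]
            )

        assert median_cell_corr(final) > median_cell_corr(obs)

    def test_exponent_floor_reduces_to_plain_diffusion(self, small_dataset):
        """With the power range collapsed to [1, 1+eps] the pipeline is
        numerically indistinguishable from unconstrained diffusion."""
        cfg = ac.ImputeConfig(seed=11, power_hi=1.0 + 1e-12)
        res = ac.run_pipeline(small_dataset.observed, cfg)
        norm = res.normalized
        plain = norm.xn @ res.transition.m.T
        assert np.allclose(res.imputed.xhat, plain, atol=1e-8)
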