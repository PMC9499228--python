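"""Velocity-embedding checks against brute-force and structural oracles."""

import numpy as np
import pytest

import veloscope as v
from veloscope import diagnostics as dg
from veloscope import embedding as em
from veloscope import pipeline as pl

from oracles import brute_grid_arrows, brute_softmax_weights


class TestLinearEmbedding:
    def test_zero_velocity_zero_arrows(self):
        rng = np.random.default_rng(0)
        s = rng.poisson(5.0, size=(20, 6)).astype(float)
        _, basis = pl.compute_pca(s, n_pcs=3)
        field = em.linear_velocity_embedding(s, s, basis)
        assert np.allclose(field.cell_arrows, 0.0)

    def test_negative_extrapolation_rejected(self):
        s = np.ones((5, 3))
        _, basis = pl.compute_pca(s + np.eye(5, 3), n_pcs=2)
        bad = s.copy()
        bad[0, 0] = -0.5
        with pytest.raises(ValueError):
            em.linear_velocity_embedding(s, bad, basis)

    def test_halving_delta_t_is_not_linear_in_arrows(self):
        # log1p makes the projection nonlinear in the displacement
        rng = np.random.default_rng(1)
        s = rng.poisson(10.0, size=(6, 4)).astype(float)
        vel = rng.normal(0, 2, size=(6, 4))
        _, basis = pl.compute_pca(s, n_pcs=2)
        _, full = pl.extrapolation_time(s, vel)
        _, half = pl.extrapolation_time(s, 0.5 * vel)
        a_full = em.linear_velocity_embedding(s, full, basis).cell_arrows
        a_half = em.linear_velocity_embedding(s, half, basis).cell_arrows
        assert not np.allclose(a_half, 0.5 * a_full, rtol=1e-3)

    def test_linear_arrows_track_ground_truth_on_aba(
        self, aba_dataset, aba_pipeline
    ):
        processed, _, field = aba_pipeline
        lin = em.linear_velocity_embedding(
            processed.imputed_spliced, field.extrapolated_spliced, processed.basis
        )
        schedules = aba_dataset.gene_schedules["ABA"]
        betas = np.array([s.beta for s in schedules])
        gammas = np.array([s.gamma for s in schedules])
        mu_u, mu_s = aba_dataset.true_means()
        v_true = betas * mu_u - gammas * mu_s
        _, extrap_true = pl.extrapolation_time(processed.imputed_spliced, v_true)
        truth = em.linear_velocity_embedding(
            processed.imputed_spliced, extrap_true, processed.basis
        )
        angles = dg.angle_deviation(lin.cell_arrows, truth.cell_arrows)
        assert np.median(angles) < 90.0


class TestTransitionWeights:
    def test_uniform_for_equal_concordance(self):
        # all displacements identical: every correlation equals the same value
        d = np.tile(np.array([[1.0, -2.0, 3.0]]), (4, 1))
        delta = np.array([0.5, -1.0, 2.0])
        w = em.transition_weights(d, delta)
        assert np.allclose(w, 0.25)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.normal(size=(7, 5))
            delta = rng.normal(size=5)
            for mode in ("correlation", "boolean"):
                w = em.transition_weights(d, delta, mode=mode)
                assert w.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(w >= 0)

    def test_matches_brute_force_softmax_of_correlations(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(5, 2))
        delta = rng.normal(size=2)
        cfg = em.EmbedConfig(sigma=0.05, transform="sqrt")
        got = em.transition_weights(d, delta, cfg)
        tfm = lambda x: np.sign(x) * np.sqrt(np.abs(x))
        ref = brute_softmax_weights(d, delta, 0.05, tfm)
        assert np.allclose(got, ref, atol=1e-10)


class TestBooleanConcordance:
    def test_identical_signs(self):
        assert em.boolean_concordance([1.0, -2.0, 3.0], [0.5, -1.0, 9.0]) == 1.0

    def test_opposite_signs(self):
        assert em.boolean_concordance([1.0, -2.0], [-1.0, 2.0]) == 0.0

    def test_zero_zero_counts_as_match(self):
        r = em.boolean_concordance([0.0, 1.0, -2.0], [0.0, 3.0, 5.0])
        assert r == pytest.approx(2.0 / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            em.boolean_concordance([], [])


class TestNonlinearEmbedding:
    def test_single_neighbor_parallel_arrow(self):
        coords = np.array([[0.0, 0.0], [1.0, 2.0], [10.0, 10.0]])
        high = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        delta = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        cfg = em.EmbedConfig(k_embed_neighbors=1, density_correction=False)
        field = em.nonlinear_velocity_embedding(coords, high, delta, cfg)
        direction = field.cell_arrows[0]
        expected = coords[1] - coords[0]
        cos = direction @ expected / (
            np.linalg.norm(direction) * np.linalg.norm(expected)
        )
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_with_correction_zero_arrows(self):
        # identical high-dimensional states give constant concordance to every
        # neighbor, hence uniform weights; the density correction subtracts
        # exactly the uniform mean direction, so every arrow vanishes
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(12, 2))
        high = np.tile(rng.random(4), (12, 1))
        delta = np.ones((12, 4))
        cfg = em.EmbedConfig(k_embed_neighbors=3, density_correction=True)
        field = em.nonlinear_velocity_embedding(
            coords, high, delta, cfg, mode="boolean"
        )
        assert np.allclose(field.cell_arrows, 0.0, atol=1e-12)

    def test_zero_delta_s_gives_zero_arrow(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(8, 2))
        high = rng.normal(size=(8, 3))
        delta = rng.normal(size=(8, 3))
        delta[2] = 0.0
        field = em.nonlinear_velocity_embedding(
            coords, high, delta, em.EmbedConfig(k_embed_neighbors=3)
        )
        assert np.allclose(field.cell_arrows[2], 0.0)

    def test_false_positive_arrows_on_stationary_data(self, bursty_dataset):
        """A completely static ground truth still yields a velocity field,
        of the same magnitude as one computed from sign-randomized velocities."""
        cfg_pl = pl.PipelineConfig(do_filter=False, normalize=False, n_pcs=10)
        processed, fits, field = pl.run_pipeline(
            bursty_dataset.spliced, bursty_dataset.unspliced, cfg_pl
        )
        delta_s = field.v * field.delta_t_star
        cfg = em.EmbedConfig(k_embed_neighbors=50)
        arrows = em.nonlinear_velocity_embedding(
            processed.pc_coords[:, :2], processed.imputed_spliced, delta_s, cfg
        ).cell_arrows
        norms = np.linalg.norm(arrows, axis=1)
        assert np.median(norms) > 0  # false-positive field exists

        rng = np.random.default_rng(6)
        flipped = delta_s * rng.choice([-1.0, 1.0], size=delta_s.shape)
        arrows_flip = em.nonlinear_velocity_embedding(
            processed.pc_coords[:, :2], processed.imputed_spliced, flipped, cfg
        ).cell_arrows
        norms_flip = np.linalg.norm(arrows_flip, axis=1)
        ratio = np.median(norms) / np.median(norms_flip)
        assert 0.5 < ratio < 2.0


class TestGridAggregate:
    def test_constant_arrows_preserved(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(30, 2))
        arrows = np.tile(np.array([[0.3, -0.2]]), (30, 1))
        field = em.ArrowField(coords, arrows, "linear")
        out = em.grid_aggregate(field, em.EmbedConfig(grid_shape=(5, 5)))
        assert np.allclose(out.grid_arrows, [0.3, -0.2])

    def test_zero_in_zero_out(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(15, 2))
        field = em.ArrowField(coords, np.zeros((15, 2)), "linear")
        out = em.grid_aggregate(field, em.EmbedConfig(grid_shape=(4, 4)))
        assert np.allclose(out.grid_arrows, 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(10, 2))
        arrows = rng.normal(size=(10, 2))
        cfg = em.EmbedConfig(grid_shape=(3, 3), grid_neighbors=6, grid_smoothing=0.5)
        out = em.grid_aggregate(em.ArrowField(coords, arrows, "linear"), cfg)
        xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), 3)
        ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), 3)
        spacing = 0.5 * ((xs[1] - xs[0]) + (ys[1] - ys[0]))
        ref = brute_grid_arrows(coords, arrows, out.grid_points, 6, 0.5 * spacing)
        assert np.allclose(out.grid_arrows, ref, atol=1e-10)


@pytest.fixture(scope="module")
def aba_fields(aba_pipeline):
    processed, _, field = aba_pipeline
    delta_s = field.v * field.delta_t_star
    lin = em.linear_velocity_embedding(
        processed.imputed_spliced, field.extrapolated_spliced, processed.basis
    )
    cfg = em.EmbedConfig()
    coords2 = processed.pc_coords[:, :2]
    nonlin = em.nonlinear_velocity_embedding(
        coords2, processed.imputed_spliced, delta_s, cfg
    )
    boolean = em.nonlinear_velocity_embedding(
        coords2, processed.imputed_spliced, delta_s, cfg, mode="boolean"
    )
    return lin, nonlin, boolean


class TestEmbeddingComparisons:
    def test_boolean_close_to_correlation_mode(self, aba_fields):
        lin, nonlin, boolean = aba_fields
        ang_nl = dg.angle_deviation(lin.cell_arrows, nonlin.cell_arrows)
        ang_bo = dg.angle_deviation(lin.cell_arrows, boolean.cell_arrows)
        assert abs(np.median(ang_nl) - np.median(ang_bo)) < 15.0

    def test_nonlinear_embedding_is_biased_vs_linear(self, aba_fields):
        lin, nonlin, _ = aba_fields
        angles = dg.angle_deviation(lin.cell_arrows, nonlin.cell_arrows)
        assert np.median(angles) > 0.0


class TestPropertyInvariants:
    """Randomized invariants (hypothesis, derandomized for reproducibility)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import array_shapes, arrays

    vec = arrays(
        np.float64,
        st.integers(min_value=1, max_value=12),
        elements=st.floats(-50, 50, allow_nan=False),
    )

    @given(a=vec)
    @settings(derandomize=True, max_examples=50)
    def test_boolean_concordance_bounds_and_self_match(self, a):
        assert em.boolean_concordance(a, a) == 1.0
        other = -a
        r = em.boolean_concordance(a, other)
        assert 0.0 <= r <= 1.0

    @given(
        data=arrays(
            np.float64, (6, 4), elements=st.floats(-20, 20, allow_nan=False)
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_transition_weights_form_a_distribution(self, data):
        d, delta = data[:5], data[5]
        for mode in ("correlation", "boolean"):
            w = em.transition_weights(d, delta, mode=mode)
            assert w.shape == (5,)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
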