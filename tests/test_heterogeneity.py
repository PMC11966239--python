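"""Deformation fields: identity start, bending, similarity, clustering."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import cryofield as cf
from cryofield.forward_model import build_projection_map
from cryofield.heterogeneity import bend_forward


class TestVectorFieldModel:
    def test_fresh_model_predicts_zero_field(self, rng):
        model = cf.VectorFieldModel(16, n_field=4, seed=0)
        img = rng.normal(0, 1, (16, 16))
        assert np.array_equal(model.predict_field(img), np.zeros((3, 4, 4, 4)))

    def test_identical_images_identical_fields(self, rng):
        model = cf.VectorFieldModel(16, n_field=4, seed=0)
        # randomize the head so the output is non-trivial
        last = model.mlp.n_layers - 1
        model.mlp.params[f"W{last}"][...] = rng.normal(
            0, 0.1, model.mlp.params[f"W{last}"].shape
        )
        img = rng.normal(0, 1, (16, 16))
        assert np.array_equal(
            model.predict_field(img), model.predict_field(img.copy())
        )

    def test_shape_mismatch_rejected(self):
        model = cf.VectorFieldModel(16, n_field=4)
        with pytest.raises(ValueError):
            model.predict_field(np.zeros((8, 8)))

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = cf.VectorFieldModel(16, n_field=4, seed=2)
        last = model.mlp.n_layers - 1
        model.mlp.params[f"W{last}"][...] = rng.normal(
            0, 0.1, model.mlp.params[f"W{last}"].shape
        )
        model.field_mean = rng.normal(0, 0.1, model.field_mean.shape)
        img = rng.normal(0, 1, (16, 16))
        before = model.predict_field(img)
        path = tmp_path / "enc.npz"
        model.save(path)
        loaded = cf.VectorFieldModel.load(path)
        assert np.array_equal(loaded.predict_field(img), before)


class TestBend:
    def test_zero_field_is_identity(self, rng):
        pts = rng.uniform(-4, 4, (30, 3))
        out = cf.bend(pts, np.zeros((3, 4, 4, 4)), box_extent=8.0)
        assert np.array_equal(out, pts)

    def test_constant_field_is_uniform_shift(self, rng):
        field = np.zeros((3, 4, 4, 4))
        field[0] = 1.5
        pts = rng.uniform(-3, 3, (30, 3))
        out = cf.bend(pts, field, box_extent=8.0)
        assert np.allclose(out - pts, [[1.5, 0, 0]] * 30, atol=1e-12)

    def test_matches_regular_grid_interpolator(self, rng):
        nf, extent = 5, 8.0
        field = rng.normal(0, 1, (3, nf, nf, nf))
        pts = rng.uniform(-extent / 2, extent / 2, (100, 3))
        out = cf.bend(pts, field, extent)
        nodes = np.linspace(-extent / 2, extent / 2, nf)
        for d in range(3):
            oracle = RegularGridInterpolator((nodes,) * 3, field[d])(pts)
            assert np.allclose(out[:, d] - pts[:, d], oracle, atol=1e-6)

    def test_bend_gradient_scatter(self, rng):
        """bend_backward is the exact adjoint of the interpolation."""
        nf, extent = 4, 8.0
        field = rng.normal(0, 1, (3, nf, nf, nf))
        pts = rng.uniform(-3, 3, (20, 3))
        _, cache = bend_forward(pts, field, extent)
        dbent = rng.normal(0, 1, (20, 3))
        dfield = cf.heterogeneity.bend_backward(cache, dbent)
        eps = 1e-6
        for ix in [(0, 1, 2, 3), (2, 0, 0, 0), (1, 2, 3, 1)]:
            f2 = field.copy()
            f2[ix] += eps
            up = float(np.sum(cf.bend(pts, f2, extent) * dbent))
            f2[ix] -= 2 * eps
            dn = float(np.sum(cf.bend(pts, f2, extent) * dbent))
            fd = (up - dn) / (2 * eps)
            assert fd == pytest.approx(dfield[ix], abs=1e-5)


class TestPipelineConsistency:
    def test_zero_field_reproduces_homogeneous_render(self, tiny_hash_field):
        grid = cf.build_grid(8, 1.0, 4)
        pmap = build_projection_map(grid)
        pose = cf.Pose.identity()
        homo = cf.render_particle(tiny_hash_field, grid, pose, pmap=pmap)
        hetero = cf.render_particle(
            tiny_hash_field, grid, pose, pmap=pmap,
            vf=np.zeros((3, 4, 4, 4)),
        )
        assert np.array_equal(homo, hetero)

    def test_se3_equivariance_of_bent_render(self, rng):
        """Rendering with a canonical field equals the homogeneous render
        of the bent canonical density at the same pose."""
        from scipy.spatial.transform import Rotation

        n, extent = 12, 12.0
        base = cf.AnalyticField(
            extent, lambda p: np.exp(-np.sum(p**2, axis=1) / (2 * 2.0**2))
        )
        nf = 4
        vf = 0.5 * rng.normal(0, 1, (3, nf, nf, nf))
        grid = cf.build_grid(n, 1.0, 8)
        pmap = build_projection_map(grid)
        pose = cf.Pose(
            Rotation.random(random_state=np.random.default_rng(4)).as_matrix()
        )
        via_pipeline = cf.render_particle(base, grid, pose, pmap=pmap, vf=vf)
        bent_density = cf.AnalyticField(
            extent, lambda p: base.query(cf.bend(p, vf, extent))
        )
        via_bent_field = cf.render_particle(bent_density, grid, pose, pmap=pmap)
        assert np.allclose(via_pipeline, via_bent_field, atol=1e-12)


class TestSimilarity:
    def test_self_and_negated(self, rng):
        f = rng.normal(0, 1, (3, 4, 4, 4))
        S = cf.cosine_similarity_matrix([f, -f])
        assert S[0, 0] == pytest.approx(1.0)
        assert S[0, 1] == pytest.approx(-1.0)
        assert np.allclose(S, S.T)

    def test_matches_direct_dot_products(self, rng):
        fields = [rng.normal(0, 1, 24) for _ in range(4)]
        S = cf.cosine_similarity_matrix(fields)
        for i in range(4):
            for j in range(4):
                direct = np.dot(fields[i], fields[j]) / (
                    np.linalg.norm(fields[i]) * np.linalg.norm(fields[j])
                )
                assert S[i, j] == pytest.approx(direct, abs=1e-10)

    def test_zero_norm_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-norm"):
            cf.cosine_similarity_matrix([rng.normal(0, 1, 8), np.zeros(8)])


class TestExports:
    def test_field_archive_roundtrip(self, rng, tmp_path):
        fields = [rng.normal(0, 1, (3, 4, 4, 4)) for _ in range(3)]
        path = tmp_path / "fields.npz"
        cf.heterogeneity.export_fields(fields, path)
        with np.load(path) as arch:
            assert np.allclose(arch["fields"], np.stack(fields))

    def test_state_average_slices_quiver_frame(self, rng):
        from cryofield.heterogeneity import state_average_slices

        fields = [rng.normal(0, 1, (3, 6, 6, 6)) for _ in range(4)]
        labels = np.array([0, 0, 1, 1])
        slices = state_average_slices(fields, labels, box_extent=12.0,
                                      thickness=2)
        assert set(slices) == {0, 1}
        df = slices[0]
        assert list(df.columns) == ["x", "y", "dx", "dy", "magnitude"]
        assert len(df) == 36
        # the slice is the mean over the two state-0 fields and the two
        # central z layers
        manual = np.stack(fields[:2]).mean(axis=0)[:, :, :, 2:4].mean(axis=3)
        assert np.allclose(df["dx"].to_numpy(), manual[0].ravel())


class TestClustering:
    def test_perfect_blocks_recovered_exactly(self):
        S = np.zeros((10, 10))
        S[:5, :5] = 1.0
        S[5:, 5:] = 1.0
        labels = cf.cluster_states(S, 2, seed=0)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_order_invariance_up_to_permutation(self, rng):
        S = np.full((8, 8), 0.1)
        S[:4, :4] = 0.9
        S[4:, 4:] = 0.9
        np.fill_diagonal(S, 1.0)
        truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        labels = cf.cluster_states(S, 2, seed=0)
        perm = rng.permutation(8)
        labels_shuffled = cf.cluster_states(S[np.ix_(perm, perm)], 2, seed=0)
        a = cf.match_labels(truth, labels)
        b = cf.match_labels(truth[perm], labels_shuffled)
        assert np.array_equal(a, truth)
        assert np.array_equal(b, truth[perm])

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cf.cluster_states(np.eye(3), 4)

    def test_match_labels_resolves_permutation(self):
        true = np.array([0, 0, 1, 1, 1])
        pred = np.array([1, 1, 0, 0, 0])  # flipped labels
        assert np.array_equal(cf.match_labels(true, pred), true)
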