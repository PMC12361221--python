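"""Point decoder: uncertainty scoring, ranked sampling vs an exhaustive-sort
oracle, scatter locality, determinism and conservative refinement."""

import numpy as np
import pytest

from bisenext.config import PointParams
from bisenext.nn import autograd as A
from bisenext.pointrefine import (PointHead, point_loss, refine, sample_points,
                                  scatter_points, uncertainty_map, _point_uncertainty)


def test_uncertainty_examples():
    logits = np.array([[[[2.0]], [[1.9]], [[0.1]]]])
    assert uncertainty_map(logits)[0, 0, 0] == pytest.approx(-0.1)
    logits = np.array([[[[5.0]], [[1.0]], [[0.0]]]])
    assert uncertainty_map(logits)[0, 0, 0] == pytest.approx(-4.0)
    tied = np.array([[[[3.0]], [[3.0]], [[0.0]]]])
    assert uncertainty_map(tied)[0, 0, 0] == pytest.approx(0.0)   # maximal


def test_uncertainty_requires_two_classes():
    with pytest.raises(ValueError, match="2 classes"):
        uncertainty_map(np.zeros((1, 1, 4, 4)))


def test_sample_points_counts_and_determinism(rng):
    logits = rng.normal(size=(2, 3, 8, 8))
    params = PointParams(j=3, n=64, beta=0.75, m=2)
    assert (params.n_ranked, params.n_random) == (48, 16)
    a = sample_points(logits, params, 99)
    b = sample_points(logits, params, 99)
    assert a.coords.shape == (2, 64, 2)
    np.testing.assert_array_equal(a.coords, b.coords)
    assert ((a.coords >= 0) & (a.coords <= 1)).all()


def test_sample_points_beta_zero_is_pure_uniform(rng):
    params = PointParams(j=3, n=32, beta=0.0)
    ps = sample_points(rng.normal(size=(1, 3, 4, 4)), params, 5)
    assert ps.coords.shape == (1, 32, 2)
    assert np.isinf(ps.uncertainties).all()    # nothing ranked


def test_ranked_selection_matches_exhaustive_sort(rng):
    """The ranked subset equals a brute-force stable sort of all candidate
    uncertainties (ties broken by candidate index)."""
    logits = rng.normal(size=(1, 3, 8, 8))
    params = PointParams(j=4, n=16, beta=1.0)
    rng_pts = np.random.default_rng(7)
    ps = sample_points(logits, params, np.random.default_rng(7))
    cand = np.random.default_rng(7).uniform(0, 1, (1, 64, 2))
    scores = _point_uncertainty(logits, cand)[0]
    order = sorted(range(64), key=lambda i: (-scores[i], i))[:16]
    np.testing.assert_array_equal(ps.coords[0], cand[0, order])


def test_point_head_shapes_and_permutation_equivariance(rng):
    head = PointHead(8, 3, fc_dim=16, hidden=16, rng=rng)
    fine = A.Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
    coarse = A.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
    from bisenext.pointrefine import PointSet
    coords = rng.uniform(0, 1, (2, 10, 2))
    out = head(fine, coarse, PointSet(coords, np.zeros((2, 10)))).data
    assert out.shape == (2, 10, 3)
    perm = rng.permutation(10)
    out_p = head(fine, coarse, PointSet(coords[:, perm], np.zeros((2, 10)))).data
    np.testing.assert_allclose(out_p, out[:, perm], rtol=1e-5, atol=1e-6)


def test_point_sample_exact_at_pixel_centres(rng):
    x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    coords = np.array([[[(3 + 0.5) / 8, (5 + 0.5) / 8]]])
    out = A.point_sample(A.Tensor(x), coords).data
    np.testing.assert_allclose(out[0, :, 0], x[0, :, 5, 3], rtol=1e-6)


def test_scatter_points_only_touches_selected_pixels(rng):
    from bisenext.pointrefine import PointSet
    base = rng.normal(size=(1, 3, 8, 8))
    coords = rng.uniform(0, 1, (1, 5, 2))
    new_logits = rng.normal(size=(1, 5, 3))
    out = scatter_points(base, PointSet(coords, np.zeros((1, 5))), new_logits)
    ix = np.clip(np.floor(coords[0, :, 0] * 8).astype(int), 0, 7)
    iy = np.clip(np.floor(coords[0, :, 1] * 8).astype(int), 0, 7)
    touched = set(zip(iy, ix))
    for y in range(8):
        for x in range(8):
            if (y, x) not in touched:
                np.testing.assert_array_equal(out[0, :, y, x], base[0, :, y, x])


def test_refine_shapes_and_unselected_pixels_keep_bilinear_values(rng):
    head = PointHead(4, 3, fc_dim=8, hidden=8, rng=rng)
    params = PointParams(j=2, n=16, beta=0.75, m=2)
    coarse = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
    fine = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    out = refine(coarse, fine, head, params, 3, (64, 64))
    assert out.shape == (1, 3, 64, 64)
    # replay the loop to find pixels never selected in the final step
    from bisenext.pointrefine import snap_to_grid
    with A.no_grad():
        cur = A.interpolate_bilinear(A.Tensor(coarse), (16, 16)).data
        r = np.random.default_rng(3)
        ps1 = snap_to_grid(sample_points(cur, params, r), (16, 16))
        cur = scatter_points(cur, ps1, head(A.Tensor(fine), A.Tensor(cur), ps1).data)
        cur2 = A.interpolate_bilinear(A.Tensor(cur), (32, 32)).data
        ps2 = snap_to_grid(sample_points(cur2, params, r), (32, 32))
        ix = np.clip(np.floor(ps2.coords[0, :, 0] * 32).astype(int), 0, 31)
        iy = np.clip(np.floor(ps2.coords[0, :, 1] * 32).astype(int), 0, 31)
    out32 = refine(coarse, fine, head, params, 3, (32, 32))
    untouched = np.ones((32, 32), dtype=bool)
    untouched[iy, ix] = False
    np.testing.assert_allclose(out32[0, :, untouched], cur2[0, :, untouched], rtol=1e-5)


def test_refine_is_identity_with_zero_correction_head(rng):
    """A freshly built head predicts a zero residual, so refinement leaves
    the chained bilinear upsampling bit-identical — the decoder starts as a
    no-op and can only learn to deviate."""
    head = PointHead(4, 3, fc_dim=8, hidden=8, rng=rng)
    params = PointParams(j=2, n=32, beta=0.75, m=2)
    labels = rng.integers(0, 3, (1, 8, 8))
    coarse = (np.eye(3)[labels].transpose(0, 3, 1, 2) * 10).astype(np.float32)
    fine = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    out = refine(coarse, fine, head, params, 0, (32, 32))
    with A.no_grad():
        chain = A.interpolate_bilinear(A.Tensor(coarse), (16, 16))
        chain = A.interpolate_bilinear(chain, (32, 32)).data
    np.testing.assert_array_equal(out, chain)


def test_refine_is_conservative_on_confident_maps(rng):
    """Constant-class logits with a large margin: a head with small nonzero
    weights cannot overturn any pixel's argmax."""
    head = PointHead(4, 3, fc_dim=8, hidden=8, rng=rng)
    for layer in head.mlp:
        for p in layer.parameters() if hasattr(layer, "parameters") else []:
            p.data[...] = rng.normal(0, 1e-3, p.shape)
    params = PointParams(j=2, n=32, beta=0.75, m=2)
    coarse = np.zeros((1, 3, 8, 8), dtype=np.float32)
    coarse[:, 1] = 1e3                         # everything is confidently leaf
    fine = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    out = refine(coarse, fine, head, params, 0, (64, 64))
    assert (out.argmax(1) == 1).all()


def test_point_loss_gradients_confined_to_point_paths(tiny_config, small_scenes):
    from bisenext.backbone import BiSeNeXt
    from bisenext.nn import SGD
    from bisenext.train import _to_batch

    net = BiSeNeXt(tiny_config, seed=9)
    x, y = _to_batch(small_scenes[:2])
    net.train()
    opt = SGD(net.point_head.parameters(), lr=0.1)
    # step 1: only the zero-initialised output layer receives gradient;
    # once it moves off zero, gradient reaches every point-head parameter
    for step in range(2):
        net.zero_grad()
        res = net(x)
        loss, _ = point_loss(net.point_head, res.fine_features, res.main_logits,
                             y, net.config.point_params, step)
        loss.backward()
        opt.step()
    assert all(p.grad is not None and np.abs(p.grad).sum() > 0
               for p in net.point_head.parameters())
    # the semantic-only booster heads take no part in the point loss
    assert all(p.grad is None for p in net.aux_heads.parameters())


def test_empty_point_set_gives_empty_logits(rng):
    from bisenext.pointrefine import PointSet
    head = PointHead(4, 3, fc_dim=8, hidden=8, rng=rng)
    out = head(A.Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32)),
               A.Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32)),
               PointSet(np.zeros((1, 0, 2)), np.zeros((1, 0))))
    assert out.shape == (1, 0, 3)
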