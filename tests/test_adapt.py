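"""Adversarial-adaptation heads: reversal, conditioning, weighting, losses."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizadapt import adapt
from seizadapt.adapt import (Discriminator, DomainBatch, build_discriminator,
                             cdan_loss, dann_loss, entropy_weight,
                             grad_reverse, lambda_schedule, multilinear_map)
from seizadapt.model import ModelConfig, build_model
from seizadapt.nn import Adam, Tensor, autodiff as ad

SMALL = ModelConfig(C=2, T=256, F1=2, F2=1, F3=2, dropout_p=0.0)


def small_batch(seed=0, n=8):
    rng = np.random.default_rng(seed)
    return DomainBatch(
        xs=rng.standard_normal((n, 1, 2, 256)).astype(np.float32),
        ys=rng.integers(0, 2, n),
        xt=rng.standard_normal((n, 1, 2, 256)).astype(np.float32))


# ---------------------------------------------------------------------------
# gradient reversal


def test_grad_reverse_is_identity_forward():
    x = np.random.default_rng(0).standard_normal((4, 3))
    assert np.array_equal(grad_reverse(Tensor(x), 2.5).data, x)


def test_grad_reverse_backpropagates_minus_lambda():
    """d/dx sum(grad_reverse(x, lam)) == -lam, checked by finite differences."""
    rng = np.random.default_rng(1)
    for lam in (0.0, 0.3, 1.0):
        x = ad.Parameter(rng.standard_normal(5))
        ad.sum_(grad_reverse(x, lam)).backward()
        eps = 1e-6
        for i in range(5):
            x0 = x.data.copy()
            x0[i] += eps
            num = (x0.sum() - x.data.sum()) / eps    # d sum / dx_i == 1
            assert abs(x.grad[i] - (-lam) * num) < 1e-5


# ---------------------------------------------------------------------------
# multilinear map and entropy weights


def test_multilinear_map_printed_example():
    out = multilinear_map(Tensor(np.array([[1.0, 2.0]])),
                          Tensor(np.array([[0.3, 0.7]])))
    assert np.allclose(out.data, [[0.3, 0.7, 0.6, 1.4]])


def test_multilinear_map_one_hot_interleaves_features():
    f = np.array([[1.0, 2.0, 3.0]])
    out = multilinear_map(Tensor(f), Tensor(np.array([[1.0, 0.0]])))
    assert np.allclose(out.data, [[1.0, 0.0, 2.0, 0.0, 3.0, 0.0]])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_multilinear_map_norm_identity(seed):
    """||f (x) p||_2 == ||f||_2 * ||p||_2 against an outer-product oracle."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((3, 5))
    p = rng.dirichlet(np.ones(2), size=3)
    out = multilinear_map(Tensor(f), Tensor(p)).data
    oracle = np.stack([np.outer(f[i], p[i]).ravel() for i in range(3)])
    assert np.allclose(out, oracle, atol=1e-12)
    assert np.allclose(np.linalg.norm(out, axis=1),
                       np.linalg.norm(f, axis=1) * np.linalg.norm(p, axis=1),
                       atol=1e-6)


def test_entropy_weight_closed_forms_and_bounds():
    assert entropy_weight(np.array([[1.0, 0.0]]))[0] == pytest.approx(2.0)
    assert entropy_weight(np.array([[0.5, 0.5]]))[0] == pytest.approx(1.5)
    # strictly decreasing in entropy for two classes
    ps = np.linspace(0.5, 1.0 - 1e-9, 50)
    w = entropy_weight(np.stack([ps, 1 - ps], axis=1))
    assert np.all(np.diff(w) > 0)          # H decreases as p moves from 0.5
    assert np.all((w >= 1.0) & (w <= 2.0))


def test_lambda_schedule_endpoints_and_monotonicity():
    assert lambda_schedule(0.0) == pytest.approx(0.0)
    assert lambda_schedule(1.0, gamma=10) == pytest.approx(
        2.0 / (1.0 + np.exp(-10.0)) - 1.0)
    vals = [lambda_schedule(p) for p in np.linspace(0, 1, 21)]
    assert np.all(np.diff(vals) >= 0)
    with pytest.raises(ValueError):
        lambda_schedule(1.2)


# ---------------------------------------------------------------------------
# loss assemblers


def zeroed(disc: Discriminator) -> Discriminator:
    for p in disc.params():
        p.data = np.zeros_like(p.data)
    return disc


def test_uninformative_discriminator_gives_ln2_domain_loss():
    """With D emitting 0.5 everywhere the batch-mean binary cross-entropy
    is exactly ln 2 (the documented batch-mean convention)."""
    model = build_model(SMALL, seed=0)
    disc = zeroed(build_discriminator("dann", SMALL, hidden=(8,), seed=0))
    terms = dann_loss(model, disc, small_batch(), lambda_=1.0, training=False)
    assert terms.domain_loss == pytest.approx(np.log(2.0), abs=1e-6)


def test_lambda_zero_step_identical_to_supervised():
    """At lambda=0 the adversarial step applies exactly the supervised
    parameter updates (gradient reversal scales the domain gradient away)."""
    batch = small_batch(seed=3)
    sup = build_model(SMALL, seed=9)
    da = build_model(SMALL, seed=9)
    opt_s = Adam(sup.params(), lr=0.01)
    out = sup.forward(batch.xs, training=True)
    ad.cross_entropy_logits(out.logits, batch.ys).backward()
    opt_s.step()

    disc = build_discriminator("dann", SMALL, seed=1)
    opt_d = Adam(da.params() + disc.params(), lr=0.01)
    terms = dann_loss(da, disc, batch, lambda_=0.0, training=True)
    terms.total.backward()
    opt_d.step()
    for ps, pd in zip(sup.params(), da.params()):
        assert np.array_equal(ps.data, pd.data)


def test_cdan_with_one_hot_predictions_matches_dann_on_masked_blocks():
    """With one-hot class probabilities the multilinear map places phi(x)
    in one class block; a conditional discriminator whose class-0 block
    replicates a marginal discriminator then computes the same loss."""
    model = build_model(SMALL, seed=2)
    # force logits (+50, -50): probabilities are exactly one-hot in float32
    model.dense.w.data[:] = 0
    model.dense.b.data[:] = np.array([50.0, -50.0], dtype=np.float32)
    d = SMALL.feature_dim
    disc_dann = build_discriminator("dann", SMALL, seed=5)
    disc_cdan = build_discriminator("cdan", SMALL, seed=6)
    w0 = disc_cdan.layers[0].w
    w0.data[:] = 0
    w0.data[0::2, :] = disc_dann.layers[0].w.data     # class-0 block
    for lc, ld in zip(disc_cdan.layers[1:], disc_dann.layers[1:]):
        lc.w.data[:] = ld.w.data
        lc.b.data[:] = ld.b.data
    disc_cdan.layers[0].b.data[:] = disc_dann.layers[0].b.data
    batch = small_batch(seed=4)
    t_dann = dann_loss(model, disc_dann, batch, 1.0, training=False)
    t_cdan = cdan_loss(model, disc_cdan, batch, 1.0, training=False)
    assert t_cdan.domain_loss == pytest.approx(t_dann.domain_loss, rel=1e-5)


def test_entropy_conditioning_scales_discriminator_gradient_by_1_5():
    """Uniform predictions give every example weight 1.5, so the
    discriminator gradient of CDAN+E is exactly 1.5x that of CDAN."""
    batch = small_batch(seed=5)

    def disc_grads(entropy_conditioning):
        model = build_model(SMALL, seed=3)
        model.dense.w.data[:] = 0
        model.dense.b.data[:] = 0          # logits 0 -> probs (0.5, 0.5)
        disc = build_discriminator("cdan", SMALL, seed=7)
        terms = cdan_loss(model, disc, batch, 1.0,
                          entropy_conditioning=entropy_conditioning,
                          training=False)
        if entropy_conditioning:
            assert np.allclose(terms.weights, 1.5)
        terms.total.backward()
        return [p.grad.copy() for p in disc.params()]

    g_plain = disc_grads(False)
    g_weighted = disc_grads(True)
    for a, b in zip(g_plain, g_weighted):
        # float32 forward/backward: agreement up to rounding
        assert np.allclose(b, 1.5 * a, rtol=1e-3, atol=1e-8)


def test_entropy_weights_are_detached_from_classifier():
    model = build_model(SMALL, seed=4)
    disc = build_discriminator("cdan_e", SMALL, seed=8)
    terms = cdan_loss(model, disc, small_batch(seed=6), 1.0,
                      entropy_conditioning=True, training=False)
    assert isinstance(terms.weights, np.ndarray)       # plain array, no graph
    assert np.all((terms.weights >= 1.0) & (terms.weights <= 2.0))


def test_discriminator_dimension_mismatch_raises():
    model = build_model(SMALL, seed=0)
    wrong = build_discriminator("dann", SMALL, seed=0)  # d, not d*c
    with pytest.raises(ValueError, match="input dim"):
        cdan_loss(model, wrong, small_batch(), 1.0)


def test_empty_domain_side_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="non-empty"):
        DomainBatch(xs=rng.standard_normal((0, 1, 2, 256)),
                    ys=np.zeros(0, dtype=int),
                    xt=rng.standard_normal((4, 1, 2, 256)))


# ---------------------------------------------------------------------------
# discriminator behaviour on explicit feature distributions


def train_disc_on(xs, xt, seed=0, steps=150):
    disc = Discriminator(xs.shape[1], hidden=(16, 16), seed=seed)
    opt = Adam(disc.params(), lr=0.01)
    y = np.concatenate([np.zeros(len(xs)), np.ones(len(xt))])
    h = np.concatenate([xs, xt]).astype(np.float32)
    rng = np.random.default_rng(seed)
    for _ in range(steps):
        idx = rng.permutation(len(h))[:64]
        loss = ad.bce_logits(disc.logits(Tensor(h[idx])), y[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
    return disc


def test_discriminator_at_chance_on_identical_distributions():
    rng = np.random.default_rng(10)
    disc = train_disc_on(rng.standard_normal((300, 8)),
                         rng.standard_normal((300, 8)))
    fresh_s = rng.standard_normal((500, 8))
    fresh_t = rng.standard_normal((500, 8))
    acc = np.mean(np.concatenate([
        disc.predict_proba(fresh_s.astype(np.float32)) < 0.5,
        disc.predict_proba(fresh_t.astype(np.float32)) >= 0.5]))
    assert 0.38 < acc < 0.62


def test_discriminator_separates_strongly_shifted_distributions():
    rng = np.random.default_rng(11)
    disc = train_disc_on(rng.standard_normal((300, 8)),
                         rng.standard_normal((300, 8)) + 3.0)
    acc = np.mean(np.concatenate([
        disc.predict_proba(rng.standard_normal((300, 8)).astype(np.float32))
        < 0.5,
        disc.predict_proba((rng.standard_normal((300, 8)) + 3.0)
                           .astype(np.float32)) >= 0.5]))
    assert acc > 0.9
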