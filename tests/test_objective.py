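"""Loss-term correctness: naive-loop oracles, analytic Jacobian cases,
finite-difference agreement for the contractive penalty, and the weighted
total-objective identities."""

import numpy as np
import pytest

from fecgdenoise.model import DenoisingModel
from fecgdenoise.nn import Conv1d, InstanceNorm1d, LeakyReLU
from fecgdenoise.objective import (LossWeights, adversarial_feature_loss,
                                   contractive_penalty, discriminator_loss,
                                   latent_consistency_loss,
                                   reconstruction_loss, total_objective)


def naive_mse(a, b):
    total, count = 0.0, 0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        total += (x - y) ** 2
        count += 1
    return total / count


class IdentityEncoder:
    """Encoder stub: f_E(x) = x, so the Jacobian is the identity."""

    def forward(self, x):
        return np.asarray(x, dtype=float), {}, None

    def backward(self, g, g_skips, cache, accumulate=True):
        return g


class LinearEncoder:
    """f_E(x) = W @ vec(x); Jacobian is W itself."""

    def __init__(self, W, in_shape):
        self.W = np.asarray(W, dtype=float)
        self.in_shape = in_shape

    def forward(self, x):
        flat = np.asarray(x, dtype=float).reshape(x.shape[0], -1)
        return flat @ self.W.T, {}, None

    def backward(self, g, g_skips, cache, accumulate=True):
        return (g @ self.W).reshape(g.shape[0], *self.in_shape)


class TinyConvEncoder:
    """A sub-1000-parameter two-layer convolutional encoder exposing the
    same functional protocol as the real encoder."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.c1 = Conv1d(4, 4, 4, stride=2, dilation=1, padding=(1, 1), rng=rng)
        self.a1 = LeakyReLU(0.2)
        self.n1 = InstanceNorm1d(4)
        self.c2 = Conv1d(4, 8, 4, stride=2, dilation=1, padding=(1, 1), rng=rng)

    def n_params(self):
        return sum(l.n_params() for l in (self.c1, self.n1, self.c2))

    def forward(self, x):
        h, k1 = self.c1.forward(np.asarray(x, dtype=float))
        h, k2 = self.a1.forward(h)
        h, k3 = self.n1.forward(h)
        h, k4 = self.c2.forward(h)
        return h, {}, (k1, k2, k3, k4)

    def backward(self, g, g_skips, cache, accumulate=True):
        k1, k2, k3, k4 = cache
        g = self.c2.backward(g, k4, accumulate)
        g = self.n1.backward(g, k3, accumulate)
        g = self.a1.backward(g, k2, accumulate)
        return self.c1.backward(g, k1, accumulate)


def test_reconstruction_loss_basic_and_oracle(rng):
    x = rng.standard_normal((4, 100))
    assert reconstruction_loss(x, x) == 0.0
    assert reconstruction_loss(x, x + 1.0) == pytest.approx(1.0, abs=1e-12)
    y = rng.standard_normal((4, 100))
    assert reconstruction_loss(x, y) == pytest.approx(naive_mse(x, y), abs=1e-12)
    with pytest.raises(ValueError, match="shape"):
        reconstruction_loss(x, x[:, :50])


def test_latent_consistency_loss_symmetric_and_oracle(rng):
    z = rng.standard_normal((8, 15))
    w = rng.standard_normal((8, 15))
    assert latent_consistency_loss(z, z) == 0.0
    assert latent_consistency_loss(z, w) == latent_consistency_loss(w, z)
    assert latent_consistency_loss(z, w) == pytest.approx(naive_mse(z, w), abs=1e-12)


def test_adversarial_feature_loss_contract(rng):
    model = DenoisingModel.build(width_scale=0.05, seed=2)
    disc = model.discriminator
    x = rng.standard_normal((1, 4, 1920))
    y = rng.standard_normal((1, 4, 1920))
    assert adversarial_feature_loss(x, x, disc) == 0.0

    loss = adversarial_feature_loss(x, y, disc)
    fx, _, _ = disc.forward(x)
    fy, _, _ = disc.forward(y)
    assert loss == pytest.approx(naive_mse(fx, fy), abs=1e-12)

    # invariant under changes to the final (sigmoid) layer: the loss uses
    # only the intermediate feature representation
    disc.out_linear.params["W"] += 3.0
    disc.out_linear.params["b"] += 1.0
    assert adversarial_feature_loss(x, y, disc) == pytest.approx(loss, rel=1e-12)


def test_contractive_penalty_identity_encoder(rng):
    x = rng.standard_normal((3, 4, 32))
    omega = contractive_penalty(IdentityEncoder(), x, mode="exact")
    assert omega == pytest.approx(4 * 32, rel=1e-12)


def test_contractive_penalty_linear_encoder(rng):
    W = rng.standard_normal((8, 4 * 32))
    enc = LinearEncoder(W, (4, 32))
    x = rng.standard_normal((2, 4, 32))
    omega = contractive_penalty(enc, x, mode="exact")
    assert omega == pytest.approx(np.sum(W ** 2), rel=1e-10)


def test_contractive_penalty_exact_matches_finite_differences(rng):
    enc = TinyConvEncoder(seed=3)
    assert enc.n_params() < 1000
    x = rng.standard_normal((1, 4, 32))
    exact = contractive_penalty(enc, x, mode="exact")

    # central finite differences, column by column of the Jacobian
    h = 1e-4
    total = 0.0
    for i in range(4):
        for t in range(32):
            xp = x.copy()
            xp[0, i, t] += h
            xm = x.copy()
            xm[0, i, t] -= h
            zp, _, _ = enc.forward(xp)
            zm, _, _ = enc.forward(xm)
            total += np.sum(((zp - zm) / (2 * h)) ** 2)
    assert exact == pytest.approx(total, rel=1e-4)


@pytest.mark.parametrize("mode", ["hutchinson", "fd"])
def test_contractive_penalty_estimators_are_consistent(mode, rng):
    """Stochastic estimators converge to the exact Frobenius norm."""
    W = rng.standard_normal((6, 4 * 16))
    enc = LinearEncoder(W, (4, 16))
    x = rng.standard_normal((1, 4, 16))
    exact = np.sum(W ** 2)
    est = contractive_penalty(enc, x, mode=mode, n_probes=4000,
                              rng=np.random.default_rng(0))
    assert est == pytest.approx(exact, rel=0.1)


def test_contractive_penalty_unknown_mode(rng):
    with pytest.raises(ValueError, match="mode"):
        contractive_penalty(IdentityEncoder(), rng.standard_normal((1, 4, 8)),
                            mode="magic")


def test_total_objective_weighting():
    assert total_objective(2.0, 0.0, 0.0, 0.0,
                           LossWeights(0, 0, 1, 0)).l_total == 2.0
    bd = total_objective(1.0, 1.0, 1.0, 1.0)
    assert bd.l_total == pytest.approx(29.0101, abs=1e-12)
    assert total_objective(0, 0, 0, 0).l_total == 0.0


def test_loss_breakdown_identities(rng):
    """L_ctr = L_rec + Omega and the weighted-total identity hold to
    machine precision for random components."""
    for _ in range(20):
        comps = rng.uniform(0, 10, size=4)
        w = LossWeights(*rng.uniform(0, 5, size=4))
        bd = total_objective(*comps, w)
        assert bd.l_ctr == bd.l_rec + bd.omega
        expected = (w.w_enc * bd.l_enc + w.w_adv * bd.l_adv
                    + w.w_rec * bd.l_rec + w.w_omega * bd.omega)
        assert bd.l_total == expected


def test_total_objective_rejects_nan():
    with pytest.raises(FloatingPointError, match="l_adv"):
        total_objective(1.0, 1.0, float("nan"), 1.0)


def test_discriminator_loss_reference_points(rng):
    class ConstantDisc:
        def __init__(self, p):
            self.p = p

        def forward(self, x):
            n = x.shape[0]
            return np.zeros((n, 8)), np.full(n, self.p), None

    class OracleDisc:
        """Perfect discriminator: recognizes the stored clean batch."""

        def __init__(self, real):
            self.real = real

        def forward(self, x):
            p = np.array([1.0 - 1e-12 if np.array_equal(xi, ri) else 1e-12
                          for xi, ri in zip(x, self.real)])
            return np.zeros((x.shape[0], 8)), p, None

    x = rng.standard_normal((4, 4, 1920))
    y = rng.standard_normal((4, 4, 1920))
    assert discriminator_loss(x, y, ConstantDisc(0.5)) == pytest.approx(np.log(2))
    assert discriminator_loss(x, y, OracleDisc(x)) < 1e-9
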