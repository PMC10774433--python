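"""Loss terms of the composite denoising objective.

The denoiser is trained with a weighted sum of four terms:

* ``L_rec`` — per-channel mean-squared error between the clean window and
  the decoder output (classical denoising-autoencoder loss);
* ``Ω`` — squared Frobenius norm of the encoder's input–output Jacobian
  evaluated at the noisy window (contractive penalty);
* ``L_adv`` — feature-matching adversarial loss: MSE between the
  discriminator's penultimate-layer features of the clean window and of
  the decoder output;
* ``L_enc`` — latent-consistency loss: MSE between the encoder codes of
  the clean and the noisy window.

``L_ctr = L_rec + Ω`` is the contractive-autoencoder loss; the total is
``L = w_enc·L_enc + w_adv·L_adv + w_rec·L_rec + w_ω·Ω`` with default
weights (4, 1e-2, 25, 1e-4). Every MSE is computed along each channel and
then averaged, which for equal-length channels equals the plain mean over
all entries.

The Jacobian norm is exact only on tiny encoders (``mode="exact"``); at
the real architecture it is estimated stochastically, either by Hutchinson
probing with vector–Jacobian products (``mode="hutchinson"``) or by the
finite-difference directional estimator ``‖f_E(x̂+εu)−f_E(x̂)‖²/ε²`` with
``u ~ N(0, I)`` (``mode="fd"``), both unbiased for ``‖J‖²_F``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossWeights", "LossBreakdown", "reconstruction_loss",
           "contractive_penalty", "adversarial_feature_loss",
           "latent_consistency_loss", "total_objective", "discriminator_loss"]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the four loss terms in the total objective."""

    w_enc: float = 4.0
    w_adv: float = 1e-2
    w_rec: float = 25.0
    w_omega: float = 1e-4

    def __post_init__(self):
        vals = (self.w_enc, self.w_adv, self.w_rec, self.w_omega)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("loss weights must be finite and non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    l_rec: float
    omega: float
    l_adv: float
    l_enc: float
    l_total: float

    @property
    def l_ctr(self) -> float:
        return self.l_rec + self.omega


def _check_shapes(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def reconstruction_loss(x: np.ndarray, x_tilde: np.ndarray) -> float:
    """Per-channel MSE between clean and denoised windows, averaged over
    channels (and batch)."""
    x, x_tilde = _check_shapes(x, x_tilde)
    return float(np.mean((x - x_tilde) ** 2))


def latent_consistency_loss(x: np.ndarray, x_hat: np.ndarray,
                            encoder=None) -> float:
    """MSE between the latent codes of the clean and noisy windows.

    With ``encoder`` given, ``x`` and ``x_hat`` are windows and are encoded
    first; otherwise they are taken to be latent codes already.
    """
    if encoder is not None:
        single = np.asarray(x).ndim == 2
        xs = np.asarray(x)[None] if single else np.asarray(x)
        hs = np.asarray(x_hat)[None] if single else np.asarray(x_hat)
        x, _, _ = encoder.forward(xs)
        x_hat, _, _ = encoder.forward(hs)
    z, z_hat = _check_shapes(x, x_hat)
    return float(np.mean((z - z_hat) ** 2))


def adversarial_feature_loss(x: np.ndarray, x_tilde: np.ndarray,
                             discriminator) -> float:
    """MSE between discriminator features of the clean window and of the
    decoder output; independent of the discriminator's sigmoid output."""
    single = np.asarray(x).ndim == 2
    xs = np.asarray(x)[None] if single else np.asarray(x)
    ts = np.asarray(x_tilde)[None] if single else np.asarray(x_tilde)
    feat_x, _, _ = discriminator.forward(xs)
    feat_t, _, _ = discriminator.forward(ts)
    return float(np.mean((feat_x - feat_t) ** 2))


def total_objective(l_rec: float, omega: float, l_adv: float, l_enc: float,
                    weights: LossWeights | None = None) -> LossBreakdown:
    """Combine the four loss components into the weighted total."""
    weights = weights or LossWeights()
    comps = {"l_rec": l_rec, "omega": omega, "l_adv": l_adv, "l_enc": l_enc}
    for name, v in comps.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {name}={v}")
    total = (weights.w_enc * l_enc + weights.w_adv * l_adv
             + weights.w_rec * l_rec + weights.w_omega * omega)
    return LossBreakdown(l_rec=float(l_rec), omega=float(omega),
                         l_adv=float(l_adv), l_enc=float(l_enc),
                         l_total=float(total))


def discriminator_loss(x: np.ndarray, x_tilde: np.ndarray, discriminator,
                       eps: float = 1e-12) -> float:
    """Binary cross-entropy of the discriminator, targets 1 for clean
    windows and 0 for decoder outputs; averaged so that a discriminator
    emitting 0.5 everywhere scores ``ln 2`` per (clean, denoised) pair."""
    single = np.asarray(x).ndim == 2
    xs = np.asarray(x)[None] if single else np.asarray(x)
    ts = np.asarray(x_tilde)[None] if single else np.asarray(x_tilde)
    _, p_real, _ = discriminator.forward(xs)
    _, p_fake, _ = discriminator.forward(ts)
    real_term = -np.log(np.clip(p_real, eps, 1.0))
    fake_term = -np.log(np.clip(1.0 - p_fake, eps, 1.0))
    return float(0.5 * (real_term.mean() + fake_term.mean()))


def contractive_penalty(encoder, x_hat: np.ndarray, mode: str = "hutchinson",
                        n_probes: int = 1, eps: float = 1e-4,
                        rng: np.random.Generator | None = None) -> float:
    """Squared Frobenius norm of the encoder Jacobian ``∂f_E(x̂)/∂x̂``.

    ``encoder`` must expose the functional protocol
    ``forward(x) -> (latent, skips, cache)`` and
    ``backward(g_latent, g_skips, cache, accumulate) -> g_x``
    (the :class:`~fecgdenoise.model.Encoder` interface). For a batch the
    per-sample norms are averaged.

    Modes: ``exact`` loops a vector–Jacobian product over every latent
    entry (use on tiny encoders only); ``hutchinson`` probes with Gaussian
    cotangents; ``fd`` uses forward finite differences along Gaussian input
    directions (the estimator differentiated during training).
    """
    x = np.asarray(x_hat, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    n = x.shape[0]
    latent, _, cache = encoder.forward(x)
    if not np.all(np.isfinite(latent)):
        raise FloatingPointError("encoder produced non-finite activations")
    out_shape = latent.shape[1:]

    if mode == "exact":
        total = 0.0
        for idx in np.ndindex(*out_shape):
            cot = np.zeros_like(latent)
            cot[(slice(None),) + idx] = 1.0
            gx = encoder.backward(cot, None, cache, accumulate=False)
            total += float(np.sum(gx ** 2))
        return total / n
    if mode == "hutchinson":
        rng = rng or np.random.default_rng(0)
        acc = 0.0
        for _ in range(n_probes):
            v = rng.standard_normal(latent.shape)
            gx = encoder.backward(v, None, cache, accumulate=False)
            acc += float(np.sum(gx ** 2)) / n
        return acc / n_probes
    if mode == "fd":
        rng = rng or np.random.default_rng(0)
        acc = 0.0
        for _ in range(n_probes):
            u = rng.standard_normal(x.shape)
            pert, _, _ = encoder.forward(x + eps * u)
            acc += float(np.sum(((pert - latent) / eps) ** 2)) / n
        return acc / n_probes
    raise ValueError(f"unknown contractive-penalty mode {mode!r}")
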