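"""Encoder, decoder and discriminator networks of the fetal-ECG denoiser.

The denoising filter is the composition ``f = f_D ∘ f_E`` of

* an **encoder** ``f_E`` of eight dilated-convolution layers (each:
  1-D convolution → LeakyReLU(0.2) → affine instance normalization) that
  compresses a standardized 4×1920 window into a 2048×15 latent code, and
* a **decoder** ``f_D`` of eight transposed-convolution layers (same
  layer recipe) plus a final plain convolution with no activation or
  normalization, mapping the latent code back to 4×1920.

Encoder activations of layers 1, 3, 5 and 7 are concatenated (channel-wise)
onto the inputs of decoder layers 8, 6, 4 and 2 respectively — skip
connections that double those decoder layers' input channel counts.

A third network, the **discriminator**, is a four-layer MLP on the
flattened window (7680 → 1920 → 480 → 120 → 1, ReLU between layers,
sigmoid output). Its penultimate 120-unit ReLU activation is the feature
vector used by the adversarial feature-matching loss.

``width_scale`` shrinks every channel count proportionally (minimum 1) so
the same topology can be trained at desk scale; 1.0 reproduces the full
architecture exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    AdamW,
    Conv1d,
    ConvTranspose1d,
    InstanceNorm1d,
    LeakyReLU,
    Linear,
    ReLU,
    Sigmoid,
    conv1d_output_length,
)

__all__ = ["ArchitectureSpec", "Encoder", "Decoder", "Discriminator",
           "DenoisingModel", "WINDOW_CHANNELS", "WINDOW_LENGTH"]

WINDOW_CHANNELS = 4
WINDOW_LENGTH = 1920
KERNEL = 8

# (out_channels, stride, dilation, padding) per encoder layer; padding is
# derived so a 1920-sample input halves in temporal extent at layers 1-7
# and keeps length 15 at layer 8.
_ENCODER_PLAN = [
    (16, 2, 2, (7, 7)),
    (32, 2, 2, (7, 7)),
    (64, 2, 4, (14, 14)),
    (128, 2, 4, (14, 14)),
    (256, 2, 4, (14, 14)),
    (512, 2, 4, (14, 14)),
    (1024, 2, 2, (7, 7)),
    (2048, 1, 2, (7, 7)),
]

# (out_channels, stride, dilation, padding, output_padding, skip_source)
# skip_source is the 1-based encoder layer whose activation is concatenated
# onto this decoder layer's input (None = no skip).
_DECODER_PLAN = [
    (1024, 1, 2, 7, 0, None),
    (512, 2, 4, 14, 1, 7),
    (256, 2, 4, 14, 1, None),
    (128, 2, 4, 14, 1, 5),
    (64, 2, 4, 14, 1, None),
    (32, 2, 2, 7, 1, 3),
    (16, 2, 2, 7, 1, None),
    (WINDOW_CHANNELS, 2, 2, 7, 1, 1),
]

# final decoder layer: plain convolution, stride 1, dilation 1, kernel 8,
# asymmetric padding (3, 4) to preserve length; no activation, no norm
_FINAL_CONV_PAD = (3, 4)

_DISC_HIDDEN = [1920, 480, 120]


def _scaled(ch: int, width_scale: float) -> int:
    return max(1, round(ch * width_scale))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Channel/stride/dilation plan of the three networks at a given width."""

    width_scale: float = 1.0
    in_channels: int = WINDOW_CHANNELS
    window_length: int = WINDOW_LENGTH

    def __post_init__(self):
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must be in (0, 1]")

    @property
    def encoder_channels(self) -> list[int]:
        return [_scaled(ch, self.width_scale) for ch, *_ in _ENCODER_PLAN]

    @property
    def decoder_channels(self) -> list[int]:
        return [_scaled(ch, self.width_scale) if ch != WINDOW_CHANNELS else ch
                for ch, *_ in _DECODER_PLAN]

    @property
    def discriminator_widths(self) -> list[int]:
        return [_scaled(w, self.width_scale) for w in _DISC_HIDDEN]

    @property
    def latent_shape(self) -> tuple[int, int]:
        ch = self.encoder_channels[-1]
        length = self.window_length
        for (_, s, d, pad), _ch in zip(_ENCODER_PLAN, self.encoder_channels):
            length = conv1d_output_length(length, KERNEL, s, d, *pad)
        return ch, length

    def encoder_shapes(self, length: int | None = None) -> list[tuple[int, int]]:
        length = self.window_length if length is None else length
        shapes = []
        for (_, s, d, pad), ch in zip(_ENCODER_PLAN, self.encoder_channels):
            length = conv1d_output_length(length, KERNEL, s, d, *pad)
            shapes.append((ch, length))
        return shapes


class Encoder:
    """Eight dilated-convolution layers; emits latent code + skip stack."""

    #: encoder layers (1-based) whose post-normalization activations feed
    #: the decoder skip connections
    SKIP_LAYERS = (1, 3, 5, 7)

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.spec = spec
        self.blocks = []
        in_ch = spec.in_channels
        for (_, s, d, pad), out_ch in zip(_ENCODER_PLAN, spec.encoder_channels):
            conv = Conv1d(in_ch, out_ch, KERNEL, s, d, pad, rng=rng, dtype=dtype)
            self.blocks.append((conv, LeakyReLU(0.2), InstanceNorm1d(out_ch, dtype=dtype)))
            in_ch = out_ch

    @property
    def layers(self):
        return [unit for block in self.blocks for unit in block]

    def forward(self, x: np.ndarray):
        """Return ``(latent, skips, cache)``; ``skips`` maps encoder layer
        index (1-based) to its post-normalization activation."""
        caches = []
        skips = {}
        h = x
        for i, (conv, act, norm) in enumerate(self.blocks, start=1):
            h, c1 = conv.forward(h)
            h, c2 = act.forward(h)
            h, c3 = norm.forward(h)
            caches.append((c1, c2, c3))
            if i in self.SKIP_LAYERS:
                skips[i] = h
        return h, skips, caches

    def backward(self, g_latent: np.ndarray, g_skips: dict | None, caches,
                 accumulate: bool = True) -> np.ndarray:
        g = g_latent
        for i in range(len(self.blocks), 0, -1):
            conv, act, norm = self.blocks[i - 1]
            c1, c2, c3 = caches[i - 1]
            if g_skips and i in g_skips:
                g = g + g_skips[i]
            g = norm.backward(g, c3, accumulate)
            g = act.backward(g, c2, accumulate)
            g = conv.backward(g, c1, accumulate)
        return g


class Decoder:
    """Eight transposed-convolution layers plus a final plain convolution."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.spec = spec
        enc_ch = spec.encoder_channels
        self.blocks = []
        self.skip_sources = []
        in_ch = enc_ch[-1]
        for (_, s, d, p, op, src), out_ch in zip(_DECODER_PLAN, spec.decoder_channels):
            if src is not None:
                in_ch += enc_ch[src - 1]
            tconv = ConvTranspose1d(in_ch, out_ch, KERNEL, s, d, p, op,
                                    rng=rng, dtype=dtype)
            self.blocks.append((tconv, LeakyReLU(0.2), InstanceNorm1d(out_ch, dtype=dtype)))
            self.skip_sources.append(src)
            in_ch = out_ch
        self.final_conv = Conv1d(in_ch, spec.in_channels, KERNEL, 1, 1,
                                 _FINAL_CONV_PAD, rng=rng, dtype=dtype)

    @property
    def layers(self):
        return [unit for block in self.blocks for unit in block] + [self.final_conv]

    def forward(self, latent: np.ndarray, skips: dict):
        missing = {s for s in self.skip_sources if s is not None} - set(skips)
        if missing:
            raise ValueError(f"missing skip activations for encoder layers {sorted(missing)}")
        caches = []
        h = latent
        for (tconv, act, norm), src in zip(self.blocks, self.skip_sources):
            split = None
            if src is not None:
                split = h.shape[1]
                h = np.concatenate([h, skips[src]], axis=1)
            h, c1 = tconv.forward(h)
            h, c2 = act.forward(h)
            h, c3 = norm.forward(h)
            caches.append((split, c1, c2, c3))
        y, cf = self.final_conv.forward(h)
        caches.append(cf)
        return y, caches

    def backward(self, gy: np.ndarray, caches, accumulate: bool = True):
        """Return ``(g_latent, g_skips)``."""
        g = self.final_conv.backward(gy, caches[-1], accumulate)
        g_skips: dict[int, np.ndarray] = {}
        for i in range(len(self.blocks) - 1, -1, -1):
            tconv, act, norm = self.blocks[i]
            split, c1, c2, c3 = caches[i]
            g = norm.backward(g, c3, accumulate)
            g = act.backward(g, c2, accumulate)
            g = tconv.backward(g, c1, accumulate)
            if split is not None:
                src = self.skip_sources[i]
                g_skips[src] = g[:, split:, :]
                g = g[:, :split, :]
        return g, g_skips


class Discriminator:
    """Four-layer MLP on the flattened window; exposes the penultimate
    120-unit ReLU activation as the feature vector for feature matching."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.spec = spec
        self.in_features = spec.in_channels * spec.window_length
        widths = spec.discriminator_widths
        dims = [self.in_features] + widths
        self.hidden = [(Linear(dims[i], dims[i + 1], rng=rng, dtype=dtype), ReLU())
                       for i in range(len(widths))]
        self.out_linear = Linear(widths[-1], 1, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()

    @property
    def layers(self):
        return [unit for pair in self.hidden for unit in pair] + [self.out_linear, self.sigmoid]

    @property
    def feature_dim(self) -> int:
        return self.spec.discriminator_widths[-1]

    def forward(self, x: np.ndarray):
        """Return ``(features, probability, cache)`` for a batch of windows."""
        n = x.shape[0]
        h = x.reshape(n, -1)
        caches = []
        for lin, relu in self.hidden:
            h, c1 = lin.forward(h)
            h, c2 = relu.forward(h)
            caches.append((c1, c2))
        features = h
        logit, c_out = self.out_linear.forward(h)
        prob, c_sig = self.sigmoid.forward(logit)
        caches.append((c_out, c_sig))
        return features, prob[:, 0], caches

    def backward(self, g_features, g_prob, caches, accumulate: bool = True):
        c_out, c_sig = caches[-1]
        g = np.zeros_like(caches[-1][0] if g_features is None else g_features)
        if g_prob is not None:
            gp = self.sigmoid.backward(g_prob[:, None], c_sig, accumulate)
            g = g + self.out_linear.backward(gp, c_out, accumulate)
        if g_features is not None:
            g = g + g_features
        for i in range(len(self.hidden) - 1, -1, -1):
            lin, relu = self.hidden[i]
            c1, c2 = caches[i]
            g = relu.backward(g, c2, accumulate)
            g = lin.backward(g, c1, accumulate)
        n = g.shape[0]
        return g.reshape(n, self.spec.in_channels, self.spec.window_length)


@dataclass
class DenoisingModel:
    """The three networks bundled with their architecture spec."""

    spec: ArchitectureSpec
    encoder: Encoder
    decoder: Decoder
    discriminator: Discriminator
    dtype: object = np.float64

    @classmethod
    def build(cls, width_scale: float = 1.0, seed: int = 0,
              dtype=np.float64) -> "DenoisingModel":
        spec = ArchitectureSpec(width_scale=width_scale)
        rng = np.random.default_rng(seed)
        return cls(spec, Encoder(spec, rng, dtype), Decoder(spec, rng, dtype),
                   Discriminator(spec, rng, dtype), dtype)

    # ---- inference -------------------------------------------------------

    def encode(self, window: np.ndarray):
        """Map windows (n, 4, 1920) or a single (4, 1920) window to latent
        codes plus the skip stack."""
        x, squeeze = _as_batch(window, self.spec)
        latent, skips, _ = self.encoder.forward(x.astype(self.dtype, copy=False))
        if squeeze:
            return latent[0], {k: v[0] for k, v in skips.items()}
        return latent, skips

    def decode(self, latent: np.ndarray, skips: dict):
        single = latent.ndim == 2
        if single:
            latent = latent[None]
            skips = {k: v[None] for k, v in skips.items()}
        y, _ = self.decoder.forward(latent.astype(self.dtype, copy=False),
                                    {k: v.astype(self.dtype, copy=False)
                                     for k, v in skips.items()})
        return y[0] if single else y

    def denoise(self, window: np.ndarray) -> np.ndarray:
        """The inference filter ``f = f_D ∘ f_E``."""
        x, squeeze = _as_batch(window, self.spec)
        latent, skips, _ = self.encoder.forward(x.astype(self.dtype, copy=False))
        y, _ = self.decoder.forward(latent, skips)
        return y[0] if squeeze else y

    def discriminate(self, window: np.ndarray):
        x, squeeze = _as_batch(window, self.spec)
        features, prob, _ = self.discriminator.forward(x.astype(self.dtype, copy=False))
        if squeeze:
            return features[0], float(prob[0])
        return features, prob

    # ---- introspection ---------------------------------------------------

    def count_parameters(self, subnetwork: str | None = None) -> int:
        nets = {"encoder": self.encoder, "decoder": self.decoder,
                "discriminator": self.discriminator}
        if subnetwork is None:
            return sum(self.count_parameters(k) for k in nets)
        try:
            net = nets[subnetwork]
        except KeyError:
            raise ValueError(f"unknown subnetwork {subnetwork!r}") from None
        return sum(layer.n_params() for layer in net.layers)

    def parameter_table(self) -> list[tuple[str, str, int]]:
        """Per-layer trainable-parameter counts, one row per convolution /
        normalization / linear unit, in execution order."""
        rows = []
        for i, (conv, _act, norm) in enumerate(self.encoder.blocks, start=1):
            rows.append(("encoder", f"conv{i}", conv.n_params()))
            rows.append(("encoder", f"instnorm{i}", norm.n_params()))
        for i, (tconv, _act, norm) in enumerate(self.decoder.blocks, start=1):
            rows.append(("decoder", f"tconv{i}", tconv.n_params()))
            rows.append(("decoder", f"instnorm{i}", norm.n_params()))
        rows.append(("decoder", "final_conv", self.decoder.final_conv.n_params()))
        for i, (lin, _relu) in enumerate(self.discriminator.hidden, start=1):
            rows.append(("discriminator", f"linear{i}", lin.n_params()))
        rows.append(("discriminator",
                     f"linear{len(self.discriminator.hidden) + 1}",
                     self.discriminator.out_linear.n_params()))
        return rows

    def layer_output_shapes(self, input_shape: tuple[int, int] | None = None):
        """(channels, length) after every encoder and decoder layer for the
        given input shape — fully convolutional, so any length works."""
        ch_in, length = input_shape or (self.spec.in_channels, self.spec.window_length)
        if ch_in != self.spec.in_channels:
            raise ValueError(f"model expects {self.spec.in_channels} input channels")
        shapes = []
        for conv, _act, _norm in self.encoder.blocks:
            length = conv.output_length(length)
            shapes.append((conv.out_ch, length))
        for tconv, _act, _norm in self.decoder.blocks:
            length = tconv.output_length(length)
            shapes.append((tconv.out_ch, length))
        length = self.decoder.final_conv.output_length(length)
        shapes.append((self.decoder.final_conv.out_ch, length))
        return shapes

    # ---- serialization ---------------------------------------------------

    def _named_layers(self):
        for name, net in (("enc", self.encoder), ("dec", self.decoder),
                          ("disc", self.discriminator)):
            for i, layer in enumerate(net.layers):
                if layer.params:
                    yield f"{name}.{i}", layer

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": p.copy() for name, layer in self._named_layers()
                for k, p in layer.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._named_layers():
            for k in layer.params:
                src = state[f"{name}.{k}"]
                if src.shape != layer.params[k].shape:
                    raise ValueError(f"shape mismatch for {name}.{k}")
                layer.params[k] = src.astype(self.dtype).copy()

    def generator_layers(self):
        return self.encoder.layers + self.decoder.layers

    def make_optimizers(self, lr: float = 1e-5, weight_decay: float = 5e-2):
        gen = AdamW(self.generator_layers(), lr=lr, weight_decay=weight_decay)
        disc = AdamW(self.discriminator.layers, lr=lr, weight_decay=weight_decay)
        return gen, disc


def _as_batch(window: np.ndarray, spec: ArchitectureSpec):
    w = np.asarray(window)
    squeeze = w.ndim == 2
    if squeeze:
        w = w[None]
    if w.ndim != 3 or w.shape[1] != spec.in_channels:
        raise ValueError(
            f"expected ({spec.in_channels}, L) or (n, {spec.in_channels}, L) "
            f"window, got shape {np.asarray(window).shape}")
    return w, squeeze
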