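"""Encoder and the MLP decoder baseline.

The encoder is deliberately plain: particle images enter as
phase-flipped Fourier coefficients below a resolution cutoff
(concatenated real/imaginary parts) and pass through a 3-layer MLP to a
d-dimensional latent code.  Architecture changes on the decoder side
dominate performance, so the encoder is shared verbatim between the
Point Transformer model and the MLP baseline, and the two decoders are
plug-compatible: identical output channels and bounded activations, so
the trainer, evaluator and interpretability code run unchanged with
either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Linear, Tensor
from .image_model import GmmProjector, CtfParams, ctf_2d
from .pt_decoder import (CENTER_SCALE, GATE_MAX, LOG_SIGMA_SCALE,
                         DecoderOutput)

__all__ = [
    "EncoderConfig",
    "Encoder",
    "MlpDecoder",
    "build_encoder_inputs",
]


@dataclass
class EncoderConfig:
    input_dim: int
    latent_dim: int = 4
    hidden: int = 256
    n_hidden: int = 3


def build_encoder_inputs(
    projector: GmmProjector,
    images: np.ndarray,
    ctf_list: list[CtfParams],
    cutoff: float,
    normalize: bool = True,
) -> np.ndarray:
    """Per-particle encoder input vectors.

    Fourier coefficients of each image on the projector's frequency
    subset, restricted to |k| <= cutoff (cycles/box), phase-flipped by
    the sign of that particle's CTF, split into real/imaginary parts.
    Optionally standardized per particle (zero mean, unit std).
    """
    coeffs = projector.observed_coeffs(images)          # (B, F) complex
    sub = np.sqrt(projector.k2) <= cutoff + 1e-9
    coeffs = coeffs[:, sub]
    k = np.sqrt(projector.k2[sub].astype(np.float64))
    flip = np.stack([
        np.sign(ctf_2d(c, k, projector.box_size)) for c in ctf_list
    ])
    coeffs = coeffs * flip
    x = np.concatenate([coeffs.real, coeffs.imag], axis=1).astype(np.float32)
    if normalize:
        x = (x - x.mean(axis=1, keepdims=True))
        x = x / (x.std(axis=1, keepdims=True) + 1e-8)
    return x


class Encoder:
    """MLP mapping encoder-input vectors to latent codes."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.cfg = config
        dims = [config.input_dim] + [config.hidden] * config.n_hidden \
            + [config.latent_dim]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims, dims[1:])]

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"encoder input length {x.shape[-1]} != "
                f"configured {self.cfg.input_dim}"
            )
        for l in self.layers[:-1]:
            x = l(x).relu()
        return self.layers[-1](x)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self(Tensor(np.atleast_2d(x))).data


class MlpDecoder:
    """Baseline decoder: latent -> N x 5 deltas through plain MLP layers.

    Shares the Point Transformer decoder's output activations so that
    comparisons between the two isolate the architecture.
    """

    OUT_CHANNELS = 5

    def __init__(self, latent_dim: int, n_gaussians: int,
                 rng: np.random.Generator, hidden: int = 256,
                 n_hidden: int = 3,
                 center_scale: float = CENTER_SCALE,
                 gate_max: float = GATE_MAX,
                 log_sigma_scale: float = LOG_SIGMA_SCALE):
        self.n_gaussians = n_gaussians
        self.center_scale = center_scale
        self.gate_max = gate_max
        self.log_sigma_scale = log_sigma_scale
        dims = [latent_dim] + [hidden] * n_hidden
        self.layers = [Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.head = Linear(dims[-1], n_gaussians * self.OUT_CHANNELS, rng,
                           zero=True)

    @property
    def params(self):
        ps = [p for l in self.layers for p in l.params]
        return ps + self.head.params

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params)

    def forward_raw(self, latent: Tensor) -> Tensor:
        x = latent
        for l in self.layers:
            x = l(x).relu()
        out = self.head(x)
        return out.reshape(out.shape[0], self.n_gaussians, self.OUT_CHANNELS)

    def forward_deltas(self, latent: Tensor):
        raw = self.forward_raw(latent)
        d_center = raw[..., 0:3].tanh() * self.center_scale
        gate = raw[..., 3].sigmoid() * self.gate_max
        wfac = (raw[..., 4].tanh() * self.log_sigma_scale).exp()
        return d_center, gate, wfac

    def decode(self, latent: np.ndarray) -> DecoderOutput:
        z = Tensor(np.asarray(latent, dtype=np.float32)[None, :])
        raw = self.forward_raw(z).data[0]
        return DecoderOutput(
            d_center=np.tanh(raw[:, 0:3]) * self.center_scale,
            d_amplitude=raw[:, 3].astype(np.float64),
            d_sigma=raw[:, 4].astype(np.float64),
        )
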