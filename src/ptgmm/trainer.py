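"""Unsupervised end-to-end training of encoder + decoder.

The optimization target is the Fourier-ring-correlation loss between
each observed particle and the CTF-modulated projection of its decoded
per-particle GMM:

    minimize  mean_i  FRC( CTF_i . P(R_i, apply_deltas(neutral,
                           decode(encode(x_i)))),  particle_i )

Orientations, shifts and CTF parameters are taken from the particle
metadata (poses are known inputs, not estimated here).  All randomness
(weight init, shuffling) flows from a single seed, and training on one
CPU is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .autodiff import Adam, Tensor
from .gmm_core import GaussianMixtureModel
from .image_model import CtfParams, GmmProjector
from .networks import Encoder, EncoderConfig, MlpDecoder, build_encoder_inputs
from .pt_decoder import (DecoderConfig, PointTransformerDecoder,
                         build_hierarchy)

__all__ = [
    "ParticleDataset",
    "ModelConfig",
    "TrainConfig",
    "HeteroModel",
    "InferenceResult",
    "train",
    "infer",
]


@dataclass
class ParticleDataset:
    """In-memory particle stack with per-particle pose and CTF."""

    images: np.ndarray          # (n, D, D) float32
    rot_quats: np.ndarray       # (n, 4) scipy (x, y, z, w)
    shifts_px: np.ndarray       # (n, 2)
    ctfs: list                  # n CtfParams
    pixel_size_A: float

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.rot_quats) == len(self.shifts_px)
                == len(self.ctfs) == n):
            raise ValueError("metadata rows must match particle count")

    @property
    def n_particles(self) -> int:
        return len(self.images)

    @property
    def box_size(self) -> int:
        return self.images.shape[-1]

    def rot_matrices(self) -> np.ndarray:
        return Rotation.from_quat(self.rot_quats).as_matrix()


@dataclass
class ModelConfig:
    decoder: str = "pt"              # "pt" | "mlp"
    latent_dim: int = 4
    level_sizes: tuple = (64, 256, None)
    channels: tuple = (256, 128, 64)
    k_attn: int = 16
    resid_channels: int = 32
    encoder_hidden: int = 256
    mlp_hidden: int = 256
    enc_cutoff: float | None = None  # cycles/box; default box/4

    def canonical(self) -> str:
        d = asdict(self)
        d["level_sizes"] = list(d["level_sizes"])
        d["channels"] = list(d["channels"])
        return json.dumps(d, sort_keys=True)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    max_freq: float | None = None    # loss cutoff, cycles/box; default box/3
    # which decoder channels the loss trains: "all", or restrict to
    # "amplitude" / "position" (the untouched channels stay neutral,
    # removing the amplitude-vs-motion degeneracy when the experiment
    # class is known)
    channels: str = "all"
    # L2 penalty weight on per-Gaussian center displacement (box units);
    # suppresses sub-resolution jitter of static regions that the
    # band-limited loss cannot see
    motion_l2: float = 0.0


@dataclass
class InferenceResult:
    """Per-particle decoder outputs keyed by particle index (row order)."""

    latents: np.ndarray        # (n, d)
    d_center: np.ndarray       # (n, N, 3) box units
    gate: np.ndarray           # (n, N) amplitude gate in [0, gate_max]
    width_factor: np.ndarray   # (n, N)


class HeteroModel:
    """Bundle of neutral GMM, hierarchy, encoder and decoder."""

    def __init__(self, neutral: GaussianMixtureModel, box_size: int,
                 model_cfg: ModelConfig, seed: int):
        self.neutral = neutral
        self.box_size = box_size
        self.cfg = model_cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        enc_cutoff = model_cfg.enc_cutoff or box_size / 4
        self.enc_cutoff = float(enc_cutoff)
        # encoder input length depends only on box and cutoff
        probe = GmmProjector(box_size, enc_cutoff)
        input_dim = 2 * probe.n_freqs
        self.encoder = Encoder(
            EncoderConfig(input_dim, model_cfg.latent_dim,
                          model_cfg.encoder_hidden), rng
        )
        if model_cfg.decoder == "pt":
            self.hierarchy = build_hierarchy(
                neutral.centers, model_cfg.level_sizes,
                model_cfg.k_attn, seed=seed,
            )
            dcfg = DecoderConfig(
                latent_dim=model_cfg.latent_dim,
                level_sizes=model_cfg.level_sizes,
                channels=model_cfg.channels,
                k_attn=model_cfg.k_attn,
                resid_channels=model_cfg.resid_channels,
            )
            self.decoder = PointTransformerDecoder(self.hierarchy, dcfg, rng)
        elif model_cfg.decoder == "mlp":
            self.hierarchy = None
            self.decoder = MlpDecoder(
                model_cfg.latent_dim, neutral.n_gaussians, rng,
                hidden=model_cfg.mlp_hidden,
            )
        else:
            raise ValueError(f"unknown decoder kind {model_cfg.decoder!r}")

    # ------------------------------------------------------------------
    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def config_hash(self) -> str:
        key = self.cfg.canonical() + f"|box={self.box_size}" \
            + f"|n={self.neutral.n_gaussians}|seed={self.seed}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]

    def particle_gmm_tensors(self, latent: Tensor, channels: str = "all"):
        """Decoded per-particle GMM parameters as Tensors (B, N, ...)."""
        d_center, gate, wfac = self.decoder.forward_deltas(latent)
        b = latent.shape[0]
        n = self.neutral.n_gaussians
        if channels == "amplitude":
            d_center = Tensor(np.zeros((b, n, 3), np.float32))
            wfac = Tensor(np.ones((b, n), np.float32))
        elif channels == "position":
            gate = Tensor(np.ones((b, n), np.float32))
            wfac = Tensor(np.ones((b, n), np.float32))
        elif channels != "all":
            raise ValueError(f"unknown channel mode {channels!r}")
        centers = d_center + self.neutral.centers[None].astype(np.float32)
        amps = gate * self.neutral.amplitudes[None].astype(np.float32)
        sigmas = wfac * self.neutral.widths[None].astype(np.float32)
        return centers, amps, sigmas, d_center

    # -- persistence -----------------------------------------------------
    def save(self, path):
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        meta = {
            "model_cfg": json.loads(self.cfg.canonical()),
            "box_size": self.box_size,
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }
        np.savez(
            path,
            neutral_centers=self.neutral.centers,
            neutral_amplitudes=self.neutral.amplitudes,
            neutral_widths=self.neutral.widths,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "HeteroModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            neutral = GaussianMixtureModel(
                z["neutral_centers"], z["neutral_amplitudes"],
                z["neutral_widths"],
            )
            mc = meta["model_cfg"]
            mc["level_sizes"] = tuple(mc["level_sizes"])
            mc["channels"] = tuple(mc["channels"])
            model = cls(neutral, meta["box_size"], ModelConfig(**mc),
                        meta["seed"])
            for i, p in enumerate(model.params):
                p.data = z[f"param_{i}"].astype(np.float32)
        return model


def _precompute(model: HeteroModel, dataset: ParticleDataset,
                max_freq: float):
    proj = GmmProjector(dataset.box_size, max_freq)
    obs = proj.observed_coeffs(dataset.images)
    ctf_vals = np.stack([proj.ctf_values(c) for c in dataset.ctfs])
    enc_in = build_encoder_inputs(proj, dataset.images, dataset.ctfs,
                                  model.enc_cutoff)
    rot = dataset.rot_matrices()
    shifts_box = dataset.shifts_px / dataset.box_size
    return proj, obs, ctf_vals, enc_in, rot, shifts_box


def _batch_loss(model, proj, enc_in, obs, ctf_vals, rot, shifts_box, idx,
                channels="all", motion_l2=0.0):
    z = model.encoder(Tensor(enc_in[idx]))
    centers, amps, sigmas, d_center = model.particle_gmm_tensors(z, channels)
    pred = proj.project(centers, amps, sigmas, rot[idx], shifts_box[idx])
    loss = proj.frc_loss_t(pred, obs[idx], ctf=ctf_vals[idx])
    if motion_l2:
        loss = loss + motion_l2 * (d_center * d_center).sum(axis=-1).mean()
    return loss


def train(
    dataset: ParticleDataset,
    neutral: GaussianMixtureModel,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[HeteroModel, list[float]]:
    """Train a model on a particle dataset; returns (model, loss trace).

    The trace holds the mean FRC loss per epoch.  Training aborts with a
    diagnostic if the loss goes non-finite.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    model = HeteroModel(neutral, dataset.box_size, model_cfg, train_cfg.seed)
    max_freq = train_cfg.max_freq or dataset.box_size / 3
    proj, obs, ctf_vals, enc_in, rot, shifts_box = _precompute(
        model, dataset, max_freq
    )
    n = dataset.n_particles
    bs = min(train_cfg.batch_size, n)
    steps = max(n // bs, 1) * train_cfg.epochs
    opt = Adam(model.params, lr=train_cfg.lr, total_steps=steps)
    rng = np.random.default_rng(train_cfg.seed + 1)
    trace: list[float] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            loss = _batch_loss(model, proj, enc_in, obs, ctf_vals, rot,
                               shifts_box, idx, train_cfg.channels,
                               train_cfg.motion_l2)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // bs}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


def initial_loss(dataset: ParticleDataset, model: HeteroModel,
                 max_freq: float | None = None) -> float:
    """Mean FRC loss of the current model state over the whole dataset."""
    max_freq = max_freq or dataset.box_size / 3
    proj, obs, ctf_vals, enc_in, rot, shifts_box = _precompute(
        model, dataset, max_freq
    )
    losses = []
    for start in range(0, dataset.n_particles, 256):
        idx = np.arange(start, min(start + 256, dataset.n_particles))
        loss = _batch_loss(model, proj, enc_in, obs, ctf_vals, rot,
                           shifts_box, idx)
        losses.append(float(loss.data) * len(idx))
    return sum(losses) / dataset.n_particles


def infer(model: HeteroModel, dataset: ParticleDataset,
          expected_hash: str | None = None,
          batch_size: int = 256) -> InferenceResult:
    """Deterministic forward pass over all particles."""
    if expected_hash is not None and expected_hash != model.config_hash():
        raise ValueError("checkpoint config hash does not match request")
    if dataset.box_size != model.box_size:
        raise ValueError("dataset box size does not match model")
    proj = GmmProjector(model.box_size, model.enc_cutoff)
    enc_in = build_encoder_inputs(proj, dataset.images, dataset.ctfs,
                                  model.enc_cutoff)
    n = dataset.n_particles
    ngauss = model.neutral.n_gaussians
    d = model.cfg.latent_dim
    latents = np.zeros((n, d), dtype=np.float32)
    d_center = np.zeros((n, ngauss, 3), dtype=np.float32)
    gate = np.zeros((n, ngauss), dtype=np.float32)
    wfac = np.zeros((n, ngauss), dtype=np.float32)
    from .autodiff import no_grad

    with no_grad():
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            z = model.encoder(Tensor(enc_in[sl]))
            dc, g, w = model.decoder.forward_deltas(z)
            latents[sl] = z.data
            d_center[sl] = dc.data
            gate[sl] = g.data
            wfac[sl] = w.data
    return InferenceResult(latents, d_center, gate, wfac)
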