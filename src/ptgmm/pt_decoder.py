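"""Upsampling Point Transformer decoder over a precomputed GMM hierarchy.

The decoder maps a low-dimensional conformation code to per-Gaussian
deltas (Δcenter, Δamplitude, Δσ) of the neutral mixture.  The geometry
of the point cloud is fixed per dataset, so the multi-level point sets
(coarse → full, default 64 / 256 / N), the k-nearest-neighbor tables for
self-attention, and the 3-NN inverse-distance interpolation tables for
transition-up are all precomputed once from the neutral GMM.

Per level the decoder runs a vector self-attention block

    y_i = sum_{j in N(i)} softmax_j( gamma(phi(x_i) - psi(x_j) + d_ij) )
          ⊙ ( alpha(x_j) + d_ij ),      d_ij = theta(p_i - p_j)

with learned MLPs gamma/theta and linear maps phi/psi/alpha, a residual
connection around the block, and interpolation-based upsampling between
levels.  The outputs of the first two levels are additionally upsampled
straight to the full point set ("residual branches") and concatenated
before the final pointwise head, which emits 5 channels per Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .autodiff import Linear, ScatterPlan, Tensor, concatenate
from .gmm_core import GaussianMixtureModel

__all__ = [
    "PointHierarchy",
    "DecoderOutput",
    "DecoderConfig",
    "build_hierarchy",
    "PtBlock",
    "transition_up",
    "PointTransformerDecoder",
    "apply_deltas",
    "apply_deltas_batch_numpy",
    "GATE_MAX",
    "CENTER_SCALE",
    "LOG_SIGMA_SCALE",
]

# bounded output activations: tanh * CENTER_SCALE box units on Δcenter,
# sigmoid * GATE_MAX amplitude gate, tanh * LOG_SIGMA_SCALE on log-width
CENTER_SCALE = 0.1
GATE_MAX = 2.0
LOG_SIGMA_SCALE = 0.5


@dataclass
class PointHierarchy:
    """Precomputed point sets, kNN and upsampling tables for the decoder."""

    level_points: list[np.ndarray]       # per level (P_l, 3)
    neighbor_idx: list[np.ndarray]       # per level (P_l, k)
    up_idx: list[np.ndarray]             # per level pair (P_{l+1}, 3)
    up_weight: list[np.ndarray]          # per level pair (P_{l+1}, 3)
    resid_idx: list[np.ndarray]          # levels 0..L-2 -> full (N, 3)
    resid_weight: list[np.ndarray]

    def __post_init__(self):
        sizes = [len(p) for p in self.level_points]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("level sizes must be strictly increasing")
        for w in self.up_weight + self.resid_weight:
            if not np.allclose(w.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("interpolation weights must sum to 1")

    @property
    def n_levels(self) -> int:
        return len(self.level_points)

    @property
    def n_full(self) -> int:
        return len(self.level_points[-1])


@dataclass
class DecoderOutput:
    """Per-particle GMM deltas.

    ``d_center`` is already in box units (post-activation); ``d_amplitude``
    and ``d_sigma`` are raw pre-gate values — :func:`apply_deltas` turns
    them into the bounded amplitude gate and width factor.
    """

    d_center: np.ndarray      # (N, 3) box units
    d_amplitude: np.ndarray   # (N,) raw; gate = GATE_MAX * sigmoid(raw)
    d_sigma: np.ndarray       # (N,) raw; factor = exp(LOG_SIGMA_SCALE*tanh(raw))

    def amplitude_gate(self) -> np.ndarray:
        return GATE_MAX / (1.0 + np.exp(-self.d_amplitude))

    def width_factor(self) -> np.ndarray:
        return np.exp(LOG_SIGMA_SCALE * np.tanh(self.d_sigma))


def _interp_tables(fine: np.ndarray, coarse: np.ndarray):
    """3-NN inverse-distance interpolation tables fine <- coarse."""
    k = min(3, len(coarse))
    tree = cKDTree(coarse)
    dist, idx = tree.query(fine, k=k)
    dist = np.atleast_2d(dist).reshape(len(fine), k)
    idx = np.atleast_2d(idx).reshape(len(fine), k)
    w = 1.0 / np.maximum(dist, 1e-12)
    exact = dist[:, 0] < 1e-12          # coincident point takes all weight
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    if k < 3:                            # pad to fixed width
        pad = 3 - k
        idx = np.concatenate([idx, np.repeat(idx[:, :1], pad, axis=1)], axis=1)
        w = np.concatenate([w, np.zeros((len(fine), pad))], axis=1)
    return idx.astype(np.int64), w.astype(np.float64)


def build_hierarchy(
    neutral_centers: np.ndarray,
    level_sizes: tuple[int, ...] = (64, 256, None),
    k_attn: int = 16,
    seed: int = 0,
) -> PointHierarchy:
    """K-means point hierarchy over the neutral GMM centers.

    ``level_sizes`` must be ascending and end with the full model size
    (``None`` is replaced by N).  Intermediate levels are k-means
    centroids of the neutral centers; the last level is the centers
    themselves.  kNN tables (k_attn, including self) and interpolation
    tables are computed once.
    """
    pts = np.asarray(neutral_centers, dtype=np.float64)
    n = len(pts)
    sizes = [n if s is None else int(s) for s in level_sizes]
    # a small model may not support the default coarse sizes; drop
    # any level not strictly smaller than the next
    sizes = [s for i, s in enumerate(sizes)
             if s < min(sizes[i + 1:], default=n + 1)]
    if sizes[-1] != n:
        if sizes[-1] > n:
            raise ValueError(f"level size {sizes[-1]} exceeds model size {n}")
        sizes.append(n)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("level sizes must be ascending")

    level_points = []
    for s in sizes[:-1]:
        km = KMeans(n_clusters=s, n_init=10, random_state=seed).fit(pts)
        level_points.append(km.cluster_centers_.astype(np.float64))
    level_points.append(pts)

    neighbor_idx = []
    for p in level_points:
        k = min(k_attn, len(p))
        _, idx = cKDTree(p).query(p, k=k)
        neighbor_idx.append(np.atleast_2d(idx).reshape(len(p), k))

    up_idx, up_weight = [], []
    for coarse, fine in zip(level_points, level_points[1:]):
        i, w = _interp_tables(fine, coarse)
        up_idx.append(i)
        up_weight.append(w)
    resid_idx, resid_weight = [], []
    for coarse in level_points[:-1]:
        i, w = _interp_tables(level_points[-1], coarse)
        resid_idx.append(i)
        resid_weight.append(w)
    return PointHierarchy(level_points, neighbor_idx, up_idx, up_weight,
                          resid_idx, resid_weight)


# ---------------------------------------------------------------------------
# network blocks
# ---------------------------------------------------------------------------


class PtBlock:
    """Vector self-attention over precomputed k nearest neighbors."""

    def __init__(self, channels: int, points: np.ndarray,
                 neighbor_idx: np.ndarray, rng: np.random.Generator,
                 pos_hidden: int = 32):
        c = channels
        self.phi = Linear(c, c, rng)
        self.psi = Linear(c, c, rng)
        self.alpha = Linear(c, c, rng)
        self.gamma1 = Linear(c, c, rng)
        self.gamma2 = Linear(c, c, rng)
        self.theta1 = Linear(3, pos_hidden, rng)
        self.theta2 = Linear(pos_hidden, c, rng)
        self.idx = np.asarray(neighbor_idx, dtype=np.int64)
        self.plan = ScatterPlan(self.idx, len(points))
        # relative positions are fixed per dataset: (P, k, 3)
        p = np.asarray(points, dtype=np.float32)
        self.rel_pos = Tensor(p[:, None, :] - p[self.idx])

    @property
    def params(self):
        layers = (self.phi, self.psi, self.alpha, self.gamma1, self.gamma2,
                  self.theta1, self.theta2)
        return [p for l in layers for p in l.params]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, P, C) -> (B, P, C) with residual connection."""
        delta = self.theta2(self.theta1(self.rel_pos).relu())   # (P, k, C)
        q = self.phi(x)                                         # (B, P, C)
        k = self.psi(x).neighbor_gather(self.idx, self.plan)    # (B, P, k, C)
        v = self.alpha(x).neighbor_gather(self.idx, self.plan)  # (B, P, k, C)
        scores = q.reshape(*q.shape[:-1], 1, q.shape[-1]) - k + delta
        scores = self.gamma2(self.gamma1(scores).relu())
        attn = scores.softmax(axis=-2)                          # over k
        y = (attn * (v + delta)).sum(axis=-2)
        return x + y


def transition_up(coarse_feat: Tensor, up_idx: np.ndarray,
                  up_weight: np.ndarray, proj: Linear | None = None,
                  plan: ScatterPlan | None = None) -> Tensor:
    """Inverse-distance interpolation of features coarse -> fine.

    coarse_feat: (B, P1, C1) -> (B, P2, C_out); the optional linear
    projection changes the channel width before interpolation.
    """
    f = proj(coarse_feat) if proj is not None else coarse_feat
    gathered = f.neighbor_gather(np.asarray(up_idx, dtype=np.int64), plan)
    w = Tensor(np.asarray(up_weight, dtype=np.float32)[..., None])
    return (gathered * w).sum(axis=-2)


@dataclass
class DecoderConfig:
    latent_dim: int = 4
    level_sizes: tuple = (64, 256, None)
    channels: tuple = (256, 128, 64)     # per-level attention width
    k_attn: int = 16
    resid_channels: int = 32
    seed_hidden: int = 128
    center_scale: float = CENTER_SCALE
    gate_max: float = GATE_MAX
    log_sigma_scale: float = LOG_SIGMA_SCALE


class PointTransformerDecoder:
    """Latent code -> per-Gaussian deltas through upsampling PT levels."""

    OUT_CHANNELS = 5        # Δx, Δy, Δz, Δamplitude, Δσ

    def __init__(self, hierarchy: PointHierarchy, config: DecoderConfig,
                 rng: np.random.Generator):
        self.h = hierarchy
        self.cfg = config
        nl = hierarchy.n_levels
        ch = list(config.channels)[:nl]
        while len(ch) < nl:
            ch.append(ch[-1])
        self.ch = ch
        p0 = len(hierarchy.level_points[0])
        self.p0 = p0
        self.seed1 = Linear(config.latent_dim, config.seed_hidden, rng)
        self.seed2 = Linear(config.seed_hidden, p0 * ch[0], rng)
        self.blocks = [
            PtBlock(ch[l], hierarchy.level_points[l],
                    hierarchy.neighbor_idx[l], rng)
            for l in range(nl)
        ]
        self.up_proj = [
            Linear(ch[l], ch[l + 1], rng) for l in range(nl - 1)
        ]
        self.resid_proj = [
            Linear(ch[l], config.resid_channels, rng) for l in range(nl - 1)
        ]
        self.up_plans = [
            ScatterPlan(hierarchy.up_idx[l], len(hierarchy.level_points[l]))
            for l in range(nl - 1)
        ]
        self.resid_plans = [
            ScatterPlan(hierarchy.resid_idx[l], len(hierarchy.level_points[l]))
            for l in range(nl - 1)
        ]
        head_in = ch[-1] + config.resid_channels * (nl - 1)
        # zero-initialized head: an untrained decoder is the identity
        # (all deltas zero, particle GMM = neutral GMM)
        self.head = Linear(head_in, self.OUT_CHANNELS, rng, zero=True)

    @property
    def params(self):
        ps = self.seed1.params + self.seed2.params + self.head.params
        for b in self.blocks:
            ps += b.params
        for l in self.up_proj + self.resid_proj:
            ps += l.params
        return ps

    def latent_seed(self, latent: Tensor) -> Tensor:
        """(B, d) latent -> (B, 64, C0) features on the coarsest points."""
        z = self.seed2(self.seed1(latent).relu())
        return z.reshape(z.shape[0], self.p0, self.ch[0])

    def forward_raw(self, latent: Tensor) -> Tensor:
        """(B, d) -> (B, N, 5) raw head output (pre-activation)."""
        x = self.latent_seed(latent)
        resid = []
        for l, block in enumerate(self.blocks):
            x = block(x)
            if l < len(self.blocks) - 1:
                resid.append(
                    transition_up(x, self.h.resid_idx[l],
                                  self.h.resid_weight[l], self.resid_proj[l],
                                  self.resid_plans[l])
                )
                x = transition_up(x, self.h.up_idx[l], self.h.up_weight[l],
                                  self.up_proj[l], self.up_plans[l])
        full = concatenate([x] + resid, axis=-1)
        return self.head(full)

    def forward_deltas(self, latent: Tensor):
        """Raw head output -> bounded (d_center, gate, width_factor) Tensors.

        Shapes: (B, N, 3), (B, N), (B, N).
        """
        raw = self.forward_raw(latent)
        d_center = raw[..., 0:3].tanh() * self.cfg.center_scale
        gate = raw[..., 3].sigmoid() * self.cfg.gate_max
        wfac = (raw[..., 4].tanh() * self.cfg.log_sigma_scale).exp()
        return d_center, gate, wfac

    def decode(self, latent: np.ndarray) -> DecoderOutput:
        """Single-latent convenience wrapper returning numpy deltas."""
        z = Tensor(np.asarray(latent, dtype=np.float32)[None, :])
        raw = self.forward_raw(z).data[0]
        if raw.shape != (self.h.n_full, self.OUT_CHANNELS):
            raise AssertionError("decoder output shape mismatch")
        return DecoderOutput(
            d_center=np.tanh(raw[:, 0:3]) * self.cfg.center_scale,
            d_amplitude=raw[:, 3].astype(np.float64),
            d_sigma=raw[:, 4].astype(np.float64),
        )


def apply_deltas(neutral: GaussianMixtureModel,
                 delta: DecoderOutput) -> GaussianMixtureModel:
    """Per-particle GMM = neutral GMM perturbed by the decoder output."""
    n = neutral.n_gaussians
    if delta.d_center.shape != (n, 3):
        raise ValueError("delta shape does not match neutral GMM")
    try:
        return GaussianMixtureModel(
            neutral.centers + delta.d_center,
            neutral.amplitudes * delta.amplitude_gate(),
            neutral.widths * delta.width_factor(),
        )
    except ValueError as e:
        raise ValueError(f"deltas violate GMM invariants: {e}") from e


def apply_deltas_batch_numpy(neutral: GaussianMixtureModel,
                             d_center: np.ndarray, gate: np.ndarray,
                             wfac: np.ndarray):
    """Vectorized (B, ...) variant used by evaluation code."""
    centers = neutral.centers[None] + d_center
    amps = neutral.amplitudes[None] * gate
    widths = neutral.widths[None] * wfac
    return centers, amps, widths
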