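"""Synthetic cryo-EM datasets with complete ground truth.

Two experiment classes are generated, mirroring the canonical hard
cases for heterogeneity analysis:

* **Compositional** — a structure divided into K segments where every
  non-core segment is independently absent with probability ``p_absent``
  per particle (ribosome-assembly-style intermediates; with K = 9 and
  p = 0.5 the ensemble spans 2^8 = 256 states).
* **Conformational** — chosen regions rigidly rotated about fixed axes
  by independent uniform random angles per particle (continuous domain
  tilting, ABC-transporter-style).

Particles are rendered as noisy CTF-modulated projections with
quasi-evenly distributed orientations; poses and CTFs are recorded in
the metadata, and the ground truth (presence masks or per-atom
displacements) in a sidecar table.  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

from .gmm_core import Structure
from .image_model import CtfParams, FourierGrid, fourier_to_image
from .trainer import ParticleDataset

__all__ = [
    "CompositionGroundTruth",
    "MotionGroundTruth",
    "make_toy_structure",
    "simulate_compositional",
    "simulate_motion",
    "render_particles",
    "quasi_uniform_rotations",
]


@dataclass
class CompositionGroundTruth:
    presence: np.ndarray      # (n, K) bool; column 0 (core) all True
    state_id: np.ndarray      # (n,) int, binary encoding of columns 1..K-1

    def __post_init__(self):
        if not self.presence[:, 0].all():
            raise ValueError("core segment must always be present")
        enc = _encode_states(self.presence)
        if not np.array_equal(enc, self.state_id):
            raise ValueError("state_id inconsistent with presence rows")

    def to_frame(self) -> pd.DataFrame:
        k = self.presence.shape[1]
        df = pd.DataFrame(
            self.presence.astype(int),
            columns=[f"seg_{i}" for i in range(k)],
        )
        df["state_id"] = self.state_id
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionGroundTruth":
        segs = [c for c in df.columns if c.startswith("seg_")]
        return cls(df[segs].to_numpy().astype(bool),
                   df["state_id"].to_numpy().astype(np.int64))


def _encode_states(presence: np.ndarray) -> np.ndarray:
    toggle = presence[:, 1:].astype(np.int64)
    powers = 2 ** np.arange(toggle.shape[1])
    return toggle @ powers


@dataclass
class MotionGroundTruth:
    angles_deg: np.ndarray        # (n, R)
    displacement_A: np.ndarray    # (n, M, 3) per-atom movement from neutral
    moving_mask: np.ndarray       # (M,) bool: atoms inside moving regions

    def __post_init__(self):
        off = self.displacement_A[:, ~self.moving_mask, :]
        if off.size and np.abs(off).max() > 1e-9:
            raise ValueError("displacement must be zero outside regions")

    def per_particle_rmsd_A(self) -> np.ndarray:
        """RMSD of the true movement over all atoms (the rigid baseline)."""
        return np.sqrt(
            (self.displacement_A**2).sum(axis=2).mean(axis=1)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.angles_deg,
            columns=[f"angle_{i}" for i in range(self.angles_deg.shape[1])],
        )


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def make_toy_structure(
    n_segments: int = 9,
    pts_per_segment: int = 60,
    seed: int = 0,
    core_radius_A: float = 24.0,
    blob_radius_A: float = 11.0,
    shell_radius_A: float = 46.0,
    box_size_A: float = 140.0,
) -> Structure:
    """Segmented blob model: one central core + peripheral segments.

    Segment 0 is a large spherical core blob; segments 1..K-1 are
    compact blobs placed on a shell around it, pairwise separated by at
    least one blob radius.  Stands in for a segmented large complex in
    the download-free experiments.
    """
    if n_segments < 2:
        raise ValueError("need at least a core and one peripheral segment")
    rng = np.random.default_rng(seed)
    n_per = n_segments - 1
    # even shell placement: golden-spiral directions, then check packing
    i = np.arange(n_per)
    phi = np.arccos(1 - 2 * (i + 0.5) / n_per)
    theta = np.pi * (1 + 5**0.5) * (i + 0.5)
    dirs = np.stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ], axis=1)
    centers = dirs * shell_radius_A
    min_sep = blob_radius_A * 3.0        # centers >= 3r => gap >= 1 blob radius
    if n_per > 1:
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < min_sep:
            raise ValueError(
                "cannot pack segments without overlap; reduce n_segments "
                "or blob_radius_A, or increase shell_radius_A"
            )
    if shell_radius_A - core_radius_A < blob_radius_A * 2.0:
        raise ValueError("shell too close to core; increase shell_radius_A")

    coords, labels = [], []
    core_n = pts_per_segment * 3         # core is the largest piece
    coords.append(_blob(rng, core_n, core_radius_A))
    labels.append(np.zeros(core_n, dtype=np.int64))
    for s in range(1, n_segments):
        npts = pts_per_segment + int(rng.integers(-pts_per_segment // 4,
                                                  pts_per_segment // 4 + 1))
        coords.append(centers[s - 1] + _blob(rng, npts, blob_radius_A))
        labels.append(np.full(npts, s, dtype=np.int64))
    coords = np.concatenate(coords)
    labels = np.concatenate(labels)
    if np.abs(coords).max() > box_size_A / 2:
        raise ValueError("box_size_A too small for the requested geometry")
    weights = np.ones(len(coords))
    return Structure(coords, labels, weights, box_size_A)


def _blob(rng, n, radius):
    """Roughly uniform ball of points with soft edges."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.uniform(0, 1, size=(n, 1)) ** (1 / 3)
    return pts * r


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------


def simulate_compositional(
    structure: Structure,
    n_particles: int,
    p_absent: float = 0.5,
    seed: int = 0,
) -> tuple[list[np.ndarray], CompositionGroundTruth]:
    """Per-particle coordinates with segments independently dropped.

    Segment 0 (core) is always present; each other segment is present
    with probability 1 - p_absent, independently per particle.
    Returns per-particle atom index arrays (into structure.coordinates)
    plus the ground-truth presence table.
    """
    k = structure.n_segments
    if k < 2:
        raise ValueError("structure must have >= 2 segments")
    rng = np.random.default_rng(seed)
    presence = np.ones((n_particles, k), dtype=bool)
    presence[:, 1:] = rng.random((n_particles, k - 1)) >= p_absent
    truth = CompositionGroundTruth(presence, _encode_states(presence))
    atom_indices = [
        np.flatnonzero(presence[i][structure.segment_labels])
        for i in range(n_particles)
    ]
    return atom_indices, truth


def simulate_motion(
    structure: Structure,
    regions: list[int],
    axes: list[tuple[np.ndarray, np.ndarray]],
    angle_range_deg: float,
    n_particles: int,
    seed: int = 0,
) -> tuple[np.ndarray, MotionGroundTruth]:
    """Rigidly rotate each region about its axis by a random angle.

    ``axes[r]`` is (point_on_axis_A, unit_direction); angles are drawn
    independently per particle and region from
    Uniform(-angle_range/2, +angle_range/2) degrees.

    Returns per-particle coordinates (n, M, 3) in Å and the ground truth
    (angles + per-atom displacements).
    """
    if len(set(regions)) != len(regions):
        raise ValueError("regions must be disjoint segment ids")
    for _, direction in axes:
        if abs(np.linalg.norm(direction) - 1.0) > 1e-8:
            raise ValueError("axis directions must be unit norm")
    if len(axes) != len(regions):
        raise ValueError("one axis per region")
    rng = np.random.default_rng(seed)
    m = len(structure.coordinates)
    angles = rng.uniform(-angle_range_deg / 2, angle_range_deg / 2,
                         size=(n_particles, len(regions)))
    coords = np.broadcast_to(
        structure.coordinates, (n_particles, m, 3)
    ).copy()
    moving = np.zeros(m, dtype=bool)
    for r, (seg, (point, direction)) in enumerate(zip(regions, axes)):
        sel = structure.segment_labels == seg
        moving |= sel
        base = structure.coordinates[sel] - point
        rots = Rotation.from_rotvec(
            np.deg2rad(angles[:, r])[:, None] * np.asarray(direction)[None, :]
        )
        moved = np.einsum("nij,mj->nmi", rots.as_matrix(), base) + point
        coords[:, sel, :] = moved
    disp = coords - structure.coordinates
    truth = MotionGroundTruth(angles, disp, moving)
    return coords, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def quasi_uniform_rotations(n: int, seed: int = 0) -> Rotation:
    """Low-discrepancy covering of SO(3).

    Halton points mapped through the subgroup algorithm for uniform
    quaternions (Shoemake); deterministic for a given seed.
    """
    h = qmc.Halton(d=3, scramble=True, seed=seed).random(n)
    u1, u2, u3 = h[:, 0], h[:, 1], h[:, 2]
    q = np.stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ], axis=1)
    return Rotation.from_quat(q)


def _atom_projection_fourier(coords_box, weights, sigma_box, rot_mat, grid):
    """Fourier half-plane of a Gaussian-splat projection of atoms."""
    u = coords_box @ rot_mat.T
    s2 = sigma_box**2
    env = weights[:, None, None] * (2.0 * np.pi * s2) * np.exp(
        -2.0 * np.pi**2 * s2 * grid.kmag**2
    )
    phase = -2.0 * np.pi * (
        grid.kx * u[:, 0, None, None] + grid.ky * u[:, 1, None, None]
    )
    return (env * np.exp(1j * phase)).sum(axis=0)


def render_particles(
    per_particle_coords,
    box_size: int,
    pixel_size_A: float,
    box_size_A: float,
    snr: float = 0.1,
    defocus_range_um: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    weights: np.ndarray | None = None,
    atom_sigma_A: float = 3.0,
    voltage_kv: float = 300.0,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.1,
) -> tuple[ParticleDataset, pd.DataFrame]:
    """Render atom coordinate sets into a noisy CTF-modulated stack.

    ``per_particle_coords`` is either an (n, M, 3) array (Å) or a list
    of per-particle (M_i, 3) arrays (compositional data has variable
    atom counts).  Orientations come from a low-discrepancy rotation
    sequence ("evenly distributed"); defocus is Uniform over the range;
    white Gaussian noise is scaled so that per-dataset
    signal-variance / noise-variance = snr (``snr=inf`` disables noise).

    Returns the in-memory dataset plus a STAR-style metadata table.
    """
    n = len(per_particle_coords)
    rng = np.random.default_rng(seed)
    rots = quasi_uniform_rotations(n, seed=seed)
    quats = rots.as_quat()
    mats = rots.as_matrix()
    defoci = rng.uniform(*defocus_range_um, size=n)
    grid = FourierGrid(box_size)
    sigma_box = atom_sigma_A / box_size_A
    d = box_size
    images = np.empty((n, d, d), dtype=np.float32)
    ctfs = []
    signal_var = 0.0
    from .image_model import ctf_2d  # local import to avoid cycle at top

    for i in range(n):
        coords_box = np.asarray(per_particle_coords[i]) / box_size_A
        w = (np.ones(len(coords_box)) if weights is None
             else np.asarray(weights[i]))
        f = _atom_projection_fourier(coords_box, w, sigma_box, mats[i], grid)
        ctf = CtfParams(defocus_um=float(defoci[i]), voltage_kv=voltage_kv,
                        cs_mm=cs_mm, amplitude_contrast=amplitude_contrast,
                        pixel_size_A=pixel_size_A)
        f *= ctf_2d(ctf, grid.kmag, box_size)
        img = fourier_to_image(f, box_size)
        images[i] = img
        ctfs.append(ctf)
        signal_var += img.var()
    signal_var /= n
    if np.isfinite(snr):
        noise_std = np.sqrt(signal_var / snr)
        images += rng.normal(0.0, noise_std, size=images.shape).astype(
            np.float32
        )
    shifts = np.zeros((n, 2))
    euler = rots.as_euler("ZYZ", degrees=True)
    meta = pd.DataFrame({
        "rlnAngleRot": euler[:, 0],
        "rlnAngleTilt": euler[:, 1],
        "rlnAnglePsi": euler[:, 2],
        "rlnOriginXAngst": shifts[:, 0] * pixel_size_A,
        "rlnOriginYAngst": shifts[:, 1] * pixel_size_A,
        "rlnDefocusU": defoci * 1e4,
        "rlnDefocusV": defoci * 1e4,
        "rlnDefocusAngle": np.zeros(n),
        "rlnVoltage": np.full(n, voltage_kv),
        "rlnSphericalAberration": np.full(n, cs_mm),
        "rlnAmplitudeContrast": np.full(n, amplitude_contrast),
        "rlnImagePixelSize": np.full(n, pixel_size_A),
    })
    dataset = ParticleDataset(images, quats, shifts, ctfs, pixel_size_A)
    return dataset, meta
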