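"""Forward image-formation model and training loss.

A per-particle Gaussian mixture is projected analytically in Fourier
space, modulated by the contrast transfer function (CTF), and compared
to the observed particle image with a Fourier-ring-correlation (FRC)
loss.  All three steps are differentiable with respect to the Gaussian
parameters, either through the autodiff engine or through the fused
projection primitive with a hand-written adjoint.

Fourier convention (normative)
------------------------------
Half-plane layout as produced by ``numpy.fft.rfft2``, DC at index
(0, 0); frequencies are measured in cycles per box edge, so on a D-pixel
box the integer grid runs to Nyquist at D/2.  Phases are referenced to
the box *center*: a Gaussian at box-normalized position u contributes

    amp * (2 pi sigma^2) * exp(-2 pi^2 sigma^2 |k|^2) * exp(-2 pi i k.u)

``fourier_to_image`` / ``image_to_fourier`` convert between this
convention and real-space images (box center at pixel (D/2, D/2)).

CTF sign convention: underfocus positive, leading minus sign
(RELION/CTFFIND):  CTF(k) = -( sqrt(1-A^2) sin chi + A cos chi ) * env.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .autodiff import Tensor
from .gmm_core import GaussianMixtureModel

__all__ = [
    "CtfParams",
    "ParticleRecord",
    "FourierGrid",
    "electron_wavelength_A",
    "ctf_2d",
    "ctf_apply",
    "project_gmm",
    "fourier_to_image",
    "image_to_fourier",
    "frc_loss",
    "GmmProjector",
]


@dataclass
class CtfParams:
    defocus_um: float = 1.5        # underfocus positive
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1
    b_factor_A2: float = 0.0
    pixel_size_A: float = 1.0

    def __post_init__(self):
        if self.pixel_size_A <= 0:
            raise ValueError("pixel_size must be positive")
        if self.voltage_kv <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class ParticleRecord:
    """One particle: image plus its known pose and CTF."""

    image: np.ndarray              # (D, D) real
    rotation: np.ndarray           # unit quaternion (x, y, z, w), scipy order
    shift_px: np.ndarray           # (2,) translation in pixels
    ctf: CtfParams

    def __post_init__(self):
        d = self.image.shape[0]
        if self.image.shape != (d, d) or d % 2:
            raise ValueError("image must be square with even side")
        q = np.asarray(self.rotation, dtype=np.float64)
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("rotation quaternion must be unit norm")
        self.rotation = q
        self.shift_px = np.asarray(self.shift_px, dtype=np.float64)


def electron_wavelength_A(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


class FourierGrid:
    """Frequency bookkeeping for a D-pixel box (rfft2 half-plane)."""

    def __init__(self, box_size: int):
        if box_size < 16 or box_size % 2:
            raise ValueError("box size must be even and >= 16")
        self.box_size = box_size
        d = box_size
        ky = np.fft.fftfreq(d) * d           # integer cycles/box
        kx = np.fft.rfftfreq(d) * d
        self.kx = np.broadcast_to(kx[None, :], (d, d // 2 + 1)).copy()
        self.ky = np.broadcast_to(ky[:, None], (d, d // 2 + 1)).copy()
        self.kmag = np.sqrt(self.kx**2 + self.ky**2)
        self.ring = np.rint(self.kmag).astype(np.int64)
        # checkerboard phase = shift by half a box in both axes
        self.center_phase = (-1.0) ** np.rint(
            np.abs(self.kx) + np.abs(self.ky)
        )

    def mask(self, max_freq: float) -> np.ndarray:
        """Boolean half-plane mask of |k| <= max_freq (cycles/box)."""
        return self.kmag <= max_freq + 1e-9

    def masked_freqs(self, max_freq: float):
        """Flat frequency list under the mask: (kxy (F,2), ring (F,))."""
        m = self.mask(max_freq)
        kxy = np.stack([self.kx[m], self.ky[m]], axis=1)
        return kxy, self.ring[m]


def ctf_2d(ctf: CtfParams, kmag_cycles: np.ndarray, box_size: int) -> np.ndarray:
    """Evaluate the CTF at frequencies given in cycles/box."""
    k_inv_A = kmag_cycles / (box_size * ctf.pixel_size_A)   # 1/Å
    lam = electron_wavelength_A(ctf.voltage_kv)
    z = ctf.defocus_um * 1e4                                 # Å
    cs = ctf.cs_mm * 1e7                                     # Å
    chi = np.pi * lam * z * k_inv_A**2 \
        - 0.5 * np.pi * cs * lam**3 * k_inv_A**4
    a = ctf.amplitude_contrast
    c = -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    if ctf.b_factor_A2 != 0.0:
        c = c * np.exp(-ctf.b_factor_A2 * k_inv_A**2 / 4.0)
    return c


def ctf_apply(fimage: np.ndarray, ctf: CtfParams,
              grid: FourierGrid) -> np.ndarray:
    """Multiply a half-plane Fourier image by the CTF."""
    return fimage * ctf_2d(ctf, grid.kmag, grid.box_size)


def project_gmm(
    gmm: GaussianMixtureModel,
    rotation: np.ndarray,
    shift_px: np.ndarray,
    box_size: int,
    pixel_size_A: float = 1.0,
) -> np.ndarray:
    """Analytic Fourier-space projection of a GMM (full half-plane).

    The model is rotated into the lab frame (r_lab = R r_model), the z
    axis is integrated out, and each Gaussian contributes its closed
    form.  ``shift_px`` translates the projection in the image plane.
    """
    grid = FourierGrid(box_size)
    rot = Rotation.from_quat(np.asarray(rotation, dtype=np.float64))
    u = gmm.centers @ rot.as_matrix().T          # lab-frame centers
    uxy = u[:, :2] + np.asarray(shift_px, dtype=np.float64) / box_size
    s2 = gmm.widths**2
    env = gmm.amplitudes[:, None, None] * (2.0 * np.pi * s2)[:, None, None] \
        * np.exp(-2.0 * np.pi**2 * s2[:, None, None] * grid.kmag**2)
    phase = -2.0 * np.pi * (
        grid.kx * uxy[:, 0, None, None] + grid.ky * uxy[:, 1, None, None]
    )
    return (env * np.exp(1j * phase)).sum(axis=0)


def fourier_to_image(fimage: np.ndarray, box_size: int) -> np.ndarray:
    """Centered-convention Fourier half-plane -> real-space image."""
    grid = FourierGrid(box_size)
    return np.fft.irfft2(fimage * grid.center_phase, s=(box_size, box_size)) \
        * box_size**2


def image_to_fourier(image: np.ndarray) -> np.ndarray:
    """Real-space image -> centered-convention Fourier half-plane."""
    d = image.shape[0]
    grid = FourierGrid(d)
    return np.fft.rfft2(image) * grid.center_phase / d**2


def frc_loss(
    predicted: np.ndarray,
    observed: np.ndarray,
    max_freq: float,
    box_size: int,
) -> float:
    """Negative mean Fourier-ring correlation over rings <= max_freq.

    Bounded in [-1, 1]; equals -1 when predicted is a positive per-ring
    rescaling of observed.  All-zero rings contribute 0.
    """
    if predicted.shape != observed.shape:
        raise ValueError("shape mismatch")
    if max_freq > box_size / 2:
        raise ValueError("max_freq beyond Nyquist")
    grid = FourierGrid(box_size)
    m = grid.mask(max_freq)
    ring = grid.ring[m]
    p, o = predicted[m], observed[m]
    nr = int(ring.max()) + 1
    cross = np.bincount(ring, weights=(p * o.conj()).real, minlength=nr)
    pp = np.bincount(ring, weights=np.abs(p) ** 2, minlength=nr)
    oo = np.bincount(ring, weights=np.abs(o) ** 2, minlength=nr)
    denom = np.sqrt(pp * oo)
    corr = np.divide(cross, denom, out=np.zeros_like(cross),
                     where=denom > 0)
    return float(-corr.mean())


# ---------------------------------------------------------------------------
# differentiable, batched path used by the trainer
# ---------------------------------------------------------------------------


class GmmProjector:
    """Batched differentiable projection + FRC loss on a frequency subset.

    Training never needs the full Nyquist half-plane: frequencies are
    restricted to |k| <= max_freq once, and per-particle observed
    coefficients / CTF values are precomputed on that subset.
    """

    def __init__(self, box_size: int, max_freq: float):
        self.box_size = box_size
        self.max_freq = float(max_freq)
        self.grid = FourierGrid(box_size)
        self.fmask = self.grid.mask(max_freq)
        kxy, ring = self.grid.masked_freqs(max_freq)
        self.kxy = kxy.astype(np.float32)                  # (F, 2)
        self.k2 = (kxy**2).sum(axis=1).astype(np.float32)  # (F,)
        self.ring = ring
        nr = int(ring.max()) + 1
        ringmat = np.zeros((len(ring), nr), dtype=np.float32)
        ringmat[np.arange(len(ring)), ring] = 1.0
        self.ringmat = ringmat

    @property
    def n_freqs(self) -> int:
        return len(self.k2)

    def observed_coeffs(self, images: np.ndarray) -> np.ndarray:
        """(B, D, D) images -> (B, F) complex coefficients on the subset."""
        d = self.box_size
        f = np.fft.rfft2(images, axes=(-2, -1)) * self.grid.center_phase / d**2
        return f[..., self.fmask]

    def ctf_values(self, ctf: CtfParams) -> np.ndarray:
        return ctf_2d(ctf, np.sqrt(self.k2.astype(np.float64)),
                      self.box_size).astype(np.float32)

    # -- fused projection primitive -------------------------------------
    def project(
        self,
        centers: Tensor,     # (B, N, 3)
        amps: Tensor,        # (B, N)
        sigmas: Tensor,      # (B, N)
        rot_mats: np.ndarray,   # (B, 3, 3)
        shifts_box: np.ndarray,  # (B, 2) in box units
    ) -> Tensor:
        """Returns a (B, 2, F) Tensor: real and imaginary parts."""
        r = rot_mats.astype(np.float32)
        c = centers.data                                     # (B,N,3)
        u = np.einsum("bij,bnj->bni", r[:, :2, :], c)        # (B,N,2)
        u = u + shifts_box.astype(np.float32)[:, None, :]
        s2 = sigmas.data**2                                  # (B,N)
        env0 = (2.0 * np.pi) * s2[..., None] * np.exp(
            -2.0 * np.pi**2 * s2[..., None] * self.k2
        )                                                    # (B,N,F)
        env = amps.data[..., None] * env0
        phase = -2.0 * np.pi * (u @ self.kxy.T)              # (B,N,F)
        cosp, sinp = np.cos(phase), np.sin(phase)
        out = np.stack([(env * cosp).sum(axis=1),
                        (env * sinp).sum(axis=1)], axis=1)   # (B,2,F)

        kx, ky = self.kxy[:, 0], self.kxy[:, 1]
        k2 = self.k2
        sig = sigmas.data

        def vjp(g):
            gre = g[:, 0, None, :]                           # (B,1,F)
            gim = g[:, 1, None, :]
            d_env = gre * cosp + gim * sinp
            d_phase = env * (gim * cosp - gre * sinp)
            d_amp = (d_env * env0).sum(axis=-1)
            # d env / d sigma = env * (2/sigma - 4 pi^2 sigma k^2)
            de = d_env * env
            d_sigma = de.sum(axis=-1) * (2.0 / sig) \
                - 4.0 * np.pi**2 * sig * (de @ k2)
            d_ux = -2.0 * np.pi * (d_phase @ kx)
            d_uy = -2.0 * np.pi * (d_phase @ ky)
            # chain through the rotation: u = R[:2] c
            d_c = (
                r[:, 0, :][:, None, :] * d_ux[..., None]
                + r[:, 1, :][:, None, :] * d_uy[..., None]
            )
            return d_c, d_amp, d_sigma

        return Tensor(out, parents=(centers, amps, sigmas), vjp=vjp)

    # -- differentiable FRC loss ----------------------------------------
    def frc_loss_t(
        self,
        predicted: Tensor,      # (B, 2, F) re/im
        obs: np.ndarray,        # (B, F) complex
        ctf: np.ndarray | None = None,   # (B, F) multiplier on predicted
        eps: float = 1e-8,
    ) -> Tensor:
        if ctf is not None:
            predicted = predicted * ctf[:, None, :].astype(np.float32)
        obs_ri = np.stack([obs.real, obs.imag], axis=1).astype(np.float32)
        m = Tensor(self.ringmat)
        cross = (predicted * obs_ri).sum(axis=1) @ m         # (B, R)
        pp = (predicted * predicted).sum(axis=1) @ m
        oo = (obs_ri**2).sum(axis=1) @ self.ringmat          # constant
        denom = (pp * oo).sqrt() + eps
        corr = cross / denom
        return -corr.mean()
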