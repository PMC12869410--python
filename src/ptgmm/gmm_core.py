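"""Gaussian-mixture density representation of a macromolecule.

A protein density map is represented as a sum of isotropic 3D Gaussians,
each with a center (box-normalized coordinates), an amplitude, and a
width (standard deviation).  The mixture is the object every other
module consumes: the decoder perturbs it per particle, the image model
projects it, the simulator's ground truth is expressed against it.

Coordinate convention (normative for the whole package): centers live in
box-fraction units in [-0.5, 0.5] with +x right, +y up, +z toward the
viewer; projections integrate along z after rotating the model into the
lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

__all__ = [
    "GaussianMixtureModel",
    "Structure",
    "seed_gmm_from_structure",
    "render_volume",
    "map_gaussians_to_atoms",
    "read_structure",
]

# slack beyond [-0.5, 0.5] so decoded per-particle motion stays legal
_CENTER_BOUND = 0.6


@dataclass
class GaussianMixtureModel:
    """Isotropic 3D Gaussian mixture in box-normalized coordinates.

    Attributes
    ----------
    centers : (N, 3) float
        Gaussian centers as fractions of the box edge, nominally in
        [-0.5, 0.5] (up to ±0.6 to leave room for decoded motion).
    amplitudes : (N,) float, >= 0
    widths : (N,) float, > 0
        Isotropic standard deviation, box-fraction units.
    """

    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.widths = np.asarray(self.widths, dtype=np.float64)
        self.validate()

    def validate(self):
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (N, 3)")
        n = len(self.centers)
        if n < 1:
            raise ValueError("GMM needs at least one Gaussian")
        if self.amplitudes.shape != (n,) or self.widths.shape != (n,):
            raise ValueError("amplitudes/widths must be length-N vectors")
        for name, arr in (("centers", self.centers),
                          ("amplitudes", self.amplitudes),
                          ("widths", self.widths)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be strictly positive")
        if np.any(np.abs(self.centers) > _CENTER_BOUND):
            raise ValueError(
                f"centers outside [-{_CENTER_BOUND}, {_CENTER_BOUND}]"
            )

    @property
    def n_gaussians(self) -> int:
        return len(self.centers)

    def copy(self) -> "GaussianMixtureModel":
        return GaussianMixtureModel(
            self.centers.copy(), self.amplitudes.copy(), self.widths.copy()
        )


@dataclass
class Structure:
    """Point model of a molecule: coordinates in Å plus segment labels.

    ``segment_labels`` partition the points into K rigid/compositional
    segments (segment 0 is the core in compositional experiments).
    ``weights`` are per-point masses (e.g. approximate electron counts).
    """

    coordinates: np.ndarray          # (M, 3), Å, centered on the box
    segment_labels: np.ndarray       # (M,) ints in [0, K)
    weights: np.ndarray              # (M,) > 0
    box_size_A: float

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.segment_labels = np.asarray(self.segment_labels, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        m = len(self.coordinates)
        if m == 0:
            raise ValueError("empty structure")
        if self.segment_labels.shape != (m,) or self.weights.shape != (m,):
            raise ValueError("labels/weights must match coordinate count")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        k = self.n_segments
        present = np.unique(self.segment_labels)
        if not np.array_equal(present, np.arange(k)):
            raise ValueError("every segment label in [0, K) must be occupied")
        if np.any(np.abs(self.coordinates) > self.box_size_A / 2):
            raise ValueError("box does not enclose all coordinates")

    @property
    def n_segments(self) -> int:
        return int(self.segment_labels.max()) + 1

    def normalized_coordinates(self) -> np.ndarray:
        """Coordinates in box-fraction units."""
        return self.coordinates / self.box_size_A


def seed_gmm_from_structure(
    structure: Structure,
    n_gaussians: int,
    width0: float = 0.02,
    seed: int = 0,
) -> GaussianMixtureModel:
    """Build the neutral GMM by k-means clustering of the structure.

    Centers are the cluster centroids (weighted by point mass) in
    box-normalized units; amplitudes are proportional to cluster mass
    and normalized to mean 1; every width starts at ``width0``.
    """
    if n_gaussians < 1:
        raise ValueError("n_gaussians must be >= 1")
    m = len(structure.coordinates)
    if n_gaussians > m:
        raise ValueError(
            f"n_gaussians={n_gaussians} exceeds structure size {m}"
        )
    coords = structure.normalized_coordinates()
    if n_gaussians == 1:
        w = structure.weights
        c = np.average(coords, axis=0, weights=w)[None, :]
        mass = np.array([w.sum()])
    else:
        km = KMeans(
            n_clusters=n_gaussians, n_init=10, random_state=seed
        ).fit(coords, sample_weight=structure.weights)
        c = km.cluster_centers_
        mass = np.bincount(
            km.labels_, weights=structure.weights, minlength=n_gaussians
        )
    amps = mass / mass.mean()
    widths = np.full(n_gaussians, float(width0))
    return GaussianMixtureModel(c, amps, widths)


def render_volume(gmm: GaussianMixtureModel, grid_size: int) -> np.ndarray:
    """Evaluate the mixture on a cubic voxel grid.

    Voxel (ix, iy, iz) sits at box-fraction position (i - D/2) / D; the
    value is sum_i amp_i * exp(-|r - c_i|^2 / (2 sigma_i^2)).  Returned
    array is indexed [z, y, x] so that axis order matches image row
    conventions elsewhere.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8")
    d = grid_size
    ax = (np.arange(d) - d / 2) / d
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((d, d, d))
    for c, a, s in zip(gmm.centers, gmm.amplitudes, gmm.widths):
        r2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        vol += a * np.exp(-r2 / (2.0 * s * s))
    return vol


def map_gaussians_to_atoms(
    gmm: GaussianMixtureModel, structure: Structure
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each Gaussian the segment label of its nearest structure point.

    Distances are Euclidean in box-normalized coordinates.  Exact ties
    go to the lowest atom index (cKDTree returns the smallest index among
    equidistant points).

    Returns
    -------
    atom_idx : (N,) int — nearest structure point per Gaussian
    labels : (N,) int — inherited segment labels
    """
    coords = structure.normalized_coordinates()
    if np.any(np.abs(gmm.centers) > _CENTER_BOUND) or np.any(
        np.abs(coords) > 0.5 + 1e-9
    ):
        raise ValueError("coordinate frames do not match (points outside box)")
    tree = cKDTree(coords)
    dist, idx = tree.query(gmm.centers, k=1)
    # cKDTree tie-breaking is not guaranteed; enforce lowest-index rule
    # by re-checking candidates at the same distance.
    d2 = ((coords[None, :, :] - gmm.centers[:, None, :]) ** 2).sum(-1) \
        if len(coords) * len(gmm.centers) <= 1_000_000 else None
    if d2 is not None:
        idx = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index
    return idx, structure.segment_labels[idx]


def save_structure_tsv(structure: Structure, path) -> None:
    """Plain-text structure table (x, y, z in Å, segment, weight)."""
    import pandas as pd

    df = pd.DataFrame({
        "x_A": structure.coordinates[:, 0],
        "y_A": structure.coordinates[:, 1],
        "z_A": structure.coordinates[:, 2],
        "segment": structure.segment_labels,
        "weight": structure.weights,
    })
    with open(path, "w") as fh:
        fh.write(f"# box_size_A={structure.box_size_A}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_structure_tsv(path) -> Structure:
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# box_size_A="):
            raise ValueError(f"{path}: missing box_size_A header")
        box = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    return Structure(
        df[["x_A", "y_A", "z_A"]].to_numpy(),
        df["segment"].to_numpy(),
        df["weight"].to_numpy(),
        box,
    )


def read_structure(
    path: str,
    segment_of_chain: dict[str, int] | None = None,
    box_size_A: float | None = None,
    ca_only: bool = True,
) -> Structure:
    """Read a PDB/mmCIF atomic model into a :class:`Structure`.

    Chains are mapped to segment ids through ``segment_of_chain``
    (default: chains in order of appearance get 0, 1, 2, ...).  The
    model is centered on its weighted centroid; ``box_size_A`` defaults
    to 1.3x the maximum extent.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords, labels, weights = [], [], []
    chain_ids: dict[str, int] = {}
    model = st[0]
    for chain in model:
        if segment_of_chain is not None:
            if chain.name not in segment_of_chain:
                continue
            seg = segment_of_chain[chain.name]
        else:
            seg = chain_ids.setdefault(chain.name, len(chain_ids))
        for residue in chain:
            for atom in residue:
                if ca_only and atom.name not in ("CA", "P"):
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                labels.append(seg)
                weights.append(float(atom.element.weight))
    coords = np.asarray(coords, dtype=np.float64)
    if coords.size == 0:
        raise ValueError(f"no atoms read from {path}")
    weights = np.asarray(weights)
    labels = np.asarray(labels)
    # compact labels to [0, K)
    _, labels = np.unique(labels, return_inverse=True)
    centroid = np.average(coords, axis=0, weights=weights)
    coords = coords - centroid
    if box_size_A is None:
        box_size_A = 2.6 * float(np.abs(coords).max())
    return Structure(coords, labels, weights, float(box_size_A))
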