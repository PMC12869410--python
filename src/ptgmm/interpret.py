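"""Divide-and-conquer interpretability of the learned heterogeneity.

The decoder output across particles is a rich description of each
Gaussian's behaviour: Gaussians that assemble or move as a unit have
correlated output profiles.  The workflow here exploits that:

1. Build a Gaussian feature matrix (one row per Gaussian, columns = a
   subsample of particles, values = amplitude gate or motion magnitude).
2. Embed the rows with UMAP and cluster with DBSCAN — clusters are
   regions of correlated dynamics (a data-driven segmentation of the
   GMM).
3. Pick one region and embed the *particles* using only that region's
   outputs; k-means on that focused embedding yields particle classes
   that differ only in the chosen region.
4. Render per-class mean GMMs and their difference volume to visualise
   what distinguishes the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN, KMeans

from .gmm_core import GaussianMixtureModel, render_volume
from .pt_decoder import DecoderOutput, apply_deltas
from .trainer import InferenceResult

__all__ = [
    "GaussianFeatureMatrix",
    "RegionSet",
    "build_feature_matrix",
    "segment_gmm",
    "focus_embed_particles",
    "class_difference_volume",
    "match_regions_to_segments",
]


@dataclass
class GaussianFeatureMatrix:
    matrix: np.ndarray          # (N_gaussians, F)
    particle_idx: np.ndarray    # (F,) columns' particle indices
    channel: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class RegionSet:
    labels: np.ndarray          # (N,) region id per Gaussian; -1 = noise
    embedding: np.ndarray       # (N, 2) UMAP coordinates

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])

    def members(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


def build_feature_matrix(
    outputs: InferenceResult,
    channel: str = "amplitude",
    max_particles: int = 2000,
    seed: int = 0,
) -> GaussianFeatureMatrix:
    """Per-Gaussian output profiles across a particle subsample.

    ``channel='amplitude'`` uses the gate value; ``'motion'`` uses the
    Δcenter magnitude.  Columns are a uniform random subsample of at
    most ``max_particles`` particles (all of them, in order, if the
    table is smaller).
    """
    n = outputs.gate.shape[0]
    if n == 0:
        raise ValueError("empty output table")
    if channel == "amplitude":
        values = outputs.gate
    elif channel == "motion":
        values = np.linalg.norm(outputs.d_center, axis=2)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    if n > max_particles:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(n, size=max_particles, replace=False))
    else:
        cols = np.arange(n)
    return GaussianFeatureMatrix(values[cols].T.astype(np.float64), cols,
                                 channel)


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    out = (m - mu) / np.where(sd > 1e-12, sd, 1.0)
    return out


def _umap_embed(x: np.ndarray, n_neighbors: int, min_dist: float,
                seed: int) -> np.ndarray:
    import umap

    # random (seeded) init rather than the default spectral one: on the
    # disconnected neighbor graphs these feature matrices produce, the
    # spectral path is not reproducible run-to-run even with a fixed
    # random_state, and seeded reproducibility is part of this module's
    # contract
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(x) - 1),
        min_dist=min_dist,
        random_state=seed,
        init="random",
        n_jobs=1,
    )
    return reducer.fit_transform(x).astype(np.float64)


def _knee_eps(emb: np.ndarray, k: int = 4, quantile: float = 0.9) -> float:
    """DBSCAN eps from the knee of the k-NN distance curve.

    Falls back to a fixed quantile of the sorted 4-NN distances when the
    curve has no pronounced knee.
    """
    from scipy.spatial import cKDTree

    d, _ = cKDTree(emb).query(emb, k=k + 1)
    dk = np.sort(d[:, -1])
    # knee = point of maximum distance to the chord of the curve
    x = np.linspace(0, 1, len(dk))
    y = (dk - dk[0]) / (dk[-1] - dk[0] + 1e-12)
    knee = np.argmax(x - y) if dk[-1] > dk[0] else None
    if knee is not None and 0 < knee < len(dk) - 1:
        eps = dk[knee]
    else:
        eps = np.quantile(dk, quantile)
    return float(max(eps, 1e-6))


def segment_gmm(
    features: GaussianFeatureMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    eps: float | None = None,
    min_samples: int = 5,
    standardize: bool = True,
    seed: int = 0,
) -> RegionSet:
    """UMAP-embed Gaussian profiles and density-cluster into regions.

    If every point is labelled noise the whole model is returned as a
    single region (with a warning) rather than failing.
    """
    m = features.matrix
    if len(m) < 10:
        raise ValueError("need at least 10 Gaussians to segment")
    x = _standardize_rows(m) if standardize else m
    emb = _umap_embed(x, n_neighbors, min_dist, seed)
    if eps is None:
        eps = _knee_eps(emb)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    if (labels >= 0).sum() == 0:
        import warnings

        warnings.warn("DBSCAN labelled everything noise; "
                      "returning a single region")
        labels = np.zeros(len(m), dtype=np.int64)
    return RegionSet(labels.astype(np.int64), emb)


def focus_embed_particles(
    outputs: InferenceResult,
    regions: RegionSet,
    region: int,
    k: int = 2,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    channel: str = "amplitude",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed particles using only one region's Gaussians, then k-means.

    Returns (embedding (n, 2), class labels (n,)).  Class ids are
    relabelled by descending class size so they are stable across runs.
    """
    members = regions.members(region)
    if len(members) == 0:
        raise ValueError(f"region {region} is empty")
    if channel == "amplitude":
        feat = outputs.gate[:, members]
    elif channel == "motion":
        feat = np.linalg.norm(outputs.d_center[:, members, :], axis=2)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    feat = feat.astype(np.float64)
    if len(members) >= 3:
        emb = _umap_embed(feat, n_neighbors, min_dist, seed)
    else:
        emb = feat[:, :2] if feat.shape[1] >= 2 else np.repeat(feat, 2, 1)
    if k == 1:
        return emb, np.zeros(len(emb), dtype=np.int64)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    labels = km.labels_
    order = np.argsort(-np.bincount(labels, minlength=k), kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return emb, remap[labels]


def mean_decoder_output(outputs: InferenceResult,
                        particle_idx: np.ndarray) -> DecoderOutput:
    """Class-mean deltas (gate/width averaged in gated space)."""
    from .pt_decoder import GATE_MAX, LOG_SIGMA_SCALE

    gate = outputs.gate[particle_idx].mean(axis=0)
    wfac = outputs.width_factor[particle_idx].mean(axis=0)
    dc = outputs.d_center[particle_idx].mean(axis=0).astype(np.float64)
    # invert the bounded activations to store raw values
    g = np.clip(gate / GATE_MAX, 1e-6, 1 - 1e-6)
    raw_amp = np.log(g / (1 - g))
    t = np.clip(np.log(wfac) / LOG_SIGMA_SCALE, -1 + 1e-6, 1 - 1e-6)
    raw_sig = np.arctanh(t)
    return DecoderOutput(dc, raw_amp, raw_sig)


def class_difference_volume(
    outputs: InferenceResult,
    class_labels: np.ndarray,
    neutral: GaussianMixtureModel,
    grid_size: int = 64,
    class_a: int = 0,
    class_b: int = 1,
) -> tuple[np.ndarray, GaussianMixtureModel, GaussianMixtureModel]:
    """Difference volume between the mean GMMs of two particle classes."""
    ids, counts = np.unique(class_labels, return_counts=True)
    for c in (class_a, class_b):
        if c not in ids or counts[list(ids).index(c)] == 0:
            raise ValueError(f"class {c} has no particles")
    gmm_a = apply_deltas(
        neutral, mean_decoder_output(outputs,
                                     np.flatnonzero(class_labels == class_a))
    )
    gmm_b = apply_deltas(
        neutral, mean_decoder_output(outputs,
                                     np.flatnonzero(class_labels == class_b))
    )
    diff = render_volume(gmm_a, grid_size) - render_volume(gmm_b, grid_size)
    return diff, gmm_a, gmm_b


def match_regions_to_segments(
    regions: RegionSet,
    gaussian_segments: np.ndarray,
    exclude_core: bool = True,
) -> dict[int, list[int]]:
    """Majority-label matching of recovered regions to true segments.

    Every region is assigned the true segment that the majority of its
    Gaussians belong to.  A segment counts as correctly separated when
    the regions assigned to it jointly contain more than half of its
    Gaussians: a segment split into several pure regions is still
    separated from everything else, whereas two segments merged into
    one region leave the minority segment unmatched.

    Returns {segment: [region ids assigned to it]} for the separated
    segments.
    """
    majority: dict[int, int] = {}
    for r in regions.region_ids:
        segs, counts = np.unique(
            gaussian_segments[regions.labels == r], return_counts=True
        )
        top = segs[counts.argmax()]
        if counts.max() > 0.5 * counts.sum():
            majority[int(r)] = int(top)
    matches: dict[int, list[int]] = {}
    for seg in np.unique(gaussian_segments):
        if exclude_core and seg == 0:
            continue
        in_seg = gaussian_segments == seg
        assigned = [r for r, s in majority.items() if s == seg]
        covered = sum(
            int((in_seg & (regions.labels == r)).sum()) for r in assigned
        )
        if covered > 0.5 * in_seg.sum():
            matches[int(seg)] = assigned
    return matches
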