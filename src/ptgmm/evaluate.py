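"""Ground-truth accuracy metrics for the synthetic experiments.

Compositional data: per-particle Gaussian amplitude gates are compared
to the presence/absence of the segment each Gaussian sits in (the
Gaussian inherits the segment of its nearest atom).  A Gaussian counts
as predicted-present when its gate clears the threshold (0.5 by
default, matching the reported cutoff).

Conformational data: the decoder's per-Gaussian center displacement is
transferred to each atom from its nearest Gaussian and compared to the
true per-atom movement as an RMSD in Å; the zero-displacement baseline
equals the magnitude of the true motion and is what a rigid consensus
model would score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gmm_core import GaussianMixtureModel, Structure
from .simulator import CompositionGroundTruth, MotionGroundTruth
from .trainer import InferenceResult

__all__ = [
    "AmplitudeAccuracy",
    "amplitude_accuracy",
    "MotionRmsd",
    "motion_rmsd",
]


@dataclass
class AmplitudeAccuracy:
    accuracy: float                      # pooled over (particle, Gaussian)
    per_segment: pd.DataFrame            # segment id -> accuracy, n
    hist_present: np.ndarray             # amplitude histogram, truly present
    hist_absent: np.ndarray
    hist_edges: np.ndarray


def amplitude_accuracy(
    outputs: InferenceResult,
    gaussian_segments: np.ndarray,
    truth: CompositionGroundTruth,
    threshold: float = 0.5,
    include_core: bool = False,
    per_particle_mean: bool = False,
    n_bins: int = 50,
) -> AmplitudeAccuracy:
    """Fraction of (particle, Gaussian) amplitude calls that are correct.

    By default the score pools all predictions of Gaussians belonging to
    toggleable segments (core Gaussians have constant truth and are
    excluded); ``per_particle_mean`` averages per-particle accuracies
    instead of pooling.
    """
    gate = outputs.gate
    n_part, n_gauss = gate.shape
    if gaussian_segments.shape != (n_gauss,):
        raise ValueError("every Gaussian needs a segment assignment")
    if not 0.0 < threshold < 2.0:
        raise ValueError("threshold must lie inside the gate range")
    true_presence = truth.presence[:, gaussian_segments]   # (n, N)
    pred_presence = gate >= threshold
    keep = np.ones(n_gauss, dtype=bool)
    if not include_core:
        keep = gaussian_segments != 0
    if not keep.any():
        raise ValueError("no toggleable-segment Gaussians to score")
    correct = (pred_presence == true_presence)[:, keep]
    if per_particle_mean:
        acc = float(correct.mean(axis=1).mean())
    else:
        acc = float(correct.mean())

    rows = []
    for seg in np.unique(gaussian_segments):
        sel = gaussian_segments == seg
        rows.append({
            "segment": int(seg),
            "n_gaussians": int(sel.sum()),
            "accuracy": float(
                (pred_presence[:, sel] == true_presence[:, sel]).mean()
            ),
        })
    per_segment = pd.DataFrame(rows)

    edges = np.linspace(0.0, 2.0, n_bins + 1)
    amp_on = gate[:, keep][true_presence[:, keep]]
    amp_off = gate[:, keep][~true_presence[:, keep]]
    hist_on, _ = np.histogram(amp_on, bins=edges)
    hist_off, _ = np.histogram(amp_off, bins=edges)
    return AmplitudeAccuracy(acc, per_segment, hist_on, hist_off, edges)


@dataclass
class MotionRmsd:
    per_particle_A: np.ndarray
    mean_A: float
    baseline_per_particle_A: np.ndarray   # zero-motion (rigid) reference
    baseline_mean_A: float


def motion_rmsd(
    outputs: InferenceResult,
    neutral: GaussianMixtureModel,
    structure: Structure,
    truth: MotionGroundTruth,
) -> MotionRmsd:
    """Per-particle RMSD between decoded and true atomic movement.

    Each atom takes the Δcenter of its nearest Gaussian (converted from
    box units to Å); RMSD runs over all atoms of the structure.
    """
    n_part = outputs.d_center.shape[0]
    m = len(structure.coordinates)
    if truth.displacement_A.shape[:2] != (n_part, m):
        raise ValueError("ground truth shape mismatch")
    box_A = structure.box_size_A
    coords_box = structure.normalized_coordinates()
    tree = cKDTree(neutral.centers)
    _, nearest = tree.query(coords_box, k=1)
    pred_A = outputs.d_center[:, nearest, :].astype(np.float64) * box_A
    err = pred_A - truth.displacement_A
    per_particle = np.sqrt((err**2).sum(axis=2).mean(axis=1))
    baseline = truth.per_particle_rmsd_A()
    return MotionRmsd(per_particle, float(per_particle.mean()),
                      baseline, float(baseline.mean()))
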