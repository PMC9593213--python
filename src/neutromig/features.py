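"""Per-trajectory migration dynamics, per-cell morphology, experiment profiles.

Dynamic parameters per trajectory (gradient axis = +x unless overridden):

* speed — total path length / elapsed time, in um/min (mean step speed);
* directedness — whether the net displacement projects positively onto the
  gradient axis (strict inequality; a zero projection counts as not
  directed);
* gradient precision — the forward migration index: net displacement along
  the gradient axis divided by total path length, in [-1, 1];
* straightness — |net displacement| / path length, in [0, 1].

For every trajectory |gradient precision| <= straightness <= 1.

Morphology per cell and frame uses standard region properties (area,
perimeter, eccentricity, solidity, intensity statistics) plus a grey-level
co-occurrence contrast restricted to the instance mask.

An experiment profile is the mean of every feature over its QC-passed
tracks (morphology first averaged per track so long tracks do not
dominate), plus the chemotactic response: the fraction of tracks whose net
displacement points up the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

if TYPE_CHECKING:  # pragma: no cover
    from .imaging import Trajectory

__all__ = [
    "DynamicProfile",
    "ExperimentProfile",
    "GRADIENT_AXIS",
    "compute_speed",
    "compute_directedness",
    "compute_gradient_precision",
    "compute_straightness",
    "compute_dynamic_profile",
    "compute_morphology",
    "aggregate_experiment",
    "profiles_to_frame",
    "MORPHOLOGY_FEATURES",
    "DYNAMIC_FEATURES",
]

#: Unit vector of increasing chemoattractant concentration (+x in image coords).
GRADIENT_AXIS: tuple[float, float] = (1.0, 0.0)

DYNAMIC_FEATURES = ("speed", "gradient_precision", "straightness",
                    "net_displacement", "path_length")
MORPHOLOGY_FEATURES = ("area", "perimeter", "eccentricity", "solidity",
                       "intensity_mean", "intensity_sd", "texture_contrast")


@dataclass(frozen=True)
class DynamicProfile:
    """Scalar migration dynamics of one trajectory."""

    track_id: int
    speed: float                 # um/min
    directed: bool
    gradient_precision: float    # forward migration index, [-1, 1]
    straightness: float          # [0, 1]
    net_displacement: float      # um
    path_length: float           # um


@dataclass(frozen=True)
class ExperimentProfile:
    """Mean feature vector of one recording."""

    experiment_id: str
    chemokine: str
    donor_id: str
    chemotactic_response: float
    n_cells: int
    features: dict[str, float]

    def to_row(self) -> dict:
        row = {
            "experiment_id": self.experiment_id,
            "chemokine": self.chemokine,
            "donor_id": self.donor_id,
            "chemotactic_response": self.chemotactic_response,
            "n_cells": self.n_cells,
        }
        row.update(self.features)
        return row


def _path_and_net(positions: np.ndarray) -> tuple[float, np.ndarray]:
    steps = np.diff(positions, axis=0)
    path = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = positions[-1] - positions[0]
    return path, net


def _axis_unit(gradient_axis: Sequence[float]) -> np.ndarray:
    axis = np.asarray(gradient_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("gradient axis must be a nonzero vector")
    return axis / norm


def compute_speed(traj: "Trajectory") -> float:
    """Mean step speed: path length / elapsed time, um/min.

    Requires at least two detections; a single-point track has no defined
    speed and must be excluded upstream.
    """
    if len(traj) < 2:
        raise ValueError("speed is undefined for a track with < 2 detections")
    path, _ = _path_and_net(traj.positions)
    elapsed_min = (traj.times_s[-1] - traj.times_s[0]) / 60.0
    return path / elapsed_min


def compute_directedness(traj: "Trajectory",
                         gradient_axis: Sequence[float] = GRADIENT_AXIS) -> bool:
    """True iff the net displacement projects strictly positively on the axis."""
    if len(traj) < 2:
        raise ValueError("directedness is undefined for a track with < 2 detections")
    _, net = _path_and_net(traj.positions)
    return bool(net @ _axis_unit(gradient_axis) > 0)


def compute_gradient_precision(traj: "Trajectory",
                               gradient_axis: Sequence[float] = GRADIENT_AXIS) -> float:
    """Forward migration index: net displacement along the axis / path length."""
    path, net = _path_and_net(traj.positions)
    if path <= 0:
        raise ValueError("gradient precision is undefined for a zero-length path")
    return float(net @ _axis_unit(gradient_axis)) / path


def compute_straightness(traj: "Trajectory") -> float:
    """|net displacement| / path length, in [0, 1]."""
    path, net = _path_and_net(traj.positions)
    if path <= 0:
        raise ValueError("straightness is undefined for a zero-length path")
    return float(np.linalg.norm(net)) / path


def compute_dynamic_profile(traj: "Trajectory",
                            gradient_axis: Sequence[float] = GRADIENT_AXIS,
                            ) -> DynamicProfile | None:
    """All dynamic parameters of one trajectory; None for degenerate tracks.

    Tracks with fewer than two detections or zero path length (perfectly
    static, a non-mover) are excluded from dynamics.
    """
    if len(traj) < 2:
        return None
    path, net = _path_and_net(traj.positions)
    if path <= 0:
        return None
    axis = _axis_unit(gradient_axis)
    proj = float(net @ axis)
    return DynamicProfile(
        track_id=traj.track_id,
        speed=compute_speed(traj),
        directed=proj > 0,
        gradient_precision=proj / path,
        straightness=float(np.linalg.norm(net)) / path,
        net_displacement=float(np.linalg.norm(net)),
        path_length=path,
    )


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def compute_morphology(mask: np.ndarray, intensity: np.ndarray | None = None,
                       pixel_size: float = 0.96, glcm_levels: int = 16,
                       ) -> dict[str, float]:
    """Region properties + GLCM texture contrast for one instance mask.

    ``mask`` is a boolean (or labeled, nonzero = instance) image containing
    exactly one instance. Area and perimeter are converted to um^2 / um via
    ``pixel_size``. Texture contrast is the grey-level co-occurrence
    contrast at distance 1 (4 symmetric directions averaged), computed only
    over pixel pairs inside the mask; a uniform-intensity instance has
    contrast exactly 0.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty mask: no instance to measure")
    rp = regionprops(m.astype(np.uint8),
                     intensity_image=None if intensity is None else np.asarray(intensity, float))[0]
    out = {
        "area": float(rp.area) * pixel_size**2,
        "perimeter": float(rp.perimeter) * pixel_size,
        "eccentricity": float(rp.eccentricity),
        "solidity": float(rp.solidity),
    }
    if intensity is not None:
        vals = np.asarray(intensity, dtype=float)[m]
        out["intensity_mean"] = float(vals.mean())
        out["intensity_sd"] = float(vals.std())
        out["texture_contrast"] = _masked_glcm_contrast(m, np.asarray(intensity, float),
                                                        levels=glcm_levels)
    else:
        out["intensity_mean"] = np.nan
        out["intensity_sd"] = np.nan
        out["texture_contrast"] = np.nan
    return out


def _masked_glcm_contrast(mask: np.ndarray, intensity: np.ndarray,
                          levels: int = 16) -> float:
    """GLCM contrast restricted to in-mask pixel pairs.

    Intensities inside the mask are quantized to ``levels`` grey levels;
    pixels outside the mask get a reserved level whose co-occurrence rows
    and columns are discarded, so only pairs with both pixels inside the
    mask contribute.
    """
    ys, xs = np.nonzero(mask)
    sub = intensity[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    submask = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    vals = sub[submask]
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        return 0.0
    quant = np.zeros(sub.shape, dtype=np.uint8)  # level 0 reserved for outside
    quant[submask] = 1 + np.minimum(
        ((sub[submask] - lo) / (hi - lo) * levels).astype(int), levels - 1)
    glcm = graycomatrix(quant, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)  # drop the outside level
    totals = glcm.sum(axis=(0, 1), keepdims=True)
    totals[totals == 0] = 1.0
    glcm /= totals
    return float(graycoprops(glcm, "contrast").mean())


# ---------------------------------------------------------------------------
# experiment aggregation
# ---------------------------------------------------------------------------

def aggregate_experiment(
        dynamic_profiles: Sequence[DynamicProfile],
        morphology_by_track: Mapping[int, pd.DataFrame] | None = None,
        experiment_id: str = "exp",
        chemokine: str = "LTB4",
        donor_id: str = "D000",
) -> ExperimentProfile:
    """Mean experiment profile over QC-passed tracks.

    Every dynamic feature is averaged over tracks; morphology is averaged
    per track over its frames first, then over tracks. The chemotactic
    response is the fraction of tracks with positive net displacement along
    the gradient axis. Permutation-invariant over tracks.
    """
    if not dynamic_profiles:
        raise ValueError(
            "no tracks to aggregate: experiment should have been removed by QC")
    feats: dict[str, float] = {}
    n = len(dynamic_profiles)
    for name in DYNAMIC_FEATURES:
        # fsum: exactly permutation-invariant mean
        feats[name] = math.fsum(getattr(p, name) for p in dynamic_profiles) / n
    response = sum(p.directed for p in dynamic_profiles) / n

    if morphology_by_track:
        per_track = []
        for tid, df in morphology_by_track.items():
            per_track.append(df.mean(numeric_only=True))
        morph_mean = pd.concat(per_track, axis=1).mean(axis=1)
        for name, value in morph_mean.items():
            feats[str(name)] = float(value)

    return ExperimentProfile(
        experiment_id=experiment_id,
        chemokine=chemokine,
        donor_id=donor_id,
        chemotactic_response=response,
        n_cells=len(dynamic_profiles),
        features=feats,
    )


def profiles_to_frame(profiles: Sequence[ExperimentProfile]) -> pd.DataFrame:
    """One row per experiment, columns = metadata + features."""
    return pd.DataFrame([p.to_row() for p in profiles]).set_index("experiment_id")
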