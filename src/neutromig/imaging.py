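"""Frames -> detections -> trajectories -> experiment-level quality control.

Segmentation follows a three-class contract: every frame is first turned
into a per-pixel probability map over {background, boundary, foreground}.
The deterministic classical generator below (smoothing + intensity/gradient
soft assignment) fills the role a trained semantic-segmentation network
plays on real recordings; externally produced probability maps with the
same layout are accepted everywhere downstream.

Instances are connected components of the foreground class after removing
boundary-class pixels (which split touching cells); boundary pixels are
then re-assigned to the nearest instance. Linking is per-frame optimal
one-to-one assignment (Hungarian) with a hard distance gate and gap
closing up to ``max_gap`` frames.

Experiment-level QC: only minutes 15-30 of a recording are analyzed (the
gradient is not stable earlier); tracks observed for less than 50% of that
window are removed; experiments with fewer than 25 surviving tracks, with
lateral flow, or dominated by non-moving (pre-activated) cells are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import expit
from skimage.filters import gaussian, sobel
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels

logger = logging.getLogger("neutromig.imaging")

__all__ = [
    "ProbabilityMap",
    "Detection",
    "Trajectory",
    "QCResult",
    "compute_class_probabilities",
    "segment_instances",
    "segment_frame",
    "link_tracks",
    "detect_and_track",
    "apply_quality_control",
    "crop_to_window",
    "read_frames",
    "trajectories_to_frame",
    "trajectories_from_ground_truth",
    "BACKGROUND",
    "BOUNDARY",
    "FOREGROUND",
]

BACKGROUND, BOUNDARY, FOREGROUND = 0, 1, 2


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class probabilities, shape (H, W, 3): bg, boundary, fg."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("probability map must have shape (H, W, 3)")
        if np.any(p < -1e-9):
            raise ValueError("probabilities must be non-negative")
        if np.any(np.abs(p.sum(axis=2) - 1.0) > 1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def argmax(self) -> np.ndarray:
        return np.argmax(self.probs, axis=2)


@dataclass
class Detection:
    """One segmented cell in one frame."""

    frame: int
    x_um: float
    y_um: float
    area_um2: float
    label: int
    morphology: dict[str, float] | None = None


@dataclass
class Trajectory:
    """A linked track: ordered detections of one cell over time."""

    track_id: int
    detections: list[Detection]
    frame_interval: float  # s
    first_frame: int = 0   # observation-window start (frames)
    last_frame: int = -1   # observation-window end, inclusive

    def __post_init__(self) -> None:
        frames = self.frames
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("detection frame indices must be strictly increasing")
        if self.last_frame < 0 and len(frames):
            self.first_frame = int(frames[0])
            self.last_frame = int(frames[-1])

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of centroids in um."""
        return np.array([[d.x_um, d.y_um] for d in self.detections], dtype=float)

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class QCResult:
    """Outcome of experiment-level quality control."""

    experiment_id: str
    window_frames: tuple[int, int]  # inclusive frame range analyzed
    n_tracks_kept: int
    n_tracks_removed: int
    low_cell_number: bool
    lateral_flow: bool
    pre_activated: bool
    median_lateral_index: float

    @property
    def passed(self) -> bool:
        return not (self.low_cell_number or self.lateral_flow or self.pre_activated)


# ---------------------------------------------------------------------------
# probability maps
# ---------------------------------------------------------------------------

def compute_class_probabilities(frame: np.ndarray, smooth_sigma: float = 1.0,
                                ) -> ProbabilityMap:
    """Deterministic three-class probability map from a single-channel frame.

    The frame is Gaussian-smoothed; a foreground score is a logistic ramp
    of intensity between the robust background level (median) and the
    bright-cell level (99.9th percentile), and a boundary score is the
    normalized Sobel gradient magnitude. The three pseudo-probabilities
    ``(bg, boundary, fg) = ((1-b)(1-s), b, (1-b)s)`` sum to 1 exactly.

    A constant (or near-constant) frame maps to all-background with a
    logged warning.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    bg_level = float(np.median(smoothed))
    fg_level = float(np.percentile(smoothed, 99.9))
    contrast = fg_level - bg_level
    # robust noise scale of the (mostly background) smoothed frame; a frame
    # whose brightest pixels sit within the noise band has no cells
    noise_scale = 1.4826 * float(np.median(np.abs(smoothed - bg_level)))
    if contrast <= max(6.0 * noise_scale, 1e-6 * max(1.0, abs(bg_level))):
        logger.warning("frame has no contrast above noise; returning all-background map")
        probs = np.zeros(img.shape + (3,))
        probs[..., BACKGROUND] = 1.0
        return ProbabilityMap(probs)

    midpoint = bg_level + 0.5 * contrast
    s = expit((smoothed - midpoint) / (0.08 * contrast))
    # Sobel of a smoothed step edge of height `contrast` peaks near
    # 0.25 * contrast; normalize so the rim reaches b ~ 0.7.
    grad = sobel(smoothed)
    b = np.clip(grad / (0.35 * contrast), 0.0, 0.95)
    probs = np.empty(img.shape + (3,))
    probs[..., BACKGROUND] = (1.0 - b) * (1.0 - s)
    probs[..., BOUNDARY] = b
    probs[..., FOREGROUND] = (1.0 - b) * s
    return ProbabilityMap(probs)


# ---------------------------------------------------------------------------
# instance segmentation
# ---------------------------------------------------------------------------

def segment_instances(pmap: ProbabilityMap, min_area: float = 20.0,
                      pixel_size: float = 0.96, frame_index: int = 0,
                      intensity: np.ndarray | None = None,
                      compute_morphology_features: bool = False,
                      ) -> list[Detection]:
    """Extract cell instances from a three-class probability map.

    Foreground connected components are found with boundary-class pixels
    excluded (splitting touching cells); boundary pixels are then
    re-assigned to the nearest instance. Components smaller than
    ``min_area`` (um^2) are dropped. Centroids are intensity-weighted
    (background-subtracted) when an intensity frame is given, which gives
    sub-pixel accuracy on rendered data, else geometric.
    """
    cls = pmap.argmax
    fg_core = cls == FOREGROUND
    labels = sk_label(fg_core, connectivity=2)
    if labels.max() > 0:
        grown = expand_labels(labels, distance=np.inf)
        boundary = cls == BOUNDARY
        labels = np.where(fg_core | boundary, grown, 0)

    min_area_px = min_area / pixel_size**2
    detections: list[Detection] = []
    bg_level = float(np.median(intensity)) if intensity is not None else 0.0
    for rp in regionprops(labels, intensity_image=intensity):
        if rp.area < min_area_px:
            continue
        if intensity is not None:
            weights = np.clip(rp.image_intensity - bg_level, 0.0, None)
            total = weights.sum()
            if total > 0:
                yy, xx = np.nonzero(rp.image)
                cy = (yy * weights[yy, xx]).sum() / total + rp.bbox[0]
                cx = (xx * weights[yy, xx]).sum() / total + rp.bbox[1]
            else:
                cy, cx = rp.centroid
        else:
            cy, cx = rp.centroid
        morph = None
        if compute_morphology_features:
            from .features import compute_morphology
            mask = labels == rp.label
            morph = compute_morphology(mask, intensity, pixel_size=pixel_size)
        detections.append(Detection(
            frame=frame_index,
            x_um=float(cx) * pixel_size,
            y_um=float(cy) * pixel_size,
            area_um2=float(rp.area) * pixel_size**2,
            label=int(rp.label),
            morphology=morph,
        ))
    return detections


def segment_frame(frame: np.ndarray, min_area: float = 20.0,
                  pixel_size: float = 0.96, frame_index: int = 0,
                  compute_morphology_features: bool = False) -> list[Detection]:
    """Probability map + instance extraction for one raw frame."""
    pmap = compute_class_probabilities(frame)
    return segment_instances(
        pmap, min_area=min_area, pixel_size=pixel_size, frame_index=frame_index,
        intensity=np.asarray(frame, dtype=float),
        compute_morphology_features=compute_morphology_features)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _group_by_frame(detections: Iterable[Detection]) -> dict[int, list[Detection]]:
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    return by_frame


def link_tracks(detections: Iterable[Detection], max_disp: float = 10.0,
                max_gap: int = 2, frame_interval: float = 10.0,
                rescue_factor: float = 3.0) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame by frame, open tracks are matched to the new detections by
    minimum-total-displacement one-to-one assignment (Hungarian), gated at
    ``max_disp`` um per elapsed frame (so a track absent for g frames may
    move up to (g+1) x max_disp). Pairs left unmatched by the primary gate
    get a second assignment pass at ``rescue_factor`` x the gate: step
    lengths are heavy-tailed, and without the rescue pass a single large
    step would split an otherwise unambiguous track. Tracks unmatched for
    more than ``max_gap`` frames are closed; detections that remain
    unmatched start new tracks.
    """
    by_frame = _group_by_frame(detections)
    if not by_frame:
        return []
    frames = sorted(by_frame)

    next_id = 0
    open_tracks: list[dict] = []   # {'id', 'dets', 'last'}
    closed: list[dict] = []

    for f in frames:
        dets = by_frame[f]
        # retire tracks whose gap would exceed max_gap
        still_open = []
        for t in open_tracks:
            if f - t["dets"][-1].frame - 1 > max_gap:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open

        if open_tracks and dets:
            dist = np.zeros((len(open_tracks), len(dets)))
            gates = np.zeros(len(open_tracks))
            for i, t in enumerate(open_tracks):
                last = t["dets"][-1]
                gates[i] = max_disp * (f - last.frame)
                for j, d in enumerate(dets):
                    dist[i, j] = np.hypot(d.x_um - last.x_um, d.y_um - last.y_um)

            matched_tracks: set[int] = set()
            matched_dets: set[int] = set()
            for factor in (1.0, rescue_factor):
                free_i = [i for i in range(len(open_tracks)) if i not in matched_tracks]
                free_j = [j for j in range(len(dets)) if j not in matched_dets]
                if not free_i or not free_j:
                    break
                cost = np.full((len(free_i), len(free_j)), 1e12)
                for a, i in enumerate(free_i):
                    for b, j in enumerate(free_j):
                        if dist[i, j] <= factor * gates[i]:
                            cost[a, b] = dist[i, j]
                rows, cols = linear_sum_assignment(cost)
                for a, b in zip(rows, cols):
                    if cost[a, b] < 1e11:
                        i, j = free_i[a], free_j[b]
                        open_tracks[i]["dets"].append(dets[j])
                        matched_tracks.add(i)
                        matched_dets.add(j)
            unmatched = [d for j, d in enumerate(dets) if j not in matched_dets]
        else:
            unmatched = list(dets)

        for d in unmatched:
            open_tracks.append({"id": next_id, "dets": [d]})
            next_id += 1

    closed.extend(open_tracks)
    closed.sort(key=lambda t: t["id"])
    return [
        Trajectory(track_id=t["id"], detections=t["dets"], frame_interval=frame_interval)
        for t in closed
    ]


def detect_and_track(frames: Iterable[np.ndarray], min_area: float = 20.0,
                     pixel_size: float = 0.96, max_disp: float = 10.0,
                     max_gap: int = 2, frame_interval: float = 10.0,
                     compute_morphology_features: bool = False) -> list[Trajectory]:
    """Segment a frame stream and link the detections (memory-friendly)."""
    all_dets: list[Detection] = []
    for f_idx, frame in enumerate(frames):
        all_dets.extend(segment_frame(
            frame, min_area=min_area, pixel_size=pixel_size, frame_index=f_idx,
            compute_morphology_features=compute_morphology_features))
    return link_tracks(all_dets, max_disp=max_disp, max_gap=max_gap,
                       frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def crop_to_window(traj: Trajectory, first_frame: int, last_frame: int) -> Trajectory:
    """Restrict a trajectory to detections inside [first_frame, last_frame]."""
    dets = [d for d in traj.detections if first_frame <= d.frame <= last_frame]
    return Trajectory(track_id=traj.track_id, detections=dets,
                      frame_interval=traj.frame_interval,
                      first_frame=first_frame, last_frame=last_frame)


def apply_quality_control(
        trajectories: Sequence[Trajectory],
        experiment_id: str = "exp",
        frame_interval: float = 10.0,
        recording_duration_min: float | None = None,
        window_start_min: float = 15.0,
        window_end_min: float = 30.0,
        min_track_fraction: float = 0.5,
        min_cell_number: int = 25,
        lateral_flow_threshold: float = 0.3,
        cell_diameter_um: float = 8.0,
        pre_activated_fraction: float = 0.5,
) -> tuple[QCResult, list[Trajectory]]:
    """Crop to the analysis window and apply experiment-level QC.

    The analysis window covers minutes ``window_start_min`` to
    ``window_end_min`` inclusive (frames 90..180 at 10 s/frame, 91 frames):
    the gradient is considered unstable earlier. A track observed in fewer
    than ``min_track_fraction`` of the window's frames is removed (strict
    "< 50%"). Flags:

    * ``low_cell_number``: fewer than 25 tracks survive,
    * ``lateral_flow``: |median lateral migration index| (net displacement
      perpendicular to the gradient / path length) exceeds 0.3,
    * ``pre_activated``: more than half of the surviving tracks travel less
      than one cell diameter in total.

    Raises ``ValueError`` for recordings shorter than the window end
    (the assay requires at least 30 min of migration). Idempotent.
    """
    if recording_duration_min is None:
        last = max((int(t.frames[-1]) for t in trajectories if len(t)), default=0)
        recording_duration_min = last * frame_interval / 60.0
    if recording_duration_min < window_end_min:
        raise ValueError(
            f"recording of {recording_duration_min:g} min rejected: at least "
            f"{window_end_min:g} min of migration are required")

    f0 = int(np.ceil(window_start_min * 60.0 / frame_interval))
    f1 = int(np.floor(window_end_min * 60.0 / frame_interval))
    n_window = f1 - f0 + 1

    kept: list[Trajectory] = []
    n_removed = 0
    for tr in trajectories:
        cropped = crop_to_window(tr, f0, f1)
        if len(cropped) >= 2 and len(cropped) >= min_track_fraction * n_window:
            kept.append(cropped)
        else:
            n_removed += 1

    lateral_indices = []
    path_lengths = []
    for tr in kept:
        pos = tr.positions
        steps = np.diff(pos, axis=0)
        path = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        path_lengths.append(path)
        if path > 0:
            lateral_indices.append((pos[-1, 1] - pos[0, 1]) / path)
    median_lat = float(np.median(lateral_indices)) if lateral_indices else 0.0
    frac_static = (float(np.mean([p < cell_diameter_um for p in path_lengths]))
                   if path_lengths else 0.0)

    result = QCResult(
        experiment_id=experiment_id,
        window_frames=(f0, f1),
        n_tracks_kept=len(kept),
        n_tracks_removed=n_removed,
        low_cell_number=len(kept) < min_cell_number,
        lateral_flow=abs(median_lat) > lateral_flow_threshold,
        pre_activated=frac_static > pre_activated_fraction,
        median_lateral_index=median_lat,
    )
    return result, kept


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_frames(path) -> np.ndarray:
    """Read a frame stack from a multi-page TIFF or a PNG/JPEG sequence dir."""
    import pathlib

    import imageio.v3 as iio
    import tifffile

    p = pathlib.Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no image files in {p}")
        return np.stack([np.asarray(iio.imread(f), dtype=np.float32) for f in files])
    if p.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(p), dtype=np.float32)
    return np.asarray(iio.imread(p), dtype=np.float32)


def trajectories_to_frame(trajectories: Sequence[Trajectory],
                          experiment_id: str = "exp") -> pd.DataFrame:
    """Tabulate trajectories as one row per (track, frame)."""
    rows = []
    for tr in trajectories:
        for d in tr.detections:
            row = {
                "experiment_id": experiment_id,
                "track_id": tr.track_id,
                "frame": d.frame,
                "t_s": d.frame * tr.frame_interval,
                "x_um": d.x_um,
                "y_um": d.y_um,
                "area_um2": d.area_um2,
            }
            if d.morphology:
                row.update(d.morphology)
            rows.append(row)
    return pd.DataFrame(rows)


def trajectories_from_ground_truth(gts, frame_interval: float = 10.0,
                                   ) -> list[Trajectory]:
    """Convert ground-truth simulated trajectories to tracked Trajectory objects.

    Bypasses rendering/segmentation: used to run the feature pipeline
    directly on simulated positions (area and morphology are absent).
    """
    out = []
    for gt in gts:
        dets = [
            Detection(frame=gt.first_frame + i, x_um=float(x), y_um=float(y),
                      area_um2=np.nan, label=gt.cell_id)
            for i, (x, y) in enumerate(gt.positions)
        ]
        out.append(Trajectory(track_id=gt.cell_id, detections=dets,
                              frame_interval=frame_interval))
    return out
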