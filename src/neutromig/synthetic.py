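"""Ground-truthed synthetic data for the chemotaxis pipeline.

Every downstream stage (segmentation, tracking, feature extraction,
harmonization, landscape) is testable against data generated here:

* cell trajectories as biased random walks in a rectangular arena, with a
  configurable fraction of gradient-responding cells,
* rendered time-lapse frames (anti-aliased disks plus Gaussian noise) in
  the geometry of the real assay (1280x720 px, 0.96 um/px, 10 s frames),
* cohort feature matrices with planted group and covariate effects,
* serum cytokine panels (27-plex) with a planted Th1-high subgroup.

The gradient axis is +x throughout: chemoattractant concentration increases
toward larger x. Responder cells draw step directions from a von Mises
distribution centered on +x with concentration ``kappa``; non-responders
draw uniform directions. Step lengths are Rayleigh with the scale chosen so
the mean step equals ``speed * frame_interval``. Arena walls reflect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("neutromig.synthetic")

__all__ = [
    "SimulationConfig",
    "GroundTruthTrajectory",
    "ImageSpec",
    "CohortConfig",
    "CytokinePanel",
    "simulate_trajectories",
    "render_frame",
    "render_frames",
    "iter_rendered_frames",
    "simulate_cytokines",
    "simulate_cohort",
    "ground_truth_to_frame",
    "write_ground_truth_csv",
    "write_frames_tiff",
    "CYTOKINE_PANEL_27PLEX",
    "DEFAULT_FEATURES",
]

# Bio-Plex Pro human 27-plex analyte panel.
CYTOKINE_PANEL_27PLEX: tuple[str, ...] = (
    "IL-1b", "IL-1ra", "IL-2", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8",
    "IL-9", "IL-10", "IL-12p70", "IL-13", "IL-15", "IL-17A", "Eotaxin",
    "FGF-basic", "G-CSF", "GM-CSF", "IFN-g", "IP-10", "MCP-1", "MIP-1a",
    "MIP-1b", "PDGF-BB", "RANTES", "TNF-a", "VEGF",
)

# Default feature catalogue: 4 dynamic + 7 morphology features.
DEFAULT_FEATURES: tuple[str, ...] = (
    "chemotactic_response", "speed", "gradient_precision", "straightness",
    "area", "perimeter", "eccentricity", "solidity",
    "intensity_mean", "intensity_sd", "texture_contrast",
)

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the biased-random-walk trajectory simulation.

    Parameters
    ----------
    n_cells:
        Number of trajectories.
    frac_responder:
        Fraction of cells whose step directions are biased toward the
        gradient (+x) axis; in [0, 1].
    kappa:
        Von Mises concentration of responder step directions about +x.
        kappa = 0 reduces responders to unbiased walkers.
    speed_mean, speed_sd:
        Mean and SD (um/min) of the per-cell mean speed; each cell's mean
        speed is drawn from a normal truncated at zero.
    frame_interval:
        Seconds between frames (default 10 s, the assay's frame rate).
    duration:
        Recording length in minutes; a valid recording is at least 30 min.
    arena:
        (width, height) of the chamber in um; walls reflect. Default is
        the full camera field of view, 1280 x 720 px at 0.96 um/px.
    seed:
        Seed for the trajectory RNG; fixed seed gives bit-identical output.
    """

    n_cells: int = 50
    frac_responder: float = 0.7
    kappa: float = 2.0
    speed_mean: float = 8.0
    speed_sd: float = 2.0
    frame_interval: float = 10.0
    duration: float = 30.0
    arena: tuple[float, float] = (1280 * 0.96, 720 * 0.96)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_responder <= 1.0):
            raise InvalidConfigError(
                f"frac_responder must be in [0, 1], got {self.frac_responder}")
        if not np.isfinite(self.kappa) or self.kappa < 0:
            raise InvalidConfigError(f"kappa must be finite and >= 0, got {self.kappa}")
        for name in ("speed_mean", "speed_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.speed_mean <= 0:
            raise InvalidConfigError("speed_mean must be positive")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")
        if self.duration < 30.0:
            raise InvalidConfigError(
                f"duration must be >= 30 min for a valid recording, got {self.duration}")
        if self.n_cells < 0:
            raise InvalidConfigError("n_cells must be >= 0")
        if min(self.arena) <= 0:
            raise InvalidConfigError("arena dimensions must be positive")

    @property
    def n_frames(self) -> int:
        """Number of frames including frame 0."""
        return int(round(self.duration * 60.0 / self.frame_interval)) + 1


@dataclass(frozen=True)
class GroundTruthTrajectory:
    """One simulated cell: true positions per frame plus responder label."""

    cell_id: int
    is_responder: bool
    positions: np.ndarray  # (n_frames, 2) in um
    first_frame: int = 0
    last_frame: int = -1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        last = self.last_frame if self.last_frame >= 0 else self.first_frame + len(pos) - 1
        object.__setattr__(self, "last_frame", last)
        if len(pos) != last - self.first_frame + 1:
            raise ValueError("positions length must equal last_frame - first_frame + 1")


@dataclass(frozen=True)
class ImageSpec:
    """Rendering geometry matching the real recordings."""

    width_px: int = 1280
    height_px: int = 720
    pixel_size: float = 0.96   # um per px
    cell_radius: float = 4.0   # um
    fg_intensity: float = 200.0
    bg_intensity: float = 50.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidConfigError("pixel_size must be positive")
        if self.fg_intensity <= self.bg_intensity:
            raise InvalidConfigError("fg_intensity must exceed bg_intensity")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Planted-effect cohort generator settings.

    ``group_effects`` maps feature name -> additive shift applied to the
    "case" group (the other half of the cohort is "control").
    ``covariate_effects`` maps covariate name ('age', 'gender', 'season',
    'batch') -> {feature: coefficient}. Gender and batch are two-level
    (coefficient added for the second level), season four-level with a
    linear contrast, age enters linearly per year centered at the cohort
    mean.
    """

    n_donors: int = 60
    group_effects: Mapping[str, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    th1_frac: float = 0.09
    noise_sd: float = 1.0
    features: Sequence[str] = DEFAULT_FEATURES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.th1_frac <= 1.0):
            raise InvalidConfigError("th1_frac must be in [0, 1]")
        if self.n_donors < 1:
            raise InvalidConfigError("n_donors must be >= 1")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _reflect(coord: np.ndarray, limit: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, limit] (reflecting walls)."""
    period = 2.0 * limit
    folded = np.mod(coord, period)
    return limit - np.abs(limit - folded)


def simulate_trajectories(config: SimulationConfig) -> list[GroundTruthTrajectory]:
    """Simulate biased-random-walk trajectories in a reflecting arena.

    Responder cells (the first ``round(frac_responder * n_cells)`` ids,
    shuffled) draw step directions from von Mises(0, kappa) about the +x
    gradient axis; the rest draw uniform directions. Step lengths are
    Rayleigh-distributed with mean = cell speed x frame interval, where
    each cell's speed is drawn from N(speed_mean, speed_sd) truncated > 0.

    Reproducible: a fixed config (including seed) yields bit-identical
    trajectories.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_steps = config.n_frames - 1
    w, h = config.arena

    n_resp = int(round(config.frac_responder * n))
    is_resp = np.zeros(n, dtype=bool)
    is_resp[:n_resp] = True
    rng.shuffle(is_resp)

    speeds = rng.normal(config.speed_mean, config.speed_sd, size=n)
    while np.any(speeds <= 0):  # truncate at zero; negligible for default params
        bad = speeds <= 0
        speeds[bad] = rng.normal(config.speed_mean, config.speed_sd, size=bad.sum())

    dt_min = config.frame_interval / 60.0
    mean_step = speeds * dt_min                      # um per frame, per cell
    rayleigh_scale = mean_step / np.sqrt(np.pi / 2.0)

    theta = rng.uniform(-np.pi, np.pi, size=(n, n_steps))
    if n_resp and config.kappa > 0:
        theta[is_resp] = rng.vonmises(0.0, config.kappa, size=(int(is_resp.sum()), n_steps))
    lengths = rng.rayleigh(scale=rayleigh_scale[:, None], size=(n, n_steps))

    start = np.column_stack([rng.uniform(0, w, size=n), rng.uniform(0, h, size=n)])
    dx = lengths * np.cos(theta)
    dy = lengths * np.sin(theta)
    # integrate with per-step reflection: a biased cell presses against the
    # wall instead of bouncing away (folding the cumulative sum would
    # reverse the drift after a wall contact)
    x = np.empty((n, n_steps + 1))
    y = np.empty((n, n_steps + 1))
    x[:, 0] = start[:, 0]
    y[:, 0] = start[:, 1]
    for t in range(n_steps):
        x[:, t + 1] = _reflect(x[:, t] + dx[:, t], w)
        y[:, t + 1] = _reflect(y[:, t] + dy[:, t], h)

    return [
        GroundTruthTrajectory(
            cell_id=i,
            is_responder=bool(is_resp[i]),
            positions=np.column_stack([x[i], y[i]]),
        )
        for i in range(n)
    ]


def ground_truth_to_frame(trajectories: Sequence[GroundTruthTrajectory],
                          frame_interval: float) -> pd.DataFrame:
    """Tabulate ground truth as (cell_id, frame, t_s, x_um, y_um, is_responder)."""
    rows = []
    for tr in trajectories:
        frames = np.arange(tr.first_frame, tr.last_frame + 1)
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "frame": frames,
            "t_s": frames * frame_interval,
            "x_um": tr.positions[:, 0],
            "y_um": tr.positions[:, 1],
            "is_responder": tr.is_responder,
        }))
    if not rows:
        return pd.DataFrame(
            columns=["cell_id", "frame", "t_s", "x_um", "y_um", "is_responder"])
    return pd.concat(rows, ignore_index=True)


def write_ground_truth_csv(trajectories: Sequence[GroundTruthTrajectory],
                           frame_interval: float, path) -> None:
    ground_truth_to_frame(trajectories, frame_interval).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_disk(img: np.ndarray, cx_px: float, cy_px: float, r_px: float,
               amplitude: float) -> None:
    """Add an anti-aliased disk in place (coverage-weighted edge)."""
    h, w = img.shape
    x0 = max(int(np.floor(cx_px - r_px - 1)), 0)
    x1 = min(int(np.ceil(cx_px + r_px + 2)), w)
    y0 = max(int(np.floor(cy_px - r_px - 1)), 0)
    y1 = min(int(np.ceil(cy_px + r_px + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx_px, yy - cy_px)
    cover = np.clip(r_px + 0.5 - d, 0.0, 1.0)
    img[y0:y1, x0:x1] += amplitude * cover


def render_frame(trajectories: Sequence[GroundTruthTrajectory], frame: int,
                 spec: ImageSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame (float32, grey levels) of the given trajectories.

    Cells are anti-aliased disks of radius ``spec.cell_radius`` at their
    true position; positions outside the field of view are clipped to the
    frame with a warning. Gaussian noise of sd ``spec.noise_sd`` is added
    when ``rng`` is given and noise_sd > 0.
    """
    img = np.full((spec.height_px, spec.width_px), spec.bg_intensity, dtype=np.float64)
    r_px = spec.cell_radius / spec.pixel_size
    amp = spec.fg_intensity - spec.bg_intensity
    wx = spec.width_px - 1
    wy = spec.height_px - 1
    n_clipped = 0
    for tr in trajectories:
        if not (tr.first_frame <= frame <= tr.last_frame):
            continue
        x_um, y_um = tr.positions[frame - tr.first_frame]
        cx = x_um / spec.pixel_size
        cy = y_um / spec.pixel_size
        if not (0 <= cx <= wx and 0 <= cy <= wy):
            n_clipped += 1
            cx = min(max(cx, 0.0), wx)
            cy = min(max(cy, 0.0), wy)
        _draw_disk(img, cx, cy, r_px, amp)
    if n_clipped:
        logger.warning("frame %d: %d cell position(s) outside the field of "
                       "view; clipped to the frame edge", frame, n_clipped)
    if rng is not None and spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img.astype(np.float32)


def iter_rendered_frames(trajectories: Sequence[GroundTruthTrajectory],
                         spec: ImageSpec, n_frames: int,
                         seed: int = 0) -> Iterator[np.ndarray]:
    """Yield rendered frames one at a time (memory-friendly for long stacks)."""
    rng = np.random.default_rng(seed)
    for f in range(n_frames):
        yield render_frame(trajectories, f, spec, rng if spec.noise_sd > 0 else None)


def render_frames(trajectories: Sequence[GroundTruthTrajectory], spec: ImageSpec,
                  n_frames: int | None = None, seed: int = 0) -> np.ndarray:
    """Render a full image stack, shape (n_frames, height, width), float32."""
    if n_frames is None:
        n_frames = max((tr.last_frame for tr in trajectories), default=-1) + 1
    return np.stack(list(iter_rendered_frames(trajectories, spec, n_frames, seed)))


def write_frames_tiff(stack: np.ndarray, path) -> None:
    """Write an image stack as a multi-page 8-bit TIFF."""
    tifffile.imwrite(path, np.clip(stack, 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# cytokines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytokinePanel:
    """Simulated serum panel: concentrations (pg/ml), donor metadata, truth."""

    values: pd.DataFrame        # donors x analytes, pg/ml
    meta: pd.DataFrame          # age, gender, date, is_control per donor
    is_th1_planted: pd.Series   # ground-truth planted Th1-high labels


# log-scale population SD shared by all analytes; planted IL-2/IFN-g shift
# of 4.0 (= 5 such SDs) puts planted donors above the cohort 75% quantile
# with probability >> 0.99.
_CYTO_LOG_SD = 0.8
_TH1_SHIFT = 4.0
# secondary inflammation markers elevated in the Th1-high subgroup
_TH1_SECONDARY = {"IL-6": 1.0, "IL-1b": 1.0, "TNF-a": 1.0, "G-CSF": 1.0}


def simulate_cytokines(config: CohortConfig) -> CytokinePanel:
    """Simulate a 27-plex serum cytokine panel with a planted Th1-high subgroup.

    Concentrations are lognormal per analyte. ``round(th1_frac * n_donors)``
    donors receive a +4.0 shift (log scale, 5 population SDs) on IL-2 and
    IFN-g, which exceeds the cohort 75% quantile with probability >= 0.99,
    plus milder shifts on IL-6, IL-1b, TNF-a and G-CSF. Age, gender and
    measurement-date effects are added on the log scale. Deterministic for
    a fixed config.
    """
    if config.th1_frac > 0.25:
        warnings.warn(
            "th1_frac > 0.25: planted Th1-high donors cannot all exceed the "
            "75% quantile; planted labels may be unrecoverable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    n = config.n_donors
    analytes = list(CYTOKINE_PANEL_27PLEX)

    age = rng.integers(6, 18, size=n).astype(float)
    gender = rng.choice(["female", "male"], size=n)
    day = rng.integers(0, 365 * 2, size=n)  # days since study start
    date = pd.to_datetime("2019-01-01") + pd.to_timedelta(day, unit="D")

    n_th1 = int(round(config.th1_frac * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_th1, replace=False)] = True

    # per-analyte baseline log-concentration, fixed by the seed
    mu = rng.uniform(np.log(2.0), np.log(200.0), size=len(analytes))
    logc = mu[None, :] + rng.normal(0.0, _CYTO_LOG_SD, size=(n, len(analytes)))
    # covariate effects on the log scale (small, realistic nuisance structure)
    logc += 0.02 * (age[:, None] - age.mean())
    logc += 0.1 * (gender == "male")[:, None]
    logc += 0.0004 * (day[:, None] - day.mean())
    for analyte, shift in {"IL-2": _TH1_SHIFT, "IFN-g": _TH1_SHIFT, **_TH1_SECONDARY}.items():
        logc[planted, analytes.index(analyte)] += shift

    donors = pd.Index([f"D{i:03d}" for i in range(n)], name="donor_id")
    values = pd.DataFrame(np.exp(logc), index=donors, columns=analytes)
    meta = pd.DataFrame(
        {"age": age, "gender": gender, "date": date, "is_control": False},
        index=donors)
    return CytokinePanel(values=values, meta=meta,
                         is_th1_planted=pd.Series(planted, index=donors, name="th1_planted"))


# ---------------------------------------------------------------------------
# cohort feature matrices
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an experiments x features matrix with planted effects.

    Each feature is unit-normal noise plus the configured group shift
    (applied to the "case" half of the cohort) and covariate effects.
    Returns ``(features, meta)`` where ``meta`` carries group, gender, age,
    season and batch per experiment for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_donors
    feats = list(config.features)

    group = np.array(["control"] * (n - n // 2) + ["case"] * (n // 2))
    rng.shuffle(group)
    gender = rng.choice(["female", "male"], size=n)
    age = rng.integers(6, 18, size=n).astype(float)
    season = rng.choice(SEASONS, size=n)
    batch = rng.choice(["B1", "B2"], size=n)

    X = rng.normal(0.0, config.noise_sd, size=(n, len(feats)))
    for j, f in enumerate(feats):
        X[:, j] += config.group_effects.get(f, 0.0) * (group == "case")
        eff = config.covariate_effects
        X[:, j] += eff.get("age", {}).get(f, 0.0) * (age - age.mean())
        X[:, j] += eff.get("gender", {}).get(f, 0.0) * (gender == "male")
        X[:, j] += eff.get("batch", {}).get(f, 0.0) * (batch == "B2")
        season_idx = np.array([SEASONS.index(s) for s in season], dtype=float)
        X[:, j] += eff.get("season", {}).get(f, 0.0) * (season_idx - 1.5)

    idx = pd.Index([f"E{i:03d}" for i in range(n)], name="experiment_id")
    features = pd.DataFrame(X, index=idx, columns=feats)
    meta = pd.DataFrame(
        {"group": group, "gender": gender, "age": age, "season": season, "batch": batch},
        index=idx)
    return features, meta
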