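"""End-to-end orchestration: simulate -> track -> features -> harmonize ->
landscape -> report, with one config object, stage toggles and fixed seeds.

Every threshold that has an assay-defined value is a named default here:
the 15-30 min analysis window, the 50% track-length filter, the 25-cell
minimum, the 0.85 correlation threshold for feature selection and the 0.75
quantile of the Th1 rule. Stage outputs are pure functions of inputs,
config and seed; a rerun with the same config writes byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import harmonize, imaging, landscape, synthetic

logger = logging.getLogger("neutromig.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_config",
           "load_config", "save_config"]

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage parameters and toggles of a pipeline run."""

    # stages
    do_simulate: bool = True
    do_imaging: bool = False          # render + segment + track (slow path)
    do_features: bool = True
    do_harmonize: bool = True
    do_landscape: bool = True
    do_report: bool = True

    # reproducibility / output
    seed: int = 0
    outdir: str = "neutromig_out"

    # simulated cohort: two planted migration phenotype groups
    n_per_group: int = 30
    n_cells: int = 40
    frac_responder_a: float = 0.75
    frac_responder_b: float = 0.50
    kappa: float = 2.0
    speed_mean: float = 8.0
    speed_sd: float = 2.0
    frame_interval: float = 10.0      # s
    duration: float = 30.0            # min
    chemokine: str = "LTB4"

    # imaging / tracking
    pixel_size: float = 0.96          # um per px
    min_area: float = 20.0            # um^2
    max_disp: float = 10.0            # um per frame (linking gate)
    max_gap: int = 2                  # frames

    # QC (assay-defined defaults)
    window_start_min: float = 15.0
    window_end_min: float = 30.0
    min_track_fraction: float = 0.5
    min_cell_number: int = 25
    lateral_flow_threshold: float = 0.3
    cell_diameter_um: float = 8.0

    # harmonization
    r_threshold: float = 0.85

    # landscape / phenotype
    n_neighbors: int = 15
    min_dist: float = 0.1
    dbscan_min_pts: int = 5
    th1_quantile: float = 0.75
    th1_frac: float = 0.09
    exclude_outliers: bool = False


@dataclass
class RunReport:
    """Per-stage record counts, exclusions and parameter echo."""

    version: str
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        """Rows leaving each stage equal rows entering the next minus the
        logged exclusions."""
        s = self.stages
        ok = True
        if "simulate" in s and "features" in s:
            ok &= (s["features"]["n_experiments_in"] == s["simulate"]["n_experiments"])
            ok &= (s["features"]["n_experiments_out"]
                   == s["features"]["n_experiments_in"] - s["features"]["n_excluded"])
        if "features" in s and "harmonize" in s:
            ok &= s["harmonize"]["n_rows"] == s["features"]["n_experiments_out"]
        if "harmonize" in s and "landscape" in s:
            ok &= s["landscape"]["n_rows"] == s["harmonize"]["n_rows"]
        return bool(ok)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every violation in the config; an empty list means valid."""
    v: list[str] = []
    if not (0 <= config.frac_responder_a <= 1):
        v.append(f"frac_responder_a must be in [0, 1], got {config.frac_responder_a}")
    if not (0 <= config.frac_responder_b <= 1):
        v.append(f"frac_responder_b must be in [0, 1], got {config.frac_responder_b}")
    if not (0 < config.r_threshold <= 1):
        v.append(f"r_threshold must be in (0, 1], got {config.r_threshold}")
    if not (0 < config.th1_quantile < 1):
        v.append(f"th1_quantile must be in (0, 1), got {config.th1_quantile}")
    if config.window_end_min <= config.window_start_min:
        v.append("analysis window end must be after its start")
    for name in ("n_per_group", "n_cells", "min_cell_number", "n_neighbors",
                 "dbscan_min_pts"):
        if getattr(config, name) < 1:
            v.append(f"{name} must be >= 1, got {getattr(config, name)}")
    for name in ("speed_mean", "frame_interval", "duration", "pixel_size",
                 "max_disp", "cell_diameter_um"):
        if getattr(config, name) <= 0:
            v.append(f"{name} must be positive, got {getattr(config, name)}")
    for name in ("speed_sd", "min_area", "lateral_flow_threshold",
                 "min_track_fraction", "th1_frac", "min_dist"):
        if getattr(config, name) < 0:
            v.append(f"{name} must be >= 0, got {getattr(config, name)}")
    if config.max_gap < 0:
        v.append(f"max_gap must be >= 0, got {config.max_gap}")
    return v


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _experiment_seed(base_seed: int, index: int) -> int:
    # stable per-experiment seed, kept below 2**31
    return int((base_seed * 100003 + 17 * index + 1) % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in fixed order and write all artifacts.

    Simulation builds a two-group cohort (group A responds more strongly
    to the gradient than group B); each experiment is an independent
    trajectory simulation. With ``do_imaging`` the trajectories are
    rendered and re-extracted by segmentation + linking, otherwise the
    feature stage consumes the simulated positions directly.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed,
                       config=dataclasses.asdict(config))

    profiles_df: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None

    if config.do_simulate:
        try:
            profiles_df, meta, qc_rows, n_tracks = _simulate_cohort_stage(config)
        except Exception as err:
            raise RuntimeError(f"stage 'simulate' failed: {err}") from err
        report.stages["simulate"] = {
            "n_experiments": 2 * config.n_per_group,
            "n_tracks_total": int(n_tracks),
        }
        pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.csv", index=False)

    if config.do_features and profiles_df is not None:
        n_in = 2 * config.n_per_group
        excluded = int(n_in - len(profiles_df))
        report.stages["features"] = {
            "n_experiments_in": n_in,
            "n_experiments_out": len(profiles_df),
            "n_excluded": excluded,
        }
        profiles_df.to_csv(outdir / "experiment_profiles.csv")
        meta.to_csv(outdir / "experiment_metadata.csv")

    if config.do_harmonize and profiles_df is not None:
        try:
            if profiles_df.empty:
                raise ValueError("no experiments passed QC")
            feature_cols = [c for c in profiles_df.columns
                            if c not in ("chemokine", "donor_id", "n_cells")]
            covs = meta[["gender", "age", "season", "batch"]]
            normalized, removal_log = harmonize.harmonize_profiles(
                profiles_df[feature_cols], covs, r_threshold=config.r_threshold)
            # group contrasts are reported for every feature, selected or not
            normalized_all = harmonize.zscore(
                harmonize.residualize(profiles_df[feature_cols], covs))
        except Exception as err:
            raise RuntimeError(f"stage 'harmonize' failed: {err}") from err
        report.stages["harmonize"] = {
            "n_rows": len(normalized),
            "n_features_in": len(feature_cols),
            "n_features_out": normalized.shape[1],
            "n_features_removed": len(removal_log),
        }
        normalized.to_csv(outdir / "normalized_profiles.csv")
        removal_log.to_csv(outdir / "feature_removal_log.csv", index=False)

    if config.do_landscape and normalized is not None:
        try:
            emb = landscape.embed_landscape(
                normalized, n_neighbors=config.n_neighbors,
                min_dist=config.min_dist, seed=config.seed)
            clusters = landscape.cluster_landscape(emb, min_pts=config.dbscan_min_pts)
            if config.exclude_outliers:
                outliers = landscape.flag_embedding_outliers(emb)
                clusters = clusters[~outliers]
            comparisons = [
                landscape.compare_groups(
                    normalized_all[c], meta.loc[normalized_all.index, "group"],
                    test="t", feature=c)
                for c in normalized_all.columns
            ]
        except Exception as err:
            raise RuntimeError(f"stage 'landscape' failed: {err}") from err
        emb_out = emb.coords.copy()
        emb_out["cluster"] = clusters
        emb_out.to_csv(outdir / "landscape_embedding.csv")
        pd.DataFrame([dataclasses.asdict(c) for c in comparisons]).to_csv(
            outdir / "group_comparisons.csv", index=False)
        report.stages["landscape"] = {
            "n_rows": len(emb.coords),
            "n_clusters": int(len(set(clusters[clusters >= 0]))),
            "umap_params": {"n_neighbors": config.n_neighbors,
                            "min_dist": config.min_dist, "seed": config.seed},
        }

        # serum phenotype side-channel: one cytokine panel per donor
        cyto_cfg = synthetic.CohortConfig(
            n_donors=len(meta.index.unique()), th1_frac=config.th1_frac,
            seed=_experiment_seed(config.seed, 999983))
        panel = synthetic.simulate_cytokines(cyto_cfg)
        norm_cyto = harmonize.preprocess_cytokines(panel.values, panel.meta)
        th1 = landscape.classify_th1(norm_cyto, is_control=panel.meta["is_control"],
                                     quantile=config.th1_quantile)
        th1.to_csv(outdir / "th1_phenotypes.csv")
        report.stages["phenotype"] = {
            "n_donors": len(th1),
            "n_th1_high": int((th1["th1_class"] == "high").sum()),
            "n_th1_low": int((th1["th1_class"] == "low").sum()),
        }

    if config.do_report:
        report.to_json(outdir / "run_report.json")
        save_config(config, outdir / "config_echo.yaml")
        logger.info("pipeline finished; report written to %s", outdir / "run_report.json")

    return report


def _simulate_cohort_stage(config: PipelineConfig):
    """Simulate, (optionally image), QC and profile every experiment."""
    rows = []
    qc_rows = []
    meta_rows = []
    n_tracks = 0
    rng = np.random.default_rng(_experiment_seed(config.seed, 0))
    n_total = 2 * config.n_per_group

    for i in range(n_total):
        group = "A" if i < config.n_per_group else "B"
        frac = config.frac_responder_a if group == "A" else config.frac_responder_b
        sim = synthetic.SimulationConfig(
            n_cells=config.n_cells, frac_responder=frac, kappa=config.kappa,
            speed_mean=config.speed_mean, speed_sd=config.speed_sd,
            frame_interval=config.frame_interval, duration=config.duration,
            seed=_experiment_seed(config.seed, i + 1))
        gts = synthetic.simulate_trajectories(sim)

        if config.do_imaging:
            spec = synthetic.ImageSpec(pixel_size=config.pixel_size)
            frames = synthetic.iter_rendered_frames(
                gts, spec, sim.n_frames, seed=_experiment_seed(config.seed, i + 1))
            tracks = imaging.detect_and_track(
                frames, min_area=config.min_area, pixel_size=config.pixel_size,
                max_disp=config.max_disp, max_gap=config.max_gap,
                frame_interval=config.frame_interval)
        else:
            tracks = imaging.trajectories_from_ground_truth(
                gts, frame_interval=config.frame_interval)
        n_tracks += len(tracks)

        exp_id = f"E{i:03d}"
        qc, kept = imaging.apply_quality_control(
            tracks, experiment_id=exp_id,
            frame_interval=config.frame_interval,
            recording_duration_min=config.duration,
            window_start_min=config.window_start_min,
            window_end_min=config.window_end_min,
            min_track_fraction=config.min_track_fraction,
            min_cell_number=config.min_cell_number,
            lateral_flow_threshold=config.lateral_flow_threshold,
            cell_diameter_um=config.cell_diameter_um)
        qc_rows.append(dataclasses.asdict(qc))

        # covariates for the harmonization stage
        meta_rows.append({
            "experiment_id": exp_id, "group": group,
            "gender": ["female", "male"][int(rng.integers(2))],
            "age": float(rng.integers(6, 18)),
            "season": synthetic.SEASONS[int(rng.integers(4))],
            "batch": ["B1", "B2"][int(rng.integers(2))],
        })

        if qc.low_cell_number or qc.lateral_flow or qc.pre_activated:
            continue
        profs = [p for p in (feat.compute_dynamic_profile(t) for t in kept)
                 if p is not None]
        profile = feat.aggregate_experiment(
            profs, experiment_id=exp_id, chemokine=config.chemokine,
            donor_id=f"D{i:03d}")
        rows.append(profile.to_row())

    if rows:
        profiles_df = pd.DataFrame(rows).set_index("experiment_id")
    else:
        profiles_df = pd.DataFrame(columns=["experiment_id"]).set_index("experiment_id")
    meta = pd.DataFrame(meta_rows).set_index("experiment_id")
    return profiles_df, meta, qc_rows, n_tracks
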