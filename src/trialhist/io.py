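"""Session persistence, run configuration and end-to-end orchestration.

A session is stored as plain files in one directory: ``trials.csv`` and
``pose.csv`` tables, array containers for the video factors and activity,
``ground_truth.json`` plus an array container for the planted weights, and
``config.yaml`` with the fully resolved generation parameters. ``run_all``
drives simulate -> behavior -> align -> decode -> encode -> geometry from a
single config and writes a machine-readable summary whose metadata records
the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import alignment, behavior, decoding, encoding, geometry, synthetic
from .synthetic import (
    BehaviorParams,
    GroundTruth,
    NeuralRecording,
    PopulationConfig,
    PoseTrack,
    Session,
    SessionConfig,
    VideoFactors,
)
from .task import TaskConfig

SCHEMA_VERSION = 1

TRIALS_COLUMNS = [
    "stimulus_rate", "stim_events", "completed", "choice", "outcome",
    "t_initiation", "t_stim_onset", "t_go_cue", "t_center_exit",
    "t_report", "t_outcome_end",
]


class SchemaError(ValueError):
    pass


# --------------------------------------------------------------------------
# trial table and pose CSV
# --------------------------------------------------------------------------

def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    out["stim_events"] = [
        ";".join(f"{t:.6f}" for t in np.atleast_1d(ev)) for ev in out["stim_events"]
    ]
    out["choice"] = out["choice"].fillna("")
    out["outcome"] = out["outcome"].fillna("")
    out.insert(0, "schema_version", SCHEMA_VERSION)
    out.to_csv(path, index_label="trial")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="trial", keep_default_na=False, na_values=[])
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trials.csv missing column(s): {missing}")
    df = df.drop(columns=["schema_version"], errors="ignore")
    if len(df) == 0:
        df["stim_events"] = df.get("stim_events", pd.Series(dtype=object))
        return df
    df["stim_events"] = [
        np.array([float(x) for x in str(s).split(";") if x != ""])
        for s in df["stim_events"]
    ]
    df["choice"] = df["choice"].replace("", None)
    df["outcome"] = df["outcome"].replace("", None)
    df["completed"] = df["completed"].astype(bool)
    for c in TRIALS_COLUMNS[5:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_pose_csv(pose: PoseTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "x": pose.position[:, 0],
            "y": pose.position[:, 1],
            "pitch": pose.angles[:, 0],
            "roll": pose.angles[:, 1],
            "yaw": pose.angles[:, 2],
        }
    )
    df.insert(0, "schema_version", SCHEMA_VERSION)
    df.to_csv(path, index_label="frame")


def read_pose_csv(path: str | Path, frame_rate: float) -> PoseTrack:
    df = pd.read_csv(path, index_col="frame")
    for c in ("x", "y", "pitch", "roll", "yaw"):
        if c not in df.columns:
            raise SchemaError(f"pose.csv missing column {c!r}")
    return PoseTrack(
        position=df[["x", "y"]].to_numpy(float),
        angles=df[["pitch", "roll", "yaw"]].to_numpy(float),
        frame_rate=frame_rate,
    )


# --------------------------------------------------------------------------
# session directory
# --------------------------------------------------------------------------

def _config_dict(cfg: SessionConfig) -> dict:
    return dataclasses.asdict(cfg)


def _config_from_dict(d: dict) -> SessionConfig:
    task = dict(d["task"])
    task["stimulus_rates"] = tuple(task["stimulus_rates"])
    task["arena_size"] = tuple(task["arena_size"])
    beh = dict(d["behavior"])
    beh["beta_hist"] = tuple(beh["beta_hist"])
    return SessionConfig(
        task=TaskConfig(**task),
        behavior=BehaviorParams(**beh),
        population=PopulationConfig(**d["population"]),
        n_trials=d["n_trials"],
        n_video_components=d["n_video_components"],
        video_noise_sd=d["video_noise_sd"],
    )


def save_session(session: Session, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials_csv(session.trial_table, out / "trials.csv")
    write_pose_csv(session.pose, out / "pose.csv")
    np.savez_compressed(
        out / "video_factors.npz",
        video=session.video_factors.video,
        motion_energy=session.video_factors.motion_energy,
    )
    np.savez_compressed(
        out / "activity.npz",
        fluorescence=session.recording.fluorescence,
        spike_rate=session.recording.spike_rate,
    )
    if session.ground_truth is not None:
        gt = session.ground_truth
        arrays = {
            f.name: getattr(gt, f.name)
            for f in dataclasses.fields(gt)
            if f.name != "classes"
        }
        np.savez_compressed(out / "ground_truth.npz", **arrays)
        (out / "ground_truth.json").write_text(
            json.dumps({"classes": gt.classes.tolist(),
                        "schema_version": SCHEMA_VERSION})
        )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"schema_version": SCHEMA_VERSION, "seed": session.seed,
             "session_config": _config_dict(session.session_config)},
            fh,
        )
    return out


def load_session(in_dir: str | Path) -> Session:
    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    config = _config_from_dict(meta["session_config"])
    fs = config.task.frame_rate
    trials = read_trials_csv(src / "trials.csv")
    pose = read_pose_csv(src / "pose.csv", fs)
    vf = np.load(src / "video_factors.npz")
    act = np.load(src / "activity.npz")
    truth = None
    if (src / "ground_truth.npz").exists():
        gt_arrays = dict(np.load(src / "ground_truth.npz"))
        classes = np.array(
            json.loads((src / "ground_truth.json").read_text())["classes"],
            dtype=object,
        )
        truth = GroundTruth(classes=classes, **gt_arrays)
    return Session(
        trial_table=trials,
        pose=pose,
        video_factors=VideoFactors(
            video=vf["video"], motion_energy=vf["motion_energy"]
        ),
        recording=NeuralRecording(
            fluorescence=act["fluorescence"],
            spike_rate=act["spike_rate"],
            frame_rate=fs,
        ),
        ground_truth=truth,
        config=config.task,
        session_config=config,
        seed=int(meta["seed"]),
    )


# --------------------------------------------------------------------------
# run configuration and orchestration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable end-to-end run configuration."""

    out_dir: str = "trialhist_run"
    seed: int = 0
    session: SessionConfig = field(default_factory=SessionConfig)
    stages: tuple[str, ...] = ("behavior", "decode", "encode", "geometry")
    decode_timepoint_stride: int = 10
    decode_rounds: int = 20
    encode_variables: tuple[str, ...] | None = None
    encode_n_video: int | None = None
    encode_n_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "session" in d:
            d["session"] = _config_from_dict(d["session"])
        for key in ("stages", "encode_variables"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"] = _config_dict(self.session)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the configured pipeline stages and write a summary bundle.

    Any stage failure aborts with an error naming the stage. Returns the
    summary dict (also written as ``summary.json`` with a human-readable
    ``report.md``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "metadata": {"config_hash": config.digest(), "seed": config.seed},
        "warnings": {},
    }

    always = {"simulate", "align"}

    def run_stage(name, fn):
        if name not in always and name not in config.stages:
            return None
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    session = run_stage("simulate", lambda: synthetic.make_session(
        config.session, seed=config.seed
    ))
    save_session(session, out / "session")
    summary["simulate"] = {
        "n_trials": int(len(session.trial_table)),
        "n_completed": int(session.trial_table["completed"].sum()),
        "n_neurons": session.recording.n_neurons,
        "n_frames": session.recording.n_frames,
    }

    def _behavior():
        fit = behavior.fit_choice_model(
            session.trial_table, session.config, seed=config.seed
        )
        psy = behavior.fit_psychometric(session.trial_table, cfg=session.config)
        return {
            "choice_model": {
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "beta_hist": fit.beta_hist.tolist(),
                "history_strength": fit.history_strength,
            },
            "psychometric": {
                "alpha": psy.alpha, "beta": psy.beta,
                "gamma": psy.gamma, "lambda": psy.lambda_,
            },
        }

    res = run_stage("behavior", _behavior)
    if res:
        summary["behavior"] = res

    tensor = None
    if {"decode", "encode", "geometry"} & set(config.stages):
        tensor = run_stage("align", lambda: alignment.align_activity(
            session.recording.spike_rate, session.config.frame_rate,
            session.trial_table, smooth=True,
        ))
        summary["align"] = {
            "n_trials_aligned": tensor.n_trials,
            "n_timepoints": tensor.n_timepoints,
            "n_dropped": tensor.n_dropped,
        }

    def _decode():
        protocol = decoding.DecoderProtocol(n_rounds=config.decode_rounds)
        tps = np.arange(0, tensor.n_timepoints, config.decode_timepoint_stride)
        result = decoding.decode_timecourse(
            tensor, protocol, seed=config.seed, timepoints=tps
        )
        return {
            "overall_accuracy": result.overall_accuracy,
            "shuffled_accuracy": float(np.mean(result.shuffled_accuracy)),
            "per_class_accuracy": {
                c: float(result.class_accuracy[:, j].mean())
                for j, c in enumerate(result.classes)
            },
        }

    res = run_stage("decode", _decode)
    if res:
        summary["decode"] = res

    part = None

    def _encode():
        nonlocal part
        tensor_f = alignment.align_activity(
            session.recording.fluorescence, session.config.frame_rate,
            session.trial_table, smooth=False,
        )
        design = encoding.build_design_matrix(
            session, tensor_f,
            variables=config.encode_variables,
            n_video=config.encode_n_video,
        )
        design = encoding.orthogonalize_video(design)
        Y = tensor_f.activity.reshape(-1, tensor_f.n_neurons)
        part = encoding.variance_partition(
            design, Y, n_folds=config.encode_n_folds, seed=config.seed
        )
        part.unique.to_csv(out / "unique_variance.csv")
        part.maximal.to_csv(out / "maximal_variance.csv")
        summary["_design"] = design
        return {
            "mean_cv_r2_full": float(np.nanmean(part.cv_r2_full)),
            "mean_unique": {
                v: float(part.unique[v].mean()) for v in part.variables
            },
            "mean_maximal": {
                v: float(part.maximal[v].mean()) for v in part.variables
            },
        }

    res = run_stage("encode", _encode)
    if res:
        summary["encode"] = res

    def _geometry():
        design = summary.pop("_design")
        gout = {}
        for var in ("trial_history", "chest_position", "video"):
            if var not in design.blocks:
                continue
            W, _ = geometry.weight_tensor(part.full_fit, design, var)
            gout[var] = {"pca_dimensionality_90": geometry.pca_dimensionality(W)}
        return gout

    if "geometry" in config.stages and "encode" in config.stages:
        res = run_stage("geometry", _geometry)
        if res:
            summary["geometry"] = res
    summary.pop("_design", None)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    lines = ["# trialhist run report", ""]
    for k, v in summary.items():
        lines.append(f"## {k}\n\n```\n{json.dumps(v, indent=2, default=str)}\n```\n")
    (out / "report.md").write_text("\n".join(lines))
    return summary


# --------------------------------------------------------------------------
# cross-session correlation (plumbing statistic)
# --------------------------------------------------------------------------

def correlate_behavior_neural(
    behavioral: np.ndarray,
    neural: np.ndarray,
    n_permutations: int = 10000,
    seed: int = 0,
) -> dict:
    """Pearson correlation with a permutation p-value across sessions.

    Returns ``{"r": nan, "p": nan, "n": n, "defined": False}`` for fewer
    than 3 paired sessions.
    """
    x = np.asarray(behavioral, dtype=float)
    y = np.asarray(neural, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have the same length")
    if len(x) < 3:
        return {"r": np.nan, "p": np.nan, "n": int(len(x)), "defined": False}
    res = stats.pearsonr(
        x, y,
        method=stats.PermutationMethod(
            n_resamples=n_permutations, rng=np.random.default_rng(seed)
        ),
    )
    return {
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(len(x)),
        "defined": True,
    }
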