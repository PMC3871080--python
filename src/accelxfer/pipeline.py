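"""End-to-end orchestration: one configured run from simulation to report.

A run executes simulate -> shaker-compare -> extract-features ->
transfer-eval, writing every stage output as plain CSV plus a run manifest
(config echo, seed, package versions) and a human-readable summary.  All
randomness flows from the single master seed through named child streams
(:func:`accelxfer.synthetic_data.child_rng`), so two runs with the same
config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import DEFAULT_BAND, extract_table
from .shaker_analysis import (
    DEFAULT_RPMS,
    NOMINAL_HZ,
    ShakerTrial,
    compare_devices,
)
from .signal_core import make_windows, write_recording
from .synthetic_data import (
    DEFAULT_DEVICE_A,
    DEFAULT_DEVICE_B,
    ActivityModel,
    DeviceModel,
    ShakerConfig,
    StudyConfig,
    apply_device_model,
    build_study,
    child_rng,
    default_activity_models,
    true_shaker_recording,
)
from .transfer_eval import ModelSpec, transfer_grid, two_proportion_z

log = logging.getLogger("accelxfer")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; round-trips through YAML."""

    master_seed: int = 0
    fs: float = 80.0
    subjects: tuple[str, ...] = tuple(f"S{i:02d}" for i in range(1, 9))
    duration_s: float = 120.0
    rpms: tuple[float, ...] = DEFAULT_RPMS
    n_shaker_trials: int = 10
    radius_m: float = 0.0508
    window_s: float = 20.0
    use_last_s: float = 60.0
    band: tuple[float, float] = DEFAULT_BAND
    n_perm: int = 2000
    device_a: DeviceModel = DEFAULT_DEVICE_A
    device_b: DeviceModel | None = DEFAULT_DEVICE_B
    activities: dict[str, ActivityModel] = field(default_factory=default_activity_models)
    n_trees: int = 500
    classifier_seed: int = 0

    # -- config file round-trip ------------------------------------------

    @staticmethod
    def _plain(obj):
        """Recursively convert tuples to lists for YAML serialisation."""
        if isinstance(obj, (list, tuple)):
            return [RunConfig._plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: RunConfig._plain(v) for k, v in obj.items()}
        return obj

    def to_dict(self) -> dict:
        d = {
            "master_seed": self.master_seed,
            "fs": self.fs,
            "subjects": list(self.subjects),
            "duration_s": self.duration_s,
            "rpms": list(self.rpms),
            "n_shaker_trials": self.n_shaker_trials,
            "radius_m": self.radius_m,
            "window_s": self.window_s,
            "use_last_s": self.use_last_s,
            "band": list(self.band),
            "n_perm": self.n_perm,
            "n_trees": self.n_trees,
            "classifier_seed": self.classifier_seed,
            "devices": [
                self._plain(dataclasses.asdict(d))
                for d in ([self.device_a] if self.device_b is None
                          else [self.device_a, self.device_b])
            ],
            "activities": {
                k: self._plain(dataclasses.asdict(v))
                for k, v in self.activities.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        devices = d.pop("devices", None)
        activities = d.pop("activities", None)
        kwargs = {}
        for f in (
            "master_seed", "fs", "duration_s", "n_shaker_trials", "radius_m",
            "window_s", "use_last_s", "n_perm", "n_trees", "classifier_seed",
        ):
            if f in d:
                kwargs[f] = d.pop(f)
        if "subjects" in d:
            subj = d.pop("subjects")
            if isinstance(subj, int):
                subj = [f"S{i:02d}" for i in range(1, subj + 1)]
            kwargs["subjects"] = tuple(subj)
        if "rpms" in d:
            kwargs["rpms"] = tuple(d.pop("rpms"))
        if "band" in d:
            kwargs["band"] = tuple(d.pop("band"))
        if devices is not None:
            models = []
            for spec in devices:
                spec = dict(spec)
                for key in ("gain", "offset"):
                    if isinstance(spec.get(key), list):
                        spec[key] = tuple(spec[key])
                models.append(DeviceModel(**spec))
            kwargs["device_a"] = models[0]
            kwargs["device_b"] = models[1] if len(models) > 1 else None
        if activities is not None and activities != "default":
            kwargs["activities"] = {
                k: ActivityModel(
                    label=v.get("label", k),
                    harmonics=tuple(tuple(h) for h in v.get("harmonics", ())),
                    burst_rate=v.get("burst_rate", 0.0),
                    burst_amp=v.get("burst_amp", 0.0),
                    baseline_sd=v.get("baseline_sd", 0.01),
                    subject_cv=v.get("subject_cv", 0.2),
                )
                for k, v in activities.items()
            }
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def simulate_shaker_trials(cfg: RunConfig) -> dict[float, list[ShakerTrial]]:
    """Paired shaker trials per platform speed.

    Each trial draws its own orbit phase (devices are repositioned between
    trials); the two devices record the same true motion with independent
    sensor noise keyed, as in the wear study, by device parameters.
    """
    devices = [d for d in (cfg.device_a, cfg.device_b) if d is not None]
    out: dict[float, list[ShakerTrial]] = {}
    for rpm in cfg.rpms:
        trials = []
        for k in range(1, cfg.n_shaker_trials + 1):
            phase = float(child_rng(cfg.master_seed, "shaker-phase", rpm, k).uniform(0, 2 * np.pi))
            sc = ShakerConfig(
                rpm=rpm, radius_m=cfg.radius_m, duration_s=cfg.duration_s,
                fs=cfg.fs, phase0=phase,
            )
            truth = true_shaker_recording(sc)
            recs = {}
            for dev in devices:
                params_key = (dev.gain3, dev.offset3, dev.noise_sd,
                              dev.lowpass_hz, dev.adc_bits, dev.range_g)
                seed = int(
                    child_rng(cfg.master_seed, "shaker-dev", rpm, k, params_key)
                    .integers(2**31)
                )
                recs[dev.device_id] = apply_device_model(truth, dev, seed)
            trials.append(
                ShakerTrial(rpm=rpm, radius_m=cfg.radius_m, trial_index=k,
                            recordings=recs)
            )
        out[rpm] = trials
    return out


def shaker_comparison_table(cfg: RunConfig) -> pd.DataFrame:
    """Stage-1 report: per-speed oracle, device means/peaks, % diff and p."""
    trials_by_rpm = simulate_shaker_trials(cfg)
    rows = []
    a_id = cfg.device_a.device_id
    b_id = cfg.device_b.device_id if cfg.device_b is not None else None
    for rpm, trials in trials_by_rpm.items():
        if b_id is None:
            from .shaker_analysis import centripetal_acceleration, trial_mean_vm
            rows.append({
                "rpm": rpm,
                "nominal_hz": NOMINAL_HZ.get(rpm, rpm / 60.0),
                "oracle_g": centripetal_acceleration(rpm, cfg.radius_m),
                f"mean_vm_{a_id}": float(np.mean([trial_mean_vm(t, a_id) for t in trials])),
            })
            continue
        comp = compare_devices(
            trials, a_id, b_id, n_perm=cfg.n_perm,
            seed=int(child_rng(cfg.master_seed, "perm", rpm).integers(2**31)),
        )
        rows.append(
            {
                "rpm": rpm,
                "nominal_hz": NOMINAL_HZ.get(rpm, rpm / 60.0),
                "oracle_g": comp.oracle_g,
                f"mean_vm_{a_id}": comp.mean_vm[a_id],
                f"mean_vm_{b_id}": comp.mean_vm[b_id],
                f"mean_peak_{a_id}": comp.mean_peak[a_id],
                f"mean_peak_{b_id}": comp.mean_peak[b_id],
                "pct_difference": comp.pct_difference,
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows)


def study_feature_tables(cfg: RunConfig) -> dict[tuple[str, str], pd.DataFrame]:
    """Stage-2: simulate the wear study and extract TD+FD tables per device."""
    study_cfg = StudyConfig(
        subjects=cfg.subjects,
        activities=cfg.activities,
        device_a=cfg.device_a,
        device_b=cfg.device_b,
        duration_s=cfg.duration_s,
        fs=cfg.fs,
        master_seed=cfg.master_seed,
    )
    study = build_study(study_cfg)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for device_id, recordings in study.items():
        windows = []
        for rec in recordings:
            windows.extend(make_windows(rec, cfg.window_s, cfg.use_last_s))
        log.info("device %s: %d recordings -> %d windows",
                 device_id, len(recordings), len(windows))
        for fset in ("TD", "FD"):
            tables[(device_id, fset)] = extract_table(windows, fset, band=cfg.band)
    return tables


_Z_PAIRS = (
    ("FD", "same_vs_cross_A", ("A", "A"), ("A", "B")),
    ("FD", "same_vs_cross_B", ("B", "B"), ("B", "A")),
    ("TD", "same_vs_cross_A", ("A", "A"), ("A", "B")),
    ("TD", "same_vs_cross_B", ("B", "B"), ("B", "A")),
)


def ztest_report(results: dict, device_a: str, device_b: str) -> pd.DataFrame:
    """Two-proportion z-tests comparing same-device vs cross-device cells."""
    name = {"A": device_a, "B": device_b}
    rows = []
    for fset, tag, (tr1, te1), (tr2, te2) in _Z_PAIRS:
        r1 = results[(fset, name[tr1], name[te1])]
        r2 = results[(fset, name[tr2], name[te2])]
        z, p = two_proportion_z(r1.n_correct, r1.n_total, r2.n_correct, r2.n_total)
        rows.append(
            {
                "feature_set": fset,
                "comparison": tag,
                "cell_1": f"{name[tr1]}->{name[te1]}",
                "acc_1": r1.accuracy,
                "cell_2": f"{name[tr2]}->{name[te2]}",
                "acc_2": r2.accuracy,
                "z": round(z, 3),
                "p_value": round(p, 4),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir: str, force: bool = False,
                 write_signals: bool = False) -> dict[str, str]:
    """Execute every stage and write the report bundle into ``outdir``.

    Refuses to overwrite a completed run directory unless ``force``.
    Returns a mapping of artifact names to file paths.
    """
    os.makedirs(outdir, exist_ok=True)
    summary_path = os.path.join(outdir, "summary.txt")
    if os.path.exists(summary_path) and not force:
        raise FileExistsError(
            f"{outdir} already contains a completed run; use force=True to overwrite"
        )
    artifacts: dict[str, str] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    shaker_df = _stage("shaker-compare", lambda: shaker_comparison_table(cfg))
    artifacts["shaker_comparison"] = p = os.path.join(outdir, "shaker_comparison.csv")
    shaker_df.to_csv(p, index=False, float_format="%.6g")
    log.info("shaker comparison: %d speeds", len(shaker_df))

    tables = _stage("extract-features", lambda: study_feature_tables(cfg))
    for (dev, fset), tbl in tables.items():
        artifacts[f"features_{dev}_{fset}"] = p = os.path.join(
            outdir, f"features_{dev}_{fset}.csv"
        )
        tbl.to_csv(p, index=False, float_format="%.8g")

    lines = [
        f"accelxfer {__version__} run (master_seed={cfg.master_seed})",
        "",
        "Shaker comparison (mean VM over 2nd minute, % difference B vs A):",
        shaker_df.to_string(index=False),
        "",
    ]
    if cfg.device_b is not None:
        a_id, b_id = cfg.device_a.device_id, cfg.device_b.device_id
        spec = ModelSpec(n_trees=cfg.n_trees, seed=cfg.classifier_seed)
        grid_df, results = _stage(
            "transfer-eval", lambda: transfer_grid(tables, a_id, b_id, spec)
        )
        artifacts["transfer_grid"] = p = os.path.join(outdir, "transfer_grid.csv")
        grid_df.to_csv(p, index=False)
        for (fset, tr, te), res in results.items():
            artifacts[f"confusion_{fset}_{tr}_{te}"] = p = os.path.join(
                outdir, f"confusion_{fset}_{tr}_to_{te}.csv"
            )
            res.confusion.to_frame().to_csv(p)
        zdf = ztest_report(results, a_id, b_id)
        artifacts["ztest_report"] = p = os.path.join(outdir, "ztest_report.csv")
        zdf.to_csv(p, index=False)
        lines += [
            "Transfer grid (LOSO accuracy, %):",
            grid_df.to_string(index=False),
            "",
            "Two-proportion z-tests (same-device vs cross-device):",
            zdf.to_string(index=False),
            "",
        ]
    else:
        log.info("single device configured: transfer grid skipped")
        lines += ["Single device configured: transfer grid skipped.", ""]

    if write_signals:
        sigdir = os.path.join(outdir, "signals")
        os.makedirs(sigdir, exist_ok=True)
        study = build_study(
            StudyConfig(
                subjects=cfg.subjects, activities=cfg.activities,
                device_a=cfg.device_a, device_b=cfg.device_b,
                duration_s=cfg.duration_s, fs=cfg.fs, master_seed=cfg.master_seed,
            )
        )
        manifest = []
        for dev_id, recs in study.items():
            for rec in recs:
                b = rec.annotations[0]
                fname = f"{dev_id}_{b.subject_id}_{b.label}.csv"
                write_recording(rec, os.path.join(sigdir, fname))
                manifest.append({"path": os.path.join("signals", fname),
                                 "device_id": dev_id, "fs": rec.fs,
                                 "subject": b.subject_id, "label": b.label})
        artifacts["signal_manifest"] = p = os.path.join(outdir, "signal_manifest.csv")
        pd.DataFrame(manifest).to_csv(p, index=False)

    artifacts["config"] = p = os.path.join(outdir, "config.yaml")
    cfg.to_yaml(p)
    manifest = {
        "accelxfer_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": cfg.master_seed,
        "artifacts": sorted(os.path.basename(v) for v in artifacts.values()),
    }
    artifacts["manifest"] = p = os.path.join(outdir, "manifest.yaml")
    with open(p, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    artifacts["summary"] = summary_path
    with open(summary_path, "w") as fh:
        fh.write("\n".join(lines))
    return artifacts
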