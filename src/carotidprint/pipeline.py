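"""End-to-end orchestration: simulate -> quality -> CWT -> segment ->
fingerprint/images -> train-eval -> report.

A :class:`PipelineConfig` (TOML-serializable, unknown keys rejected)
carries every stage's parameters and one master seed; left and right
sides are processed independently.  Stage outputs are cached
content-addressed: each stage's cache key hashes its own parameters
together with its upstream stage's key, so editing a config key
invalidates exactly the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tomllib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import vascsim
from .vascsim import make_profiles, simulate_recording
from .audio_quality import QualityConfig, assess_quality
from .cwt_spectral import MorseParams, compute_cwt
from .hs_segmentation import (SegConfig, extract_features, estimate_heart_rate,
                              fit_hsmm, viterbi_segment, extract_cycles)
from .fingerprint import (resize_cycle, segment_spectrum, render_cycle_image,
                          save_fingerprint_png, default_colormap_lut)
from .identify_cnn import CnnConfig, CvPlan, train_and_eval
from .metrics_report import (confusion_to_metrics, aggregate_runs,
                             summary_table, normalize_confusion, format_pm,
                             save_confusion_heatmap)

STAGES = ("simulate", "quality", "cwt", "segment", "fingerprint",
          "train_eval", "report")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class SimParams:
    n_users: int = 7
    recordings_per_user: int = 10     # per side, for the identification set
    seg_train_per_user: int = 2       # extra labelled recordings for the HSMM
    duration: float = 11.0
    fs: int = 16000
    separation: float = 0.8
    low_quality_fraction: float = vascsim.DEFAULT_LOW_QUALITY_FRACTION


@dataclass
class CwtParams:
    time_bandwidth: float = 60.0
    gamma: float = 3.0
    voices_per_octave: int = 10
    f_min: float = 1.0
    f_max: float = 200.0

    def morse(self) -> MorseParams:
        return MorseParams.from_time_bandwidth(self.time_bandwidth, self.gamma)


@dataclass
class FingerprintParams:
    target_len: int = 16000
    image_size: int = 134
    cycles_per_user_cap: int = 80
    log_eps_rel: float = 1e-3


@dataclass
class PipelineConfig:
    seed: int = 1
    side: str = "both"                # "L", "R", or "both"
    quality_bypass: bool = False
    sim: SimParams = field(default_factory=SimParams)
    quality: QualityConfig = field(default_factory=QualityConfig)
    cwt: CwtParams = field(default_factory=CwtParams)
    seg: SegConfig = field(default_factory=SegConfig)
    fingerprint: FingerprintParams = field(default_factory=FingerprintParams)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    cv: CvPlan = field(default_factory=CvPlan)

    def sides(self) -> list[str]:
        if self.side not in ("L", "R", "both"):
            raise ConfigError("side must be 'L', 'R' or 'both'")
        return ["L", "R"] if self.side == "both" else [self.side]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, obj, path):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(obj) - set(names)
            if unknown:
                raise ConfigError(
                    f"unknown config key(s) {sorted(unknown)} under '{path}'")
            kwargs = {}
            for key, value in obj.items():
                ftype = names[key].type
                sub = _NESTED.get((dc_type, key))
                if sub is not None:
                    kwargs[key] = build(sub, value, f"{path}.{key}")
                elif isinstance(value, list):
                    kwargs[key] = tuple(value) if key in _TUPLE_KEYS else value
                else:
                    kwargs[key] = value
            return dc_type(**kwargs)

        return build(cls, data, "config")

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_toml_dumps(self.to_dict()))

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


_NESTED = {
    (PipelineConfig, "sim"): SimParams,
    (PipelineConfig, "quality"): QualityConfig,
    (PipelineConfig, "cwt"): CwtParams,
    (PipelineConfig, "seg"): SegConfig,
    (PipelineConfig, "fingerprint"): FingerprintParams,
    (PipelineConfig, "cnn"): CnnConfig,
    (PipelineConfig, "cv"): CvPlan,
}
_TUPLE_KEYS = {"band", "psd_band", "hr_lag_range", "beat_lag_range",
               "s2_window", "input_shape"}


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v).__name__} to TOML")


def _toml_dumps(d: dict) -> str:
    scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in d.items() if isinstance(v, dict)}
    lines = [f"{k} = {_toml_value(v)}" for k, v in scalars.items()]
    for name, tab in tables.items():
        lines.append(f"\n[{name}]")
        lines.extend(f"{k} = {_toml_value(v)}" for k, v in tab.items())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Content-addressed stage keys
# ---------------------------------------------------------------------------

def stage_keys(cfg: PipelineConfig) -> dict[str, str]:
    """Cache key per stage: hash of own params chained with upstream key."""
    d = cfg.to_dict()
    own = {
        "simulate": {"seed": d["seed"], "side": d["side"], "sim": d["sim"]},
        "quality": {"quality": d["quality"],
                    "quality_bypass": d["quality_bypass"]},
        "cwt": {"cwt": d["cwt"]},
        "segment": {"seg": d["seg"]},
        "fingerprint": {"fingerprint": d["fingerprint"]},
        "train_eval": {"cnn": d["cnn"], "cv": d["cv"]},
        "report": {},
    }
    keys = {}
    upstream = ""
    for stage in STAGES:
        payload = json.dumps({"stage": stage, "params": own[stage],
                              "upstream": upstream}, sort_keys=True)
        upstream = hashlib.sha256(payload.encode()).hexdigest()[:16]
        keys[stage] = upstream
    return keys


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _rec_seed(master: int, *ids: int) -> int:
    return int(np.random.SeedSequence([int(master), *ids]).generate_state(1)[0]
               % (2 ** 31))


def _build_side_images(cfg: PipelineConfig, side: str):
    """Simulate one side's dataset and turn it into labelled cycle images.

    Returns ``(images [n,134,134,3] float32, labels, fingerprints,
    n_rejected)``.
    """
    sim = cfg.sim
    if sim.n_users < 2:
        raise StageError("train-eval requires >= 2 classes "
                         f"(config has n_users={sim.n_users})")
    profiles = make_profiles(sim.n_users, cfg.seed, sim.separation)
    side_id = 0 if side == "L" else 1

    # labelled, clean recordings for fitting the segmentation model
    training = []
    for u, profile in enumerate(profiles):
        for i in range(sim.seg_train_per_user):
            rec = simulate_recording(
                profile, sim.duration, sim.fs,
                seed=_rec_seed(cfg.seed, 0xA0, side_id, u, i),
                low_quality=False, side=side)
            feats = extract_features(rec, cfg.seg)
            training.append((feats, rec.truth_states.to_rate(
                cfg.seg.frame_rate, len(feats))))
    model = fit_hsmm(training, cfg.seg)

    morse = cfg.cwt.morse()
    lut = default_colormap_lut()
    flag_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0xF1A6, side_id]))
    images_by_user: dict[str, list] = {p.user_id: [] for p in profiles}
    fp_sum: dict[str, np.ndarray | None] = {p.user_id: None for p in profiles}
    fp_count = {p.user_id: 0 for p in profiles}
    n_rejected = 0

    for u, profile in enumerate(profiles):
        for i in range(sim.recordings_per_user):
            low = bool(flag_rng.random() < sim.low_quality_fraction)
            rec = simulate_recording(
                profile, sim.duration, sim.fs,
                seed=_rec_seed(cfg.seed, 0xB0, side_id, u, i),
                low_quality=low, side=side,
                device_id=vascsim.DEVICES[i % len(vascsim.DEVICES)])
            if not cfg.quality_bypass:
                if not assess_quality(rec, cfg.quality).passed:
                    n_rejected += 1
                    continue
            feats = extract_features(rec, cfg.seg)
            hr = estimate_heart_rate(feats, cfg.seg)
            states = viterbi_segment(feats, model, hr)
            cycles = extract_cycles(
                states.to_rate(rec.fs, len(rec.samples)))
            if len(cycles) == 0:
                continue
            spec = compute_cwt(rec, morse, cfg.cwt.voices_per_octave,
                               cfg.cwt.f_min, cfg.cwt.f_max,
                               single_precision=True)
            for ci, mat in enumerate(segment_spectrum(spec, cycles)):
                cyc = resize_cycle(mat, spec.freqs, cfg.fingerprint.target_len,
                                   meta={"user": profile.user_id, "side": side,
                                         "recording": i, "cycle": ci,
                                         "device": rec.device_id})
                img = render_cycle_image(cyc, lut, cfg.fingerprint.image_size,
                                         cfg.fingerprint.log_eps_rel)
                images_by_user[profile.user_id].append(img.pixels)
                if fp_sum[profile.user_id] is None:
                    fp_sum[profile.user_id] = cyc.magnitude.astype(np.float64)
                else:
                    fp_sum[profile.user_id] += cyc.magnitude
                fp_count[profile.user_id] += 1
            del spec

    images, labels, fingerprints = [], [], {}
    cap = cfg.fingerprint.cycles_per_user_cap
    for profile in profiles:
        uid = profile.user_id
        imgs = images_by_user[uid]
        if len(imgs) == 0:
            raise StageError(f"segment: no cycles extracted for user {uid}")
        if cap and len(imgs) > cap:
            keep = np.linspace(0, len(imgs), cap, endpoint=False).astype(int)
            imgs = [imgs[k] for k in keep]
        images.extend(imgs)
        labels.extend([uid] * len(imgs))
        fingerprints[uid] = average_spectra_from_sum(
            fp_sum[uid], fp_count[uid], uid, side)
    return (np.stack(images), np.asarray(labels), fingerprints, n_rejected)


def average_spectra_from_sum(total, count, user_id, side):
    from .fingerprint import Fingerprint

    return Fingerprint(total / count, np.arange(total.shape[0]), count,
                       user_id, side)


def fit_hsmm_from_manifest(manifest, cfg: PipelineConfig):
    """Fit the segmentation model from a simulated dataset on disk,
    using the ground-truth state CSVs written next to each WAV."""
    from .audio_quality import load_recording

    training = []
    for i in range(len(manifest)):
        rec = load_recording(manifest.paths()[i])
        feats = extract_features(rec, cfg.seg)
        truth = vascsim.truth_for(manifest, i, fs=rec.fs)
        training.append((feats, truth.to_rate(cfg.seg.frame_rate, len(feats))))
    return fit_hsmm(training, cfg.seg)


def images_from_manifest(manifest, model, cfg: PipelineConfig,
                         side: str | None = None):
    """File-based stage chain: quality -> CWT -> segment -> cycle images.

    Returns ``(images, labels, fingerprints)`` over the manifest rows
    (optionally restricted to one side); rows failing quality screening
    are skipped unless ``cfg.quality_bypass``.
    """
    lut = default_colormap_lut()
    morse = cfg.cwt.morse()
    images, labels = [], []
    fp_sum, fp_count = {}, {}
    from .audio_quality import load_recording

    for i, row in manifest.frame.iterrows():
        if side is not None and row["side"] != side:
            continue
        rec = load_recording(manifest.paths()[i], row["user"],
                             row["device"], row["side"])
        if not cfg.quality_bypass and not assess_quality(rec,
                                                         cfg.quality).passed:
            continue
        feats = extract_features(rec, cfg.seg)
        states = viterbi_segment(feats, model,
                                 estimate_heart_rate(feats, cfg.seg))
        cycles = extract_cycles(states.to_rate(rec.fs, len(rec.samples)))
        if len(cycles) == 0:
            continue
        spec = compute_cwt(rec, morse, cfg.cwt.voices_per_octave,
                           cfg.cwt.f_min, cfg.cwt.f_max,
                           single_precision=True)
        for ci, mat in enumerate(segment_spectrum(spec, cycles)):
            cyc = resize_cycle(mat, spec.freqs, cfg.fingerprint.target_len,
                               meta={"user": row["user"], "side": row["side"],
                                     "recording": i, "cycle": ci})
            img = render_cycle_image(cyc, lut, cfg.fingerprint.image_size,
                                     cfg.fingerprint.log_eps_rel)
            images.append(img.pixels)
            labels.append(row["user"])
            key = (row["user"], row["side"])
            if key not in fp_sum:
                fp_sum[key] = cyc.magnitude.astype(np.float64)
                fp_count[key] = 0
            else:
                fp_sum[key] += cyc.magnitude
            fp_count[key] += 1
    fingerprints = {key: average_spectra_from_sum(fp_sum[key],
                                                  fp_count[key], *key)
                    for key in fp_sum}
    return np.stack(images), np.asarray(labels), fingerprints


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute the full analysis; artifacts land under ``out_dir``.

    Returns the report dictionary (also written as ``report.json``):
    per side, the overall accuracy mean±sd over CV runs, the per-class
    metric table, and the mean normalized confusion matrix.
    """
    os.makedirs(out_dir, exist_ok=True)
    keys = stage_keys(cfg)
    cache_dir = os.path.join(out_dir, "cache")
    os.makedirs(cache_dir, exist_ok=True)
    report = {"sides": {}, "stage_keys": keys}

    for side in cfg.sides():
        img_cache = os.path.join(
            cache_dir, f"images-{side}-{keys['fingerprint']}.npz")
        if os.path.exists(img_cache):
            with np.load(img_cache, allow_pickle=False) as z:
                images, labels = z["images"], z["labels"]
                n_rejected = int(z["n_rejected"])
        else:
            try:
                images, labels, fingerprints, n_rejected = \
                    _build_side_images(cfg, side)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"fingerprint ({side}): {exc}") from exc
            np.savez_compressed(img_cache, images=images, labels=labels,
                                n_rejected=np.int64(n_rejected))
            for uid, fp in fingerprints.items():
                save_fingerprint_png(
                    fp, os.path.join(out_dir, f"fingerprint_{uid}_{side}.png"))

        cnn = dataclasses.replace(cfg.cnn,
                                  n_classes=len(np.unique(labels)))
        plan = dataclasses.replace(cfg.cv, seed=_rec_seed(cfg.seed, 0xC5))
        cm_cache = os.path.join(
            cache_dir, f"cms-{side}-{keys['train_eval']}.npz")
        if os.path.exists(cm_cache):
            with np.load(cm_cache) as z:
                cms = [z[k] for k in sorted(z.files)]
        else:
            try:
                cms = train_and_eval(images, labels, cnn, plan,
                                     seed=_rec_seed(cfg.seed, 0xE7))
            except Exception as exc:
                raise StageError(f"train-eval ({side}): {exc}") from exc
            np.savez_compressed(
                cm_cache, **{f"cm{i:03d}": c for i, c in enumerate(cms)})

        classes = [str(c) for c in np.unique(labels)]
        metrics = [confusion_to_metrics(c, classes) for c in cms]
        agg = aggregate_runs(metrics)
        table = summary_table(agg, side)
        table.to_csv(os.path.join(out_dir, f"metrics_{side}.csv"), index=False)
        norm = normalize_confusion(cms)
        np.savetxt(os.path.join(out_dir, f"confusion_{side}.csv"), norm,
                   delimiter=",", fmt="%.6f")
        save_confusion_heatmap(
            norm, classes, os.path.join(out_dir, f"confusion_{side}.png"))
        mean_acc, sd_acc = agg["overall_acc"]
        report["sides"][side] = {
            "n_images": int(len(labels)),
            "n_rejected_recordings": int(n_rejected),
            "n_cv_runs": len(cms),
            "overall_accuracy_pct": {"mean": round(mean_acc, 4),
                                     "sd": round(sd_acc, 4),
                                     "formatted": format_pm(mean_acc, sd_acc)},
            "per_class": {
                name: {cls: format_pm(agg["per_class"][name][0][i],
                                      agg["per_class"][name][1][i])
                       for i, cls in enumerate(classes)}
                for name in ("SEN", "SPE", "PRE", "F1", "ACC")},
            "mean_normalized_confusion": np.round(norm, 6).tolist(),
        }

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_identification_experiment(seed: int = 1, n_users: int = 7,
                                  recordings_per_user: int = 10,
                                  separation: float = 0.8,
                                  k: int = 5, repetitions: int = 2,
                                  side: str = "L",
                                  out_dir: str | None = None) -> dict:
    """The left-side identification experiment at the package's demo scale.

    Simulates the cohort, runs the full pipeline on one side with a
    reduced k-fold x repetitions schedule, and returns the side's report
    entry (overall accuracy in percent, per-class metrics, confusion).
    """
    import tempfile

    cfg = PipelineConfig(seed=seed, side=side)
    cfg.sim.n_users = n_users
    cfg.sim.recordings_per_user = recordings_per_user
    cfg.sim.separation = separation
    cfg.cv = CvPlan(k=k, repetitions=repetitions)
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            report = run_pipeline(cfg, tmp)
    else:
        report = run_pipeline(cfg, out_dir)
    return report["sides"][side]
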