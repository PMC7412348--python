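"""Pipeline orchestration: simulate -> window -> rp -> pca -> features ->
evaluate, with per-stage caching and deterministic artifacts.

Each stage writes its outputs plus a ``stage.json`` carrying a content
key (hash of the stage parameters and the upstream key). Re-running an
identical config skips stages whose keys match. Timing goes to
``run.log`` only, so all other artifacts are byte-identical across
reruns of one config.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from gaitrp import io as gio
from gaitrp.evaluation import (
    CVScheme,
    confusion_matrix,
    binary_metrics,
    multiclass_metrics,
    select_best_channel,
    loocv,
)
from gaitrp.features import (
    ClassifierSpec,
    FeatureExtractorSpec,
    FeatureMatrix,
    extract_features,
)
from gaitrp.pca import fit_pca, apply_pca, reshape_to_images, save_model
from gaitrp.preprocessing import WindowingParams, window_record
from gaitrp.recurrence import RPImage, compute_rp, to_image
from gaitrp.records import LABELS
from gaitrp.synthetic import ClassProfile, SimulationConfig, generate_cohort, write_cohort

#: The experiment grid: seven two-class tasks (positive class first;
#: NDD pools ALS, PD and HD) plus the four-class task.
DEFAULT_TASKS = (
    "ALS_vs_HC",
    "HD_vs_HC",
    "PD_vs_HC",
    "ALS_vs_HD",
    "PD_vs_ALS",
    "HD_vs_PD",
    "NDD_vs_HC",
    "multiclass",
)

STAGES = ("simulate", "window", "rp", "pca", "features", "evaluate")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "duration": 90.0,
        "sampling_rate": 100.0,
        "subjects_per_class": 4,
        "profiles": {},  # overrides of DEFAULT_PROFILES fields, per label
    },
    "ingest": None,  # {"manifest": path} to use external records instead
    "exclude_subjects": [],
    "windowing": {"tw": 10.0, "d": None, "trim": 20.0},
    "rp": {"resolution": 227, "method": "bilinear"},
    "pca": {"enabled": True, "center": False},
    "extractor": {"backend": "tiny-cnn-test", "seed": 0},
    "classifier": {"kernel": "linear", "C": 1.0, "seed": 0, "zscore": False},
    "cv": {"unit": "window"},
    "channels": ["LF", "RF", "CF"],
    "tasks": list(DEFAULT_TASKS),
}


def make_config(**overrides) -> dict:
    """Deep-merge overrides onto the default config."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in overrides.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _key(*parts) -> str:
    payload = json.dumps(parts, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


class _Runner:
    def __init__(self, config: dict, run_dir: str | Path,
                 stages: tuple[str, ...] | None = None) -> None:
        self.config = make_config(**config)
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.stages = stages or STAGES
        self.log_path = self.run_dir / "run.log"
        gio.write_json(self.run_dir / "config.json", self.config)

    def _log(self, msg: str) -> None:
        with open(self.log_path, "a") as fh:
            fh.write(msg + "\n")

    def _cached(self, stage: str, key: str) -> bool:
        path = self.run_dir / stage / "stage.json"
        if not path.exists():
            return False
        return gio.read_json(path).get("key") == key

    def _mark(self, stage: str, key: str, extra: dict | None = None) -> None:
        d = self.run_dir / stage
        d.mkdir(exist_ok=True)
        gio.write_json(d / "stage.json", {"key": key, **(extra or {})})

    def _timed(self, stage: str, fn) -> None:
        t0 = time.perf_counter()
        fn()
        self._log(f"stage {stage}: {time.perf_counter() - t0:.3f} s")

    # ------------------------------------------------------------------
    def run(self) -> Path:
        cfg = self.config
        sim_key = _key("simulate", cfg["seed"], cfg["simulate"], cfg["ingest"],
                       cfg["exclude_subjects"])
        if not self._cached("simulate", sim_key):
            self._timed("simulate", lambda: self._stage_simulate(sim_key))

        win_key = _key("window", sim_key, cfg["windowing"], cfg["channels"])
        if not self._cached("window", win_key):
            self._timed("window", lambda: self._stage_window(win_key))

        rp_key = _key("rp", win_key, cfg["rp"])
        if not self._cached("rp", rp_key):
            self._timed("rp", lambda: self._stage_rp(rp_key))

        pca_key = _key("pca", rp_key, cfg["pca"])
        if not self._cached("pca", pca_key):
            self._timed("pca", lambda: self._stage_pca(pca_key))

        feat_key = _key("features", pca_key, cfg["extractor"])
        if not self._cached("features", feat_key):
            self._timed("features", lambda: self._stage_features(feat_key))

        eval_key = _key("evaluate", feat_key, cfg["classifier"], cfg["cv"],
                        cfg["tasks"])
        if not self._cached("evaluate", eval_key):
            self._timed("evaluate", lambda: self._stage_evaluate(eval_key))
        return self.run_dir / "evaluate" / "report.json"

    # ------------------------------------------------------------------
    def _stage_simulate(self, key: str) -> None:
        cfg = self.config
        out = self.run_dir / "simulate"
        out.mkdir(exist_ok=True)
        if cfg["ingest"]:
            records = gio.read_cohort(cfg["ingest"]["manifest"])
            sim_cfg = None
        else:
            sim = cfg["simulate"]
            from gaitrp.synthetic import DEFAULT_PROFILES

            profiles = {}
            for lab in LABELS:
                base = DEFAULT_PROFILES[lab].__dict__.copy()
                base.update(sim.get("profiles", {}).get(lab, {}))
                profiles[lab] = ClassProfile(**base)
            sim_cfg = SimulationConfig(
                duration=sim["duration"],
                sampling_rate=sim["sampling_rate"],
                subjects_per_class=sim["subjects_per_class"],
                seed=cfg["seed"],
                profiles=profiles,
            )
            records = generate_cohort(sim_cfg)
        excluded = set(cfg["exclude_subjects"])
        records = [r for r in records if r.subject_id not in excluded]
        if not records:
            raise RuntimeError("stage simulate: no records after exclusions")
        write_cohort(records, out, sim_cfg)
        self._mark("simulate", key, {"n_records": len(records)})

    def _records(self):
        return gio.read_cohort(self.run_dir / "simulate" / "manifest.csv")

    def _stage_window(self, key: str) -> None:
        cfg = self.config
        params = WindowingParams(**cfg["windowing"])
        out = self.run_dir / "window"
        out.mkdir(exist_ok=True)
        records = self._records()
        for channel in cfg["channels"]:
            samples, rows = [], []
            for rec in records:
                try:
                    ws = window_record(rec, params, channel)
                except ValueError as exc:
                    raise RuntimeError(
                        f"stage window: subject {rec.subject_id}: {exc}"
                    ) from exc
                for w in ws:
                    samples.append(w.samples)
                    rows.append((w.subject_id, w.label, w.channel, w.start))
            np.save(out / f"{channel}_samples.npy", np.stack(samples))
            with open(out / f"{channel}_manifest.csv", "w") as fh:
                fh.write("subject_id,label,channel,start\n")
                for r in rows:
                    fh.write(f"{r[0]},{r[1]},{r[2]},{r[3]:.9g}\n")
        self._mark("window", key)

    def _load_windows(self, channel: str):
        out = self.run_dir / "window"
        samples = np.load(out / f"{channel}_samples.npy")
        subj, labels = [], []
        with open(out / f"{channel}_manifest.csv") as fh:
            next(fh)
            for line in fh:
                s, lab, _, _ = line.strip().split(",")
                subj.append(s)
                labels.append(lab)
        return samples, np.array(subj), np.array(labels)

    def _stage_rp(self, key: str) -> None:
        cfg = self.config
        res = cfg["rp"]["resolution"]
        method = cfg["rp"]["method"]
        out = self.run_dir / "rp"
        out.mkdir(exist_ok=True)
        for channel in cfg["channels"]:
            samples, _, _ = self._load_windows(channel)
            images = np.empty((len(samples), res, res), dtype=np.float32)
            for i, x in enumerate(samples):
                try:
                    rp = compute_rp(x)
                except ValueError as exc:
                    raise RuntimeError(
                        f"stage rp: {channel} window {i}: {exc}"
                    ) from exc
                images[i] = to_image(rp, res, method).pixels
            np.save(out / f"{channel}_images.npy", images)
        self._mark("rp", key)

    def _stage_pca(self, key: str) -> None:
        cfg = self.config
        out = self.run_dir / "pca"
        out.mkdir(exist_ok=True)
        res = cfg["rp"]["resolution"]
        for channel in cfg["channels"]:
            images = np.load(self.run_dir / "rp" / f"{channel}_images.npy")
            if not cfg["pca"]["enabled"]:
                np.save(out / f"{channel}_images.npy", images)
                continue
            X = images.reshape(len(images), -1).astype(float)
            model = fit_pca(X, center=cfg["pca"]["center"])
            F = apply_pca(model, X)
            enhanced = reshape_to_images(F, res)
            stack = np.stack([im.pixels for im in enhanced]).astype(np.float32)
            np.save(out / f"{channel}_images.npy", stack)
            save_model(model, out / f"{channel}_model.npz")
        self._mark("pca", key, {"enabled": cfg["pca"]["enabled"]})

    def _stage_features(self, key: str) -> None:
        cfg = self.config
        out = self.run_dir / "features"
        out.mkdir(exist_ok=True)
        ex = dict(cfg["extractor"])
        if "input_size" in ex:
            ex["input_size"] = tuple(ex["input_size"])
        spec = FeatureExtractorSpec(**ex)
        for channel in cfg["channels"]:
            images = np.load(self.run_dir / "pca" / f"{channel}_images.npy")
            imgs = [RPImage(pixels=p.astype(float)) for p in images]
            F = extract_features(imgs, spec)
            np.save(out / f"{channel}_F.npy", F.astype(np.float32))
        self._mark("features", key, {"backend": spec.backend})

    def _stage_evaluate(self, key: str) -> None:
        cfg = self.config
        out = self.run_dir / "evaluate"
        out.mkdir(exist_ok=True)
        scheme = CVScheme(**cfg["cv"])
        clf = ClassifierSpec(**cfg["classifier"])
        report: dict = {"tasks": {}, "cv_unit": scheme.unit}
        for task in cfg["tasks"]:
            report["tasks"][task] = {}
            per_channel = []
            for channel in cfg["channels"]:
                F = np.load(self.run_dir / "features" / f"{channel}_F.npy").astype(float)
                _, subj, labels = self._load_windows(channel)
                fm = FeatureMatrix(F, labels, subj)
                if task == "multiclass":
                    preds, _ = loocv(fm, scheme, clf)
                    order = tuple(lab for lab in LABELS if lab in set(labels))
                    cm = confusion_matrix(fm.labels, preds, order)
                    mm = multiclass_metrics(cm, order, task=task, channel=channel)
                    report["tasks"][task][channel] = {
                        "overall_accuracy": mm["overall_accuracy"],
                        "per_class": {
                            lab: m.to_dict() for lab, m in mm["per_class"].items()
                        },
                        "confusion": cm.tolist(),
                        "class_order": list(order),
                    }
                else:
                    pos, neg = task.split("_vs_")
                    lab2 = labels.copy()
                    if pos == "NDD":
                        lab2 = np.where(np.isin(lab2, ("ALS", "PD", "HD")),
                                        "NDD", lab2)
                    fm2 = FeatureMatrix(F, lab2, subj)
                    mask = np.isin(lab2, (pos, neg))
                    sub = fm2.subset(mask)
                    preds, _ = loocv(sub, scheme, clf)
                    cm = confusion_matrix(sub.labels, preds, (pos, neg))
                    m = binary_metrics(cm, pos, (pos, neg), task=task,
                                       channel=channel)
                    m.cv_unit = scheme.unit
                    per_channel.append(m)
                    report["tasks"][task][channel] = m.to_dict()
            if per_channel:
                report["tasks"][task]["best_channel"] = select_best_channel(
                    per_channel
                )
        if scheme.unit == "window":
            report["leakage_warning"] = (
                "window-level LOOCV: overlapping windows of one subject may "
                "appear in both train and test folds"
            )
        gio.write_json(out / "report.json", report)
        self._write_summary(out, report)
        self._mark("evaluate", key)

    def _write_summary(self, out: Path, report: dict) -> None:
        lines = ["task,channel,accuracy,sensitivity,specificity,auc_balanced,J"]
        for task, channels in report["tasks"].items():
            for channel, m in channels.items():
                if channel == "best_channel" or "accuracy" not in m:
                    continue
                fmt = lambda v: "" if v is None else f"{v:.6g}"
                lines.append(
                    f"{task},{channel},{fmt(m['accuracy'])},"
                    f"{fmt(m['sensitivity'])},{fmt(m['specificity'])},"
                    f"{fmt(m['auc_balanced'])},{fmt(m['J'])}"
                )
        (out / "summary.csv").write_text("\n".join(lines) + "\n")


def run(config: dict, run_dir: str | Path) -> Path:
    """Run the full pipeline; returns the report path."""
    return _Runner(config, run_dir).run()
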