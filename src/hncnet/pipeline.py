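"""End-to-end experiment orchestration: synthesize -> preprocess -> split ->
train -> select -> evaluate, driven by a single config and a master seed.

The master seed expands into named substreams (phantom, split, init,
training, bootstrap) so stages can be rerun in isolation with identical
results; rerunning an experiment with an identical config reproduces a
byte-identical evaluation report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from .errors import ConfigurationError
from .evaluation import EvalReport, SelectionCriterion, bootstrap_ci, kruskal_wallis, roc_auc, run_cv, select_model
from .models import build_cnn, build_fused_cnn, load_architecture, save_checkpoint
from .phantom import SyntheticCohortConfig, cohort_phantom_specs, generate_phantom_volume
from .preprocess import (
    HU_MIN,
    PreprocessConfig,
    WindowSpec,
    crop_about_center,
    gaussian_smooth,
    mask_volume,
    quantize_png8,
    resample_inplane,
    select_largest_gtv_slice,
    tumor_center,
    window_normalize,
    write_png,
)
from .training import TrainConfig, logs_to_jsonl, restore_epoch, train_model

#: Named substream ids for deriving stage seeds from the master seed.
_STREAMS = {"phantom": 1, "split": 2, "init": 3, "training": 4, "bootstrap": 5}

#: Default mapping of the five synthetic centers onto the cohort split.
DEFAULT_INSTITUTION_MAP = {
    "SYN_A": "train", "SYN_B": "train",
    "SYN_C": "validation", "SYN_D": "validation",
    "SYN_E": "test",
}


def substream_seed(master_seed: int, name: str) -> int:
    if name not in _STREAMS:
        raise ConfigurationError(f"unknown seed stream {name!r}")
    ss = np.random.SeedSequence([int(master_seed), _STREAMS[name]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class ExperimentConfig:
    outcome: str = "DM"
    split_mode: str = "cohort_split"  # | "kfold"
    k: int = 5
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    architecture_path: str | None = None  # None -> packaged default
    train: TrainConfig = field(default_factory=TrainConfig)
    selection: SelectionCriterion = field(default_factory=SelectionCriterion)
    fusion: bool = False
    fusion_inject_at_fc: int = 4
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("ExperimentConfig requires an explicit master seed")
        if self.outcome not in coh.OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.split_mode not in ("cohort_split", "kfold"):
            raise ConfigurationError(f"unknown split_mode {self.split_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["window"] = {"level": self.preprocess.window.level,
                                     "width": self.preprocess.window.width}
        return d


def smoke_config(seed: int = 0) -> ExperimentConfig:
    """Small configuration exercising the full path in about a minute."""
    return ExperimentConfig(
        cohort=SyntheticCohortConfig(n_patients=60, prevalence=0.3, effect_size=2.0,
                                     censoring_fraction=0.1, seed=substream_seed(seed, "phantom")),
        train=TrainConfig(max_epochs=20, seed=substream_seed(seed, "training")),
        seed=seed,
    )


def load_experiment_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ConfigurationError("experiment config must define a master seed")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = SyntheticCohortConfig(**kwargs["cohort"])
    if "preprocess" in kwargs:
        pp = dict(kwargs["preprocess"])
        if "window" in pp:
            pp["window"] = WindowSpec(**pp["window"])
        kwargs["preprocess"] = PreprocessConfig(**pp)
    if "train" in kwargs:
        kwargs["train"] = TrainConfig(**kwargs["train"])
    if "selection" in kwargs:
        kwargs["selection"] = SelectionCriterion(**kwargs["selection"])
    return ExperimentConfig(**kwargs)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def prepare_image_dataset(cohort_cfg: SyntheticCohortConfig, pp: PreprocessConfig):
    """Stream phantoms into pre-window HU crops plus records and a manifest.

    The returned ``hu_crops`` are masked, resampled, tumor-centered crops in
    raw HU with the background at the minimum HU; windowing maps that fill
    to 0, identical to filling with the lower window bound. Keeping crops in
    HU lets the windowing ablation re-window without re-rendering phantoms.
    """
    specs, records = cohort_phantom_specs(cohort_cfg)
    crops = np.empty((len(specs), pp.crop_size, pp.crop_size), dtype=np.float32)
    manifest = []
    for i, (spec, rec) in enumerate(zip(specs, records)):
        vol, mask = generate_phantom_volume(spec)
        vol, mask = resample_inplane(vol, mask, pp.target_inplane_spacing)
        masked = mask_volume(vol, mask, fill_hu=HU_MIN)
        k = select_largest_gtv_slice(mask)
        center = tumor_center(mask.voxels[k])
        crops[i] = crop_about_center(masked.voxels[k], center, pp.crop_size, pad_value=HU_MIN)
        dz, dy, dx = mask.spacing
        manifest.append({
            "patient_id": rec.patient_id, "source_slice_index": k,
            "center_row": center[0], "center_col": center[1],
            "gtv_area_mm2": float(mask.voxels[k].sum() * dy * dx),
            "gtv_volume_mm3": float(mask.voxels.sum() * dz * dy * dx),
            "inplane_resampled_only": True,
        })
    return crops, records, pd.DataFrame(manifest)


def window_images(hu_crops: np.ndarray, window: WindowSpec, sigma: float) -> np.ndarray:
    """Window + smooth + clip a stack of HU crops into CNN inputs."""
    imgs = window_normalize(hu_crops, window)
    if sigma > 0:
        for i in range(len(imgs)):
            imgs[i] = gaussian_smooth(imgs[i], sigma)
    return np.clip(imgs, 0.0, 1.0)


def _labelled_subset(records, outcome):
    spec = coh.OutcomeSpec(outcome=outcome)
    labels, keep = [], []
    for i, rec in enumerate(records):
        lab = coh.derive_label(rec, spec)
        if lab != coh.EXCLUDED:
            keep.append(i)
            labels.append(1 if lab == coh.POSITIVE else 0)
    return np.array(keep), np.array(labels)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(cfg: ExperimentConfig, out_dir) -> Path:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png_dir = out / "preprocessed"
    png_dir.mkdir(exist_ok=True)

    cohort_cfg = replace(cfg.cohort, seed=substream_seed(cfg.seed, "phantom"))
    crops, records, manifest = prepare_image_dataset(cohort_cfg, cfg.preprocess)
    images = window_images(crops, cfg.preprocess.window, cfg.preprocess.gaussian_sigma)

    paths = []
    for rec, img in zip(records, images):
        p = png_dir / f"{rec.patient_id}.png"
        write_png(quantize_png8(img), p)
        paths.append(str(p.relative_to(out)))
    manifest["png_path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    coh.records_to_frame(records).to_csv(out / "clinical.csv", index=False)

    keep, labels = _labelled_subset(records, cfg.outcome)
    images, records_l = images[keep], [records[i] for i in keep]
    x = images[:, None, :, :]

    arch = load_architecture(cfg.architecture_path)
    init_seed = substream_seed(cfg.seed, "init")
    train_cfg = replace(cfg.train, seed=substream_seed(cfg.seed, "training"))
    boot_seed = substream_seed(cfg.seed, "bootstrap")

    clinical = None
    if cfg.split_mode == "cohort_split":
        plan = coh.cohort_split(records_l, DEFAULT_INSTITUTION_MAP)
        roles = np.array([plan.assignment[r.patient_id] for r in records_l])
        idx = {role: np.nonzero(roles == role)[0] for role in ("train", "validation", "test")}
        plan.to_frame().to_csv(out / "split.csv", index=False)

        if cfg.fusion:
            enc = coh.fit_clinical_encoding([records_l[i] for i in idx["train"]])
            clinical = coh.encode_cohort(records_l, enc)
            from .models import FusionSpec
            model = build_fused_cnn(arch, FusionSpec(enc.dim, cfg.fusion_inject_at_fc), seed=init_seed)
        else:
            model = build_cnn(arch, seed=init_seed)

        def _clin(role_idx):
            return None if clinical is None else clinical[role_idx]

        train_set = {"x": x[idx["train"]], "y": labels[idx["train"]], "clinical": _clin(idx["train"])}
        val_set = {"x": x[idx["validation"]], "y": labels[idx["validation"]], "clinical": _clin(idx["validation"])}
        model, logs, ckpts = train_model(model, train_set, val_set, train_cfg)
        (out / "epochs.jsonl").write_text(logs_to_jsonl(logs))
        epoch, threshold = select_model(logs, cfg.selection)
        restore_epoch(model, ckpts, epoch)
        save_checkpoint(model, out / "selected_model.npz")

        report = EvalReport(mode="cohort_split", outcome=cfg.outcome)
        report.selection = {"epoch": epoch, "threshold": threshold,
                            "epochs_trained": len(logs)}
        for j, role in enumerate(("train", "validation", "test")):
            scores = model.predict_proba(x[idx[role]], clinical=_clin(idx[role]))
            report.auc[role] = roc_auc(labels[idx[role]], scores)
            lo, hi = bootstrap_ci(labels[idx[role]], scores, seed=boot_seed + j)
            report.ci[role] = [lo, hi]
    else:
        test_mask = np.array([r.institution == "SYN_E" for r in records_l])
        tr_idx, te_idx = np.nonzero(~test_mask)[0], np.nonzero(test_mask)[0]
        pd.DataFrame({
            "patient_id": [r.patient_id for r in records_l],
            "assignment": np.where(test_mask, "test", "cv"),
        }).to_csv(out / "split.csv", index=False)
        report = run_cv(
            x[tr_idx], labels[tr_idx], x[te_idx], labels[te_idx], k=cfg.k,
            build_fn=lambda seed: build_cnn(arch, seed=seed),
            train_cfg=train_cfg, criterion=cfg.selection,
            seed=substream_seed(cfg.seed, "split"),
        )
        report.outcome = cfg.outcome

    (out / "eval_report.json").write_text(report.to_json())
    summary = [
        f"outcome: {cfg.outcome}  split: {cfg.split_mode}  n={len(records_l)} labelled",
        f"selection: {report.selection}",
        f"auc: {report.auc or report.fold_mean}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "run_manifest.json")
    run_manifest = {
        "config": cfg.to_dict(),
        "architecture_hash": arch.config_hash(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, sort_keys=True, indent=1))
    return out


def run_window_ablation(cfg: ExperimentConfig, window_list, repetitions: int = 5) -> pd.DataFrame:
    """Repeat training per window setting and compare per-set AUCs.

    Returns a tidy frame (window, repetition, split, auc); the accompanying
    Kruskal-Wallis H and p per split across windows are attached as
    ``frame.attrs['kruskal']``.
    """
    if len(window_list) < 2 or repetitions < 2:
        raise ConfigurationError("need >= 2 windows and >= 2 repetitions")
    cohort_cfg = replace(cfg.cohort, seed=substream_seed(cfg.seed, "phantom"))
    crops, records, _ = prepare_image_dataset(cohort_cfg, cfg.preprocess)
    keep, labels = _labelled_subset(records, cfg.outcome)
    crops = crops[keep]
    records_l = [records[i] for i in keep]
    plan = coh.cohort_split(records_l, DEFAULT_INSTITUTION_MAP)
    roles = np.array([plan.assignment[r.patient_id] for r in records_l])
    idx = {role: np.nonzero(roles == role)[0] for role in ("train", "validation", "test")}

    arch = load_architecture(cfg.architecture_path)
    rows = []
    for w, window in enumerate(window_list):
        images = window_images(crops, window, cfg.preprocess.gaussian_sigma)
        x = images[:, None, :, :]
        for rep in range(repetitions):
            # seeds depend on the repetition only, so window arms are paired
            # and an identical window repeated in the list reproduces exactly
            seed_tag = rep
            model = build_cnn(arch, seed=substream_seed(cfg.seed, "init") + seed_tag)
            train_cfg = replace(cfg.train, seed=substream_seed(cfg.seed, "training") + seed_tag)
            model, logs, ckpts = train_model(
                model,
                {"x": x[idx["train"]], "y": labels[idx["train"]]},
                {"x": x[idx["validation"]], "y": labels[idx["validation"]]},
                train_cfg,
            )
            epoch, _ = select_model(logs, cfg.selection)
            restore_epoch(model, ckpts, epoch)
            for role in ("train", "validation", "test"):
                auc = roc_auc(labels[idx[role]], model.predict_proba(x[idx[role]]))
                rows.append({"arm": w, "window": f"L{window.level:g}/W{window.width:g}",
                             "repetition": rep, "split": role, "auc": auc})
    frame = pd.DataFrame(rows)
    kr = {}
    for role in ("train", "validation", "test"):
        groups = [g["auc"].to_numpy() for _, g in
                  frame[frame["split"] == role].groupby("arm", sort=True)]
        h, p = kruskal_wallis(groups)
        kr[role] = {"H": h, "p": p}
    frame.attrs["kruskal"] = kr
    return frame
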