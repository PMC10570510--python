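"""End-to-end orchestration: simulate -> preprocess -> habitats -> MSI -> models.

Each stage writes its outputs (NIfTI maps, CSV features, JSON reports)
into a stage subdirectory of the run directory and drops a ``.done``
marker; a re-run with the same config resumes from cached upstream
outputs, so deleting one stage directory recomputes only it and its
downstream stages.  The resolved configuration, seed, and package version
are written to ``manifest.json`` beside the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import metrics, post_test_positive, pre_test, to_percent
from .habitat import assign_habitats, fit_population_clusters, oversegment, superpixel_features
from .io import ensure_dir, load_labels, load_mask, load_volume, save_labels, save_mask, save_volume
from .models import (
    ClassifierSpec,
    cascade_predict,
    loocv_evaluate,
    prepare_benchmark_features,
    select_top_k,
)
from .msi import full_msi, whole_lung_radiomics, write_feature_dictionary
from .phantoms import ClinicalEffectConfig, PhantomParams, generate_clinical_table, generate_cohort
from .preprocess import make_composite, split_lungs

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with defaults; serialized into the manifest."""

    n_pneumonia: int = 8
    n_pneumonitis: int = 4
    phantom: PhantomParams = field(default_factory=PhantomParams)
    clinical: ClinicalEffectConfig = field(default_factory=ClinicalEffectConfig)
    #: texture window matched to the phantom resolution (a disk of radius 2
    #: spans ~5 mm in-plane at the default spacing)
    entropy_radius: int = 2
    entropy_bins: int = 32
    n_superpixels: int = 700
    compactness: float = 0.1
    k_range: tuple[int, int] = (2, 8)
    gap_refs: int = 10
    fixed_k: int | None = None
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k_grid: tuple[int, ...] = (2, 5, 10)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stage(run_dir: Path, name: str) -> tuple[Path, bool]:
    d = ensure_dir(run_dir / name)
    return d, (d / ".done").exists()


def _finish(d: Path) -> None:
    (d / ".done").write_text("ok\n")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run (or resume) the full pipeline; returns the run directory."""
    run_dir = ensure_dir(out_dir)
    (run_dir / "manifest.json").write_text(
        json.dumps(
            {"config": config.to_dict(), "config_hash": config.config_hash(),
             "version": __version__, "seed": config.seed},
            indent=1, default=str,
        )
    )
    spacing = config.phantom.spacing_mm
    n = config.n_pneumonia + config.n_pneumonitis
    pids = [f"P{i:03d}" for i in range(n)]

    sim, done = _stage(run_dir, "simulate")
    if not done:
        cohort = generate_cohort(
            config.n_pneumonia, config.n_pneumonitis, config.phantom, config.seed
        )
        for case in cohort.cases:
            save_volume(sim / f"{case.patient_id}_ct.nii.gz", case.volume, spacing)
            save_mask(sim / f"{case.patient_id}_mask.nii.gz", case.mask, spacing)
            save_labels(sim / f"{case.patient_id}_truth.nii.gz", case.truth, spacing)
        table = generate_clinical_table(cohort, config.clinical, seed=config.seed + 1)
        table.to_csv(sim / "clinical.csv", index=False)
        _finish(sim)
    clinical = pd.read_csv(sim / "clinical.csv")
    labels = clinical["label"].to_numpy(dtype=int)

    pre, done = _stage(run_dir, "preprocess")
    if not done:
        for pid in pids:
            vol, _ = load_volume(sim / f"{pid}_ct.nii.gz")
            mask = load_mask(sim / f"{pid}_mask.nii.gz")
            comp = make_composite(
                np.asarray(vol, dtype=float),
                mask,
                entropy_radius=config.entropy_radius,
                entropy_bins=config.entropy_bins,
            )
            save_volume(pre / f"{pid}_composite.nii.gz", comp.astype(np.float32), spacing)
        _finish(pre)

    hab, done = _stage(run_dir, "habitat")
    if not done:
        spmaps, tables = {}, []
        for pid in pids:
            comp, _ = load_volume(pre / f"{pid}_composite.nii.gz")
            mask = load_mask(sim / f"{pid}_mask.nii.gz")
            sp = oversegment(
                np.asarray(comp, dtype=float), mask, config.n_superpixels,
                config.compactness, config.seed,
            )
            spmaps[pid] = sp
            tables.append(superpixel_features(np.asarray(comp, dtype=float), sp))
        model = fit_population_clusters(
            tables, config.k_range, config.gap_refs, config.seed, k=config.fixed_k
        )
        (hab / "model.json").write_text(model.to_json())
        for pid, t in zip(pids, tables):
            hmap = assign_habitats(spmaps[pid], t, model)
            save_labels(hab / f"{pid}_habitat.nii.gz", hmap, spacing)
        _finish(hab)
    from .habitat import HabitatModel

    model = HabitatModel.from_json((hab / "model.json").read_text())

    feat, done = _stage(run_dir, "msi")
    if not done:
        rows, rad_rows = [], []
        for pid in pids:
            hmap = load_labels(hab / f"{pid}_habitat.nii.gz")
            mask = load_mask(sim / f"{pid}_mask.nii.gz")
            left, right = split_lungs(mask)
            rows.append(full_msi(hmap, left, right, model.K))
            comp, _ = load_volume(pre / f"{pid}_composite.nii.gz")
            rad_rows.append(whole_lung_radiomics(np.asarray(comp, dtype=float), mask))
        msi_df = pd.DataFrame(rows, index=pids)
        msi_df.insert(0, "patient_id", pids)
        msi_df.to_csv(feat / "msi_features.csv", index=False)
        rad_df = pd.DataFrame(rad_rows, index=pids)
        rad_df.insert(0, "patient_id", pids)
        rad_df.to_csv(feat / "radiomics_features.csv", index=False)
        write_feature_dictionary(feat / "feature_dictionary.json")
        _finish(feat)
    msi_df = pd.read_csv(feat / "msi_features.csv").drop(columns="patient_id")
    rad_df = pd.read_csv(feat / "radiomics_features.csv").drop(columns="patient_id")

    mod, done = _stage(run_dir, "models")
    if not done:
        bench_X = prepare_benchmark_features(clinical)
        prev = pre_test(labels)
        report: dict = {"pre_test_probability": prev, "pre_test_percent": to_percent(prev)}
        preds = {}
        for name, X in (
            ("habitat", msi_df),
            ("benchmark", bench_X),
            ("radiomics", rad_df),
            ("composite", pd.concat([msi_df, bench_X], axis=1)),
        ):
            grid = tuple(k for k in config.k_grid if k <= X.shape[1])
            best_k, _ = select_top_k(X, labels, config.classifier, grid, config.seed)
            cm, pred_df = loocv_evaluate(
                X, labels, config.classifier, n_top_features=best_k, seed=config.seed
            )
            acc, sens, spc = metrics(cm)
            entry = {
                "best_k": best_k,
                "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
                "accuracy": acc, "sensitivity": sens, "specificity": spc,
            }
            try:
                post = post_test_positive(prev, sens, spc)
                entry["post_test_probability"] = post
                entry["post_test_percent"] = to_percent(post)
            except ValueError as e:  # model never calls positive
                entry["post_test_probability"] = None
                entry["post_test_note"] = str(e)
            report[name] = entry
            pred_df.to_csv(mod / f"predictions_{name}.csv", index=False)
            preds[name] = pred_df["y_pred"].to_numpy()
        cascade = cascade_predict(preds["benchmark"], preds["habitat"])
        report["cascade"] = {
            "ambiguous_rate": float((cascade == "ambiguous").mean()),
            "calls": cascade.tolist(),
        }
        (mod / "report.json").write_text(json.dumps(report, indent=1))
        _finish(mod)
    return run_dir
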