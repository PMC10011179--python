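"""End-to-end experiment orchestration.

``run_experiment`` drives the whole chain on synthetic data: simulate
raw leaf cubes -> white/dark calibration -> ROI segmentation and mean
spectra -> GA effective-wavelength selection -> ReliefF reference image
and correlation-ranked reflectance-image set -> LeNet-5 image features
-> spectroscopy-image combination -> young/mature subsample fusion ->
SVM / random-forest / 1-D-DenseNet training and reporting.  Every
stochastic stage derives its seed deterministically from the global
seed, so a rerun with the same config reproduces the summary table
bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import band_select, models, ris as ris_mod, spectra as spectra_mod
from .envi import calibrate
from .fusion import BlockStandardizer, combine, make_ris_stack
from .lenet import LeNet5Features
from .relieff import relieff_weights
from .simulate import STAGES, SimParams, generate_dataset

__all__ = ["RunConfig", "run_experiment", "compare_feature_sets"]

log = logging.getLogger("hsidrought")

STRATEGY_ORDER = ["full_spectra", "ew_spectra", "spectra_image", "fusion"]


@dataclass
class RunConfig:
    """Declarative configuration of one experiment run."""

    design: tuple[int, int, int] = (108, 105, 102)
    seed: int = 0
    sim: dict = field(default_factory=dict)
    ga: dict = field(default_factory=lambda: {"pop_size": 100, "generations": 400,
                                              "crossover_p": 0.5, "mutation_p": 0.1,
                                              "cv_folds": 5, "stall_limit": 20})
    ris: dict = field(default_factory=lambda: {"threshold": 0.3, "max_members": 4,
                                               "single_sample": False})
    lenet: dict = field(default_factory=lambda: {"input_hw": 32, "search_epochs": 8,
                                                 "final_epochs": 25, "batch_size": 16,
                                                 "lr": 1e-3})
    densenet: dict = field(default_factory=lambda: {"epochs": 60, "batch_size": 16,
                                                    "lr": 1e-3})
    svm: dict = field(default_factory=lambda: {"C": 1.0})
    rf: dict = field(default_factory=lambda: {"n_estimators": 500})
    model_names: tuple[str, ...] = ("svm", "rf", "densenet")
    split_ratio: float = 0.7
    eval_cv_folds: int = 3
    segmentation_threshold: float = 0.35

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.design = tuple(cfg.design)
        cfg.model_names = tuple(cfg.model_names)
        for key in ("frame_size", "leaf_shape", "wl_range"):
            if key in cfg.sim:
                cfg.sim[key] = tuple(cfg.sim[key])
        return cfg

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["design"] = list(self.design)
        d["model_names"] = list(self.model_names)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _derive_seed(seed: int, tag: str) -> int:
    """Deterministic child seed per pipeline stage (below 2**31)."""
    return int((seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1))


def _train_one(name: str, cfg: RunConfig, X: np.ndarray, y: np.ndarray, seed: int):
    if name == "svm":
        return models.train_svm(X, y, C=cfg.svm.get("C", 1.0), seed=seed)
    if name == "rf":
        return models.train_rf(X, y, n_estimators=cfg.rf.get("n_estimators", 500), seed=seed)
    if name == "densenet":
        return models.train_densenet1d(X, y, seed=seed, **cfg.densenet)
    raise ValueError(f"unknown model {name!r}")


def _eval_models(cfg: RunConfig, X: np.ndarray, y: np.ndarray, cal: np.ndarray,
                 prd: np.ndarray, tag: str) -> dict[str, models.ModelReport]:
    out = {}
    for name in cfg.model_names:
        model = _train_one(name, cfg, X[cal], y[cal], _derive_seed(cfg.seed, f"{tag}:{name}"))
        out[name] = models.evaluate(model, (X[cal], y[cal]), (X[prd], y[prd]))
    return out


def _cv_evaluator(cfg: RunConfig):
    def evaluator(X: np.ndarray, y: np.ndarray) -> float:
        return band_select.cv_fitness(X, y, np.arange(X.shape[1]),
                                      folds=cfg.eval_cv_folds,
                                      seed=_derive_seed(cfg.seed, "superposition-cv"))
    return evaluator


def run_experiment(cfg: RunConfig, out_dir: str | None = None) -> dict:
    """Run the full pipeline; returns artifacts and the summary table."""
    t0 = time.time()
    out: dict = {"config": cfg}
    sim_params = SimParams(**{"seed": _derive_seed(cfg.seed, "simulate"), **cfg.sim})
    log.info("simulating design=%s", cfg.design)
    ds = generate_dataset(cfg.design, sim_params, as_raw=True)

    log.info("calibrating %d cubes", len(ds))
    cubes = [calibrate(c, ds.refs) for c in ds.cubes]
    qc_clipped = int(sum(c.meta["qc_clipped"] for c in cubes))

    log.info("extracting ROI spectra")
    masks = [spectra_mod.segment_roi(c, threshold=cfg.segmentation_threshold) for c in cubes]
    spec_matrix = np.array([spectra_mod.mean_spectrum(c, m) for c, m in zip(cubes, masks)])
    wavelengths = cubes[0].wavelengths

    # one pair-level split shared by every strategy so results are comparable
    stage_idx = {s: ds.stage_indices(s) for s in STAGES}
    young = stage_idx["young"]
    pair_labels = ds.labels[young]
    pair_plants = ds.plant_ids[young]
    split_spec = models.SplitSpec(ratio=cfg.split_ratio, seed=_derive_seed(cfg.seed, "split"),
                                  unit="pair")
    cal_p, prd_p = models.split(pair_labels, split_spec, groups=pair_plants)
    out["split"] = {"calibration_pairs": len(cal_p), "prediction_pairs": len(prd_p)}

    rows = []
    reports: dict = {}
    combined_all: dict[str, np.ndarray] = {}
    for stage in STAGES:
        idx = stage_idx[stage]
        # young/mature are generated pairwise in lockstep, so positions align
        X_full = spec_matrix[idx]
        y_stage = ds.labels[idx]
        assert np.array_equal(y_stage, pair_labels)
        tag = f"{stage}"

        reports[(stage, "full_spectra")] = _eval_models(cfg, X_full, y_stage, cal_p, prd_p,
                                                        f"{tag}:full")
        log.info("[%s] GA effective-wavelength selection", stage)
        ga_cfg = band_select.GAConfig(seed=_derive_seed(cfg.seed, f"{tag}:ga"), **cfg.ga)
        ew = band_select.ew_protocol(X_full[cal_p], y_stage[cal_p], ga_cfg,
                                     wavelengths=wavelengths)
        out[f"ew_{stage}"] = ew
        X_ew = X_full[:, ew.indices]
        reports[(stage, "ew_spectra")] = _eval_models(cfg, X_ew, y_stage, cal_p, prd_p,
                                                      f"{tag}:ew")

        log.info("[%s] RIS selection (%d EWs)", stage, ew.indices.size)
        w = relieff_weights(X_ew[cal_p], y_stage[cal_p],
                            k_neighbors=min(10, np.bincount(y_stage[cal_p]).min() - 1))
        ref_pos = int(np.argmax(w))
        stage_cubes = [cubes[i] for i in idx]
        stage_masks = [masks[i] for i in idx]
        if cfg.ris.get("single_sample", False):
            pick = int(np.random.default_rng(_derive_seed(cfg.seed, f"{tag}:pick")).choice(cal_p))
            corr = ris_mod.image_correlation(stage_cubes[pick], stage_masks[pick], ew.indices)
        else:
            corr = ris_mod.average_image_correlation(
                [stage_cubes[i] for i in cal_p], [stage_masks[i] for i in cal_p], ew.indices)
        out[f"corr_{stage}"] = corr
        order_pos = ris_mod.greedy_container(corr, ref_pos,
                                             threshold=cfg.ris.get("threshold", 0.3),
                                             max_members=cfg.ris.get("max_members", 4))
        candidate_wls = [float(wavelengths[ew.indices[p]]) for p in order_pos]

        hw = cfg.lenet.get("input_hw", 32)
        stacks = np.array([make_ris_stack(c, m, candidate_wls, out_hw=hw)
                           for c, m in zip(stage_cubes, stage_masks)])

        spec_scaler = BlockStandardizer().fit(X_ew[cal_p])

        def extractor(k: int, _stacks=stacks, _y=y_stage, _tag=tag) -> np.ndarray:
            net = LeNet5Features(input_hw=hw, in_channels=k,
                                 epochs=cfg.lenet.get("search_epochs", 8),
                                 batch_size=cfg.lenet.get("batch_size", 16),
                                 lr=cfg.lenet.get("lr", 1e-3),
                                 seed=_derive_seed(cfg.seed, f"{_tag}:lenet:{k}"))
            net.fit(_stacks[cal_p, :k], _y[cal_p])
            return net.transform(_stacks[cal_p, :k])

        log.info("[%s] superposition search over %d candidates", stage, len(candidate_wls))
        spec_cal_std = spec_scaler.transform(X_ew[cal_p])
        ris = ris_mod.superposition_search(spec_cal_std, y_stage[cal_p], candidate_wls,
                                           extractor, _cv_evaluator(cfg))
        out[f"ris_{stage}"] = ris
        k = ris.k_selected
        log.info("[%s] final LeNet-5 on k=%d channels", stage, k)
        net = LeNet5Features(input_hw=hw, in_channels=k,
                             epochs=cfg.lenet.get("final_epochs", 25),
                             batch_size=cfg.lenet.get("batch_size", 16),
                             lr=cfg.lenet.get("lr", 1e-3),
                             seed=_derive_seed(cfg.seed, f"{tag}:lenet:final"))
        net.fit(stacks[cal_p, :k], y_stage[cal_p])
        out[f"lenet_{stage}"] = net
        img_feats = net.transform(stacks[:, :k])
        img_scaler = BlockStandardizer().fit(img_feats[cal_p])
        X_comb = combine(X_ew, img_feats, spec_scaler, img_scaler)
        combined_all[stage] = X_comb
        reports[(stage, "spectra_image")] = _eval_models(cfg, X_comb, y_stage, cal_p, prd_p,
                                                         f"{tag}:comb")

    log.info("subsample fusion")
    X_fused = np.hstack([combined_all["young"], combined_all["mature"]])
    reports[("fused", "fusion")] = _eval_models(cfg, X_fused, pair_labels, cal_p, prd_p, "fusion")

    for (stage, strategy), by_model in reports.items():
        for model_name, rep in by_model.items():
            rows.append({"strategy": strategy, "stage": stage, "model": model_name,
                         "acc_c": round(rep.acc_c, 2), "acc_p": round(rep.acc_p, 2)})
    summary = pd.DataFrame(rows)
    summary["strategy"] = pd.Categorical(summary["strategy"], categories=STRATEGY_ORDER,
                                         ordered=True)
    summary = summary.sort_values(["strategy", "stage", "model"]).reset_index(drop=True)
    out.update({"summary": summary, "reports": reports, "qc_clipped": qc_clipped,
                "split_seed": split_spec.seed, "runtime_s": time.time() - t0})

    if out_dir is not None:
        _write_artifacts(out, cfg, spec_matrix, wavelengths, ds, out_dir)
    return out


def _write_artifacts(out: dict, cfg: RunConfig, spec_matrix, wavelengths, ds, out_dir: str) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    cols = {f"{w:.2f}": spec_matrix[:, i] for i, w in enumerate(wavelengths)}
    table = pd.DataFrame({"stage": ds.stages, "treatment": ds.labels,
                          "plant_id": ds.plant_ids, "replicate": ds.replicate_idx, **cols})
    table.to_csv(os.path.join(out_dir, "spectra.csv"), index=False)
    out["summary"].to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    from .ris import write_corr_heatmap

    for stage in STAGES:
        with open(os.path.join(out_dir, f"ews_{stage}.json"), "w") as fh:
            json.dump(out[f"ew_{stage}"].to_dict(), fh, indent=1)
        with open(os.path.join(out_dir, f"ris_{stage}.json"), "w") as fh:
            json.dump(out[f"ris_{stage}"].to_dict(), fh, indent=1)
        write_corr_heatmap(out[f"corr_{stage}"], os.path.join(out_dir, f"corr_{stage}"))
        out[f"lenet_{stage}"].save(os.path.join(out_dir, f"lenet_{stage}.npz"))
    with open(os.path.join(out_dir, "reports.json"), "w") as fh:
        json.dump({f"{s}/{strat}/{m}": rep.to_dict()
                   for (s, strat), by_model in out["reports"].items()
                   for m, rep in by_model.items()}, fh, indent=1)
    for (s, strat), by_model in out["reports"].items():
        for m, rep in by_model.items():
            rep.write_csvs(os.path.join(out_dir, f"report_{s}_{strat}_{m}"))


def compare_feature_sets(entries: list[dict]) -> pd.DataFrame:
    """Delta table of ACC_C/ACC_P between feature strategies.

    Each entry: ``{"strategy", "stage", "model", "acc_c", "acc_p",
    "split_seed"}``.  All entries must share one split seed, otherwise
    the accuracies are not comparable.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 reports to compare")
    seeds = {e.get("split_seed") for e in entries}
    if len(seeds) > 1:
        raise ValueError(f"mismatched split seeds across reports: {sorted(map(str, seeds))}")
    df = pd.DataFrame(entries)
    df["strategy"] = pd.Categorical(df["strategy"], categories=STRATEGY_ORDER, ordered=True)
    df = df.sort_values(["strategy", "stage", "model"]).reset_index(drop=True)
    base = df.iloc[0]
    df["delta_acc_c"] = (df["acc_c"] - base["acc_c"]).round(2)
    df["delta_acc_p"] = (df["acc_p"] - base["acc_p"]).round(2)
    return df
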