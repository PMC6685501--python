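"""End-to-end pipeline: synthesis/measurement -> models -> evaluation.

``run_pipeline`` ties the stages together under one seeded configuration
and writes a reproducible report bundle (feature CSV, model fit JSONs,
rank-group report).  Every output embeds the seed and a hash of the
configuration; rerunning with the same config yields byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfi as dfi_mod
from . import evaluation, modeling, morphometry, synthetic
from .errors import ConfigurationError
from .io import read_feature_table, write_feature_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's input mode, paths, seed, splits and model choices."""

    mode: str = "synthetic"                  # synthetic | features | images
    n_cells: int = 1056
    feature_path: str | None = None
    image_paths: list[str] | None = None     # image-set basepaths
    out_dir: str | None = None
    seed: int = 0
    fractions: tuple[float, float, float] = (0.65, 0.10, 0.25)
    rank_bounds: tuple = evaluation.DEFAULT_RANK_BOUNDS
    threshold_percentile: float = 80.0
    models: tuple[str, ...] = ("linear", "nn", "logistic")
    forward_selection: bool = True
    noise_sd: float | None = None            # synthetic mode override

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "features", "images"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        if self.mode == "features" and not self.feature_path:
            raise ConfigurationError("features mode needs feature_path")
        if self.mode == "images" and not self.image_paths:
            raise ConfigurationError("images mode needs image_paths")
        unknown = set(self.models) - {"linear", "nn", "logistic"}
        if unknown:
            raise ConfigurationError(f"unknown model kind(s): {sorted(unknown)}")

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # the analysis, not where it is written
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def measure_image_table(image_sets, contrast_enhance: bool = False) -> pd.DataFrame:
    """Measure morphology + DFI for a sequence of image sets into a table."""
    rows = []
    for i, images in enumerate(image_sets):
        cell = images.cell_id or f"c{i:05d}"
        try:
            px = images.pixel_size_um
            head = morphometry.segment_head(images.brightfield, px,
                                            contrast_enhance=contrast_enhance)
            dims = morphometry.measure_head(head, px)
            profile = morphometry.axial_gray_profile(images.brightfield, head)
            acro = morphometry.measure_acrosome(profile, head,
                                                images.brightfield, px)
            vac = morphometry.measure_vacuoles(images.brightfield, head,
                                               acro.region, px)
            mid = morphometry.measure_midpiece(images.brightfield, head, px)
            green = dfi_mod.channel_intensity(images.green, head)
            red = dfi_mod.channel_intensity(images.red, head)
            result = dfi_mod.compute_dfi(red, green)
        except Exception as err:
            err.add_note(f"stage: measure, cell: {cell}")
            raise
        rows.append({
            "donor": images.donor if images.donor is not None else 0,
            "cell_id": images.cell_id or f"c{i:05d}",
            "C": morphometry.circularity(dims.A, dims.P),
            "HW": dims.HW, "L": dims.L, "MW": mid.mw_um,
            "VA": vac.va_um2, "AA": acro.aa_um2,
            "DFI": result.dfi,
            "green": green, "red": red,
        })
    return pd.DataFrame(rows)


def _fit_and_score(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Fit the requested models and score them on the held-out split."""
    split = modeling.split_data(table, config.fractions, seed=config.seed)
    ln = dfi_mod.ln_dfi(table["DFI"].to_numpy(float))
    out: dict = {"split_counts": split.counts()}

    def split_r(predicted: np.ndarray) -> dict:
        return {
            name: evaluation.pearson_r(ln[split.labels == name],
                                       predicted[split.labels == name])
            for name in modeling.SPLIT_LABELS if (split.labels == name).any()
        }

    if "linear" in config.models:
        train = table[split.train]
        if config.forward_selection:
            centers = modeling.centers_from_table(train)
            spec = modeling.forward_select(train,
                                           modeling.candidate_terms(centers),
                                           seed=config.seed)
        else:
            spec = synthetic.table1_model()
        fit = modeling.fit_linear(train, modeling.LinearModelSpec(list(spec.terms)))
        predicted = fit.predict(table)
        report = evaluation.rank_group_report(
            predicted[split.test], ln[split.test], config.rank_bounds)
        out["linear"] = {"fit": fit, "r": split_r(predicted),
                         "rank_groups": report, "predicted": predicted}
    if "nn" in config.models:
        reg = modeling.fit_nn(table, split, modeling.NNConfig(seed=config.seed))
        predicted = reg.predict(table)
        report = evaluation.rank_group_report(
            predicted[split.test], ln[split.test], config.rank_bounds)
        out["nn"] = {"model": reg, "r": split_r(predicted),
                     "rank_groups": report, "predicted": predicted}
    if "logistic" in config.models:
        fit = modeling.fit_logistic(table, split,
                                    threshold_percentile=config.threshold_percentile,
                                    seed=config.seed)
        scores = fit.predict_proba(table)
        labels = fit.true_labels(table)
        pred_labels = fit.predict_label(table)
        per_split = {}
        for name in modeling.SPLIT_LABELS:
            m = split.labels == name
            if not m.any() or len(np.unique(labels[m])) < 2:
                continue
            roc = evaluation.roc_auc(scores[m], labels[m])
            cm = evaluation.confusion(pred_labels[m], labels[m])
            per_split[name] = {"auc": roc.auc, "accuracy": cm.accuracy,
                               "confusion": cm}
        out["logistic"] = {"fit": fit, "per_split": per_split}
    out["split"] = split
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and (optionally) write the bundle."""
    cfg_hash = config.hash()
    if config.mode == "synthetic":
        syn_kwargs = {"n_cells": config.n_cells, "seed": config.seed}
        if config.noise_sd is not None:
            syn_kwargs["noise_sd"] = config.noise_sd
        syn = synthetic.SyntheticConfig(**syn_kwargs)
        table, truth = synthetic.generate_feature_table(syn)
    elif config.mode == "features":
        table, truth = read_feature_table(config.feature_path), None
    else:
        from .io import read_image_set
        image_sets = (read_image_set(p) for p in config.image_paths)
        table, truth = measure_image_table(image_sets), None

    results = _fit_and_score(table, config)
    bundle = {"config": config, "config_hash": cfg_hash, "table": table,
              "truth": truth, **results}

    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _jsonify_rank_groups(groups) -> list[dict]:
    return [g.to_dict() for g in groups]


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": bundle["config_hash"]}
    write_feature_table(bundle["table"], out / "features.csv")

    summary: dict = dict(stamp)
    summary["split_counts"] = bundle["split_counts"]
    if "linear" in bundle:
        fit = bundle["linear"]["fit"]
        payload = {**stamp, "fit": fit.to_dict(), "r": bundle["linear"]["r"]}
        (out / "linear_fit.json").write_text(json.dumps(payload, indent=1))
        rows = pd.DataFrame(_jsonify_rank_groups(bundle["linear"]["rank_groups"]))
        rows.insert(0, "config_hash", bundle["config_hash"])
        rows.insert(0, "seed", config.seed)
        rows.to_csv(out / "rank_groups.csv", index=False)
        summary["linear_r"] = bundle["linear"]["r"]
    if "nn" in bundle:
        summary["nn_r"] = bundle["nn"]["r"]
        summary["nn_epochs"] = bundle["nn"]["model"].n_epochs
    if "logistic" in bundle:
        fit = bundle["logistic"]["fit"]
        payload = {**stamp, "fit": fit.to_dict(),
                   "per_split": {k: {"auc": v["auc"], "accuracy": v["accuracy"],
                                     "confusion": v["confusion"].to_dict()}
                                 for k, v in bundle["logistic"]["per_split"].items()}}
        (out / "logistic_fit.json").write_text(json.dumps(payload, indent=1))
        summary["logistic"] = {k: {"auc": v["auc"], "accuracy": v["accuracy"]}
                               for k, v in bundle["logistic"]["per_split"].items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
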