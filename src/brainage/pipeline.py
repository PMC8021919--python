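"""End-to-end orchestration: simulate -> preprocess -> features -> ML/DL ->
ensemble -> evaluate.

Each invocation creates a run directory (named after a timestamp or a caller-
supplied id) and executes the configured stages in dependency order, writing
every artifact (cohort volumes and table, feature tables, CV results,
checkpoint logs, selection manifests, metric reports) beneath it together
with a manifest recording the config hash, package versions, stage seeds and
completed stages.  A stage failure halts the run with the stage name in the
error; artifacts from completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, _as_jsonable
from .ensemble import (
    OBJECTIVE1_RECIPES,
    median_aggregate,
    select_checkpoints_objective2,
)
from .evaluation import PredictionBatch, apply_bias, fit_bias, metric_report
from .features import build_parcel_table, build_sica_table, cohort_mask, fit_spatial_ica
from .ml import fit_final, nested_cv
from .nn.resnet import ResNet26, build_model
from .nn.train import best_checkpoint, train
from .preprocess import CohortRescaler, conform_subject, stack_channels
from .synthetic import make_atlas, make_cohort

log = logging.getLogger("brainage")

STAGE_ORDER = (
    "simulate",
    "preprocess",
    "features",
    "train_ml",
    "train_dl",
    "ensemble",
    "evaluate",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineRunner:
    """Holds intermediates between stages of one run."""

    def __init__(self, config: RunConfig, run_id: str | None = None) -> None:
        self.config = config
        run_id = run_id or time.strftime("run-%Y%m%d-%H%M%S")
        self.run_dir = Path(config.outdir) / run_id
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.completed: list[str] = []
        # intermediates
        self.volumes = None
        self.table: pd.DataFrame | None = None
        self.atlas = None
        self.train_idx: np.ndarray | None = None
        self.val_idx: np.ndarray | None = None
        self.scaled_volumes = None
        self._conformed = None
        self.feature_tables: dict = {}
        self.ml_results: dict = {}
        self.dl_records: dict = {}
        self.dl_models: dict[str, ResNet26] = {}
        self.ensemble_preds: dict[str, np.ndarray] = {}

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config.phantom
        self.atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
        self.volumes, self.table = make_cohort(
            cfg, atlas=self.atlas, outdir=self.run_dir / "cohort"
        )
        rng = np.random.default_rng(cfg.seed)
        n = len(self.volumes)
        n_val = max(1, int(round(self.config.val_fraction * n)))
        order = rng.permutation(n)
        self.val_idx = np.sort(order[:n_val])
        self.train_idx = np.sort(order[n_val:])
        split = pd.DataFrame(
            {
                "subject_id": self.table["subject_id"],
                "split": ["val" if i in set(self.val_idx) else "train" for i in range(n)],
            }
        )
        split.to_csv(self.run_dir / "cohort" / "split.csv", index=False)

    def preprocess(self) -> None:
        train_vols = [self.volumes[i] for i in self.train_idx]
        scaler = CohortRescaler().fit(train_vols)
        self.scaled_volumes = [scaler.transform(v) for v in self.volumes]
        (self.run_dir / "preprocess").mkdir(exist_ok=True)
        with open(self.run_dir / "preprocess" / "rescale.json", "w") as fh:
            json.dump(scaler.channel_max_, fh, indent=2)

    def features(self) -> None:
        fcfg = self.config.features
        outdir = self.run_dir / "features"
        outdir.mkdir(exist_ok=True)
        parcel = build_parcel_table(self.volumes, self.atlas, fcfg.parcel_channels)
        parcel.to_frame().to_csv(outdir / "parcel_features.csv")
        train_vols = [self.volumes[i] for i in self.train_idx]
        bases = {}
        for ch in fcfg.sica_channels:
            mask = cohort_mask(train_vols, ch, frac=fcfg.mask_frac)
            data = np.stack([v.channels[ch][mask] for v in train_vols])
            bases[ch] = fit_spatial_ica(
                data, mask, K=fcfg.n_components, seed=self.config.cv.seed, channel=ch
            )
        sica = build_sica_table(self.volumes, bases, K=fcfg.n_components)
        sica.to_frame().to_csv(outdir / "sica_features.csv")
        self.feature_tables = {"parcel": parcel, "sica": sica}

    def _subset_table(self, table, idx):
        from .features import FeatureTable

        return FeatureTable(
            matrix=table.matrix[idx],
            feature_names=table.feature_names,
            subject_ids=[table.subject_ids[i] for i in idx],
        )

    def train_ml(self) -> None:
        ages = self.table["age"].to_numpy()
        outdir = self.run_dir / "ml"
        outdir.mkdir(exist_ok=True)
        sica = self.feature_tables["sica"]
        train_tab = self._subset_table(sica, self.train_idx)
        results = {}
        for algo in ("ridge", "svr_rbf"):
            cv = nested_cv(train_tab, ages[self.train_idx], algo, self.config.cv)
            final = fit_final(train_tab, ages[self.train_idx], algo, self.config.cv)
            val_pred = final.predict(self._subset_table(sica, self.val_idx))
            train_pred_final = final.predict(train_tab)
            results[algo] = {
                "cv": cv,
                "val_pred": val_pred,
                "train_pred": train_pred_final,
            }
            pd.DataFrame(
                {
                    "subject_id": train_tab.subject_ids,
                    "age": ages[self.train_idx],
                    "pred_oof": cv.predictions,
                }
            ).to_csv(outdir / f"{algo}_oof_predictions.csv", index=False)
            with open(outdir / f"{algo}_cv.json", "w") as fh:
                json.dump(cv.to_dict(), fh, indent=2)
        self.ml_results = results

    def _stacked(self, channels, idx):
        if self._conformed is None:
            target = self.config.dl.grid
            if tuple(self.scaled_volumes[0].shape) == tuple(target):
                self._conformed = self.scaled_volumes
            else:
                self._conformed = [
                    conform_subject(v, target) for v in self.scaled_volumes
                ]
        return np.stack(
            [stack_channels(self._conformed[i], channels).data for i in idx]
        )

    def train_dl(self) -> None:
        ages = self.table["age"].to_numpy()
        sexes = self.table["sex"].to_numpy().astype(float)
        outdir = self.run_dir / "dl"
        outdir.mkdir(exist_ok=True)
        recipes = {r.name: r for r in OBJECTIVE1_RECIPES}
        for name in self.config.dl.members:
            recipe = recipes[name]
            spec = dataclasses.replace(
                self.config.dl.spec,
                in_channels=len(recipe.channels),
                sex_input=recipe.sex_input,
            )
            tcfg = dataclasses.replace(
                self.config.dl.train, loss_mode=recipe.loss_mode
            )
            model = build_model(spec, seed=tcfg.seed)
            xt = self._stacked(recipe.channels, self.train_idx)
            xv = self._stacked(recipe.channels, self.val_idx)
            records = train(
                model,
                xt,
                ages[self.train_idx],
                xv,
                ages[self.val_idx],
                tcfg,
                train_sex=sexes[self.train_idx] if recipe.sex_input else None,
                val_sex=sexes[self.val_idx] if recipe.sex_input else None,
                config_id=name,
            )
            self.dl_records[name] = records
            self.dl_models[name] = model
            pd.DataFrame(
                [
                    {"config_id": r.config_id, "epoch": r.epoch,
                     "val_mae": r.val_mae, "val_rho": r.val_rho}
                    for r in records
                ]
            ).to_csv(outdir / f"{name}_epochs.csv", index=False)
            log.info("trained %s: best val MAE %.2f y", name,
                     best_checkpoint(records).val_mae)

    def _member_preds(self, name: str, records, idx) -> np.ndarray:
        recipes = {r.name: r for r in OBJECTIVE1_RECIPES}
        recipe = recipes[name]
        model = self.dl_models[name]
        best = best_checkpoint(records)
        if best.weights is not None:
            model.load_state_dict(best.weights)
        x = self._stacked(recipe.channels, idx)
        sexes = self.table["sex"].to_numpy().astype(float)
        s = sexes[idx] if recipe.sex_input else None
        return model.predict(x, sex=s)

    def ensemble(self) -> None:
        outdir = self.run_dir / "ensemble"
        outdir.mkdir(exist_ok=True)
        if self.config.ensemble_objective == 1:
            rows, train_rows, manifest = [], [], []
            for name, records in self.dl_records.items():
                rows.append(self._member_preds(name, records, self.val_idx))
                train_rows.append(self._member_preds(name, records, self.train_idx))
                best = best_checkpoint(records)
                manifest.append(
                    {"config_id": name, "epoch": best.epoch, "val_mae": best.val_mae}
                )
            preds = median_aggregate(np.stack(rows))
            self.ensemble_preds["dl_train"] = median_aggregate(np.stack(train_rows))
        else:
            pool = [r for recs in self.dl_records.values() for r in recs]
            selected = select_checkpoints_objective2(pool)
            manifest = [
                {"config_id": r.config_id, "epoch": r.epoch,
                 "val_mae": r.val_mae, "val_rho": r.val_rho}
                for r in selected
            ]
            rows = []
            recipes = {r.name: r for r in OBJECTIVE1_RECIPES}
            sexes = self.table["sex"].to_numpy().astype(float)
            for rec in selected:
                model = self.dl_models[rec.config_id]
                if rec.weights is not None:
                    model.load_state_dict(rec.weights)
                recipe = recipes[rec.config_id]
                xv = self._stacked(recipe.channels, self.val_idx)
                sv = sexes[self.val_idx] if recipe.sex_input else None
                rows.append(model.predict(xv, sex=sv))
            if not rows:
                raise RuntimeError("objective-2 selection returned no checkpoints")
            preds = median_aggregate(np.stack(rows))
        self.ensemble_preds["dl"] = preds
        with open(outdir / "members.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        pd.DataFrame(
            {
                "subject_id": [self.table["subject_id"][i] for i in self.val_idx],
                "pred": preds,
            }
        ).to_csv(outdir / "val_predictions.csv", index=False)

    def evaluate(self) -> None:
        ages = self.table["age"].to_numpy()
        yv = ages[self.val_idx]
        outdir = self.run_dir / "report"
        outdir.mkdir(exist_ok=True)
        report: dict = {}
        for algo, res in self.ml_results.items():
            batch = PredictionBatch(y=yv, y_pred=res["val_pred"])
            report[algo] = metric_report(batch).to_dict()
            # bias line fitted on out-of-fold training predictions: in-sample
            # predictions underestimate the regression-to-the-mean slope
            bias = fit_bias(
                PredictionBatch(
                    y=ages[self.train_idx], y_pred=res["cv"].predictions
                )
            )
            corrected = apply_bias(bias, batch)
            report[algo + "_bias_corrected"] = metric_report(corrected).to_dict()
        if "dl" in self.ensemble_preds:
            batch = PredictionBatch(y=yv, y_pred=self.ensemble_preds["dl"])
            report["ensemble_dl"] = metric_report(batch).to_dict()
            if "dl_train" in self.ensemble_preds:
                bias = fit_bias(
                    PredictionBatch(
                        y=ages[self.train_idx],
                        y_pred=self.ensemble_preds["dl_train"],
                    )
                )
                corrected = apply_bias(bias, batch)
                report["ensemble_dl_bias_corrected"] = metric_report(
                    corrected
                ).to_dict()
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        self.report = report

    # -- driver -------------------------------------------------------------
    _DEPS = {
        "simulate": (),
        "preprocess": ("simulate",),
        "features": ("simulate",),
        "train_ml": ("features",),
        "train_dl": ("preprocess",),
        "ensemble": ("train_dl",),
        "evaluate": ("train_ml", "ensemble"),
    }

    def _closure(self, stages) -> list[str]:
        needed: set[str] = set()

        def visit(s: str) -> None:
            if s in needed:
                return
            for d in self._DEPS[s]:
                visit(d)
            needed.add(s)

        for s in stages:
            visit(s)
        return [s for s in STAGE_ORDER if s in needed]

    def run(self) -> Path:
        requested = self._closure(s for s in STAGE_ORDER if s in self.config.stages)
        for stage in requested:
            log.info("stage %s ...", stage)
            try:
                getattr(self, stage)()
            except Exception as err:  # halt with stage context, keep artifacts
                self._write_manifest(failed=stage)
                raise StageError(stage, err) from err
            self.completed.append(stage)
        self._write_manifest()
        return self.run_dir

    def _write_manifest(self, failed: str | None = None) -> None:
        manifest = {
            "package_version": __version__,
            "config_hash": self.config.config_hash(),
            "config": _as_jsonable(self.config),
            "seed": self.config.seed,
            "stages_completed": list(self.completed),
        }
        if failed:
            manifest["stage_failed"] = failed
        with open(self.run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def run_pipeline(config: RunConfig, run_id: str | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    return PipelineRunner(config, run_id=run_id).run()
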