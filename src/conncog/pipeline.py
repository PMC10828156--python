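"""Pipeline orchestration: simulate -> features -> targets -> predict -> report.

The whole run is driven by one config dict (YAML-loadable) and a single
seed; each stage logs wall time, writes plain-text products into the
output directory, and records itself in a JSON manifest.  A stage whose
inputs (config section + seed) are unchanged and whose products still
exist is not recomputed on rerun — its products are reloaded instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cognition, evaluation, features, io, ml, synthetic  # noqa: F401
from .base import Connectome

logger = logging.getLogger("conncog")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "n_subjects": 120,
        "n_nodes": 60,
        "n_networks": 7,
        "n_timepoints": 120,
        "missing_rate": 0.02,
        "fc_mode": "panel",
    },
    "features": {"fset": "A", "alpha": 0.05, "n_perm": 100, "denominator": "subject_edges"},
    "predict": {
        "approach": "concat",
        "target": "global",
        "algorithms": ["ridge"],
        "deconf": "no_deconf",
        "extra_features": False,
        "outer_k": 5,
        "repeats": 2,
        "inner_k": 5,
        "reduced_grids": True,
    },
}

#: small grids for smoke runs; full printed grids used when reduced_grids=False
_REDUCED_GRIDS = {
    "ridge": {"alpha": [0.1, 10.0, 1000.0]},
    "lasso": {"alpha": [0.1, 1.0, 10.0]},
    "en": {"alpha": [0.1, 1.0, 10.0], "l1_ratio": [0.5]},
    "linsvr": {"C": [0.001, 0.1, 1.0]},
    "rf": {"n_estimators": [100], "max_depth": [4, None]},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and overrides."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _stage_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


class PipelineRun:
    """Stateful pipeline over one output directory."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.stages: dict[str, dict] = {}
        self.outputs: dict[str, str] = {}
        self._state_path = self.outdir / "stage_state.json"
        self._state = (
            json.loads(self._state_path.read_text()) if self._state_path.exists() else {}
        )

    # -- stage bookkeeping ---------------------------------------------
    def _run_stage(self, name: str, payload: dict, fn, loader=None):
        key = _stage_hash({"config": payload, "seed": self.seed})
        products = self._state.get(f"{name}_products", [])
        cached = self._state.get(name) == key and all(Path(p).exists() for p in products)
        t0 = time.time()
        try:
            if cached and loader is not None:
                loader()
                logger.info("stage %s: cached, reloaded products", name)
                self.stages[name] = {"status": "cached", "hash": key}
                for p in products:
                    self.outputs.setdefault(Path(p).stem, p)
                return
            produced = fn()
        except Exception as exc:
            self.stages[name] = {"status": "failed", "hash": key, "error": str(exc)}
            self._save_state()
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        self.stages[name] = {
            "status": "ok",
            "hash": key,
            "wall_time_s": round(time.time() - t0, 3),
        }
        self._state[name] = key
        self._state[f"{name}_products"] = [str(p) for p in produced]
        self._save_state()
        logger.info("stage %s: done in %.1fs", name, time.time() - t0)

    def _save_state(self) -> None:
        self._state_path.write_text(json.dumps(self._state, indent=2))

    # -- simulate --------------------------------------------------------
    def _make_cohort(self) -> None:
        cohort_cfg = synthetic.CohortConfig(seed=self.seed, **self.config["cohort"])
        self.cohort = synthetic.generate_cohort(cohort_cfg)

    def simulate(self) -> None:
        def _fn():
            self._make_cohort()
            cohort = self.cohort
            subj_path = self.outdir / "subjects.csv"
            cohort.subjects.to_csv(subj_path, index=False)
            parc_path = io.write_parcellation(
                cohort.parcellation, self.outdir / "parcellation.tsv"
            )
            io.write_connectome_dir(cohort.sc, self.outdir / "connectomes")
            gmv_path = self.outdir / "gmv.csv"
            pd.DataFrame(cohort.gmv, index=cohort.subjects["subject_id"]).to_csv(gmv_path)
            battery_path = self.outdir / "battery.csv"
            pd.DataFrame(
                cohort.battery.scores,
                index=cohort.subjects["subject_id"],
                columns=cohort.battery.test_names,
            ).to_csv(battery_path)
            self.outputs.update(
                subjects=str(subj_path),
                parcellation=str(parc_path),
                gmv=str(gmv_path),
                battery=str(battery_path),
            )
            return [subj_path, parc_path, gmv_path, battery_path]

        # cohort generation is deterministic and cheap relative to the
        # later stages, so a cache hit regenerates it in memory only
        self._run_stage("simulate", self.config["cohort"], _fn, loader=self._make_cohort)

    # -- features --------------------------------------------------------
    def features(self) -> None:
        cfg = self.config["features"]

        def _load():
            self.feature_matrix = io.read_feature_matrix(self.outdir / "features")

        def _fn():
            cohort = self.cohort
            parc = cohort.parcellation
            denom = cfg.get("denominator", "subject_edges")
            fc_conns, fc_neg_conns = [], []
            for i, panel in enumerate(cohort.fc_panels or []):
                sid = cohort.subjects["subject_id"].iloc[i]
                filtered = features.edge_significance_filter(
                    panel,
                    n_perm=cfg.get("n_perm", 100),
                    alpha=cfg.get("alpha", 0.05),
                    seed=self.seed + i,
                    subject_id=sid,
                )
                z = features.fisher_z(filtered.matrix)
                fc_conns.append(Connectome(sid, "FC", features.positive_part(z)))
                if cfg.get("fset") == "C":
                    fc_neg_conns.append(Connectome(sid, "FC", features.negative_part(z)))
            sc_conns = [
                Connectome(c.subject_id, "SC", features.log10_sc(c.matrix))
                for c in cohort.sc
            ]
            fm = features.assemble_feature_set(
                cfg.get("fset", "A"),
                parc,
                cohort.subjects["subject_id"].tolist(),
                fc=features.nodal_metrics(fc_conns, parc, denom) if fc_conns else None,
                sc=features.nodal_metrics(sc_conns, parc, denom),
                gmv=cohort.gmv,
                fc_neg=features.nodal_metrics(fc_neg_conns, parc, denom)
                if fc_neg_conns
                else None,
            )
            self.feature_matrix = fm
            paths = io.write_feature_matrix(fm, self.outdir / "features")
            self.outputs["features"] = str(paths[0])
            return list(paths)

        self._run_stage("features", cfg, _fn, loader=_load)

    # -- targets ---------------------------------------------------------
    def targets(self) -> None:
        def _load():
            self.targets_table = pd.read_csv(self.outdir / "targets.csv")

        def _fn():
            table, _global_sol, profile_sol, excluded = cognition.build_targets(
                self.cohort.battery, self.cohort.subjects
            )
            self.targets_table = table
            self.excluded_subjects = excluded
            path = self.outdir / "targets.csv"
            table.to_csv(path, index=False)
            loadings_path = self.outdir / "loadings.csv"
            pd.DataFrame(
                profile_sol.loadings,
                index=self.cohort.battery.test_names,
                columns=[f"comp{c + 1}" for c in range(profile_sol.n_components)],
            ).to_csv(loadings_path)
            self.outputs["targets"] = str(path)
            return [path, loadings_path]

        self._run_stage("targets", {}, _fn, loader=_load)

    # -- predict ---------------------------------------------------------
    def predict(self) -> None:
        cfg = self.config["predict"]

        def _load():
            self.fold_frames = {
                a: pd.read_csv(self.outdir / f"folds_{a}.csv")
                for a in cfg.get("algorithms", ["ridge"])
            }

        def _fn():
            table = self.targets_table
            keep = self.cohort.subjects["subject_id"].isin(table["subject_id"])
            subjects = self.cohort.subjects.loc[keep].reset_index(drop=True)
            fm = self.feature_matrix
            X = fm.values[keep.to_numpy()]
            target_col = cfg.get("target", "global")
            if target_col not in table.columns:
                raise ValueError(f"target column {target_col!r} not in targets table")
            y = table[target_col].to_numpy()
            plan = ml.make_cv_plan(
                len(subjects),
                outer_k=cfg.get("outer_k", 10),
                repeats=cfg.get("repeats", 10),
                inner_k=cfg.get("inner_k", 5),
                seed=self.seed,
            )
            deconf = ml.DeconfoundSpec(cfg.get("deconf", "no_deconf"))
            extra = (
                subjects[["age", "sex", "education"]]
                if cfg.get("extra_features", False)
                else None
            )
            produced = []
            self.fold_frames = {}
            for algorithm in cfg.get("algorithms", ["ridge"]):
                grid = _REDUCED_GRIDS[algorithm] if cfg.get("reduced_grids") else None
                mc = ml.ModelConfig(algorithm, hyper_grid=grid)
                if cfg.get("approach", "concat") == "concat":
                    folds = ml.fit_predict_concat(
                        X, y, mc, plan, deconf, subjects, extra_features=extra
                    )
                else:
                    blocks = {}
                    for modality in ("fc", "fc_neg", "sc", "gmv"):
                        cols = (fm.feature_meta["modality"] == modality).to_numpy()
                        if cols.any():
                            blocks[modality] = X[:, cols]
                    meta_grid = _REDUCED_GRIDS["rf"] if cfg.get("reduced_grids") else None
                    folds = ml.fit_predict_stacking(
                        blocks, y, mc, plan, deconf, subjects,
                        extra_features=extra, meta_grid=meta_grid,
                    )
                frame = ml.fold_results_frame(folds)
                self.fold_frames[algorithm] = frame
                path = self.outdir / f"folds_{algorithm}.csv"
                frame.to_csv(path, index=False)
                produced.append(path)
                self.outputs[f"folds_{algorithm}"] = str(path)
            return produced

        self._run_stage("predict", cfg, _fn, loader=_load)

    # -- report ----------------------------------------------------------
    def report(self) -> None:
        def _load():
            pass  # summary.csv already on disk

        def _fn():
            rows = []
            for algorithm, frame in self.fold_frames.items():
                row = {"algorithm": algorithm}
                row.update(asdict(ml.summarize_frame(frame)))
                rows.append(row)
            path = self.outdir / "summary.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            self.outputs["summary"] = str(path)
            return [path]

        self._run_stage("report", {"predict": self.config["predict"]}, _fn, loader=_load)

    # -- entry point -----------------------------------------------------
    def run(self) -> Path:
        self.simulate()
        self.features()
        self.targets()
        self.predict()
        self.report()
        return io.write_manifest(
            self.outdir / "manifest.json",
            self.config,
            self.seed,
            self.outputs,
            stages=self.stages,
        )


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute all stages; returns the manifest path."""
    if not isinstance(config, dict):
        config = load_config(config)
    return PipelineRun(config, outdir).run()
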