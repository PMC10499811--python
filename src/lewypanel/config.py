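"""Run configuration and end-to-end pipeline orchestration.

``run_pipeline`` drives: simulate-or-ingest -> bridging normalization ->
detectability QC -> pairwise contrasts -> UpSet partition -> panel
selection -> evaluation, writing every stage artifact plus a manifest
(inputs, versions, seeds, thresholds) into the run directory.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lewypanel.errors import DataError

log = logging.getLogger("lewypanel")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    # inputs: either file paths or a simulation design
    npx_path: str | None = None
    metadata_path: str | None = None
    design_path: str | None = None      # YAML CohortDesign; None -> default design
    simulate: bool = True

    # contrasts as (group_b, group_a) i.e. B_vs_A with A the reference
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("DLB", "CON"), ("DLB", "AD"), ("AD", "CON")]
    )
    panel_contrast: tuple[str, str] = ("DLB", "AD")

    detectability: float = 0.85
    nominal_alpha: float = 0.05
    q_threshold: float = 0.05
    stability_threshold: float = 0.8

    alpha_grid: list[float] = field(
        default_factory=lambda: [round(a, 1) for a in np.arange(0.1, 1.01, 0.1)]
    )
    cap_grid: list[int] = field(default_factory=lambda: [3, 5, 7, 10, 15, 21])
    n_lambda: int = 100
    ridge_penalty: float = 0.1

    cv_folds: int = 10
    eval_cv_folds: int = 5
    eval_cv_repeats: int = 1000
    bootstrap_resamples: int = 100
    direction_bootstrap: int = 2000

    seed: int = 0
    out_dir: str = "runs/run"

    def validate(self) -> None:
        for name in ("detectability", "nominal_alpha", "q_threshold",
                     "stability_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DataError(f"{name} must lie in (0, 1], got {v}")
        if self.simulate is False and (self.npx_path is None or self.metadata_path is None):
            raise DataError("non-simulation runs need npx_path and metadata_path")
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            raise DataError("alpha_grid values must lie in [0, 1]")
        if any(c < 1 for c in self.cap_grid):
            raise DataError("cap_grid values must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "contrasts" in d:
            d["contrasts"] = [tuple(c) for c in d["contrasts"]]
        if "panel_contrast" in d:
            d["panel_contrast"] = tuple(d["panel_contrast"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["panel_contrast"] = list(self.panel_contrast)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage(name: str):
    """Decorator-free stage timer/halter used inside run_pipeline."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise DataError(f"pipeline halted in stage {name!r}: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)
    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    from lewypanel import cohort as co
    from lewypanel import diff as dd
    from lewypanel import npx as nx
    from lewypanel import upset as us
    from lewypanel import panel as pn
    from lewypanel import evaluate as ev
    import lewypanel

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": lewypanel.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "thresholds": {
            "detectability": config.detectability,
            "nominal_alpha": config.nominal_alpha,
            "q_threshold": config.q_threshold,
            "stability_threshold": config.stability_threshold,
        },
        "grids": {"alpha": list(config.alpha_grid), "cap": list(config.cap_grid)},
        "stages": [],
    }

    with _stage("ingest"):
        if config.simulate:
            design = (
                co.CohortDesign.from_yaml(config.design_path)
                if config.design_path
                else co.default_paper_design()
            )
            m, meta, truth = co.generate_cohort(design, seed=config.seed)
            design.to_yaml(out / "design.yaml")
            truth.to_tsv(out / "truth.tsv")
            manifest["input"] = {"simulated": True, "design": str(out / "design.yaml")}
        else:
            m = nx.read_npx_long(config.npx_path)
            meta = nx.read_sample_metadata(config.metadata_path)
            truth = None
            manifest["input"] = {
                "simulated": False,
                "npx_path": config.npx_path,
                "metadata_path": config.metadata_path,
            }
        nx.write_npx_long(m, out / "npx_raw.csv")
        manifest["stages"].append("ingest")

    with _stage("qc"):
        batches = pd.unique(m.batch)
        if len(batches) > 1:
            bridges = co.bridge_base_ids(m)
            if bridges:
                m = nx.bridge_normalize(m, bridges, reference_batch=str(batches[0]))
        m = co.analysis_samples(m, meta)
        m, dropped = nx.filter_by_detectability(m, config.detectability)
        pd.Series(dropped, name="dropped_assay").to_csv(
            out / "qc_dropped_assays.tsv", sep="\t", index=False
        )
        manifest["qc"] = {"n_assays_kept": m.n_assays, "n_assays_dropped": len(dropped)}
        manifest["stages"].append("qc")

    tables = {}
    with _stage("diff"):
        for group_b, group_a in config.contrasts:
            name = f"{group_b}_vs_{group_a}"
            tab = dd.contrast_table(
                m, meta, group_a, group_b,
                alpha_q=config.q_threshold, alpha_p=config.nominal_alpha,
            )
            tab.to_csv(out / f"contrast_{name}.tsv", sep="\t", index=False,
                       float_format="%.10g")
            tables[name] = tab
        manifest["stages"].append("diff")

    with _stage("upset"):
        needed = {"DLB_vs_CON", "DLB_vs_AD", "AD_vs_CON"}
        if needed <= set(tables):
            part = us.build_partition(
                tables["DLB_vs_CON"], tables["DLB_vs_AD"], tables["AD_vs_CON"]
            )
            part.table.reset_index(names="assay_id").to_csv(
                out / "upset_partition.tsv", sep="\t", index=False
            )
            us.upset_counts(part).to_csv(out / "upset_counts.tsv", sep="\t", index=False)
            us.subset_direction_summary(
                part, tables["DLB_vs_CON"], tables["AD_vs_CON"],
                n_boot=config.direction_bootstrap, seed=config.seed,
            ).to_csv(out / "upset_directions.tsv", sep="\t", index=False)
        manifest["stages"].append("upset")

    with _stage("panel"):
        group_b, group_a = config.panel_contrast
        meta_rows = meta.aligned_to(m)
        mask = meta_rows["diagnosis"].isin([group_a, group_b])
        if "is_bridge" in meta_rows.columns:
            mask &= ~meta_rows["is_bridge"].astype(bool)
        sub = meta_rows.loc[mask]
        X = m.values.loc[sub.index]
        y = (sub["diagnosis"] == group_b).to_numpy(dtype=float)
        cov = dd._covariate_columns(sub)
        candidates = pn.cv_tune(
            X, y, cov,
            alpha_grid=config.alpha_grid, cap_grid=config.cap_grid,
            k=config.cv_folds, seed=config.seed, n_lambda=config.n_lambda,
        )
        grid_tab = pd.DataFrame(
            [
                {"alpha": c.alpha, "cap": c.cap, "lambda": c.lam,
                 "n_markers": c.n_markers, "cv_loglik": c.cv_loglik,
                 "cv_auc": c.cv_auc}
                for c in candidates
            ]
        )
        grid_tab.to_csv(out / "panel_grid.tsv", sep="\t", index=False)
        chosen = pn.choose_model(candidates)
        props = pn.selection_proportions(X, y, cov, chosen,
                                         k=config.cv_folds, seed=config.seed)
        props.rename("selection_proportion").to_csv(
            out / "panel_selection_proportions.tsv", sep="\t"
        )
        stable = props.index[props >= config.stability_threshold].tolist()
        if not stable:
            stable = list(chosen.selected_assays)
        model = pn.ridge_refit(
            X[stable], y, cov, penalty=config.ridge_penalty,
            training_contrast=f"{group_b}_vs_{group_a}", seed=config.seed,
        )
        model.to_json(out / "panel_model.json")
        manifest["panel"] = {
            "contrast": f"{group_b}_vs_{group_a}",
            "chosen_alpha": chosen.alpha, "chosen_lambda": chosen.lam,
            "chosen_cap": chosen.cap, "stable_markers": stable,
        }
        manifest["stages"].append("panel")

    with _stage("evaluate"):
        summary = ev.repeated_cv_auc(
            X[stable], y, cov, ridge_penalty=config.ridge_penalty,
            k=config.eval_cv_folds, repeats=config.eval_cv_repeats,
            seed=config.seed,
        )
        scores = model.linear_predictor(X[stable], cov)
        boot = ev.bootstrap_auc_ci(
            scores, y, B=config.bootstrap_resamples, seed=config.seed
        )
        boot.curve.to_csv(out / "roc_curve_training.tsv", sep="\t", index=False)
        forest = pd.DataFrame(
            [
                {"label": "panel_repeated_cv", **summary.to_dict()},
                {"label": "panel_training_bootstrap", **boot.to_dict()},
            ]
        )
        forest.to_csv(out / "evaluation.tsv", sep="\t", index=False)
        with open(out / "evaluation.json", "w") as fh:
            json.dump(
                {"repeated_cv": summary.to_dict(), "training_bootstrap": boot.to_dict()},
                fh, indent=2,
            )
        manifest["stages"].append("evaluate")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
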