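"""End-to-end study orchestration from a declarative configuration.

A study config (YAML or dict) lists datasets (raw vGRF records or
stride-interval tables), preprocessing and segmentation parameters,
the selection rule, classifier grids and evaluation options; every
default equals the pipeline's standard value (trim 20 s, 10-point
median filter, 100 selection trees, 80% cumulative relevance, beta 1,
K-NN grid 2–10, random-forest grid 10–200 step 10, SVM degree 3).
``run_study`` executes preprocess → segment → features → select →
classify → report per dataset, evaluates the with- and
without-selection arms, and writes CSV/JSON outputs plus a manifest
that suffices to rerun the study exactly.  Dropped cycles and rows are
counted in the manifest; nothing is discarded silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .classify import ClassifierSpec, grid_search, loocv_predict, under_sample
from .evaluation import report_study
from .features import features_table
from .preprocess import PreprocessConfig, preprocess
from .segmentation import SegmentationConfig, segment, stride_table_from_intervals
from .selection import rank_features, select_features
from .types import ExclusionIntervals, FeatureTable, ValidationError

__all__ = ["load_config", "default_classifier_specs", "run_study"]

DEFAULT_GRIDS = {
    "knn": {"k": list(range(2, 11))},
    "rf": {"n_trees": list(range(10, 201, 10))},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "datasets" not in cfg:
        raise ValidationError("study config must be a mapping with a 'datasets' list")
    return cfg


def default_classifier_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [
        ClassifierSpec("knn", grid=dict(DEFAULT_GRIDS["knn"]), seed=seed),
        ClassifierSpec("cart", seed=seed),
        ClassifierSpec("rf", grid=dict(DEFAULT_GRIDS["rf"]), seed=seed),
        ClassifierSpec("nb", seed=seed),
        ClassifierSpec("svm", params={"kernel": "poly", "degree": 3, "C": 1.0}, seed=seed),
        ClassifierSpec("kmeans", seed=seed),
        ClassifierSpec("gmm", params={"covariance": "full"}, seed=seed),
    ]


def _specs_from_config(cfg: dict, seed: int) -> list[ClassifierSpec]:
    entries = cfg.get("classifiers")
    if not entries:
        return default_classifier_specs(seed)
    specs = []
    for e in entries:
        specs.append(ClassifierSpec(
            name=e["name"],
            params=dict(e.get("params", {})),
            grid={k: list(v) for k, v in e.get("grid", {}).items()} or None,
            seed=int(e.get("seed", seed)),
        ))
    return specs


def _dataset_features(ds: dict, cfg: dict) -> tuple[FeatureTable, dict]:
    """Run ingestion → preprocessing → segmentation → feature
    extraction for one dataset entry; returns the table and stage
    counters for the manifest."""
    pp = PreprocessConfig(**cfg.get("preprocess", {}))
    seg_cfg = SegmentationConfig(**cfg.get("segmentation", {}))
    info: dict = {"n_records": 0, "n_dropped_cycles": 0}
    kind = ds.get("kind", "vgrf")
    if kind == "intervals":
        tables = stride_table_from_intervals(gio.read_stride_intervals(ds["path"]))
    elif kind == "vgrf":
        tables = []
        for rec_entry in ds["records"]:
            rec = gio.read_vgrf(
                rec_entry["path"],
                fs=float(rec_entry.get("fs", 100.0)),
                subject_id=rec_entry.get("subject_id"),
                label=rec_entry.get("label", "healthy"),
            )
            excl = rec_entry.get("exclusions")
            cfg_rec = PreprocessConfig(
                trim_seconds=pp.trim_seconds, median_window=pp.median_window,
                exclusion=gio.read_exclusion_intervals(excl) if excl else None,
            )
            st = segment(preprocess(rec, cfg_rec), seg_cfg)
            info["n_dropped_cycles"] += st.n_dropped_cycles
            tables.append(st)
    else:
        raise ValidationError(f"unknown dataset kind {kind!r}")
    info["n_records"] = len(tables)
    table = features_table(tables, ga_mode=cfg.get("ga_mode", "mean_of_cycles"))
    return table, info


def run_study(cfg: dict | str | Path, out_dir: str | Path,
              tables: dict[str, FeatureTable] | None = None) -> dict:
    """Execute the full study and write the report bundle.

    ``tables`` optionally supplies pre-built feature tables keyed by
    dataset name (e.g. synthetic cohorts), bypassing file ingestion for
    the matching datasets.
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    sel_cfg = cfg.get("selection", {})
    ev_cfg = cfg.get("evaluation", {})
    positive_class = ev_cfg.get("positive_class", "PD")
    beta = float(ev_cfg.get("beta", 1.0))
    grouping = cfg.get("grouping", "record")
    nested = bool(sel_cfg.get("nested", False))

    manifest: dict = {"seed": seed, "datasets": {}, "classifiers": {}}
    selected_rows = []
    with_sel: dict[str, dict] = {}
    without_sel: dict[str, dict] = {}

    for ds in cfg["datasets"]:
        name = ds["name"]
        if tables and name in tables:
            table, info = tables[name], {"n_records": len(tables[name]), "source": "in-memory"}
        else:
            table, info = _dataset_features(ds, cfg)
        if cfg.get("under_sample", False):
            table = under_sample(table, seed=seed)
            info["n_after_undersample"] = len(table)
        manifest["datasets"][name] = info

        ranking = rank_features(table, n_trees=int(sel_cfg.get("n_trees", 100)), seed=seed)
        selected = select_features(
            ranking,
            cum_threshold=float(sel_cfg.get("cum_threshold", 0.80)),
            fixed_k=sel_cfg.get("fixed_k"),
        )
        for fid, rel, cum in zip(ranking.feature_ids, ranking.relevance, ranking.cumulative):
            selected_rows.append({"dataset": name, "feature": fid,
                                  "relevance": rel, "cumulative": cum,
                                  "selected": fid in selected})

        def _nested_selector(train_table: FeatureTable):
            r = rank_features(train_table, n_trees=int(sel_cfg.get("n_trees", 100)), seed=seed)
            return select_features(r, cum_threshold=float(sel_cfg.get("cum_threshold", 0.80)),
                                   fixed_k=sel_cfg.get("fixed_k"))

        with_sel[name], without_sel[name] = {}, {}
        for spec in _specs_from_config(cfg, seed):
            try:
                if spec.grid:
                    resolved, _ = grid_search(table, spec, features=selected, grouping=grouping)
                else:
                    resolved = spec
                kwargs = {"grouping": grouping}
                if nested:
                    preds = loocv_predict(table, resolved, feature_selector=_nested_selector,
                                          **kwargs)
                else:
                    preds = loocv_predict(table, resolved, features=selected, **kwargs)
                with_sel[name][spec.name] = preds
                without_sel[name][spec.name] = loocv_predict(table, resolved, **kwargs)
                manifest["classifiers"].setdefault(name, {})[spec.name] = resolved.params
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'classify' failed on dataset {name!r}, model {spec.name!r}: {exc}"
                ) from exc

    report = report_study(with_sel, positive_class, beta=beta, baseline=without_sel)
    report["selection"] = pd.DataFrame(selected_rows)
    for key, df in report.items():
        df.to_csv(out / f"{key}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
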