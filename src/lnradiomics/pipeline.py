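"""End-to-end study replica: simulate -> extract -> select -> train -> evaluate.

The pipeline reproduces the study protocol on a synthetic cohort: an 80/20
class-stratified split, a clinical long-axis > 10 mm rule, a demographic
kernel SVM on the exhaustive-search-selected covariate subset, a radiomic
kernel SVM on LASSO-selected texture features, per-cohort Table-2-style
metrics (accuracy / sensitivity / specificity / AUC with 95% CI) and paired
DeLong comparisons between the three models.  Every stage is seeded and the
run manifest makes a run bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import evaluation as ev
from .features.registry import (
    assemble_feature_vector,
    read_feature_table,
    write_feature_table,
    write_registry_json,
)
from .models import (
    TrainedModel,
    encode_demographics,
    exhaustive_search_select,
    lasso_cv_select,
    stratified_split,
    train_svm,
)
from .synthetic import CohortConfig, generate_cohort
from .types import CaseRecord

__all__ = ["RunConfig", "StudyData", "run_pipeline", "run_study",
           "extract_features", "demographics_of"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    n_normal: int = 196
    n_metastatic: int = 194
    cohort_seed: int = 0
    split_seed: int = 0
    cv_seed: int = 0
    train_fraction: float = 0.8
    n_folds: int = 10
    kernel: str = "rbf"
    n_levels: int = 8
    out_dir: str = "results/run"
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        unknown = set(doc) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if self.n_normal + self.n_metastatic <= 0:
            raise ValueError("cohort is empty")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class StudyData:
    """In-memory bundle consumed by the modeling stages."""

    case_ids: list[str]
    labels: np.ndarray
    X: np.ndarray  # n_cases x 146 texture features
    feature_names: tuple[str, ...]
    demographics: list[dict]  # per-case records incl. axes and label


def demographics_of(case: CaseRecord) -> dict:
    return {
        "case_id": case.case_id,
        "age": case.age,
        "gender": case.gender,
        "tumor_location": case.tumor_location,
        "histological_grade": case.histological_grade,
        "short_axis": case.short_axis,
        "long_axis": case.long_axis,
        "label": case.label,
    }


def extract_features(cases: list[CaseRecord], n_levels: int = 8) -> StudyData:
    """Run the 146-feature extractor over a cohort."""
    rows = []
    for c in cases:
        rows.append(assemble_feature_vector(c, n_levels=n_levels))
    names = tuple(rows[0]) if rows else ()
    X = np.array([[r[n] for n in names] for r in rows], dtype=float)
    return StudyData(
        case_ids=[c.case_id for c in cases],
        labels=np.array([c.label for c in cases], dtype=int),
        X=X,
        feature_names=names,
        demographics=[demographics_of(c) for c in cases],
    )


def _subset(data: StudyData, ids: list[str]) -> dict:
    pos = {cid: i for i, cid in enumerate(data.case_ids)}
    idx = [pos[i] for i in ids]
    return {
        "idx": idx,
        "labels": data.labels[idx],
        "X": data.X[idx],
        "demo": [data.demographics[i] for i in idx],
        "long_axis": np.array([data.demographics[i]["long_axis"] for i in idx]),
    }


def run_study(data: StudyData, config: RunConfig,
              which=("clinical", "demographic", "radiomic")) -> dict:
    """Select, train and evaluate the study models on pre-extracted features.

    ``which`` restricts the models fitted (the clinical rule is always
    evaluated); the demographic model is the expensive one because of its
    exhaustive 63-subset search.
    """
    config.validate()
    split = stratified_split(data.case_ids, data.labels, config.train_fraction,
                             config.split_seed)
    tr = _subset(data, split.train_ids)
    te = _subset(data, split.test_ids)

    # --- radiomic signature: LASSO at the CV-MSE minimum -------------------
    path = lasso_cv_select(tr["X"], tr["labels"], data.feature_names,
                           n_folds=config.n_folds, seed=config.cv_seed)
    selected = list(path.selected_features)
    if not selected:
        # degenerate null path: fall back to the first feature entering the
        # regularization path (largest lambda with a nonzero coefficient)
        dfpos = np.flatnonzero(path.df > 0)
        j = int(np.flatnonzero(path.coefficients[dfpos[0]])[0]) if dfpos.size else 0
        selected = [path.feature_names[j]]
    col = {n: j for j, n in enumerate(data.feature_names)}
    sel_idx = [col[n] for n in selected]

    radiomic = train_svm(tr["X"][:, sel_idx], tr["labels"], selected,
                         kernel=config.kernel, n_folds=config.n_folds,
                         seed=config.cv_seed, kind="radiomic_svm")

    # --- demographic model: exhaustive subset search ------------------------
    inputs = {
        "clinical": {"train": tr["long_axis"], "test": te["long_axis"]},
        "radiomic": {"train": tr["X"][:, sel_idx], "test": te["X"][:, sel_idx]},
    }
    clinical = TrainedModel(kind="clinical_threshold", feature_names=("long_axis",),
                            threshold_mm=10.0, seed=config.split_seed)
    models = {"clinical": clinical, "radiomic": radiomic}
    demo_subset, demo_table = (), {}
    if "demographic" in which:
        Xd_tr, demo_names = encode_demographics(tr["demo"])
        Xd_te, _ = encode_demographics(te["demo"])
        demo_subset, demo_table = exhaustive_search_select(
            Xd_tr, tr["labels"], demo_names, n_folds=config.n_folds,
            seed=config.cv_seed, kernel=config.kernel)
        didx = [demo_names.index(n) for n in demo_subset]
        models["demographic"] = train_svm(
            Xd_tr[:, didx], tr["labels"], demo_subset, kernel=config.kernel,
            n_folds=config.n_folds, seed=config.cv_seed, kind="demographic_svm")
        inputs["demographic"] = {"train": Xd_tr[:, didx], "test": Xd_te[:, didx]}
    metrics: dict = {}
    scores: dict = {}
    for mname, model in models.items():
        metrics[mname] = {}
        scores[mname] = {}
        for cohort in ("train", "test"):
            Xc = inputs[mname][cohort]
            y = tr["labels"] if cohort == "train" else te["labels"]
            pred = model.predict(Xc)
            sc = model.decision_scores(Xc)
            counts = ev.counts_from_predictions(y, pred, cohort)
            m = ev.confusion_metrics(counts)
            auc = ev.roc_auc(sc, y)
            metrics[mname][cohort] = {
                "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
                "accuracy": m["accuracy"], "sensitivity": m["sensitivity"],
                "specificity": m["specificity"],
                "auc": round(auc.auc, 4),
                "auc_ci95": [round(auc.ci95[0], 4), round(auc.ci95[1], 4)],
            }
            scores[mname][cohort] = sc
    comparisons: dict = {}
    pairs = [(a, b) for a, b in (("radiomic", "clinical"),
                                 ("radiomic", "demographic"),
                                 ("demographic", "clinical"))
             if a in models and b in models]
    for a, b in pairs:
        comparisons[f"{a}_vs_{b}"] = {}
        for cohort in ("train", "test"):
            y = tr["labels"] if cohort == "train" else te["labels"]
            r = ev.delong_paired_test(scores[a][cohort], scores[b][cohort], y)
            comparisons[f"{a}_vs_{b}"][cohort] = {
                "delta_auc": round(r.delta_auc, 4), "z": round(r.z, 4),
                "p": round(r.p_value, 6), "degenerate": r.degenerate,
            }

    return {
        "split": {"train_ids": split.train_ids, "test_ids": split.test_ids,
                  "seed": split.seed,
                  "counts": split.counts(dict(zip(data.case_ids,
                                                  data.labels.tolist())))},
        "lasso": {
            "selected_lambda": path.selected_lambda,
            "selected_features": list(path.selected_features),
            "used_features": selected,
            "n_lambdas": int(path.lambdas.size),
            "cv_mse_min": float(path.cv_mse.min()),
            "df_at_min": int(path.df[int(np.argmin(path.cv_mse))]),
        },
        "demographic_search": ({
            "selected": list(demo_subset),
            "cv_error": demo_table[demo_subset],
        } if demo_subset else None),
        "metrics": metrics,
        "comparisons": comparisons,
        "_models": models,
        "_scores": scores,
        "_lasso_path": path,
    }


def replicate_model_ranking(seed: int, n_normal: int = 196, n_metastatic: int = 194,
                            include_demographic: bool = False) -> dict:
    """One seeded study replicate; returns the per-model test AUCs.

    Used to estimate how often the radiomic signature out-ranks the clinical
    size rule across independently generated cohorts.
    """
    cases = generate_cohort(CohortConfig(n_normal, n_metastatic, seed=seed))
    data = extract_features(cases)
    which = ("clinical", "radiomic") + (("demographic",) if include_demographic else ())
    cfg = RunConfig(n_normal=n_normal, n_metastatic=n_metastatic,
                    cohort_seed=seed, split_seed=seed, cv_seed=seed)
    rep = run_study(data, cfg, which=which)
    out = {m: rep["metrics"][m]["test"]["auc"] for m in rep["metrics"]}
    out["_report"] = rep
    return out


def _json_sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _json_sanitize(v) for k, v in obj.items()
                if not (isinstance(k, str) and k.startswith("_"))}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Full study replica; writes every artifact under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = CohortConfig(config.n_normal, config.n_metastatic,
                              seed=config.cohort_seed)
    cases = generate_cohort(cohort_cfg)
    data = extract_features(cases, n_levels=config.n_levels)

    write_feature_table(
        [(cid, int(lab), feats) for cid, lab, feats in
         zip(data.case_ids, data.labels,
             ({n: x for n, x in zip(data.feature_names, row)} for row in data.X))],
        out / "features.csv")
    write_registry_json(out / "feature_registry.json")

    report = run_study(data, config)

    path = report["_lasso_path"]
    with open(out / "lasso_path.json", "w") as fh:
        json.dump(_json_sanitize({
            "lambdas": path.lambdas, "cv_mse": path.cv_mse,
            "cv_mse_se": path.cv_mse_se, "df": path.df,
            "selected_lambda": path.selected_lambda,
            "selected_features": path.selected_features,
        }), fh, indent=1, sort_keys=True)

    (out / "models").mkdir(exist_ok=True)
    for name, model in report["_models"].items():
        model.save(out / "models" / f"{name}.json")

    # ROC curve exports
    split_ids = report["split"]
    lab_by_id = dict(zip(data.case_ids, data.labels.tolist()))
    for mname, sc in report["_scores"].items():
        for cohort in ("train", "test"):
            ids = split_ids[f"{cohort}_ids"]
            y = np.array([lab_by_id[i] for i in ids])
            pts = ev.roc_curve_points(sc[cohort], y)
            np.savetxt(out / f"roc_{mname}_{cohort}.csv", pts, delimiter=",",
                       header="fpr,tpr", comments="")

    with open(out / "metrics.json", "w") as fh:
        json.dump(_json_sanitize(report["metrics"]), fh, indent=1, sort_keys=True)
    with open(out / "delong.json", "w") as fh:
        json.dump(_json_sanitize(report["comparisons"]), fh, indent=1, sort_keys=True)
    _write_table2_csv(report["metrics"], out / "table2.csv")

    from . import __version__

    with open(out / "manifest.json", "w") as fh:
        json.dump(_json_sanitize({"config": asdict(config),
                                  "version": __version__}), fh,
                  indent=1, sort_keys=True)
    return report


def _write_table2_csv(metrics: dict, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "cohort", "accuracy", "sensitivity", "specificity",
                    "auc", "auc_ci_low", "auc_ci_high"])
        for model in ("clinical", "demographic", "radiomic"):
            for cohort in ("train", "test"):
                m = metrics[model][cohort]
                w.writerow([model, cohort, m["accuracy"], m["sensitivity"],
                            m["specificity"], m["auc"], m["auc_ci95"][0],
                            m["auc_ci95"][1]])
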