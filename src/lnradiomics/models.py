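"""The three study classifiers and their selection protocols.

* **Clinical model** — the size rule: a node with long-axis diameter
  strictly greater than 10 mm is called metastatic.
* **Patient-demographic model** — a kernel SVM on the demographic subset
  (age, gender, histological grade, tumor location, short- and long-axis
  diameters) whose 10-fold cross-validation error is lowest under
  exhaustive enumeration of all non-empty subsets.
* **Radiomic model** — a kernel SVM on the texture features selected by a
  LASSO regression of the 0/1 label (squared-error loss) with the penalty
  chosen at the minimum of the 10-fold cross-validation MSE.

All cross-validation folds are stratified by class and seeded; the test
cohort never influences any fitted parameter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "LassoPath",
    "TrainedModel",
    "stratified_split",
    "clinical_classify",
    "lasso_cv_select",
    "exhaustive_search_select",
    "train_svm",
    "encode_demographics",
    "DEMOGRAPHIC_CANDIDATES",
]

DEMOGRAPHIC_CANDIDATES = ("age", "gender", "grade", "location",
                          "short_axis", "long_axis")


# ---------------------------------------------------------------------------
# split


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    seed: int

    def counts(self, labels_by_id: dict) -> dict:
        tr = [labels_by_id[i] for i in self.train_ids]
        te = [labels_by_id[i] for i in self.test_ids]
        return {"train": {0: tr.count(0), 1: tr.count(1)},
                "test": {0: te.count(0), 1: te.count(1)}}


def stratified_split(case_ids, labels, train_fraction: float = 0.8,
                     seed: int = 0) -> SplitPlan:
    """Class-stratified random split, reproducible under seed.

    Per-class training counts are ``round(n_class * fraction)``, so class
    proportions are preserved to within one case.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    case_ids = list(case_ids)
    labels = np.asarray(labels)
    if len(case_ids) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.tolist())):
        members = [cid for cid, lab in zip(case_ids, labels) if lab == cls]
        if not members:
            raise ValueError(f"class {cls} has no members")
        n_train = int(round(len(members) * train_fraction))
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
    return SplitPlan(train, test, seed)


# ---------------------------------------------------------------------------
# clinical size rule


def clinical_classify(long_axis) -> np.ndarray | int:
    """Size rule: metastatic iff long-axis diameter > 10 mm (strict)."""
    arr = np.asarray(long_axis, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("long-axis diameter must be positive")
    out = (arr > 10.0).astype(int)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# LASSO selection


@dataclass
class LassoPath:
    """LASSO regularization path with per-penalty 10-fold CV error."""

    lambdas: np.ndarray  # descending
    coefficients: np.ndarray  # n_lambdas x n_features (standardized scale)
    cv_mse: np.ndarray  # mean over folds per lambda
    cv_mse_se: np.ndarray  # standard error over folds
    df: np.ndarray  # nonzero-coefficient count per lambda
    selected_lambda: float
    selected_features: list[str]
    feature_names: tuple[str, ...]
    dropped_constant: list[str] = field(default_factory=list)


def lasso_cv_select(X, y, feature_names=None, n_folds: int = 10, seed: int = 0,
                    n_lambdas: int = 100, eps: float = 1e-3,
                    lambda_rule: str = "min") -> LassoPath:
    """LASSO regression of the 0/1 label with CV-minimizing penalty.

    Features are standardized internally; the penalty grid is geometric from
    the smallest lambda that zeroes every coefficient down by a factor
    ``eps``.  The selected features are the variables with nonzero weight at
    the lambda minimizing the mean cross-validation MSE (``lambda_rule=
    "min"``, the default) or at the largest lambda within one standard error
    of that minimum (``"1se"``, sparser).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    feature_names = tuple(feature_names)
    if np.all(y == y[0]):
        raise ValueError("labels are constant: nothing to regress")
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [n for n, k in zip(feature_names, keep) if not k]
    if dropped:
        import warnings

        warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
    X = X[:, keep]
    names = tuple(n for n, k in zip(feature_names, keep) if k)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    yc = y - y.mean()

    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    lambdas = lam_max * np.logspace(0, np.log10(eps), n_lambdas)

    import warnings

    from sklearn.exceptions import ConvergenceWarning

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_mse = np.zeros((n_folds, n_lambdas))
    with warnings.catch_warnings():
        # the smallest-lambda tail of the path may stop at max_iter; the
        # selection happens far from it and is unaffected
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, te) in enumerate(cv.split(Xs, y.astype(int))):
            mu, s = X[tr].mean(axis=0), X[tr].std(axis=0)
            s[s == 0] = 1.0
            Xtr = (X[tr] - mu) / s
            Xte = (X[te] - mu) / s
            ybar = y[tr].mean()
            _, coefs, _ = lasso_path(Xtr, y[tr] - ybar, alphas=lambdas)
            pred = Xte @ coefs + ybar  # n_te x n_lambdas
            fold_mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)

        cv_mse = fold_mse.mean(axis=0)
        cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
        _, coefs_full, _ = lasso_path(Xs, yc, alphas=lambdas)
    coefs_full = coefs_full.T  # n_lambdas x n_features
    df = (coefs_full != 0).sum(axis=1)
    best = int(np.argmin(cv_mse))
    if lambda_rule == "1se":
        limit = cv_mse[best] + cv_se[best]
        best = int(np.flatnonzero(cv_mse <= limit)[0])  # lambdas descend
    elif lambda_rule != "min":
        raise ValueError("lambda_rule must be 'min' or '1se'")
    sel = [names[j] for j in np.flatnonzero(coefs_full[best])]
    return LassoPath(lambdas, coefs_full, cv_mse, cv_se, df,
                     float(lambdas[best]), sel, names, dropped)


# ---------------------------------------------------------------------------
# SVM training


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it."""

    kind: str  # clinical_threshold | demographic_svm | radiomic_svm
    feature_names: tuple[str, ...]
    threshold_mm: float | None = None
    pipeline: Pipeline | None = None
    hyperparameters: dict = field(default_factory=dict)
    cv_error: float | None = None
    seed: int = 0

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores (higher = more metastatic) for ROC analysis."""
        if self.kind == "clinical_threshold":
            return np.asarray(X, dtype=float).ravel()  # the diameter itself
        return self.pipeline.decision_function(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        if self.kind == "clinical_threshold":
            return clinical_classify(np.asarray(X, dtype=float).ravel())
        return self.pipeline.predict(np.asarray(X, dtype=float)).astype(int)

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> dict:
        doc = {"version": 1, "kind": self.kind,
               "feature_names": list(self.feature_names),
               "hyperparameters": self.hyperparameters, "seed": self.seed,
               "cv_error": self.cv_error}
        if self.kind == "clinical_threshold":
            doc["threshold_mm"] = self.threshold_mm
            return doc
        scaler: StandardScaler = self.pipeline.named_steps["scaler"]
        svc: SVC = self.pipeline.named_steps["svc"]
        doc["standardization"] = {"mean": scaler.mean_.tolist(),
                                  "sd": scaler.scale_.tolist()}
        doc["svm"] = {
            "kernel": svc.kernel,
            "gamma": float(svc._gamma) if svc.kernel == "rbf" else None,
            "C": float(svc.C),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
            "classes": svc.classes_.tolist(),
        }
        return doc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, doc: dict) -> "TrainedModel":
        if doc["kind"] == "clinical_threshold":
            return cls(kind="clinical_threshold",
                       feature_names=tuple(doc["feature_names"]),
                       threshold_mm=doc["threshold_mm"], seed=doc.get("seed", 0))
        return _SerializedSVM(doc)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


class _SerializedSVM(TrainedModel):
    """SVM decision function reconstructed from its JSON document."""

    def __init__(self, doc: dict):
        super().__init__(kind=doc["kind"], feature_names=tuple(doc["feature_names"]),
                         hyperparameters=doc.get("hyperparameters", {}),
                         seed=doc.get("seed", 0), cv_error=doc.get("cv_error"))
        self._mu = np.asarray(doc["standardization"]["mean"])
        self._sd = np.asarray(doc["standardization"]["sd"])
        svm = doc["svm"]
        self._kernel = svm["kernel"]
        self._gamma = svm["gamma"]
        self._sv = np.asarray(svm["support_vectors"])
        self._dual = np.asarray(svm["dual_coef"]).ravel()
        self._b = float(svm["intercept"][0])
        self._classes = np.asarray(svm["classes"])

    def decision_scores(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        if self._kernel == "rbf":
            d2 = ((Z[:, None, :] - self._sv[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-self._gamma * d2)
        else:
            K = Z @ self._sv.T
        return K @ self._dual + self._b

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_scores(X) > 0, self._classes[1],
                        self._classes[0]).astype(int)


_DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
_DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.1, 1.0)


def train_svm(X, y, feature_names=None, kernel: str = "rbf", n_folds: int = 10,
              seed: int = 0, c_grid=_DEFAULT_C_GRID, gamma_grid=_DEFAULT_GAMMA_GRID,
              kind: str = "radiomic_svm") -> TrainedModel:
    """Kernel SVM with grid-searched hyperparameters under stratified CV.

    Features are standardized by the training-set mean/SD inside the
    pipeline (so CV folds re-standardize on their own training part), the
    (C, gamma) pair minimizing 10-fold CV error is chosen, and the final
    model is refit on the full training set.  Decision scores are exposed
    for ROC analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel=kernel))])
    grid = {"svc__C": list(c_grid)}
    if kernel == "rbf":
        grid["svc__gamma"] = list(gamma_grid)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", n_jobs=None)
    search.fit(X, y)
    return TrainedModel(kind=kind, feature_names=tuple(feature_names),
                        pipeline=search.best_estimator_,
                        hyperparameters={k.removeprefix("svc__"): v
                                         for k, v in search.best_params_.items()},
                        cv_error=float(1.0 - search.best_score_), seed=seed)


# ---------------------------------------------------------------------------
# exhaustive demographic subset search


def encode_demographics(records: list[dict]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Numeric design matrix for the six demographic candidates.

    Binary categoricals are 0/1 encoded (gender: M=1, grade: poor=1,
    location: right=1); continuous variables pass through.
    """
    cols = {
        "age": [r["age"] for r in records],
        "gender": [1.0 if r["gender"] == "M" else 0.0 for r in records],
        "grade": [1.0 if r["histological_grade"] == "poor" else 0.0 for r in records],
        "location": [1.0 if r["tumor_location"] == "right" else 0.0 for r in records],
        "short_axis": [r["short_axis"] for r in records],
        "long_axis": [r["long_axis"] for r in records],
    }
    X = np.column_stack([cols[k] for k in DEMOGRAPHIC_CANDIDATES])
    return X, DEMOGRAPHIC_CANDIDATES


def exhaustive_search_select(X, y, candidate_names, n_folds: int = 10,
                             seed: int = 0, kernel: str = "rbf",
                             c_grid=(1.0,), gamma_grid=("scale",)) -> tuple[tuple[str, ...], dict]:
    """Best demographic subset by exhaustive 10-fold CV enumeration.

    Every non-empty subset of the candidates is scored by the stratified CV
    error of a kernel SVM restricted to it.  Ties break to the smaller
    subset, then to lexicographic name order.  Returns the winning subset
    and a per-subset CV-error table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    candidate_names = tuple(candidate_names)
    if not candidate_names:
        raise ValueError("no candidate features")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results: dict[tuple[str, ...], float] = {}
    idx = {n: j for j, n in enumerate(candidate_names)}
    for r in range(1, len(candidate_names) + 1):
        for subset in itertools.combinations(candidate_names, r):
            Xs = X[:, [idx[n] for n in subset]]
            best_err = np.inf
            for C in c_grid:
                for g in gamma_grid:
                    pipe = Pipeline([
                        ("scaler", StandardScaler()),
                        ("svc", SVC(kernel=kernel, C=C,
                                    **({"gamma": g} if kernel == "rbf" else {}))),
                    ])
                    acc = cross_val_score(pipe, Xs, y, cv=cv, scoring="accuracy").mean()
                    best_err = min(best_err, 1.0 - acc)
            results[subset] = float(best_err)
    winner = min(results, key=lambda s: (results[s], len(s), s))
    return winner, results
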