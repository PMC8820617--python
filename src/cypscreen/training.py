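"""Feature selection and RF / SVM-RBF model training.

Feature selection follows the repeated-forest importance protocol: after a
grid scan over the forest size (*ntree*, 25-500) and the per-node feature
draw (*mtry*, up to floor(sqrt(p))) under 10-fold cross-validation repeated
5 times, many independently seeded forests are grown at the winning
hyperparameters and the mean decrease in Gini impurity is averaged over the
runs.  Descriptors are then taken by rank or by an importance threshold.

Models are a random forest (majority vote over bootstrapped trees) and an
RBF-kernel support vector machine with the cost parameter scanned over
2^-2..2^7; the SVM consumes standardized descriptors, whose scaling
parameters travel inside the model bundle.  All cross-validation folding is
stratified and seeded, and the same folds are reused across every
hyperparameter point of a scan so comparisons are paired.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .curation import INHIBITOR, NON_INHIBITOR
from .descriptors import DescriptorMatrix, ScalingParams
from .errors import BundleError, CypscreenError

BUNDLE_SCHEMA_VERSION = 1
DEFAULT_NTREE_GRID = (25, 50, 100, 200, 300, 400, 500)
DEFAULT_COST_EXPONENTS = range(-2, 8)  # cost = 2^k, k in [-2, 7]
DEFAULT_SIGMA_MULTIPLIERS = (0.5, 1.0, 2.0)
DEFAULT_IMPORTANCE_RUNS = 2000


def mtry_upper_bound(p: int) -> int:
    """floor(sqrt(p)) clamped to >= 1 — the conventional ceiling for the
    per-node feature draw of a random forest."""
    if p < 1:
        raise ValueError(f"descriptor count must be >= 1, got {p}")
    return max(1, int(np.floor(np.sqrt(p))))


@dataclass
class HyperGrid:
    """Hyperparameter grids for both algorithms."""

    ntree: tuple[int, ...] = DEFAULT_NTREE_GRID
    mtry: tuple[int, ...] | None = None  # None -> derived from p at scan time
    costs: tuple[float, ...] = tuple(2.0**k for k in DEFAULT_COST_EXPONENTS)
    sigma_multipliers: tuple[float, ...] = DEFAULT_SIGMA_MULTIPLIERS

    def mtry_for(self, p: int) -> tuple[int, ...]:
        if self.mtry is not None:
            return self.mtry
        hi = mtry_upper_bound(p)
        lo = min(5, hi)
        return tuple(range(lo, hi + 1))


@dataclass
class CVResult:
    """Per-grid-point cross-validation accuracies and the winning point."""

    entries: list[dict]
    winner: dict
    n_splits: int
    n_repeats: int
    seed: int


@dataclass
class ImportanceProfile:
    """Mean decrease in Gini impurity per descriptor, averaged over runs."""

    importances: pd.Series
    n_runs: int
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if (self.importances < 0).any():
            raise ValueError("Gini importances must be non-negative")


@dataclass
class ModelBundle:
    """A fitted classifier with everything needed to reapply it."""

    algorithm: str  # "rf" | "svm_rbf"
    model: object
    hyperparameters: dict
    feature_names: list[str]
    scaling: ScalingParams | None
    calibrator: object | None
    training_fingerprint: str
    seed: int
    schema_version: int = BUNDLE_SCHEMA_VERSION


# ---------------------------------------------------------------------------
# helpers


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, DescriptorMatrix) else pd.DataFrame(matrix)


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray([1 if l == INHIBITOR else 0 if l == NON_INHIBITOR else -1 for l in labels])
    if (y == -1).any():
        bad = sorted({l for l in labels if l not in (INHIBITOR, NON_INHIBITOR)})
        raise CypscreenError(f"labels must be binary inhibitor/non_inhibitor; got {bad}")
    return y


def _folds(y: np.ndarray, n_splits: int, n_repeats: int, seed: int):
    """Stratified folds, repeat r seeded with seed + r; shared across all
    grid points of one scan so accuracy comparisons are paired."""
    if len(np.unique(y)) < 2:
        raise CypscreenError("stratified folding requires both classes present")
    folds = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + rep)
        folds.extend(skf.split(np.zeros(len(y)), y))
    return folds


def _cv_accuracy(make_model, X: np.ndarray, y: np.ndarray, folds) -> tuple[float, float, list]:
    accs = []
    for train_idx, test_idx in folds:
        model = make_model()
        model.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs)), float(np.std(accs, ddof=1)), accs


def _fingerprint(X: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(float)).tobytes())
    h.update(y.tobytes())
    h.update(",".join(X.columns).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# hyperparameter scans


def scan_rf_hyperparams(
    matrix,
    labels,
    grid: HyperGrid | None = None,
    cv: tuple[int, int] = (10, 5),
    seed: int = 2022,
) -> CVResult:
    """Scan (ntree, mtry) by repeated stratified CV accuracy.

    The winner is the highest mean accuracy; ties prefer the smaller ntree
    (cheaper forest), then the smaller mtry.
    """
    grid = grid or HyperGrid()
    X_df = _as_frame(matrix)
    y = _encode_labels(labels)
    X = X_df.to_numpy(float)
    folds = _folds(y, cv[0], cv[1], seed)
    entries = []
    for ntree in grid.ntree:
        for mtry in grid.mtry_for(X.shape[1]):
            mean, sd, accs = _cv_accuracy(
                lambda: RandomForestClassifier(
                    n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
                ),
                X,
                y,
                folds,
            )
            entries.append(
                {"ntree": ntree, "mtry": mtry, "mean_accuracy": mean, "sd_accuracy": sd}
            )
    winner = max(entries, key=lambda e: (e["mean_accuracy"], -e["ntree"], -e["mtry"]))
    return CVResult(entries=entries, winner=dict(winner), n_splits=cv[0], n_repeats=cv[1], seed=seed)


def mean_gini_importance(
    matrix,
    labels,
    params: dict | None = None,
    n_runs: int = DEFAULT_IMPORTANCE_RUNS,
    seed: int = 2022,
) -> ImportanceProfile:
    """Average the mean-decrease-Gini importances of ``n_runs``
    independently seeded forests (run r uses seed + r)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X_df = _as_frame(matrix)
    y = _encode_labels(labels)
    X = X_df.to_numpy(float)
    params = dict(params or {})
    ntree = int(params.get("ntree", 100))
    mtry = int(params.get("mtry", mtry_upper_bound(X.shape[1])))
    total = np.zeros(X.shape[1])
    for r in range(n_runs):
        forest = RandomForestClassifier(
            n_estimators=ntree, max_features=mtry, random_state=seed + r, n_jobs=1
        )
        forest.fit(X, y)
        total += forest.feature_importances_
    imp = pd.Series(total / n_runs, index=X_df.columns)
    return ImportanceProfile(
        importances=imp, n_runs=n_runs, params={"ntree": ntree, "mtry": mtry}, seed=seed
    )


def select_descriptors(
    profile: ImportanceProfile,
    top_k: int | None = None,
    above_threshold: float | None = None,
) -> list[str]:
    """Descriptor names by descending mean importance (ties alphabetical).

    Exactly one of ``top_k`` / ``above_threshold`` selects the cut.
    """
    if (top_k is None) == (above_threshold is None):
        raise ValueError("specify exactly one of top_k or above_threshold")
    imp = profile.importances
    ordered = sorted(imp.index, key=lambda c: (-imp[c], c))
    if top_k is not None:
        if top_k > len(ordered):
            raise ValueError(f"top_k={top_k} exceeds descriptor count {len(ordered)}")
        return ordered[:top_k]
    return [c for c in ordered if imp[c] > above_threshold]


# ---------------------------------------------------------------------------
# training


def train_rf(
    matrix,
    labels,
    grid: HyperGrid | None = None,
    cv: tuple[int, int] = (10, 5),
    seed: int = 2022,
) -> tuple[ModelBundle, CVResult]:
    """Scan the RF grid, then refit on the full training set at the winner."""
    X_df = _as_frame(matrix)
    if X_df.shape[1] < 2:
        raise CypscreenError("need at least 2 descriptors to train")
    result = scan_rf_hyperparams(matrix, labels, grid, cv, seed)
    y = _encode_labels(labels)
    model = RandomForestClassifier(
        n_estimators=result.winner["ntree"],
        max_features=result.winner["mtry"],
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X_df.to_numpy(float), y)
    bundle = ModelBundle(
        algorithm="rf",
        model=model,
        hyperparameters={k: result.winner[k] for k in ("ntree", "mtry")},
        feature_names=list(X_df.columns),
        scaling=None,
        calibrator=None,
        training_fingerprint=_fingerprint(X_df, y),
        seed=seed,
    )
    return bundle, result


def median_heuristic_gamma(X: np.ndarray, max_pairs: int = 2000, seed: int = 0) -> float:
    """RBF width by the median heuristic: gamma = 1 / median squared
    pairwise distance (subsampled for large n)."""
    rng = np.random.default_rng(seed)
    n = len(X)
    if n * (n - 1) // 2 <= max_pairs:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pairs = [tuple(rng.choice(n, size=2, replace=False)) for _ in range(max_pairs)]
    d2 = [float(np.sum((X[i] - X[j]) ** 2)) for i, j in pairs]
    med = float(np.median(d2))
    if med <= 0:
        med = 1.0
    return 1.0 / med


def train_svm_rbf(
    matrix,
    labels,
    scaling: ScalingParams,
    grid: HyperGrid | None = None,
    cv: tuple[int, int] = (10, 5),
    seed: int = 2022,
) -> tuple[ModelBundle, CVResult]:
    """Scan cost x RBF width on a standardized matrix, refit at the winner.

    The matrix must already be centered/scaled with the given parameters
    (checked); the bundle stores them so prediction can transform raw data.
    """
    grid = grid or HyperGrid()
    X_df = _as_frame(matrix)
    means = X_df.mean().abs()
    sds = X_df.std(ddof=1)
    if (means > 1e-6).any() or ((sds - 1).abs() > 1e-6).any():
        raise CypscreenError(
            "SVM input must be standardized (mean 0, sd 1); call standardize() first"
        )
    y = _encode_labels(labels)
    X = X_df.to_numpy(float)
    folds = _folds(y, cv[0], cv[1], seed)
    gamma0 = median_heuristic_gamma(X, seed=seed)
    entries = []
    for cost in grid.costs:
        for mult in grid.sigma_multipliers:
            gamma = gamma0 * mult
            mean, sd, _ = _cv_accuracy(
                lambda: SVC(C=cost, kernel="rbf", gamma=gamma), X, y, folds
            )
            entries.append(
                {"cost": cost, "gamma": gamma, "mean_accuracy": mean, "sd_accuracy": sd}
            )
    winner = max(entries, key=lambda e: (e["mean_accuracy"], -e["cost"], -e["gamma"]))
    model = SVC(C=winner["cost"], kernel="rbf", gamma=winner["gamma"])
    model.fit(X, y)
    # logistic link on training decision values -> auxiliary [0,1] score
    calibrator = LogisticRegression()
    calibrator.fit(model.decision_function(X).reshape(-1, 1), y)
    bundle = ModelBundle(
        algorithm="svm_rbf",
        model=model,
        hyperparameters={"cost": winner["cost"], "gamma": winner["gamma"]},
        feature_names=list(X_df.columns),
        scaling=scaling,
        calibrator=calibrator,
        training_fingerprint=_fingerprint(X_df, y),
        seed=seed,
    )
    result = CVResult(
        entries=entries, winner=dict(winner), n_splits=cv[0], n_repeats=cv[1], seed=seed
    )
    return bundle, result


# ---------------------------------------------------------------------------
# prediction and persistence


def predict(bundle: ModelBundle, matrix) -> tuple[list[str], np.ndarray]:
    """Labels and inhibitor-class scores for each row (row order preserved).

    The matrix must contain the bundle's descriptor columns; extras are
    ignored.  For the SVM path the stored training scaling is applied
    internally, so the input is raw (unscaled) descriptor values.
    """
    X_df = _as_frame(matrix)
    missing = [c for c in bundle.feature_names if c not in X_df.columns]
    if missing:
        raise CypscreenError(f"matrix missing required descriptor column(s) {missing}")
    X_df = X_df[bundle.feature_names]
    if bundle.algorithm == "svm_rbf":
        sp = bundle.scaling
        X = ((X_df - sp.means[bundle.feature_names]) / sp.sds[bundle.feature_names]).to_numpy(float)
        dec = bundle.model.decision_function(X)
        scores = bundle.calibrator.predict_proba(dec.reshape(-1, 1))[:, 1]
        y_hat = bundle.model.predict(X)
    elif bundle.algorithm == "rf":
        X = X_df.to_numpy(float)
        proba = bundle.model.predict_proba(X)
        pos_col = list(bundle.model.classes_).index(1)
        scores = proba[:, pos_col]
        y_hat = bundle.model.predict(X)
    else:
        raise BundleError(f"unknown algorithm {bundle.algorithm!r}")
    labels = [INHIBITOR if v == 1 else NON_INHIBITOR for v in y_hat]
    return labels, np.asarray(scores, dtype=float)


def save_bundle(bundle: ModelBundle, path) -> None:
    payload = {
        "schema_version": bundle.schema_version,
        "algorithm": bundle.algorithm,
        "model": bundle.model,
        "hyperparameters": bundle.hyperparameters,
        "feature_names": bundle.feature_names,
        "scaling": None
        if bundle.scaling is None
        else {"means": bundle.scaling.means.to_dict(), "sds": bundle.scaling.sds.to_dict()},
        "calibrator": bundle.calibrator,
        "training_fingerprint": bundle.training_fingerprint,
        "seed": bundle.seed,
    }
    joblib.dump(payload, path)


def load_bundle(path) -> ModelBundle:
    payload = joblib.load(path)
    version = payload.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise BundleError(
            f"bundle schema version {version!r} unsupported (expected {BUNDLE_SCHEMA_VERSION})"
        )
    scaling = payload["scaling"]
    if scaling is not None:
        scaling = ScalingParams(means=pd.Series(scaling["means"]), sds=pd.Series(scaling["sds"]))
    return ModelBundle(
        algorithm=payload["algorithm"],
        model=payload["model"],
        hyperparameters=payload["hyperparameters"],
        feature_names=payload["feature_names"],
        scaling=scaling,
        calibrator=payload["calibrator"],
        training_fingerprint=payload["training_fingerprint"],
        seed=payload["seed"],
        schema_version=version,
    )
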