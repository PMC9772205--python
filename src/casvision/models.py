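"""Per-sign classifiers: PCA + linear-SVM submodels and consensus heads.

Each inflammatory sign is predicted from its cropped region by an
ensemble of three submodels, one per expert rater, each a linear PCA
followed by a linear-kernel SVM whose hyperparameters (number of PCA
components, SVM regularization C) are tuned by stratified fivefold
cross-validation on the training set.  Two consensus architectures
combine the submodels:

* **aggregating** — a fourth PCA+SVM takes the image features together
  with the three rater readings (encoded +/-1) and is trained against
  the raters' agreed diagnosis.  At training time the head sees the
  true rater labels (as the experts' written readings); at inference it
  is fed the submodels' hard predictions.
* **voting** — simple majority of the three submodel labels; the
  continuous score is the mean of the three decision values.

Decision convention everywhere: label = (score > 0); an exactly-zero
score is classed negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .roi import CroppedImage
from .signs import IMAGE_SIGNS, SignKind

logger = logging.getLogger(__name__)

FEATURE_LENGTH = 64 * 64 * 3

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
DEFAULT_COMPONENTS_GRID: tuple[int, ...] = (8, 16, 32, 64)

BUNDLE_FORMAT_VERSION = 1


def extract_features(crop: CroppedImage | np.ndarray) -> np.ndarray:
    """Flatten a 64x64 RGB crop into a feature vector (row-major, channels last)."""
    pixels = crop.pixels if isinstance(crop, CroppedImage) else np.asarray(crop)
    if pixels.shape != (64, 64, 3):
        raise ValueError(f"expected crop of shape (64, 64, 3), got {pixels.shape}")
    return np.asarray(pixels, dtype=np.float64).reshape(-1)


@dataclass(frozen=True)
class SubmodelHyperparams:
    """Search grids for one PCA+SVM submodel."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_components_grid: tuple[int, ...] = DEFAULT_COMPONENTS_GRID
    cv_folds: int = 5
    scoring: str = "accuracy"

    def __post_init__(self) -> None:
        if not self.C_grid or not self.n_components_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _feasible_components(grid: tuple[int, ...], n_train: int, n_features: int,
                         cv_folds: int) -> list[int]:
    """Clip the component grid to what the smallest CV fold can support."""
    cap = min(n_train - int(np.ceil(n_train / cv_folds)), n_features)
    feasible = sorted({min(n, cap) for n in grid if min(n, cap) >= 1})
    if feasible != sorted(set(grid)):
        logger.warning(
            "n_components grid %s clipped to %s (n_train=%d, cap=%d)",
            grid, feasible, n_train, cap,
        )
    if not feasible:
        raise ValueError(f"no feasible n_components for n_train={n_train}")
    return feasible


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D (n_samples, n_features), got {X.shape}")
    if len(X) != len(y):
        raise ValueError("X and y have mismatched lengths")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate labels: a single class was provided")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    return X, y


def _fit_svm(Z: np.ndarray, y: np.ndarray, C: float, seed: int) -> LinearSVC:
    svm = LinearSVC(C=C, dual=False, tol=1e-5, max_iter=20000, random_state=seed)
    svm.fit(Z, y)
    return svm


class PcaLinearSvm(BaseEstimator, ClassifierMixin):
    """Linear PCA + linear-SVM classifier with internal fivefold CV tuning.

    Grid search selects (n_components, C) by mean stratified-CV
    accuracy; ties prefer fewer components, then smaller C.  The PCA is
    fitted once per fold at the largest feasible dimensionality and the
    leading components are reused for the smaller candidates.  After
    selection the winning pair is refitted on all training data.

    Optionally ``n_extra`` trailing feature columns bypass the PCA and
    are passed to the SVM untouched (used by the aggregating head for
    the +/-1 rater inputs).

    Attributes ending in ``_`` are set by :meth:`fit`; the fitted state
    is held as plain arrays so models serialize without pickling.
    """

    def __init__(
        self,
        C_grid: tuple[float, ...] = DEFAULT_C_GRID,
        n_components_grid: tuple[int, ...] = DEFAULT_COMPONENTS_GRID,
        cv_folds: int = 5,
        n_extra: int = 0,
        random_state: int = 0,
    ) -> None:
        self.C_grid = C_grid
        self.n_components_grid = n_components_grid
        self.cv_folds = cv_folds
        self.n_extra = n_extra
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PcaLinearSvm":
        X, y = _validate_xy(X, y)
        if self.n_extra:
            X_img, X_extra = X[:, : -self.n_extra], X[:, -self.n_extra:]
        else:
            X_img, X_extra = X, np.empty((len(X), 0))
        n, p = X_img.shape
        comp_grid = _feasible_components(
            tuple(self.n_components_grid), n, p, self.cv_folds
        )
        c_grid = sorted(set(self.C_grid))
        seed = int(self.random_state)
        max_nc = comp_grid[-1]

        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=seed)
        fold_scores: dict[tuple[int, float], list[float]] = {
            (nc, C): [] for nc in comp_grid for C in c_grid
        }
        for fold, (tr, va) in enumerate(cv.split(X_img, y)):
            nc_fold = min(max_nc, len(tr))
            pca = PCA(n_components=nc_fold, svd_solver="randomized", random_state=seed)
            Z_tr_full = pca.fit_transform(X_img[tr])
            Z_va_full = pca.transform(X_img[va])
            for nc in comp_grid:
                k = min(nc, nc_fold)
                Z_tr = np.hstack([Z_tr_full[:, :k], X_extra[tr]])
                Z_va = np.hstack([Z_va_full[:, :k], X_extra[va]])
                for C in c_grid:
                    svm = _fit_svm(Z_tr, y[tr], C, seed)
                    fold_scores[(nc, C)].append(float(svm.score(Z_va, y[va])))

        best_key, best_score = None, -np.inf
        for nc in comp_grid:  # ordered: fewer components, then smaller C, win ties
            for C in c_grid:
                score = float(np.mean(fold_scores[(nc, C)]))
                if score > best_score:
                    best_key, best_score = (nc, C), score
        assert best_key is not None
        self.n_components_, self.C_ = best_key
        self.cv_results_ = {k: float(np.mean(v)) for k, v in fold_scores.items()}
        self.cv_score_ = best_score

        pca = PCA(n_components=self.n_components_, svd_solver="randomized", random_state=seed)
        Z = np.hstack([pca.fit_transform(X_img), X_extra])
        svm = _fit_svm(Z, y, self.C_, seed)
        self.mean_ = pca.mean_.copy()
        self.components_ = pca.components_.copy()
        self.coef_ = svm.coef_.ravel().copy()
        self.intercept_ = float(svm.intercept_[0])
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        return self

    # -- inference (pure numpy on the stored arrays) ------------------------

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if self.n_extra:
            X_img, X_extra = X[:, : -self.n_extra], X[:, -self.n_extra:]
        else:
            X_img, X_extra = X, np.empty((len(X), 0))
        Z = (X_img - self.mean_) @ self.components_.T
        return np.hstack([Z, X_extra])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._transform(X) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0.0


class SignConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Three per-rater PCA+SVM submodels plus a consensus head for one sign.

    ``consensus`` selects the architecture: ``"voting"`` (majority of
    submodel labels) or ``"aggregating"`` (a fourth PCA+SVM over the
    image features concatenated with the three rater readings, trained
    on the agreed diagnosis with the true rater labels as inputs —
    teacher forcing; set ``head_inputs="submodel_cv"`` to train on the
    submodels' own predictions instead).
    """

    def __init__(
        self,
        sign: SignKind = SignKind.EYELID_REDNESS,
        consensus: str = "voting",
        C_grid: tuple[float, ...] = DEFAULT_C_GRID,
        n_components_grid: tuple[int, ...] = DEFAULT_COMPONENTS_GRID,
        cv_folds: int = 5,
        head_inputs: str = "true_raters",
        random_state: int = 0,
    ) -> None:
        self.sign = sign
        self.consensus = consensus
        self.C_grid = C_grid
        self.n_components_grid = n_components_grid
        self.cv_folds = cv_folds
        self.head_inputs = head_inputs
        self.random_state = random_state

    def _check_params(self) -> None:
        if self.consensus not in ("voting", "aggregating"):
            raise ValueError(f"unknown consensus type {self.consensus!r}")
        if self.head_inputs not in ("true_raters", "submodel_cv"):
            raise ValueError(f"unknown head_inputs mode {self.head_inputs!r}")

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rater_labels: np.ndarray | None = None,
    ) -> "SignConsensusClassifier":
        """Fit submodels (one per rater column) and the consensus head.

        ``y`` is the agreed consensus label per sample; ``rater_labels``
        is (n_samples, 3) boolean with each rater's reading.
        """
        self._check_params()
        if rater_labels is None:
            raise ValueError("rater_labels (n_samples, 3) are required to fit")
        X = np.asarray(X, dtype=np.float64)
        R = np.asarray(rater_labels).astype(bool)
        y = np.asarray(y).astype(bool)
        if R.shape != (len(X), 3):
            raise ValueError(f"rater_labels must have shape (n, 3), got {R.shape}")
        seed = int(self.random_state)
        self.submodels_ = []
        for r in range(3):
            sub = PcaLinearSvm(
                C_grid=self.C_grid,
                n_components_grid=self.n_components_grid,
                cv_folds=self.cv_folds,
                random_state=seed + r + 1,
            )
            sub.fit(X, R[:, r])
            self.submodels_.append(sub)
        if self.consensus == "aggregating":
            if self.head_inputs == "true_raters":
                R_head = R
            else:
                R_head = np.column_stack([m.predict(X) for m in self.submodels_])
            head_X = np.hstack([X, np.where(R_head, 1.0, -1.0)])
            self.head_ = PcaLinearSvm(
                C_grid=self.C_grid,
                n_components_grid=self.n_components_grid,
                cv_folds=self.cv_folds,
                n_extra=3,
                random_state=seed,
            )
            self.head_.fit(head_X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        return self

    def _submodel_outputs(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "submodels_")
        scores = np.column_stack([m.decision_function(X) for m in self.submodels_])
        return scores > 0.0, scores

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        labels, scores = self._submodel_outputs(X)
        if self.consensus == "voting":
            return scores.mean(axis=1)
        head_X = np.hstack([X, np.where(labels, 1.0, -1.0)])
        return self.head_.decision_function(head_X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        labels, _ = self._submodel_outputs(X)
        if self.consensus == "voting":
            return labels.sum(axis=1) >= 2
        return self.decision_function(X) > 0.0

    def predict_with_score(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Consensus label and continuous score, in one pass."""
        return self.predict(X), self.decision_function(X)


def default_consensus_assignment() -> dict[SignKind, str]:
    """Which consensus architecture serves each sign.

    The aggregating model is used for eyelid redness and caruncle/plica
    inflammation; the voting model for eyelid swelling and conjunctival
    redness/edema.
    """
    return {
        SignKind.EYELID_REDNESS: "aggregating",
        SignKind.CARUNCLE_INFLAMMATION: "aggregating",
        SignKind.EYELID_SWELLING: "voting",
        SignKind.CONJUNCTIVAL_REDNESS: "voting",
        SignKind.CONJUNCTIVAL_EDEMA: "voting",
    }


# ---------------------------------------------------------------------------
# serialization: metadata JSON + raw arrays, no pickling


def _component_arrays(prefix: str, m: PcaLinearSvm) -> dict[str, np.ndarray]:
    return {
        f"{prefix}_mean": m.mean_,
        f"{prefix}_components": m.components_,
        f"{prefix}_coef": m.coef_,
        f"{prefix}_intercept": np.array([m.intercept_]),
    }


def _restore_component(prefix: str, arrays, meta: dict) -> PcaLinearSvm:
    m = PcaLinearSvm(
        C_grid=tuple(meta["C_grid"]),
        n_components_grid=tuple(meta["n_components_grid"]),
        cv_folds=meta["cv_folds"],
        n_extra=meta["n_extra"],
        random_state=meta["random_state"],
    )
    m.mean_ = arrays[f"{prefix}_mean"]
    m.components_ = arrays[f"{prefix}_components"]
    m.coef_ = arrays[f"{prefix}_coef"]
    m.intercept_ = float(arrays[f"{prefix}_intercept"][0])
    m.n_components_ = meta["n_components"]
    m.C_ = meta["C"]
    m.n_features_in_ = meta["n_features_in"]
    m.classes_ = np.array([False, True])
    return m


def _component_meta(m: PcaLinearSvm) -> dict:
    return {
        "C_grid": list(m.C_grid),
        "n_components_grid": list(m.n_components_grid),
        "cv_folds": m.cv_folds,
        "n_extra": m.n_extra,
        "random_state": m.random_state,
        "n_components": int(m.n_components_),
        "C": float(m.C_),
        "n_features_in": int(m.n_features_in_),
    }


def save_sign_model(model: SignConsensusClassifier, path: str | Path) -> None:
    """Write a model bundle: ``meta.json`` + ``arrays.npz`` in a directory."""
    check_is_fitted(model, "submodels_")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "sign": model.sign.value,
        "consensus": model.consensus,
        "C_grid": list(model.C_grid),
        "n_components_grid": list(model.n_components_grid),
        "cv_folds": model.cv_folds,
        "head_inputs": model.head_inputs,
        "random_state": model.random_state,
        "n_features_in": int(model.n_features_in_),
        "submodels": [_component_meta(m) for m in model.submodels_],
    }
    arrays: dict[str, np.ndarray] = {}
    for r, sub in enumerate(model.submodels_):
        arrays.update(_component_arrays(f"sub{r}", sub))
    if model.consensus == "aggregating":
        meta["head"] = _component_meta(model.head_)
        arrays.update(_component_arrays("head", model.head_))
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    np.savez(path / "arrays.npz", **arrays)


def load_sign_model(path: str | Path) -> SignConsensusClassifier:
    """Load a model bundle; predictions round-trip exactly."""
    path = Path(path)
    meta_path, arr_path = path / "meta.json", path / "arrays.npz"
    if not meta_path.exists() or not arr_path.exists():
        raise FileNotFoundError(f"not a model bundle (missing meta.json/arrays.npz): {path}")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
        arrays = np.load(arr_path)
    except (json.JSONDecodeError, ValueError, OSError) as exc:
        raise ValueError(f"corrupt model bundle at {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"model bundle format version {version} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    model = SignConsensusClassifier(
        sign=SignKind(meta["sign"]),
        consensus=meta["consensus"],
        C_grid=tuple(meta["C_grid"]),
        n_components_grid=tuple(meta["n_components_grid"]),
        cv_folds=meta["cv_folds"],
        head_inputs=meta["head_inputs"],
        random_state=meta["random_state"],
    )
    model.submodels_ = [
        _restore_component(f"sub{r}", arrays, sub_meta)
        for r, sub_meta in enumerate(meta["submodels"])
    ]
    if model.consensus == "aggregating":
        model.head_ = _restore_component("head", arrays, meta["head"])
    model.n_features_in_ = meta["n_features_in"]
    model.classes_ = np.array([False, True])
    return model
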