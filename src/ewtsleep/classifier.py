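"""Hybrid sparse-representation + nearest-neighbour sleep-stage classifier.

The classifier keeps the training feature matrix as a dictionary whose atoms
(columns) are training instances grouped by class.  A test vector is coded
over the *concatenated* dictionary by orthogonal matching pursuit (OMP) at
sparsity level rho; the code is then split per class and each class is scored
by the residual of reconstructing the test vector from its own atoms alone
(the sparse-representation-classification convention).  Independently, each
class contributes the median of the distances to its ``nn`` nearest training
instances.  The two scores are summed, TD_e = Res_e + D_e, and the predicted
class minimizes the total distance.

Features are z-scored with training-set statistics before dictionary
construction, so residuals and Euclidean distances live on commensurate
scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import MetricReport, confusion, report

logger = logging.getLogger(__name__)

#: The five stage-merging strategies evaluated by the pipeline.
SCHEMES = ("2class", "3class", "4class", "5class", "6class")

_SCHEME_MAPS = {
    # wake vs sleep
    "2class": {"S0": "W", "S1": "SLEEP", "S2": "SLEEP", "S3": "SLEEP",
               "S4": "SLEEP", "REM": "SLEEP"},
    # wake vs NREM vs REM
    "3class": {"S0": "W", "S1": "NREM", "S2": "NREM", "S3": "NREM",
               "S4": "NREM", "REM": "REM"},
    # wake vs light sleep vs deep sleep vs REM
    "4class": {"S0": "W", "S1": "LS", "S2": "LS", "S3": "DS",
               "S4": "DS", "REM": "REM"},
    # wake vs S1 vs S2 vs (S3+S4) vs REM
    "5class": {"S0": "W", "S1": "S1", "S2": "S2", "S3": "S3",
               "S4": "S3", "REM": "REM"},
    "6class": {"S0": "S0", "S1": "S1", "S2": "S2", "S3": "S3",
               "S4": "S4", "REM": "REM"},
}

_SCHEME_ORDER = {
    "2class": ["W", "SLEEP"],
    "3class": ["W", "NREM", "REM"],
    "4class": ["W", "LS", "DS", "REM"],
    "5class": ["W", "S1", "S2", "S3", "REM"],
    "6class": ["S0", "S1", "S2", "S3", "S4", "REM"],
}


def merge_labels(labels, scheme: str) -> list[str]:
    """Apply one of the five class-merging strategies to stage labels."""
    if scheme not in _SCHEME_MAPS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    mapping = _SCHEME_MAPS[scheme]
    return [mapping[lab] for lab in labels]


def scheme_classes(scheme: str) -> list[str]:
    """Class labels of a scheme, in canonical (wake-first) order."""
    return list(_SCHEME_ORDER[scheme])


def omp(dictionary: np.ndarray, target: np.ndarray, sparsity: int,
        tol: float = 1e-12) -> np.ndarray:
    """Orthogonal matching pursuit over column atoms.

    Greedily selects the atom with maximal absolute correlation with the
    current residual (correlation computed on norm-1 atoms), refits all
    selected coefficients by least squares on the *raw* atoms, and stops
    after ``sparsity`` atoms or when the residual norm drops below ``tol``.

    Returns the dense coefficient vector with at most ``sparsity`` non-zeros.
    """
    D = np.asarray(dictionary, dtype=float)
    y = np.asarray(target, dtype=float)
    if D.ndim != 2 or y.shape != (D.shape[0],):
        raise ValueError("dictionary must be (dim, atoms) with matching target")
    n_atoms = D.shape[1]
    if not 1 <= sparsity <= n_atoms:
        raise ValueError(f"sparsity must be in [1, {n_atoms}]")
    norms = np.linalg.norm(D, axis=0)
    if np.any(norms == 0):
        raise ValueError("dictionary contains a zero-norm atom")
    Dn = D / norms

    coef = np.zeros(n_atoms)
    support: list[int] = []
    residual = y.copy()
    for _ in range(sparsity):
        if np.linalg.norm(residual) < tol:
            break
        corr = np.abs(Dn.T @ residual)
        corr[support] = -np.inf  # never reselect
        support.append(int(np.argmax(corr)))
        sub = D[:, support]
        sol, _, rank, _ = np.linalg.lstsq(sub, y, rcond=None)
        if rank < len(support):
            logger.warning(
                "OMP selected a rank-deficient atom set (rank %d of %d); "
                "using minimum-norm least squares", rank, len(support)
            )
        coef[:] = 0.0
        coef[support] = sol
        residual = y - sub @ sol
    return coef


@dataclass
class HybridModel:
    """Fitted hybrid classifier: per-class dictionaries + hyper-parameters.

    Build with :func:`fit`; ``classes`` fixes the class order used for
    tie-breaking (argmin ties go to the earliest class, logged).
    """

    classes: list[str]
    class_atoms: dict = field(repr=False)  # class -> (dim, n_e) raw atoms
    rho: int
    nn: int
    mean: np.ndarray = field(repr=False)
    std: np.ndarray = field(repr=False)

    @property
    def n_features(self) -> int:
        return self.mean.size

    @property
    def dictionary(self) -> np.ndarray:
        """Concatenated (dim, n_atoms) dictionary in class order."""
        return np.hstack([self.class_atoms[c] for c in self.classes])

    def _class_slices(self):
        slices, start = {}, 0
        for c in self.classes:
            n = self.class_atoms[c].shape[1]
            slices[c] = slice(start, start + n)
            start += n
        return slices

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


def fit(
    features: np.ndarray,
    labels,
    rho: int = 20,
    nn: int = 10,
    classes: list[str] | None = None,
    standardize: bool = True,
) -> HybridModel:
    """Fit the hybrid model: partition training instances into class dictionaries.

    ``rho`` is capped at the dictionary size with a warning; every class must
    hold at least ``nn`` instances so the median nearest-neighbour distance is
    well defined.
    """
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("features must be (instances, dim) matching labels")
    if classes is None:
        classes = sorted(set(labels))
    if rho < 1 or nn < 1:
        raise ValueError("rho and nn must be >= 1")
    if rho > X.shape[0]:
        warnings.warn(
            f"rho={rho} exceeds the {X.shape[0]}-atom dictionary; capping",
            stacklevel=2,
        )
        rho = X.shape[0]
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std

    atoms = {}
    lab_arr = np.asarray(labels)
    for c in classes:
        rows = Xs[lab_arr == c]
        if rows.shape[0] < nn:
            raise ValueError(
                f"class {c!r} has {rows.shape[0]} training instances, "
                f"fewer than nn={nn}"
            )
        atoms[c] = rows.T.copy()  # atoms are columns
    return HybridModel(classes=list(classes), class_atoms=atoms, rho=rho,
                       nn=nn, mean=mean, std=std)


@dataclass
class ClassScores:
    """Per-class decomposition of one prediction: TD_e = Res_e + D_e."""

    residuals: np.ndarray
    knn_distances: np.ndarray
    totals: np.ndarray
    predicted: str


def class_residuals(model: HybridModel, coef: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Residual of reconstructing ``target`` from each class's own atoms.

    ``coef`` indexes the concatenated dictionary; Res_e = ||t - D_e @ coef_e||.
    """
    slices = model._class_slices()
    res = np.empty(len(model.classes))
    for e, c in enumerate(model.classes):
        res[e] = np.linalg.norm(target - model.class_atoms[c] @ coef[slices[c]])
    return res


def knn_class_distance(model: HybridModel, target: np.ndarray) -> np.ndarray:
    """Median of the nn smallest Euclidean distances to each class's instances."""
    d = np.empty(len(model.classes))
    for e, c in enumerate(model.classes):
        dists = np.linalg.norm(model.class_atoms[c] - target[:, None], axis=0)
        nearest = np.sort(dists)[: model.nn]
        d[e] = np.median(nearest)
    return d


def predict(model: HybridModel, features: np.ndarray, return_scores: bool = False):
    """Predict class labels for a test feature matrix.

    Returns the label list, or (labels, list of :class:`ClassScores`) when
    ``return_scores`` is set.  Argmin ties are broken toward the earliest
    class in ``model.classes`` and logged.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"{X.shape[1]} features but the model was fitted with {model.n_features}"
        )
    Xs = model.standardize(X)
    D = model.dictionary
    labels, scores = [], []
    for row in Xs:
        coef = omp(D, row, model.rho)
        res = class_residuals(model, coef, row)
        knn = knn_class_distance(model, row)
        totals = res + knn
        winners = np.flatnonzero(totals == totals.min())
        if winners.size > 1:
            logger.info("total-distance tie among classes %s; picking first",
                        [model.classes[w] for w in winners])
        pred = model.classes[int(winners[0])]
        labels.append(pred)
        if return_scores:
            scores.append(ClassScores(res, knn, totals, pred))
    return (labels, scores) if return_scores else labels


@dataclass
class CVResult:
    """Per-fold metric reports plus mean +/- sd aggregates."""

    scheme: str
    protocol: str
    fold_reports: list
    mean_accuracy: float
    sd_accuracy: float
    mean_kappa: float
    sd_kappa: float
    pooled: MetricReport


def _evaluate_fold(X_tr, y_tr, X_te, y_te, classes, rho, nn):
    model = fit(X_tr, y_tr, rho=rho, nn=nn, classes=classes)
    preds = predict(model, X_te)
    cm = confusion(y_te, preds, labels=classes)
    return report(cm), list(preds)


def cross_validate(
    features: np.ndarray,
    stage_labels,
    scheme: str = "6class",
    protocol: str = "10fold",
    rho: int = 20,
    nn: int = 10,
    seed: int = 0,
    n_folds: int = 10,
) -> CVResult:
    """Evaluate the hybrid classifier under a class-merging scheme.

    protocol="10fold": stratified k-fold, 90/10 train/test per fold.
    protocol="holdout": stratified 60/10/30 train/validation/test split; the
    validation block is reserved for hyper-parameter selection and the
    returned metrics come from the 30% test block.

    All randomness flows from ``seed``; identical calls return identical
    folds and metrics.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(merge_labels(stage_labels, scheme))
    classes = [c for c in scheme_classes(scheme) if c in set(y)]
    if len(classes) < 2:
        raise ValueError("need at least two classes after merging")

    fold_reports: list[MetricReport] = []
    all_true: list[str] = []
    all_pred: list[str] = []

    if protocol == "10fold":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr_idx, te_idx in skf.split(X, y):
            if set(y[tr_idx]) != set(classes):
                raise ValueError(
                    "a training fold is missing a class; use a different "
                    "stratification seed or more instances per class"
                )
            rep, preds = _evaluate_fold(
                X[tr_idx], y[tr_idx], X[te_idx], y[te_idx], classes, rho, nn
            )
            fold_reports.append(rep)
            all_true.extend(y[te_idx])
            all_pred.extend(preds)
    elif protocol == "holdout":
        idx = np.arange(len(y))
        tr_idx, rest = train_test_split(
            idx, train_size=0.6, stratify=y, random_state=seed
        )
        # remaining 40% -> 10% validation, 30% test
        val_idx, te_idx = train_test_split(
            rest, train_size=0.25, stratify=y[rest], random_state=seed
        )
        if set(y[tr_idx]) != set(classes):
            raise ValueError(
                "training partition is missing a class; change the seed"
            )
        rep, preds = _evaluate_fold(
            X[tr_idx], y[tr_idx], X[te_idx], y[te_idx], classes, rho, nn
        )
        rep.validation_indices = val_idx  # type: ignore[attr-defined]
        fold_reports.append(rep)
        all_true.extend(y[te_idx])
        all_pred.extend(preds)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    accs = np.array([r.overall_accuracy for r in fold_reports])
    kappas = np.array([r.kappa for r in fold_reports])
    pooled = report(confusion(all_true, all_pred, labels=classes))
    return CVResult(
        scheme=scheme,
        protocol=protocol,
        fold_reports=fold_reports,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std()),
        mean_kappa=float(np.nanmean(kappas)),
        sd_kappa=float(np.nanstd(kappas)),
        pooled=pooled,
    )
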