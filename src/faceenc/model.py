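"""Ridge-regression encoding models with cross-validated shared penalty.

For every subject x region x condition, responses of the region's contacts
are concatenated row-wise (the design matrix tiled once per contact, one
weight vector serving all contacts), and a ridge model with an unpenalized
intercept is evaluated by fivefold cross-validation over contiguous
temporal segments (per contact, aligned across contacts).  Prediction
accuracy is the Pearson correlation between held-out measured and predicted
responses, averaged over folds.  A single regularization coefficient,
maximizing the unweighted mean of cross-validated accuracy across every
dataset, is shared by all fits so weight scales stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, logger
from .features import DesignMatrix, ResponseMatrix, assemble_condition
from .preproc import SubjectRecord

FIT_REGIONS = ("DLPFC", "pSTC")


@dataclass
class EncodingFit:
    """Fitted encoding model for one subject x region x condition."""

    subject_id: str
    region: str
    condition: str
    alpha: float
    weights: np.ndarray       # n_folds x n_predictors
    intercepts: np.ndarray    # n_folds
    fold_r: np.ndarray        # n_folds (NaN for degenerate folds)
    mean_r: float
    n_rows: int
    n_contacts: int
    column_labels: list[tuple[str, float]] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "subject": self.subject_id, "region": self.region,
            "condition": self.condition, "alpha": self.alpha,
            "fold_r": list(self.fold_r), "mean_r": self.mean_r,
            "n_rows": self.n_rows, "n_contacts": self.n_contacts,
        }


@dataclass
class Dataset:
    """One fitting problem: tiled design + stacked contact responses."""

    subject: SubjectRecord
    region: str
    condition: str
    X: np.ndarray             # stacked rows x predictors
    y: np.ndarray             # stacked rows
    contact_ids: np.ndarray   # stacked rows; which contact each row belongs to
    n_contacts: int
    column_labels: list[tuple[str, float]]


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def concatenate_contacts(X: np.ndarray, Y: np.ndarray,
                         mode: str = "concatenate"
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-contact responses along the row axis.

    ``Y`` is rows x contacts.  In "concatenate" mode the design is tiled
    once per contact so one weight vector serves all contacts; in "average"
    mode contacts are averaged into a single response and no tiling occurs.
    Returns ``(X_stacked, y_stacked, contact_ids)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y must be rows x contacts, aligned with X")
    n_rows, n_contacts = Y.shape
    if n_contacts < 1:
        raise ValueError("no contacts to stack")
    if mode == "average":
        return X, Y.mean(axis=1), np.zeros(n_rows, dtype=int)
    if mode != "concatenate":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if n_contacts == 1:
        return X, Y[:, 0], np.zeros(n_rows, dtype=int)
    X_stacked = np.tile(X, (n_contacts, 1))
    y_stacked = Y.T.reshape(-1)
    contact_ids = np.repeat(np.arange(n_contacts), n_rows)
    return X_stacked, y_stacked, contact_ids


# ---------------------------------------------------------------------------
# Ridge solver
# ---------------------------------------------------------------------------

def ridge_solve(X: np.ndarray, y: np.ndarray,
                alpha: float) -> tuple[np.ndarray, float]:
    """Minimize ||y - Xw - b||^2 + alpha ||w||^2, intercept unpenalized.

    Solved on centered data (mathematically identical to leaving the
    intercept out of the penalty).  Deterministic; ``alpha = 0`` falls back
    to a least-squares solve of the centered system.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y shapes incompatible")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    p = X.shape[1]
    if alpha == 0:
        w = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        G = Xc.T @ Xc + alpha * np.eye(p)
        w = np.linalg.solve(G, Xc.T @ yc)
    b = y_mean - x_mean @ w
    return w, float(b)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either side is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def contiguous_folds(contact_ids: np.ndarray, n_folds: int = 5
                     ) -> list[np.ndarray]:
    """Partition rows into contiguous-in-time segments per contact.

    Fold k collects the k-th contiguous segment of every contact, so the
    folds are temporally aligned across contacts and no fold mixes early and
    late stimulus time.
    """
    contact_ids = np.asarray(contact_ids)
    folds: list[list[np.ndarray]] = [[] for _ in range(n_folds)]
    for c in np.unique(contact_ids):
        rows = np.flatnonzero(contact_ids == c)
        if len(rows) < n_folds:
            raise ValueError("fewer rows than folds for a contact")
        for k, seg in enumerate(np.array_split(rows, n_folds)):
            folds[k].append(seg)
    return [np.concatenate(parts) for parts in folds]


def crossval_fit(X: np.ndarray, y: np.ndarray, alpha: float,
                 n_folds: int = 5,
                 contact_ids: np.ndarray | None = None,
                 folds: list[np.ndarray] | None = None,
                 subject_id: str = "", region: str = "", condition: str = "",
                 n_contacts: int = 1,
                 column_labels: list[tuple[str, float]] | None = None
                 ) -> EncodingFit:
    """Fivefold cross-validated ridge fit with per-fold held-out accuracy.

    mean_r averages the per-fold Pearson r values; folds whose held-out
    response is constant yield NaN and are excluded from the mean with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        if contact_ids is None:
            contact_ids = np.zeros(len(y), dtype=int)
        folds = contiguous_folds(contact_ids, n_folds)
    n_folds = len(folds)
    all_rows = np.arange(len(y))
    weights = np.empty((n_folds, X.shape[1]))
    intercepts = np.empty(n_folds)
    fold_r = np.empty(n_folds)
    for k, test_rows in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_rows] = False
        w, b = ridge_solve(X[train_mask], y[train_mask], alpha)
        pred = X[test_rows] @ w + b
        weights[k] = w
        intercepts[k] = b
        fold_r[k] = pearson_r(y[test_rows], pred)
    valid = np.isfinite(fold_r)
    if not valid.all():
        logger.warning("%d degenerate folds excluded from mean_r",
                       int((~valid).sum()))
    mean_r = float(fold_r[valid].mean()) if valid.any() else float("nan")
    return EncodingFit(subject_id=subject_id, region=region,
                       condition=condition, alpha=float(alpha),
                       weights=weights, intercepts=intercepts,
                       fold_r=fold_r, mean_r=mean_r, n_rows=len(y),
                       n_contacts=n_contacts,
                       column_labels=column_labels or [])


def cv_mean_r_batch(X_batch: np.ndarray, y: np.ndarray,
                    folds: list[np.ndarray], alpha: float) -> np.ndarray:
    """Cross-validated mean Pearson r for a batch of design matrices.

    ``X_batch`` is batch x rows x predictors sharing one response ``y`` and
    one fold partition.  Mathematically identical to calling
    :func:`crossval_fit` per matrix (verified in tests), but computes each
    training Gram matrix as the total Gram minus the fold's contribution,
    which makes temporal-shuffle permutation testing tractable.
    """
    X_batch = np.asarray(X_batch, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    P, n, p = X_batch.shape
    Xt = X_batch.transpose(0, 2, 1)
    G_total = Xt @ X_batch                      # P x p x p
    Xty_total = Xt @ y                          # P x p
    s_total = X_batch.sum(axis=1)               # P x p
    y_total = y.sum()
    eye = np.eye(p)
    r_sum = np.zeros(P)
    r_count = np.zeros(P)
    for test_rows in folds:
        Xte = X_batch[:, test_rows, :]
        yte = y[test_rows]
        G_fold = Xte.transpose(0, 2, 1) @ Xte
        ntr = n - len(test_rows)
        x_mean = (s_total - Xte.sum(axis=1)) / ntr          # P x p
        y_mean = (y_total - yte.sum()) / ntr
        # centered Gram and cross-products of the training rows
        Gc = (G_total - G_fold) - ntr * np.einsum("pi,pj->pij", x_mean, x_mean)
        rhs = (Xty_total - Xte.transpose(0, 2, 1) @ yte) - ntr * x_mean * y_mean
        w = np.linalg.solve(Gc + alpha * eye, rhs[..., None])[..., 0]
        pred = np.einsum("pij,pj->pi", Xte, w) + (y_mean - np.einsum(
            "pj,pj->p", x_mean, w))[:, None]
        ps = pred.std(axis=1)
        ys = yte.std()
        ok = (ps > 0) & (ys > 0)
        pc = pred - pred.mean(axis=1, keepdims=True)
        r = np.where(ok, (pc * (yte - yte.mean())).mean(axis=1)
                     / np.where(ps > 0, ps, 1) / (ys if ys > 0 else 1), np.nan)
        r_sum += np.where(ok, r, 0)
        r_count += ok
    with np.errstate(invalid="ignore"):
        return np.where(r_count > 0, r_sum / np.maximum(r_count, 1), np.nan)


# ---------------------------------------------------------------------------
# Shared regularization
# ---------------------------------------------------------------------------

def cv_curve(X: np.ndarray, y: np.ndarray, grid: np.ndarray,
             folds: list[np.ndarray]) -> np.ndarray:
    """mean_r as a function of the penalty, SVD-accelerated.

    One SVD per fold serves every grid value; the same fold partition is
    reused for all penalties (variance reduction, determinism).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    r_sum = np.zeros(len(grid))
    r_count = np.zeros(len(grid))
    for test_rows in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_rows] = False
        Xtr = X[train_mask]
        ytr = y[train_mask]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        U, s, Vt = np.linalg.svd(Xtr - x_mean, full_matrices=False)
        Uty = U.T @ (ytr - y_mean)
        Xte_c = X[test_rows] - x_mean
        yte = y[test_rows]
        TeV = Xte_c @ Vt.T
        for i, alpha in enumerate(grid):
            coef = s / (s ** 2 + alpha) * Uty
            pred = TeV @ coef + y_mean
            r = pearson_r(yte, pred)
            if np.isfinite(r):
                r_sum[i] += r
                r_count[i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(r_count > 0, r_sum / np.maximum(r_count, 1), np.nan)


def select_shared_alpha(datasets: list[Dataset], grid: np.ndarray,
                        n_folds: int = 5) -> tuple[float, np.ndarray]:
    """Penalty maximizing the mean cross-validated accuracy over datasets.

    Returns ``(alpha, mean_curve)``; ties resolve to the smallest penalty
    (np.argmax takes the first maximum).
    """
    if not datasets:
        raise ValueError("no datasets for alpha selection")
    grid = np.asarray(grid, dtype=float)
    curves = []
    for ds in datasets:
        folds = contiguous_folds(ds.contact_ids, n_folds)
        curves.append(cv_curve(ds.X, ds.y, grid, folds))
    mean_curve = np.nanmean(np.stack(curves), axis=0)
    return float(grid[int(np.nanargmax(mean_curve))]), mean_curve


# ---------------------------------------------------------------------------
# Study-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class SubjectBundle:
    """One subject's inputs to fitting: contact table + binned responses."""

    subject: SubjectRecord
    response: ResponseMatrix


def make_datasets(design: DesignMatrix, bundle: SubjectBundle,
                  config: PipelineConfig) -> list[Dataset]:
    """Per-region, per-condition datasets for one subject.

    Regions with fewer good contacts than ``config.min_contacts`` are
    skipped with a log line.
    """
    datasets = []
    channels = bundle.response.channels
    good = (channels["status"] == "good").to_numpy()
    for region in FIT_REGIONS:
        idx = np.flatnonzero((channels["region"] == region).to_numpy() & good)
        if len(idx) == 0:
            continue
        if len(idx) < config.min_contacts:
            logger.info("subject %s: %s has %d < %d contacts; skipped",
                        bundle.subject.id, region, len(idx), config.min_contacts)
            continue
        for condition in ("speech", "music"):
            Xc, Yc, _ = assemble_condition(design, bundle.response, condition)
            Xs, ys, contact_ids = concatenate_contacts(
                Xc, Yc[:, idx], config.contact_aggregation)
            datasets.append(Dataset(
                subject=bundle.subject, region=region, condition=condition,
                X=Xs, y=ys, contact_ids=contact_ids, n_contacts=len(idx),
                column_labels=design.column_labels))
    return datasets


def fit_all(design: DesignMatrix, bundles: list[SubjectBundle],
            config: PipelineConfig
            ) -> tuple[list[EncodingFit], float, list[Dataset]]:
    """Fit every available subject x region x condition with a shared alpha.

    The penalty is selected once, over all datasets jointly, then each
    dataset is refitted at that value.  Returns the fits, the shared alpha
    and the datasets (reused by permutation testing).
    """
    datasets: list[Dataset] = []
    for bundle in bundles:
        datasets.extend(make_datasets(design, bundle, config))
    if not datasets:
        raise ValueError("no subject has a qualifying region")
    alpha, _ = select_shared_alpha(datasets, config.alpha_grid, config.n_folds)
    fits = []
    for ds in datasets:
        fits.append(crossval_fit(
            ds.X, ds.y, alpha, config.n_folds, contact_ids=ds.contact_ids,
            subject_id=ds.subject.id, region=ds.region, condition=ds.condition,
            n_contacts=ds.n_contacts, column_labels=ds.column_labels))
    return fits, alpha, datasets
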