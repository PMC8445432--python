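"""Mean-centred NIPALS PCA with leverage-corrected validated variance, and
two-class linear discriminant analysis on leading PC scores.

NIPALS extracts principal components one at a time by alternating
score/loading regressions with deflation, which is the algorithm classical
chemometrics software uses for spectral matrices.  Leverage correction
approximates full cross-validation of the PCA residual variance by inflating
each observation's residual by 1/(1 - h_i), where h_i is the hat value of
observation i in the score space (plus the 1/n centring term).

The discriminant analysis is the standard two-class linear rule with pooled
within-class covariance, applied to the first k principal component scores.
PC indexing is 1-based throughout ("PC-1" is the first component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .metrics import ConfusionMatrix, confusion_from_labels
from .spectra_io import ACC, PA, SpectrumSet

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Fitted PCA: grand mean, unit-norm loadings, scores and variance shares."""

    grand_mean: np.ndarray                       # (n_variables,)
    loadings: np.ndarray                         # (n_components, n_variables)
    scores: np.ndarray                           # (n_observations, n_components)
    explained_variance_fraction: np.ndarray      # (n_components,)
    leverage_corrected_variance: np.ndarray | None = None  # (n_components,)
    variable_wavenumbers: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def to_dict(self) -> dict:
        d = {
            "grand_mean": self.grand_mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
        }
        if self.leverage_corrected_variance is not None:
            d["leverage_corrected_variance"] = (
                self.leverage_corrected_variance.tolist()
            )
        if self.variable_wavenumbers is not None:
            d["variable_wavenumbers"] = self.variable_wavenumbers.tolist()
        return d


@dataclass
class LDAModel:
    """Two-class linear discriminant over the first k PC scores."""

    classes: tuple[str, str]          # (negative, positive) = (PA, ACC)
    class_means: np.ndarray           # (2, k)
    pooled_covariance: np.ndarray     # (k, k)
    priors: np.ndarray                # (2,)
    weights: np.ndarray               # (k,) discriminant direction
    threshold: float                  # decide positive when w·x > threshold
    n_predictors: int = 6

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "n_predictors": self.n_predictors,
        }


def fit_pca_nipals(
    X: np.ndarray,
    n_components: int = 7,
    tol: float = 1e-10,
    max_iter: int = 500,
    variable_wavenumbers: np.ndarray | None = None,
) -> PCAModel:
    """Fit mean-centred PCA by NIPALS with deflation.

    Components are extracted sequentially; iteration stops when the relative
    change of the score vector drops below ``tol`` (a warning is logged when
    ``max_iter`` is reached first).  Each loading is flipped so that its
    largest-magnitude entry is positive, making output deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, m)={min(n, m)}"
        )
    grand_mean = X.mean(axis=0)
    Xr = X - grand_mean
    total_ss = float(np.sum(Xr**2))
    if total_ss <= 0:
        raise ValueError("matrix has zero variance after centring; PCA undefined")

    loadings = np.zeros((n_components, m))
    scores = np.zeros((n, n_components))
    evf = np.zeros(n_components)
    for a in range(n_components):
        col_ss = np.sum(Xr**2, axis=0)
        j = int(np.argmax(col_ss))
        if col_ss[j] <= total_ss * 1e-30:
            # residual exhausted: remaining components are exactly zero
            break
        t = Xr[:, j].copy()
        for it in range(max_iter):
            p = Xr.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = Xr @ p
            if np.linalg.norm(t_new - t) < tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            logger.warning(
                "NIPALS component %d did not converge in %d iterations", a + 1,
                max_iter,
            )
        # sign convention: largest-|loading| entry positive
        k = int(np.argmax(np.abs(p)))
        if p[k] < 0:
            p = -p
            t = -t
        loadings[a] = p
        scores[:, a] = t
        evf[a] = (t @ t) / total_ss
        Xr = Xr - np.outer(t, p)

    return PCAModel(
        grand_mean=grand_mean,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=evf,
        variable_wavenumbers=variable_wavenumbers,
    )


def leverage_corrected_variance(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Validated residual variance per component count, by leverage correction.

    For each k = 1..n_components the residual of observation i under the
    k-component model is inflated by 1/(1 - h_i), where
    h_i = 1/n + t_i' (T'T)^-1 t_i from the k score columns.  Returns the mean
    squared corrected residual for each k, a fast approximation to
    leave-one-out cross-validated residual variance.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    Xc = X - model.grand_mean
    out = np.zeros(model.n_components)
    for k in range(1, model.n_components + 1):
        T = model.scores[:, :k]
        P = model.loadings[:k]
        G = T.T @ T
        h = 1.0 / n + np.einsum("ij,jk,ik->i", T, np.linalg.pinv(G), T)
        if np.any(h >= 1.0):
            raise ValueError(
                "degenerate leverage (h >= 1): an observation fully determines "
                "a component; validated variance undefined"
            )
        E = Xc - T @ P
        out[k - 1] = float(np.mean((E / (1.0 - h)[:, None]) ** 2))
    model.leverage_corrected_variance = out
    return out


def project(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Score new observations: (X_new - grand_mean) @ loadings.T."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.grand_mean.size:
        raise ValueError(
            f"variable count {X_new.shape[1]} does not match model "
            f"({model.grand_mean.size})"
        )
    return (X_new - model.grand_mean) @ model.loadings.T


def fit_lda(
    scores: np.ndarray,
    labels,
    k: int = 6,
    priors: np.ndarray | None = None,
) -> LDAModel:
    """Fit a two-class LDA on the first ``k`` score columns.

    The discriminant direction is w = pooledCov^-1 (mu_ACC - mu_PA); an
    observation is called ACC when w·x exceeds the threshold implied by the
    class means and (by default empirical) priors.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if scores.shape[0] != len(labels):
        raise ValueError("scores and labels lengths differ")
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds available score columns {scores.shape[1]}")
    Xk = scores[:, :k]
    y = np.asarray(labels)
    classes = (PA, ACC)
    masks = [y == c for c in classes]
    counts = np.array([m.sum() for m in masks])
    if np.any(counts == 0):
        raise ValueError("both classes (PA, ACC) must be present")
    if Xk.shape[0] <= k + 1:
        raise ValueError(
            f"need more than k+1={k + 1} observations to fit LDA with k={k}"
        )
    means = np.vstack([Xk[m].mean(axis=0) for m in masks])
    pooled = np.zeros((k, k))
    for m, c_mean in zip(masks, means):
        d = Xk[m] - c_mean
        pooled += d.T @ d
    pooled /= (Xk.shape[0] - 2)
    if priors is None:
        priors = counts / counts.sum()
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()

    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "pooled within-class covariance is singular; reduce the number of "
            "PC score predictors k"
        )
    w = np.linalg.solve(pooled, means[1] - means[0])
    # decide ACC when w·x > threshold
    threshold = float(w @ (means[0] + means[1]) / 2.0 - np.log(priors[1] / priors[0]))
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance=pooled,
        priors=priors,
        weights=w,
        threshold=threshold,
        n_predictors=k,
    )


def classify(model: LDAModel, scores: np.ndarray):
    """Labels and equal-covariance Gaussian posteriors for new score rows.

    Posterior columns follow ``model.classes`` order (PA, ACC); exact ties go
    to PA (the benign class).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))[:, : model.n_predictors]
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"score dimension {X.shape[1]} != model predictors {model.weights.size}"
        )
    g = X @ model.weights - model.threshold  # log posterior odds ACC vs PA
    p_acc = expit(g)
    posteriors = np.column_stack([1.0 - p_acc, p_acc])
    labels = [ACC if gi > 0 else PA for gi in g]
    return labels, posteriors


def _majority_vote(labels: list[str]) -> str:
    n_acc = sum(1 for l in labels if l == ACC)
    n_pa = len(labels) - n_acc
    return ACC if n_acc > n_pa else PA  # tie -> PA


def _sample_table(sset: SpectrumSet) -> tuple[list[str], dict[str, str]]:
    order: list[str] = []
    entity: dict[str, str] = {}
    for s in sset:
        if s.sample_id not in entity:
            entity[s.sample_id] = s.entity
            order.append(s.sample_id)
    return order, entity


def evaluate_samples(
    sset: SpectrumSet,
    mode: str = "sample_mean",
    validation: str = "leave_one_sample_out",
    n_components: int = 7,
    n_predictors: int = 6,
) -> tuple[ConfusionMatrix, dict]:
    """Per-sample PCA-LDA evaluation of a labeled spectrum set.

    mode
        ``sample_mean``: PCA-LDA is fitted on per-sample mean spectra (one
        observation per sample).  ``spectrum_vote``: fitted on single
        spectra; each sample receives the majority label of its spectra
        (tie -> PA).
    validation
        ``resubstitution``: predict the training observations.
        ``leave_one_sample_out``: refit PCA and LDA with every spectrum of
        the held-out sample excluded, one fold per sample.

    Returns the per-sample confusion matrix (positive class ACC) and a
    detail dict with per-sample true and predicted labels.
    """
    if mode not in ("sample_mean", "spectrum_vote"):
        raise ValueError(f"unknown mode {mode!r}")
    if validation not in ("resubstitution", "leave_one_sample_out"):
        raise ValueError(f"unknown validation {validation!r}")
    sample_order, sample_entity = _sample_table(sset)
    ents = list(sample_entity.values())
    if ents.count(PA) < 2 or ents.count(ACC) < 2:
        raise ValueError("need at least 2 samples per entity")

    if mode == "sample_mean":
        from .preprocess import mean_spectrum

        means = mean_spectrum(sset, group_by="sample")
        X = np.vstack([m.mean for m in means])
        row_samples = [m.group_key for m in means]
    else:
        X = sset.to_matrix()
        row_samples = sset.sample_ids()
    row_labels = [sample_entity[sid] for sid in row_samples]

    pred_by_sample: dict[str, str] = {}
    if validation == "resubstitution":
        pca = fit_pca_nipals(X, n_components=n_components)
        lda = fit_lda(pca.scores, row_labels, k=n_predictors)
        pred_rows, _ = classify(lda, pca.scores[:, :n_predictors])
        for sid in sample_order:
            votes = [p for p, rs in zip(pred_rows, row_samples) if rs == sid]
            pred_by_sample[sid] = _majority_vote(votes)
    else:
        for sid in sample_order:
            train = [i for i, rs in enumerate(row_samples) if rs != sid]
            test = [i for i, rs in enumerate(row_samples) if rs == sid]
            train_labels = [row_labels[i] for i in train]
            if PA not in train_labels or ACC not in train_labels:
                raise ValueError(
                    f"fold holding out {sid} leaves a class absent from training"
                )
            pca = fit_pca_nipals(X[train], n_components=n_components)
            lda = fit_lda(pca.scores, train_labels, k=n_predictors)
            test_scores = project(pca, X[test])[:, :n_predictors]
            pred_rows, _ = classify(lda, test_scores)
            pred_by_sample[sid] = _majority_vote(pred_rows)

    true_labels = [sample_entity[sid] for sid in sample_order]
    pred_labels = [pred_by_sample[sid] for sid in sample_order]
    cm = confusion_from_labels(true_labels, pred_labels, positive_class=ACC)
    detail = {
        "samples": sample_order,
        "true": true_labels,
        "predicted": pred_labels,
        "mode": mode,
        "validation": validation,
    }
    return cm, detail
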