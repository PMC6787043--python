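"""PCA feature compression and Gaussian linear discriminant classification.

The classification chain is the standard chemometric PCA-LDA stack:

* band features are mean-centered and eigendecomposed (covariance by
  default; a ``scale`` flag switches to the correlation matrix);
* the first ``k`` principal-component scores (default 3, which capture >98%
  of the band-table variance under the default generator) feed a linear
  discriminant with Gaussian class models sharing a pooled within-class
  covariance;
* prediction picks the class with the smallest expected misclassification
  cost — with the default 0/1 cost matrix this is the maximum-posterior
  rule;
* performance is assessed by leave-one-out cross-validation and reported as
  integer-percent sensitivity/specificity/accuracy with tumor as the
  positive class.

Everything here is deterministic; there is no randomness to seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .bands import FeatureTable
from .errors import InsufficientSampleError, SchemaError

CLASS_ORDER = ("healthy", "tumor")


# -- PCA --------------------------------------------------------------------

@dataclass
class PCAModel:
    """Eigendecomposition of the (optionally autoscaled) feature covariance.

    Loadings columns are unit-norm eigenvectors sorted by descending
    eigenvalue, sign-fixed so each column's largest-magnitude entry is
    positive.  ``percent`` is each eigenvalue's share of total variance
    (x100); ``cum_percent`` the running sum.
    """

    feature_names: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray  # ones unless fitted on correlations
    loadings: np.ndarray  # (n_features, n_components)
    eigenvalues: np.ndarray
    percent: np.ndarray
    cum_percent: np.ndarray
    scaled: bool = False

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(features: FeatureTable, scale: bool = False) -> PCAModel:
    """Fit PCA on mean-centered band features.

    ``scale=True`` autoscales each feature to unit variance first, i.e.
    decomposes the correlation rather than the covariance matrix.  Constant
    columns and rank deficiency (n_rows <= n_cols) are warned about, not
    fatal; rank deficiency shows up as trailing ~zero eigenvalues.
    """
    X = features.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientSampleError(f"PCA needs >= 3 rows, got {n}")
    if p < 2:
        raise InsufficientSampleError(f"PCA needs >= 2 features, got {p}")
    if not np.all(np.isfinite(X)):
        raise SchemaError("feature table contains missing/non-finite values")

    means = X.mean(axis=0)
    Xc = X - means
    sds = Xc.std(axis=0, ddof=1)
    if np.any(sds == 0):
        constant = [features.band_names[i] for i in np.flatnonzero(sds == 0)]
        warnings.warn(
            f"constant feature column(s) {constant}: zero-variance direction",
            stacklevel=2,
        )
    if scale:
        scales = np.where(sds > 0, sds, 1.0)
        Xc = Xc / scales
    else:
        scales = np.ones(p)
    if n <= p:
        warnings.warn(
            f"rank-deficient table (n={n} <= p={p}); trailing eigenvalues ~0",
            stacklevel=2,
        )

    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|.| entry of each loading column positive
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    total = eigvals.sum()
    percent = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModel(
        feature_names=features.band_names,
        feature_means=means,
        feature_scales=scales,
        loadings=eigvecs,
        eigenvalues=eigvals,
        percent=percent,
        cum_percent=np.cumsum(percent),
        scaled=scale,
    )


def project(model: PCAModel, features: FeatureTable, k: int = 3) -> pd.DataFrame:
    """Score table: centered (optionally scaled) features times loadings."""
    if not 1 <= k <= model.n_components:
        raise SchemaError(
            f"k must be in [1, {model.n_components}], got {k}"
        )
    if features.band_names != model.feature_names:
        raise SchemaError(
            "feature columns do not match the fitted PCA model: "
            f"{features.band_names} vs {model.feature_names}"
        )
    X = features.values.to_numpy(dtype=float)
    scores = ((X - model.feature_means) / model.feature_scales) @ model.loadings[:, :k]
    return pd.DataFrame(
        scores, index=features.values.index, columns=[f"PC{j + 1}" for j in range(k)]
    )


# -- LDA --------------------------------------------------------------------

@dataclass
class LDAModel:
    """Gaussian discriminant with pooled within-class covariance."""

    class_names: tuple[str, str]
    class_means: np.ndarray  # (2, k)
    pooled_cov: np.ndarray  # (k, k)
    priors: np.ndarray  # (2,)
    costs: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1.0], [1.0, 0.0]])
    )
    ridge: float = 0.0  # stabilization actually added, for audit

    @property
    def dim(self) -> int:
        return self.class_means.shape[1]


def fit_lda(
    scores: pd.DataFrame | np.ndarray,
    labels: "pd.Series | list[str]",
    priors: np.ndarray | None = None,
    costs: np.ndarray | None = None,
) -> LDAModel:
    """Estimate class means and the pooled (n-2 denominator) covariance.

    Priors default to empirical class fractions.  A singular pooled
    covariance is ridge-stabilized with 1e-8 * trace/dim (warned, recorded
    on the model).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    masks = [y == c for c in CLASS_ORDER]
    counts = np.array([int(m.sum()) for m in masks])
    if np.any(counts < 2):
        raise InsufficientSampleError(
            f"LDA needs >= 2 members per class, got {dict(zip(CLASS_ORDER, counts))}"
        )
    n = counts.sum()
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    pooled = np.zeros((X.shape[1], X.shape[1]))
    for m, mu in zip(masks, means):
        D = X[m] - mu
        pooled += D.T @ D
    pooled /= n - 2

    ridge = 0.0
    try:
        np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(pooled) / pooled.shape[0]
        if ridge <= 0:
            ridge = 1e-12
        pooled = pooled + ridge * np.eye(pooled.shape[0])
        warnings.warn(
            f"singular pooled covariance; added ridge {ridge:g}", stacklevel=2
        )

    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    if costs is None:
        costs = np.array([[0.0, 1.0], [1.0, 0.0]])
    return LDAModel(
        class_names=CLASS_ORDER,
        class_means=means,
        pooled_cov=pooled,
        priors=priors,
        costs=np.asarray(costs, dtype=float),
        ridge=ridge,
    )


def predict_lda(
    model: LDAModel, scores: pd.DataFrame | np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Minimum-expected-cost class assignment plus posterior(tumor).

    Posteriors come from the shared-covariance Gaussian likelihoods and the
    priors; expected cost of deciding class c is sum_j posterior_j *
    costs[j, c].  Ties break to the first class in fixed order (healthy).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.dim:
        raise SchemaError(
            f"score dimension {X.shape[1]} does not match model ({model.dim})"
        )
    L = np.linalg.cholesky(model.pooled_cov)
    loglik = np.empty((X.shape[0], 2))
    for j, mu in enumerate(model.class_means):
        w = solve_triangular(L, (X - mu).T, lower=True)
        loglik[:, j] = -0.5 * np.sum(w * w, axis=0)
    logpost = loglik + np.log(model.priors)
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)

    expected_cost = post @ model.costs  # (n, 2): cost of deciding each class
    # argmin with first-class tie-break (argmin already takes first minimum)
    decisions = np.argmin(expected_cost, axis=1)
    labels = [model.class_names[d] for d in decisions]
    return labels, post[:, 1]


# -- metrics ----------------------------------------------------------------

def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def compute_metrics(hh: int, ht: int, th: int, tt: int) -> tuple[int, int, int]:
    """(sensitivity %, specificity %, accuracy %) from confusion counts.

    ``hh``: healthy classified healthy, ``ht``: healthy classified tumor,
    ``th``: tumor classified healthy, ``tt``: tumor classified tumor.
    Tumor is the positive class; percentages round half away from zero.
    An empty class denominator makes the affected metric None-like by
    raising — callers must handle cohorts with one class explicitly.
    """
    counts = (hh, ht, th, tt)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be >= 0")
    n = sum(counts)
    if n < 1:
        raise InsufficientSampleError("empty confusion matrix")
    if tt + th == 0 or hh + ht == 0:
        raise InsufficientSampleError(
            "a class denominator is empty; sensitivity/specificity undefined"
        )
    sens = _round_half_away(100.0 * tt / (tt + th))
    spec = _round_half_away(100.0 * hh / (hh + ht))
    acc = _round_half_away(100.0 * (hh + tt) / n)
    return sens, spec, acc


@dataclass
class ClassificationReport:
    """Confusion counts, integer-percent metrics, per-sample posteriors."""

    hh: int
    ht: int
    th: int
    tt: int
    sensitivity: int
    specificity: int
    accuracy: int
    per_sample: pd.DataFrame  # id, true label, predicted label, posterior_tumor
    skipped_folds: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.hh + self.ht + self.th + self.tt

    @classmethod
    def from_predictions(
        cls,
        ids: list[str],
        true_labels: list[str],
        predicted: list[str],
        posterior_tumor: np.ndarray,
        skipped: list[str] | None = None,
    ) -> "ClassificationReport":
        hh = ht = th = tt = 0
        for t, p in zip(true_labels, predicted):
            if t == "healthy":
                hh, ht = (hh + 1, ht) if p == "healthy" else (hh, ht + 1)
            elif t == "tumor":
                th, tt = (th + 1, tt) if p == "healthy" else (th, tt + 1)
        sens, spec, acc = compute_metrics(hh, ht, th, tt)
        per_sample = pd.DataFrame(
            {
                "site_id": ids,
                "true_label": true_labels,
                "predicted": predicted,
                "posterior_tumor": posterior_tumor,
            }
        )
        return cls(hh, ht, th, tt, sens, spec, acc, per_sample, skipped or [])

    def to_dict(self) -> dict:
        return {
            "confusion": {"hh": self.hh, "ht": self.ht, "th": self.th, "tt": self.tt},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n": self.n,
            "skipped_folds": self.skipped_folds,
            "per_sample": self.per_sample.to_dict(orient="records"),
        }


# -- leave-one-out cross-validation ----------------------------------------

def loo_cross_validate(
    features: FeatureTable,
    k: int = 3,
    refit_pca_per_fold: bool = True,
    scale: bool = False,
    priors: np.ndarray | None = None,
) -> ClassificationReport:
    """Leave-one-out PCA-LDA evaluation of a healthy/tumor feature table.

    Rows labeled neither healthy nor tumor (e.g. mixed sites) are excluded:
    mixed tissue is never a training class and is reported only through its
    continuous posterior elsewhere.  With ``refit_pca_per_fold`` (default),
    the PCA is refit inside every fold; otherwise it is fit once on the full
    table and only the LDA is refit, mirroring a fixed feature extraction.
    Deterministic: no randomness anywhere.
    """
    keep = np.asarray(features.labels.isin(CLASS_ORDER))
    ft = features.subset(keep)
    y = ft.labels.to_numpy()
    n = ft.n
    if n < 4:
        raise InsufficientSampleError(f"LOO needs >= 4 samples, got {n}")
    counts = {c: int((y == c).sum()) for c in CLASS_ORDER}
    if any(v < 2 for v in counts.values()):
        raise InsufficientSampleError(
            f"LOO needs >= 2 members per class, got {counts}"
        )

    fixed_pca = None if refit_pca_per_fold else fit_pca(ft, scale=scale)

    ids, trues, preds, posts, skipped = [], [], [], [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = ft.subset(mask)
        train_counts = train.labels.value_counts()
        if any(train_counts.get(c, 0) < 2 for c in CLASS_ORDER):
            warnings.warn(
                f"fold {i} leaves a class with <2 members; skipped",
                stacklevel=2,
            )
            skipped.append(str(ft.values.index[i]))
            continue
        pca = fit_pca(train, scale=scale) if fixed_pca is None else fixed_pca
        lda = fit_lda(project(pca, train, k=k), train.labels, priors=priors)
        test = ft.subset(~mask)
        label, post = predict_lda(lda, project(pca, test, k=k))
        ids.append(str(ft.values.index[i]))
        trues.append(str(y[i]))
        preds.append(label[0])
        posts.append(float(post[0]))
    return ClassificationReport.from_predictions(
        ids, trues, preds, np.array(posts), skipped
    )
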