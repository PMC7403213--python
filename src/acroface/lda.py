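"""Two-class linear discriminant analysis with out-of-sample evaluation.

Authored from first principles: the discriminant weight solves
``(S_pooled + ridge I) w = mu_patient - mu_control`` with the pooled
within-class covariance, the decision threshold lies midway between the
projected class means shifted by the log prior ratio (equal priors by
default), and accuracy is assessed by leave-one-out cross-validation with
z-scoring refit inside every training fold so the held-out subject never
leaks into the model.  Statistical inference on the LOOCV accuracy uses a
label-permutation null with the add-one p-value estimator
``(1 + #{null >= observed}) / (B + 1)``.  Standardized loading magnitudes
(full-sample fit on z-scored features) rank the contribution of each
variable, and Box's M with its chi-square approximation checks the
covariance-homogeneity assumption.

Class label convention: "patient" is the positive class, "control" negative;
a discriminant score of exactly zero is classified control (deterministic
tie rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationParams",
    "LdaModel",
    "CvResult",
    "PermutationResult",
    "LoadingTable",
    "BoxMResult",
    "zscore_fit",
    "zscore_apply",
    "lda_fit",
    "lda_predict",
    "loocv",
    "permutation_test",
    "loadings",
    "box_m_test",
]

POSITIVE, NEGATIVE = "patient", "control"


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean/SD estimated on a stated fitting set."""

    feature_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    dropped: tuple[str, ...] = ()


def zscore_fit(X: np.ndarray, feature_ids: Sequence[str] | None = None) -> StandardizationParams:
    """Estimate z-scoring parameters; zero-SD features are dropped with a warning."""
    X = np.asarray(X, float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("z-scoring needs a 2D array with >= 2 rows")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"f{i}" for i in range(X.shape[1]))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(np.asarray(ids)[~keep])
    if dropped:
        logger.warning("dropping zero-variance features: %s", dropped)
    return StandardizationParams(
        tuple(np.asarray(ids)[keep]), mean[keep], sd[keep], dropped)


def zscore_apply(params: StandardizationParams, X: np.ndarray,
                 feature_ids: Sequence[str] | None = None) -> np.ndarray:
    """Apply fitted z-scoring; columns are selected by id when ids are given."""
    X = np.asarray(X, float)
    if feature_ids is not None:
        idx = [list(feature_ids).index(f) for f in params.feature_ids]
        X = X[:, idx]
    elif params.dropped:
        raise ValueError("feature_ids required to select retained columns")
    return (X - params.mean) / params.sd


# ---------------------------------------------------------------------------
# LDA core
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LdaModel:
    feature_ids: tuple[str, ...]
    mean_positive: np.ndarray
    mean_negative: np.ndarray
    pooled_cov: np.ndarray
    ridge: float
    weights: np.ndarray
    threshold: float
    priors: tuple[float, float]  # (positive, negative)

    def to_json(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "mean_positive": self.mean_positive.tolist(),
            "mean_negative": self.mean_negative.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "ridge": self.ridge,
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "priors": list(self.priors),
        }


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    lab = np.asarray(labels)
    bad = set(np.unique(lab)) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"labels must be patient/control, got {sorted(bad)}")
    return lab == POSITIVE


def lda_fit(
    X: np.ndarray,
    labels: Sequence[str],
    ridge: float | None = None,
    priors: tuple[float, float] | None = None,
    feature_ids: Sequence[str] | None = None,
) -> LdaModel:
    """Fit the two-class discriminant from pooled within-class covariance.

    ``ridge`` scales the identity added to the pooled covariance; the default
    is 1e-6 × its mean diagonal, which keeps near-singular problems (p close
    to n) solvable while perturbing well-conditioned ones negligibly.  Pass
    ``ridge=0`` to forbid regularization (raises on a singular covariance).
    Priors default to equal.
    """
    X = np.asarray(X, float)
    pos = _as_binary(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both classes need >= 2 rows")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"f{i}" for i in range(X.shape[1]))
    X1, X0 = X[pos], X[~pos]
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    S = ((n1 - 1) * np.cov(X1, rowvar=False, ddof=1)
         + (n0 - 1) * np.cov(X0, rowvar=False, ddof=1)) / (n1 + n0 - 2)
    S = np.atleast_2d(S)
    if ridge is None:
        ridge = 1e-6 * float(np.mean(np.diag(S)))
    Sr = S + ridge * np.eye(S.shape[0])
    try:
        w = np.linalg.solve(Sr, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass ridge > 0") from exc
    if priors is None:
        priors = (0.5, 0.5)
    # score(x) = w.(x - (mu1+mu0)/2) + log(pi1/pi0); threshold folds both in.
    threshold = float(w @ (mu1 + mu0) / 2.0 - np.log(priors[0] / priors[1]))
    return LdaModel(ids, mu1, mu0, S, float(ridge), w, threshold, priors)


def lda_predict(model: LdaModel, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and discriminant scores for one or more feature rows.

    Score > 0 → patient; score <= 0 → control (ties go to control).
    """
    rows = np.atleast_2d(np.asarray(rows, float))
    if rows.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} features, got {rows.shape[1]}")
    scores = rows @ model.weights - model.threshold
    pred = np.where(scores > 0, POSITIVE, NEGATIVE)
    return pred, scores


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    subjects: list[str]
    true_labels: np.ndarray
    predicted: np.ndarray
    unpredictable: list[str] = field(default_factory=list)

    @property
    def confusion(self) -> pd.DataFrame:
        """Rows: predicted; columns: true (control, patient)."""
        classes = [NEGATIVE, POSITIVE]
        mat = pd.DataFrame(0, index=classes, columns=classes)
        for t, p in zip(self.true_labels, self.predicted):
            if p != "":
                mat.loc[p, t] += 1
        return mat

    @property
    def accuracy(self) -> float:
        mask = self.predicted != ""
        if not mask.any():
            return float("nan")
        return float((self.predicted[mask] == self.true_labels[mask]).mean())

    def to_json(self) -> dict:
        return {
            "subjects": self.subjects,
            "true": self.true_labels.tolist(),
            "predicted": self.predicted.tolist(),
            "unpredictable": self.unpredictable,
            "confusion": {p: {t: int(self.confusion.loc[p, t])
                              for t in self.confusion.columns}
                          for p in self.confusion.index},
            "accuracy": self.accuracy,
        }


def loocv(
    X: np.ndarray,
    labels: Sequence[str],
    ridge: float | None = None,
    priors: tuple[float, float] | None = None,
    subjects: Sequence[str] | None = None,
    feature_ids: Sequence[str] | None = None,
    standardize: str = "fold",
) -> CvResult:
    """Leave-one-out accuracy of the discriminant.

    For every subject the model — including the z-scoring parameters when
    ``standardize="fold"`` (default) — is refit on the remaining n-1 rows and
    the held-out row is predicted.  ``standardize="global"`` z-scores once on
    the full sample (fidelity mode), ``"none"`` skips scaling.  A fold whose
    training set loses an entire class leaves that subject unpredictable and
    excluded from the accuracy with a warning.
    """
    X = np.asarray(X, float)
    lab = np.asarray(labels)
    _as_binary(lab)
    n = len(X)
    if n < 4:
        raise ValueError("LOOCV needs n >= 4")
    subs = list(subjects) if subjects is not None else [str(i) for i in range(n)]
    ids = list(feature_ids) if feature_ids is not None else [
        f"f{i}" for i in range(X.shape[1])]
    if standardize == "global":
        params = zscore_fit(X, ids)
        Xg = zscore_apply(params, X, ids)
        ids_g = list(params.feature_ids)
    preds = np.empty(n, dtype=object)
    unpredictable = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        ytr = lab[mask]
        if len(np.unique(ytr)) < 2 or min(
                (ytr == POSITIVE).sum(), (ytr == NEGATIVE).sum()) < 2:
            preds[i] = ""
            unpredictable.append(subs[i])
            logger.warning("subject %s unpredictable: training fold lost a class", subs[i])
            continue
        if standardize == "fold":
            params = zscore_fit(X[mask], ids)
            Xtr = zscore_apply(params, X[mask], ids)
            Xte = zscore_apply(params, X[i : i + 1], ids)
            fids = list(params.feature_ids)
        elif standardize == "global":
            Xtr, Xte, fids = Xg[mask], Xg[i : i + 1], ids_g
        elif standardize == "none":
            Xtr, Xte, fids = X[mask], X[i : i + 1], ids
        else:
            raise ValueError(f"unknown standardization mode {standardize!r}")
        model = lda_fit(Xtr, ytr, ridge=ridge, priors=priors, feature_ids=fids)
        preds[i] = lda_predict(model, Xte)[0][0]
    return CvResult(subs, lab.copy(), preds.astype(str), unpredictable)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    B: int
    null_accuracies: np.ndarray
    observed_accuracy: float
    p_value: float
    seed: int

    def to_json(self) -> dict:
        return {
            "B": self.B,
            "null_accuracies": self.null_accuracies.tolist(),
            "observed_accuracy": self.observed_accuracy,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def permutation_test(
    X: np.ndarray,
    labels: Sequence[str],
    B: int = 10_000,
    seed: int = 0,
    ridge: float | None = None,
    priors: tuple[float, float] | None = None,
    standardize: str = "fold",
) -> PermutationResult:
    """Label-permutation null for the LOOCV accuracy.

    Each of the B permutations uniformly shuffles the group labels and reruns
    the complete leave-one-out procedure; the p-value is the add-one
    estimator (1 + #{null >= observed}) / (B + 1).  Fully reproducible from
    ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    lab = np.asarray(labels)
    observed = loocv(X, lab, ridge=ridge, priors=priors, standardize=standardize).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(lab)
        null[b] = loocv(X, perm, ridge=ridge, priors=priors,
                        standardize=standardize).accuracy
    p = (1.0 + float((null >= observed).sum())) / (B + 1.0)
    return PermutationResult(B, null, observed, p, seed)


# ---------------------------------------------------------------------------
# Loadings
# ---------------------------------------------------------------------------


@dataclass
class LoadingTable:
    table: pd.DataFrame  # index feature id; columns loading, abs_loading, rank

    def top(self, k: int) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank")


def loadings(
    X: np.ndarray,
    labels: Sequence[str],
    ridge: float | None = None,
    feature_ids: Sequence[str] | None = None,
) -> LoadingTable:
    """Standardized discriminant loadings from a full-sample z-scored fit.

    Features are ranked by absolute loading, ties broken lexicographically by
    feature id for determinism.
    """
    X = np.asarray(X, float)
    ids = list(feature_ids) if feature_ids is not None else [
        f"f{i}" for i in range(X.shape[1])]
    params = zscore_fit(X, ids)
    Z = zscore_apply(params, X, ids)
    model = lda_fit(Z, labels, ridge=ridge, feature_ids=list(params.feature_ids))
    df = pd.DataFrame(
        {"loading": model.weights, "abs_loading": np.abs(model.weights)},
        index=list(params.feature_ids),
    )
    order = sorted(range(len(df)), key=lambda i: (-df["abs_loading"].iloc[i], df.index[i]))
    df = df.iloc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return LoadingTable(df)


# ---------------------------------------------------------------------------
# Box's M
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxMResult:
    m_statistic: float
    chi2: float
    df: int
    p_value: float


def box_m_test(X: np.ndarray, labels: Sequence[str]) -> BoxMResult:
    """Box's M test of covariance homogeneity (chi-square approximation).

    For g groups with p features, M = (N - g) ln|S_pooled| - Σ (n_i - 1)
    ln|S_i|, scaled by the Box correction factor and referred to chi-square
    with (g - 1) p (p + 1) / 2 df.  Requires each class to have more rows
    than features so the class covariances are nonsingular.
    """
    X = np.asarray(X, float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    p = X.shape[1]
    groups = [X[lab == c] for c in classes]
    if any(len(g) <= p for g in groups):
        raise ValueError(
            "Box's M needs n > p in every class; reduce the feature set or "
            "use a regularized analysis instead")
    g = len(groups)
    ns = np.array([len(gr) for gr in groups])
    N = int(ns.sum())
    covs = [np.cov(gr, rowvar=False, ddof=1) for gr in groups]
    S_pooled = sum((n - 1) * C for n, C in zip(ns, covs)) / (N - g)
    sign, logdet_pooled = np.linalg.slogdet(np.atleast_2d(S_pooled))
    if sign <= 0:
        raise ValueError("pooled covariance is singular")
    M = (N - g) * logdet_pooled
    for n, C in zip(ns, covs):
        s, ld = np.linalg.slogdet(np.atleast_2d(C))
        if s <= 0:
            raise ValueError("a class covariance is singular")
        M -= (n - 1) * ld
    c1 = ((2 * p * p + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))) * (
        np.sum(1.0 / (ns - 1)) - 1.0 / (N - g))
    df = (g - 1) * p * (p + 1) // 2
    chi2 = M * (1.0 - c1)
    from scipy import stats as sps

    return BoxMResult(float(M), float(chi2), int(df), float(sps.chi2.sf(chi2, df)))
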