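"""Canonical discriminant analysis of PSD shapes and centroid geometry.

Each sliding-window PSD is one trial; its power values across frequency
bins are the features; the composite (group, nerve) class is the label.
Canonical variables CAN1..CANk are the directions that maximise
between-class relative to within-class scatter — the eigenvectors of
the generalized problem

    B v = lambda W v,

with B the between-class and W the within-class scatter matrix.  CAN1
carries the most significant one-way ANOVA F ratio; each subsequent
canonical variable maximises separation in the W-orthogonal complement
of the previous ones.

Frequency bins can outnumber trials, making W singular, so features are
first projected onto the principal components retaining 99% of variance
(capped at n - n_classes); coefficients are mapped back to frequency
space for interpretability.  A diagonal shrinkage of W is the fallback
if the reduced problem is still singular.

Canonical scores are scaled so that their pooled within-class covariance
is the identity, which makes Euclidean distance between class centroids
a Mahalanobis-type separation measure.  The BAS/BIC ratio of centroid
distances quantifies how strongly disinhibition collapses the spectral
patterns toward a shared rhythm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sstats

from .errors import ArgumentError, InsufficientDataError
from .spectral import Spectrogram

#: Canonical ordering of the six composite classes in all outputs.
CLASS_ORDER = ("R-CTRL", "R-2K1C", "R-LOS", "S-CTRL", "S-2K1C", "S-LOS")

LOG_FLOOR = 1e-300


@dataclass
class FeatureMatrix:
    """Trials-by-frequency-power features with class labels per trial."""

    X: np.ndarray
    labels: np.ndarray  # class label per row
    freq_grid: np.ndarray
    transform: str = "log10"
    animal_ids: np.ndarray | None = None  # per-row animal id, for stratified holdout

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != len(self.labels):
            raise ArgumentError("rows of X and labels must align")
        if not np.all(np.isfinite(self.X)):
            raise ArgumentError("features must be finite")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise InsufficientDataError("need at least 2 classes")
        if np.any(counts < 2):
            bad = classes[counts < 2]
            raise InsufficientDataError(f"classes with < 2 trials: {list(bad)}")

    @property
    def classes(self) -> list[str]:
        present = set(np.unique(self.labels).tolist())
        ordered = [c for c in CLASS_ORDER if c in present]
        return ordered + sorted(present - set(ordered))


def build_feature_matrix(
    spectrograms: list[Spectrogram],
    channel: str,
    freq_range: tuple[float, float],
    transform: str = "log10",
) -> FeatureMatrix:
    """Pool sliding-window PSD rows of one channel into a trials-by-bins matrix.

    Rows keep their animal of origin so held-out evaluation can be
    stratified per animal; the class label is the composite
    (group, nerve) tag, independent of condition.
    """
    if channel not in ("envelope", "burst"):
        raise ArgumentError("channel must be 'envelope' or 'burst'")
    if transform not in ("linear", "log10"):
        raise ArgumentError("transform must be 'linear' or 'log10'")
    selected = [sg for sg in spectrograms if sg.channel == channel]
    if not selected:
        raise ArgumentError(f"no spectrograms with channel {channel!r}")
    freqs = selected[0].freqs
    lo, hi = freq_range
    mask = (freqs >= lo) & (freqs < hi)
    if not np.any(mask):
        raise ArgumentError(f"freq_range {freq_range} selects no bins")
    rows, labels, animals = [], [], []
    for sg in selected:
        if len(sg.freqs) != len(freqs) or not np.allclose(sg.freqs, freqs):
            raise ArgumentError("spectrogram frequency grids differ")
        block = sg.power[:, mask]
        rows.append(block)
        labels.extend([sg.labels.class_label()] * block.shape[0])
        animals.extend([sg.labels.animal_id] * block.shape[0])
    X = np.vstack(rows)
    if transform == "log10":
        X = np.log10(np.maximum(X, LOG_FLOOR))
    return FeatureMatrix(X, np.array(labels), freqs[mask], transform, np.array(animals))


@dataclass
class CDAModel:
    """Fitted canonical discriminant directions, scores and class geometry."""

    coefficients: np.ndarray  # (n_features, k): canonical directions in feature space
    eigenvalues: np.ndarray  # top-k, non-increasing
    eigenvalues_all: np.ndarray  # all min(c-1, p_effective) eigenvalues
    scores: np.ndarray  # (n_trials, k)
    labels: np.ndarray
    class_labels: list[str]
    feature_mean: np.ndarray
    n_effective_features: int  # dimensionality after pre-projection
    preprojection: np.ndarray | None = None  # (n_features, m) orthonormal basis

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new feature rows into canonical space."""
        return (np.asarray(X, dtype=float) - self.feature_mean) @ self.coefficients


def _scatter_matrices(Z: np.ndarray, labels: np.ndarray):
    """Within-class (W) and between-class (B) scatter of pre-projected features."""
    m = Z.shape[1]
    W = np.zeros((m, m))
    B = np.zeros((m, m))
    grand = Z.mean(axis=0)
    for cls in np.unique(labels):
        Zc = Z[labels == cls]
        mu = Zc.mean(axis=0)
        D = Zc - mu
        W += D.T @ D
        d = (mu - grand)[:, None]
        B += len(Zc) * (d @ d.T)
    return W, B


def fit_cda(
    features: FeatureMatrix,
    k: int = 3,
    pre_var: float = 0.99,
    shrinkage: float | None = None,
) -> CDAModel:
    """Solve B v = lambda W v on PCA-pre-projected features.

    Eigenvalues are returned in non-increasing order; canonical vectors
    are scaled so the pooled within-class covariance of the scores is
    the identity, and their sign is fixed by making the largest-|.|
    feature-space coefficient positive.
    """
    X = features.X
    labels = features.labels
    classes = features.classes
    c = len(classes)
    n, p = X.shape
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if k > c - 1:
        warnings.warn(
            f"k={k} exceeds classes-1={c - 1}; truncating", RuntimeWarning, stacklevel=2
        )
        k = c - 1

    mean = X.mean(axis=0)
    Xc = X - mean

    # PCA pre-projection: keep components explaining pre_var of variance,
    # capped so W stays full rank (m <= n - c).
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise InsufficientDataError("features have zero variance")
    nonzero = var > max(1e-12 * var[0], 0.0)
    cum = np.cumsum(var) / total
    m = int(np.searchsorted(cum, pre_var) + 1)
    m = max(1, min(m, int(nonzero.sum()), n - c))
    P = Vt[:m].T
    Z = Xc @ P

    W, B = _scatter_matrices(Z, labels)
    if shrinkage is None:
        try:
            evals, evecs = linalg.eigh(B, W)
        except linalg.LinAlgError:
            eps = 1e-8 * np.trace(W) / m
            warnings.warn(
                "singular within-class scatter after pre-projection; "
                f"applying diagonal shrinkage eps={eps:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
            evals, evecs = linalg.eigh(B, W + eps * np.eye(m))
    else:
        evals, evecs = linalg.eigh(B, W + shrinkage * np.eye(m))

    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    s_dims = min(c - 1, m)
    evals_all = evals[:s_dims]
    k_eff = min(k, s_dims)
    V = evecs[:, :k_eff] * np.sqrt(n - c)  # v' (W/(n-c)) v = 1: unit within-class variance

    coef = P @ V
    for j in range(coef.shape[1]):
        i = int(np.argmax(np.abs(coef[:, j])))
        if coef[i, j] < 0:
            coef[:, j] = -coef[:, j]
            V[:, j] = -V[:, j]

    scores = Xc @ coef
    return CDAModel(
        coefficients=coef,
        eigenvalues=evals_all[:k_eff],
        eigenvalues_all=evals_all,
        scores=scores,
        labels=labels,
        class_labels=classes,
        feature_mean=mean,
        n_effective_features=m,
        preprojection=P,
    )


def dimension_test(model: CDAModel, alpha: float = 0.05) -> pd.DataFrame:
    """Sequential Wilks' Lambda test of canonical dimensionality.

    Dimension d tests whether class means differ beyond the first d-1
    canonical directions: Lambda_d = prod_{i>=d} 1/(1+lambda_i), with
    Bartlett's chi-square approximation
    chi2 = (n - 1 - (p + c)/2) * (-ln Lambda_d) on (p - d + 1)(c - d)
    degrees of freedom, where p is the post-projection feature count.
    """
    lam = model.eigenvalues_all
    n = model.scores.shape[0]
    c = len(model.class_labels)
    p = model.n_effective_features
    if c < 2:
        raise ArgumentError("dimension test needs at least 2 classes")
    if n <= p + c:
        raise InsufficientDataError(
            f"only {n} trials for {p} features and {c} classes; "
            "use a stronger pre-projection (lower pre_var)"
        )
    rows = []
    factor = n - 1 - (p + c) / 2.0
    for d in range(1, len(lam) + 1):
        wilks = float(np.prod(1.0 / (1.0 + lam[d - 1 :])))
        chi2 = -factor * np.log(max(wilks, np.finfo(float).tiny))
        df = (p - d + 1) * (c - d)
        pval = float(sstats.chi2.sf(chi2, df))
        rows.append(
            {
                "dimension": d,
                "wilks_lambda": wilks,
                "chi2": float(chi2),
                "df": df,
                "p_value": pval,
                "significant": pval < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CentroidGeometry:
    """Class centroids in canonical space with pairwise Euclidean distances."""

    class_labels: list[str]
    centroids: np.ndarray  # (n_classes, k)
    distance_matrix: np.ndarray  # (n_classes, n_classes)
    condition_tag: str | None = None

    def distances_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.distance_matrix, index=self.class_labels, columns=self.class_labels)


def centroid_geometry(model: CDAModel, condition_tag: str | None = None) -> CentroidGeometry:
    """Per-class mean score vectors and their pairwise Euclidean distances."""
    if len(model.class_labels) < 2:
        raise ArgumentError("need at least 2 classes")
    cents = np.vstack(
        [model.scores[model.labels == cls].mean(axis=0) for cls in model.class_labels]
    )
    diff = cents[:, None, :] - cents[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    return CentroidGeometry(list(model.class_labels), cents, D, condition_tag)


@dataclass
class DistanceContraction:
    """Per-pair BAS/BIC centroid-distance ratios and their maximum."""

    class_labels: list[str]
    ratio_matrix: np.ndarray
    max_ratio: float
    has_infinite: bool
    table: pd.DataFrame


def distance_contraction(geometry_bas: CentroidGeometry, geometry_bic: CentroidGeometry) -> DistanceContraction:
    """Elementwise d_BAS / d_BIC for every class pair.

    A zero BIC distance (fully collapsed pair) yields an infinite ratio,
    flagged rather than raised.
    """
    if geometry_bas.class_labels != geometry_bic.class_labels:
        raise ArgumentError("geometries cover different class sets")
    labels = geometry_bas.class_labels
    nc = len(labels)
    d_bas = geometry_bas.distance_matrix
    d_bic = geometry_bic.distance_matrix
    ratio = np.full((nc, nc), np.nan)
    rows = []
    has_inf = False
    for i in range(nc):
        for j in range(nc):
            if i == j:
                continue
            if d_bic[i, j] == 0.0:
                ratio[i, j] = np.inf
                has_inf = True
            else:
                ratio[i, j] = d_bas[i, j] / d_bic[i, j]
            if i < j:
                rows.append(
                    {
                        "pair": f"{labels[i]}|{labels[j]}",
                        "d_bas": d_bas[i, j],
                        "d_bic": d_bic[i, j],
                        "ratio": ratio[i, j],
                    }
                )
    off = ratio[~np.eye(nc, dtype=bool)]
    return DistanceContraction(labels, ratio, float(np.max(off)), has_inf, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# held-out evaluation


def split_feature_matrix(
    features: FeatureMatrix, holdout: str = "windows", fraction: float = 0.2
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Split into a training FeatureMatrix and held-out (X, labels).

    ``holdout='windows'`` holds out every round(1/fraction)-th row;
    ``holdout='animals'`` holds out the highest animal id within each
    class (stratified per-animal holdout, the guard against
    pseudo-replication from correlated windows).
    """
    n = features.X.shape[0]
    if holdout == "windows":
        every = max(2, int(round(1.0 / fraction)))
        test_mask = np.zeros(n, dtype=bool)
        test_mask[::every] = True
    elif holdout == "animals":
        if features.animal_ids is None:
            raise ArgumentError("feature matrix carries no animal ids")
        test_mask = np.zeros(n, dtype=bool)
        for cls in np.unique(features.labels):
            cls_mask = features.labels == cls
            held = features.animal_ids[cls_mask].max()
            test_mask |= cls_mask & (features.animal_ids == held)
    else:
        raise ArgumentError("holdout must be 'windows' or 'animals'")
    train = FeatureMatrix(
        features.X[~test_mask],
        features.labels[~test_mask],
        features.freq_grid,
        features.transform,
        None if features.animal_ids is None else features.animal_ids[~test_mask],
    )
    return train, features.X[test_mask], features.labels[test_mask]


def nearest_centroid_accuracy(model: CDAModel, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Fraction of held-out rows whose nearest class centroid matches their label."""
    cents = np.vstack(
        [model.scores[model.labels == cls].mean(axis=0) for cls in model.class_labels]
    )
    Z = model.transform(X_test)
    d2 = ((Z[:, None, :] - cents[None, :, :]) ** 2).sum(axis=-1)
    pred = np.asarray(model.class_labels)[np.argmin(d2, axis=1)]
    return float(np.mean(pred == np.asarray(y_test)))
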