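"""Amplitude-topography decoding of travel direction.

For a bimodal (bidirectional) oscillation, timepoints traveling within 45
degrees of either preferred direction form two classes. The per-electrode
analytic amplitudes at those timepoints (up to 32 features) train a
5-fold cross-validated linear SVM to predict the instantaneous travel
direction; significance is assessed against a label-shuffle null (the
same training procedure with permuted class labels), the observed mean
held-out accuracy being significant when it exceeds the null's 99th
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synth import GridGeometry
from .wavefit import AnalyticBand

__all__ = [
    "ClassifierDataset",
    "ClassifierResult",
    "build_dataset",
    "train_evaluate",
    "shuffle_null",
    "direction_ratio_and_gradient",
]

MIN_CLASS_SIZE = 50


@dataclass
class ClassifierDataset:
    features: np.ndarray  # (timepoints, electrodes) amplitude z-scores
    labels: np.ndarray  # (timepoints,), 0/1 direction condition
    balanced: bool
    counts: tuple[int, int]


@dataclass
class ClassifierResult:
    accuracy: float  # %
    null_p50: float  # %
    null_p99: float  # %
    n_iter_null: int
    significant: bool
    null_accuracies: np.ndarray | None = None  # %


def build_dataset(
    band: AnalyticBand,
    split: tuple[np.ndarray, np.ndarray],
    geometry: GridGeometry | None = None,
    seed: int = 0,
) -> ClassifierDataset:
    """Amplitude features + direction labels at angle-split timepoints.

    ``split`` holds the two timepoint index sets from the angle split.
    Bad channels are dropped from the feature dimension. Classes are
    balanced by randomly subsampling the majority class to the minority
    size; each class must keep at least 50 timepoints.
    """
    idx0, idx1 = (np.asarray(s, dtype=int) for s in split)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both direction classes must be non-empty")
    if min(idx0.size, idx1.size) < MIN_CLASS_SIZE:
        raise ValueError(
            f"each class needs >= {MIN_CLASS_SIZE} timepoints "
            f"(got {idx0.size} and {idx1.size}); too few for cross-validation"
        )
    rng = np.random.default_rng(seed)
    n = min(idx0.size, idx1.size)
    if idx0.size > n:
        idx0 = rng.choice(idx0, size=n, replace=False)
    if idx1.size > n:
        idx1 = rng.choice(idx1, size=n, replace=False)
    amp = band.amplitude
    if geometry is not None:
        amp = amp[geometry.usable]
    feats = np.concatenate([amp[:, idx0].T, amp[:, idx1].T], axis=0)
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return ClassifierDataset(
        features=feats, labels=labels, balanced=True, counts=(n, n)
    )


def _svm():
    # linear kernel, default regularization, standardized features;
    # hyperparameter optimization deliberately avoided
    return make_pipeline(StandardScaler(), SVC(kernel="linear"))


def train_evaluate(
    ds: ClassifierDataset, k_folds: int = 5, seed: int = 0
) -> float:
    """Mean held-out accuracy (%) of a k-fold cross-validated linear SVM."""
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_svm(), ds.features, ds.labels, cv=cv)
    return float(scores.mean() * 100.0)


def shuffle_null(
    ds: ClassifierDataset,
    k_folds: int = 5,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ClassifierResult:
    """Label-shuffle significance test for the direction classifier.

    The full cross-validated training procedure is repeated ``n_iter``
    times with randomly permuted labels; the observed accuracy is
    significant when it exceeds the 99th percentile of the null
    accuracies.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a stable 99th percentile")
    rng = np.random.default_rng(seed)
    observed = train_evaluate(ds, k_folds=k_folds, seed=seed)
    null_acc = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(ds.labels)
        shuffled = ClassifierDataset(
            features=ds.features, labels=perm, balanced=ds.balanced, counts=ds.counts
        )
        null_acc[i] = train_evaluate(
            shuffled, k_folds=k_folds, seed=int(rng.integers(2**31))
        )
    p50, p99 = np.percentile(null_acc, [50, 99])
    return ClassifierResult(
        accuracy=observed,
        null_p50=float(p50),
        null_p99=float(p99),
        n_iter_null=n_iter,
        significant=bool(observed > p99),
        null_accuracies=null_acc,
    )


def direction_ratio_and_gradient(
    splits_by_freq: dict[float, tuple[np.ndarray, np.ndarray]],
    bands_by_freq: dict[float, AnalyticBand],
    geometry: GridGeometry,
) -> dict:
    """Frequency-vs-direction-ratio correlation and A-P gradient contrast.

    For each frequency: the ratio of timepoints traveling toward the
    anterior (larger-x) mode vs total, and the anterior-half minus
    posterior-half mean amplitude for each direction class. Reports a
    Spearman correlation of ratio against frequency and a paired t-test
    of the A-P gradient between the two direction conditions.
    """
    freqs = sorted(splits_by_freq)
    if len(freqs) < 3:
        raise ValueError("need >= 3 frequencies for the ratio correlation")
    x = geometry.coords[:, 0]
    order = np.argsort(x, kind="stable")
    half = geometry.n_electrodes // 2
    posterior = order[:half]
    anterior = order[-half:]
    rows = []
    for f in freqs:
        idx0, idx1 = splits_by_freq[f]
        amp = bands_by_freq[f].amplitude
        ratio = idx0.size / (idx0.size + idx1.size)
        grad0 = amp[np.ix_(anterior, idx0)].mean() - amp[np.ix_(posterior, idx0)].mean()
        grad1 = amp[np.ix_(anterior, idx1)].mean() - amp[np.ix_(posterior, idx1)].mean()
        rows.append(
            {"freq": f, "ratio": ratio, "ap_gradient_c0": grad0, "ap_gradient_c1": grad1}
        )
    ratios = [r["ratio"] for r in rows]
    rho, p_rho = stats.spearmanr(freqs, ratios)
    t, p_t = stats.ttest_rel(
        [r["ap_gradient_c0"] for r in rows], [r["ap_gradient_c1"] for r in rows]
    )
    return {
        "per_freq": rows,
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "paired_t": float(t),
        "paired_t_p": float(p_t),
    }
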