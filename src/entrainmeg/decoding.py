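"""Time-resolved multivariate decoding of target-derived stimulus labels.

The decoding scheme mirrors standard MEG MVPA practice: epochs are
down-sampled to 200 Hz, trials are averaged into same-class pseudo-trials
(bins of ``bin_size`` without overlap, a fresh random ordering per repeat),
the sensor data are whitened by the shrinkage-estimated within-class error
covariance of the training partition (multivariate noise normalisation),
and a linear max-margin classifier (L2-regularised SVM, box constraint 1)
is trained and tested independently at each time point under stratified
k-fold cross-validation.  Accuracy is averaged over folds and repeats;
chance is 0.5 for the two balanced classes.

Class labels are derived from the *target* of each trial, so every
stimulus epoch of a trial (entrainers included) inherits the trial's
target class - orientation (horizontal vs vertical) or spatial frequency
(low vs high cycles per degree).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from sklearn.covariance import LedoitWolf
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .erf import EpochSet

FEATURES = ("orientation", "cpd")
CHANCE = 0.5


def derive_labels(design: pd.DataFrame, feature: str) -> np.ndarray:
    """Binary class labels per trial, derived from the target stimulus."""
    if feature == "orientation":
        return (design["target_deg"].to_numpy() == 90.0).astype(int)
    if feature == "cpd":
        return (design["target_cpd"].to_numpy()
                > design["entrainer_cpd"].to_numpy()).astype(int)
    raise ValueError(f"unknown feature {feature!r}; use one of {FEATURES}")


def downsample(epochs: EpochSet, target_sfreq: float = 200.0) -> EpochSet:
    """Anti-aliased polyphase resampling along the time axis."""
    if target_sfreq >= epochs.sfreq:
        raise ValueError("target sampling rate must be below the original")
    from fractions import Fraction

    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = resample_poly(epochs.data, up, down, axis=-1, padtype="line")
    n_out = data.shape[-1]
    times = epochs.times[0] + np.arange(n_out) * 1000.0 / target_sfreq
    return replace(epochs, data=data, times=times, sfreq=float(target_sfreq))


@dataclass
class PseudoTrialSet:
    data: np.ndarray          # (n_pseudo, channels, samples)
    labels: np.ndarray
    provenance: list          # member trial indices per pseudo-trial


def make_pseudotrials(data: np.ndarray, labels: np.ndarray,
                      bin_size: int = 10, n_orderings: int = 100,
                      seed: int | np.random.Generator = 0):
    """Yield ``n_orderings`` pseudo-trial sets: per class, shuffle the
    trials, partition into disjoint bins of ``bin_size`` and average;
    remainder trials are dropped."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    for cls in classes:
        if (labels == cls).sum() < bin_size:
            raise ValueError(f"class {cls} has fewer than bin_size="
                             f"{bin_size} trials")
    for _ in range(n_orderings):
        chunks, ys, prov = [], [], []
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(labels == cls))
            n_bins = len(idx) // bin_size
            for b in range(n_bins):
                members = idx[b * bin_size:(b + 1) * bin_size]
                chunks.append(data[members].mean(axis=0))
                ys.append(cls)
                prov.append(members)
        yield PseudoTrialSet(data=np.stack(chunks),
                             labels=np.asarray(ys), provenance=prov)


def noise_normalize(train: np.ndarray, train_labels: np.ndarray,
                    test: np.ndarray | None = None):
    """Whiten by the inverse square root of the within-class residual
    covariance of the training set (shrinkage-estimated, residuals pooled
    over time points).  The test set never influences the estimator.

    Returns ``(train_w, test_w, whitener)``.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(train_labels)
    resid = train.copy()
    for cls in np.unique(labels):
        sel = labels == cls
        if sel.sum() < 2:
            raise ValueError("need at least 2 training trials per class")
        resid[sel] -= train[sel].mean(axis=0)
    n_ch = train.shape[1]
    pooled = np.moveaxis(resid, 1, 2).reshape(-1, n_ch)
    cov = LedoitWolf(assume_centered=True).fit(pooled).covariance_
    evals, evecs = np.linalg.eigh(cov)
    whitener = (evecs / np.sqrt(evals)) @ evecs.T
    train_w = np.einsum("ij,tjs->tis", whitener, train)
    test_w = (None if test is None
              else np.einsum("ij,tjs->tis", whitener, test))
    return train_w, test_w, whitener


def _fit_predict_timecourse(train, train_y, test, cost: float = 1.0
                            ) -> np.ndarray:
    """Per-time-point linear SVM; returns (n_test, n_times) predictions."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    n_times = train.shape[-1]
    pred = np.empty((test.shape[0], n_times), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for t in range(n_times):
            clf = LinearSVC(C=cost, loss="squared_hinge", dual=True,
                            tol=1e-4, max_iter=10000, random_state=0)
            clf.fit(train[..., t], train_y)
            pred[:, t] = clf.predict(test[..., t])
    return pred


def decode_timecourse(data: np.ndarray, labels: np.ndarray,
                      bin_size: int = 10, n_folds: int = 5,
                      n_repeats: int = 25, cost: float = 1.0,
                      seed: int = 0) -> np.ndarray:
    """Cross-validated decoding accuracy per time point.

    ``data`` is (trials, channels, samples); ``labels`` binary per trial.
    Each repeat draws one fresh pseudo-trial ordering, whitens with the
    training partition of each fold, and averages accuracy over folds;
    the returned curve is the mean over repeats.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("decoding expects exactly two classes")
    if counts[0] != counts[1]:
        import warnings
        warnings.warn("unbalanced classes; stratification keeps folds "
                      "proportional but chance is no longer exactly 0.5",
                      RuntimeWarning)
    rng = np.random.default_rng(seed)
    n_times = data.shape[-1]
    acc = np.zeros(n_times)
    for pseudo in make_pseudotrials(data, labels, bin_size,
                                    n_orderings=n_repeats, seed=rng):
        if min(np.bincount(pseudo.labels)) < n_folds:
            raise ValueError(
                f"only {min(np.bincount(pseudo.labels))} pseudo-trials per "
                f"class for {n_folds}-fold CV; lower bin_size or n_folds")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        fold_acc = np.zeros(n_times)
        for train_idx, test_idx in skf.split(pseudo.data, pseudo.labels):
            tr_w, te_w, _ = noise_normalize(pseudo.data[train_idx],
                                            pseudo.labels[train_idx],
                                            pseudo.data[test_idx])
            pred = _fit_predict_timecourse(tr_w, pseudo.labels[train_idx],
                                           te_w, cost)
            fold_acc += (pred == pseudo.labels[test_idx][:, None]).mean(axis=0)
        acc += fold_acc / n_folds
    return acc / n_repeats


@dataclass
class DecodingResult:
    accuracy: np.ndarray      # (participants, times)
    times: np.ndarray
    stimulus: str
    condition: str
    feature: str
    bin_size: int
    n_folds: int
    n_repeats: int

    def group_mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, curve in enumerate(self.accuracy):
            for t, a in zip(self.times, curve):
                rows.append((p, self.condition, self.stimulus, self.feature,
                             float(t), float(a)))
        return pd.DataFrame(rows, columns=["participant", "condition",
                                           "stimulus", "feature", "time_ms",
                                           "accuracy"])
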