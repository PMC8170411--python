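"""Population decoding of spatial frequency from spike counts.

Spike counts in a time window form a (trials x units) matrix with the six
SF bands as classes; a shrinkage-regularized linear discriminant classifier
is evaluated with stratified 4-fold cross-validation repeated 5 times.
Shrinkage is required because the pseudo-population can have more units
than trials; the amount is set by the Ledoit-Wolf estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import Condition, StimulusSequence, epoch_spike_counts

__all__ = ["DecodingResult", "build_count_matrix", "decode_sf",
           "decode_windows", "DEFAULT_WINDOWS_S", "chance_error"]

N_FOLDS = 4
N_REPEATS = 5
MIN_TRIALS = 30

DEFAULT_WINDOWS_S = ((0.05, 0.5), (0.05, 0.15), (0.15, 0.25),
                     (0.25, 0.35), (0.35, 0.45))


@dataclass
class DecodingResult:
    window_s: tuple[float, float]
    error_rate: float          # mean test error over folds x repeats
    error_sem: float
    fold_errors: np.ndarray    # length folds * repeats
    n_units: int
    n_trials: int
    n_folds: int = N_FOLDS
    n_repeats: int = N_REPEATS


def chance_error(labels) -> float:
    """1 - 1/n_classes for balanced classes."""
    return 1.0 - 1.0 / np.unique(labels).size


def build_count_matrix(units_spikes: list[np.ndarray],
                       events: StimulusSequence,
                       window_s: tuple[float, float],
                       epoch_s: tuple[float, float] = (-0.3, 0.5)
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(trials x units) spike counts on the tuning block, labels = SF band.

    ``window_s`` must lie within the trial epoch.  Requires at least 30
    trials in total so a 4-fold split keeps reasonable test sizes.
    """
    if window_s[0] < epoch_s[0] or window_s[1] > epoch_s[1]:
        raise ValueError("window outside the trial epoch")
    tuning = events.select(block="tuning", condition=Condition.TUNING)
    if len(tuning) < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} tuning trials, "
                         f"found {len(tuning)}")
    onsets = tuning.onsets()
    # string class labels (SF band names) keep the classifier categorical
    labels = np.asarray([f"{e.sf_cpd:g}" for e in tuning.events])
    X = np.column_stack([epoch_spike_counts(sp, onsets, window_s)
                         for sp in units_spikes])
    return X, labels


def decode_sf(X: np.ndarray, labels: np.ndarray, n_folds: int = N_FOLDS,
              n_repeats: int = N_REPEATS, seed: int = 0) -> DecodingResult:
    """Cross-validated LDA decoding error.

    Stratified folds; each repeat reshuffles fold assignment with a seed
    derived from ``seed``.  Reported error is the mean over the
    ``n_folds * n_repeats`` test evaluations, with its SEM.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    errors = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + rep)
        for train, test in skf.split(X, labels):
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(X[train], labels[train])
            errors.append(1.0 - float(clf.score(X[test], labels[test])))
    errors = np.asarray(errors)
    sem = float(errors.std(ddof=1) / np.sqrt(errors.size)) \
        if errors.size > 1 else 0.0
    return DecodingResult((float(np.nan), float(np.nan)), float(errors.mean()),
                          sem, errors, X.shape[1], X.shape[0],
                          n_folds, n_repeats)


def decode_windows(units_spikes: list[np.ndarray], events: StimulusSequence,
                   windows_s=DEFAULT_WINDOWS_S, seed: int = 0
                   ) -> list[DecodingResult]:
    """One decoding result per window, same fold seeds across windows so
    window comparisons are paired."""
    results = []
    for win in windows_s:
        X, labels = build_count_matrix(units_spikes, events, tuple(win))
        res = decode_sf(X, labels, seed=seed)
        res.window_s = (float(win[0]), float(win[1]))
        results.append(res)
    return results
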