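"""Time-frequency MVPA: searchlight classification, cross-frequency
generalisation and group permutation statistics.

The classifier throughout is a binary linear discriminant analysis (LDA) with
Ledoit-Wolf shrinkage of the pooled within-class covariance toward a scaled
identity, evaluated by stratified cross-validation with five folds and five
repetitions (fold assignment re-randomised per repetition, seeded).  The
implementation is batched over searchlight cells — one covariance solve per
fold for *all* time-frequency points at once — which is what makes the
error-rate simulation studies tractable; scikit-learn's
LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto") computes the same
discriminant and serves as an independent cross-check in the test suite.

Group-level inference on accuracy maps tests accuracy - 0.5 against zero with
a Wilcoxon signed-rank statistic per map cell (normal approximation,
vectorised), forms clusters at p < alpha, and corrects with a sign-flip
permutation null of the maximum cluster mass followed by FDR across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialTF:
    """Per-trial time-frequency power with axes and condition labels."""

    power: np.ndarray          # (trials, times, freqs), >= 0
    times: np.ndarray          # s relative to the locking event
    freqs: np.ndarray          # Hz
    condition: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("time-frequency power must be non-negative")


@dataclass
class ClassificationMap:
    """Cross-validated accuracy per time-frequency cell."""

    accuracy: np.ndarray       # (times, freqs) in [0, 1]
    times: np.ndarray
    freqs: np.ndarray
    cv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class GeneralizationMatrix:
    """Accuracy for training on one frequency and testing on another."""

    accuracy: np.ndarray       # (train_freqs, test_freqs)
    freqs: np.ndarray
    cv: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    mask: np.ndarray
    zmap: np.ndarray
    clusters: list[dict]

    @property
    def any_significant(self) -> bool:
        return any(c["significant"] for c in self.clusters)


# ---------------------------------------------------------------------------
# Permutation helpers
# ---------------------------------------------------------------------------

def sign_flips(
    n_perm: int, n_subjects: int, rng: np.random.Generator,
) -> np.ndarray:
    """Distinct subject sign-flip patterns, identity first.  Returns (P, S) of +-1.

    When the flip universe 2**S fits in ``n_perm`` the test is exhaustive
    (all patterns); otherwise ``n_perm`` distinct patterns are sampled
    without replacement (avoiding duplicated identity permutations, which
    would inflate the attainable p floor).  Falls back to sampling with
    replacement for very large groups where enumeration is not an option.
    """
    S = n_subjects
    if S <= 22 and 2 ** S <= n_perm:
        codes = np.arange(2 ** S, dtype=np.int64)
    elif S <= 22:
        codes = rng.choice(2 ** S, size=n_perm, replace=False)
        codes[codes == 0] = codes[0]
        codes[0] = 0
    else:
        codes = rng.integers(1, 2 ** 62, size=n_perm)
        codes[0] = 0
    bits = (codes[:, None] >> np.arange(S)[None, :]) & 1
    return 1.0 - 2.0 * bits


# ---------------------------------------------------------------------------
# Batched shrinkage-LDA cross-validation
# ---------------------------------------------------------------------------

def _folds(y: np.ndarray, n_splits: int, n_repeats: int, seed: int):
    """Stratified folds, re-randomised per repetition."""
    from sklearn.model_selection import StratifiedKFold

    idx = np.arange(len(y))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed + rep)
        yield from skf.split(idx, y)


def _lda_fit_cells(Xtr: np.ndarray, ytr: np.ndarray):
    """Fit shrinkage LDA per cell.  Xtr: (n, C, d).  Returns (w, bias)."""
    n, C, d = Xtr.shape
    m0 = Xtr[ytr == 0].mean(axis=0)            # (C, d)
    m1 = Xtr[ytr == 1].mean(axis=0)
    Xc = Xtr - np.where(ytr[:, None, None] == 0, m0, m1)
    S = np.einsum("ncd,nce->cde", Xc, Xc) / n  # pooled biased covariance
    mu_t = np.trace(S, axis1=-2, axis2=-1) / d              # (C,)
    eye = np.eye(d)
    delta = ((S - mu_t[:, None, None] * eye) ** 2).sum(axis=(-2, -1)) / d
    ssq = (Xc ** 2).sum(axis=-1)               # (n, C)
    beta = ((ssq ** 2).sum(axis=0) / n - (S ** 2).sum(axis=(-2, -1))) / (n * d)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta > 1e-30, np.minimum(beta, delta) / delta, 1.0)
    shrink = np.clip(shrink, 0.0, 1.0)
    Ssh = (1.0 - shrink)[:, None, None] * S + (shrink * mu_t)[:, None, None] * eye
    w = np.linalg.solve(Ssh, (m1 - m0)[..., None])[..., 0]  # (C, d)
    n0, n1 = int((ytr == 0).sum()), int((ytr == 1).sum())
    bias = np.einsum("cd,cd->c", 0.5 * (m0 + m1), w) - np.log(n1 / n0)
    return w, bias


def _lda_cv_cells(
    X: np.ndarray, y: np.ndarray,
    folds: int = 5, repetitions: int = 5, seed: int = 0,
) -> np.ndarray:
    """Cross-validated LDA accuracy per cell.  X: (n, C, d) -> (C,)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary classification requires 2 classes, got {len(classes)}")
    yb = (y == classes[1]).astype(int)
    counts = np.bincount(yb)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class, got {counts.min()}")
    acc = np.zeros(X.shape[1])
    n_folds = 0
    for tr, te in _folds(yb, folds, repetitions, seed):
        w, bias = _lda_fit_cells(X[tr], yb[tr])
        scores = np.einsum("ncd,cd->nc", X[te], w) - bias
        acc += ((scores > 0).astype(int) == yb[te][:, None]).mean(axis=0)
        n_folds += 1
    return acc / n_folds


def classify_cv(
    features: np.ndarray, labels: np.ndarray,
    folds: int = 5, repetitions: int = 5, seed: int = 0,
) -> float:
    """Mean stratified cross-validated accuracy of the shrinkage-LDA classifier.

    ``features`` is (n_samples, n_features); accuracy is the fraction of
    correctly predicted class labels averaged over folds x repetitions, to be
    judged against the null value of 0.5.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    return float(_lda_cv_cells(X[:, None, :], labels, folds, repetitions, seed)[0])


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

def tf_searchlight(
    tf_speech: TrialTF | np.ndarray,
    tf_rest: TrialTF | np.ndarray,
    neighborhood: int = 1,
    folds: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> ClassificationMap:
    """Speech-vs-rest LDA accuracy at every time-frequency point.

    At each (t, f) the features are the power values in the
    (2r+1) x (2r+1) neighborhood (r = ``neighborhood``, clipped at the map
    edges; r=0 is single-pixel decoding).  Trial counts must be equal across
    conditions so that chance is exactly 0.5.
    """
    if isinstance(tf_speech, TrialTF):
        times = tf_speech.times if times is None else times
        freqs = tf_speech.freqs if freqs is None else freqs
        Xs, Xr = tf_speech.power, (tf_rest.power if isinstance(tf_rest, TrialTF) else tf_rest)
    else:
        Xs, Xr = tf_speech, tf_rest
    if Xs.shape[0] != Xr.shape[0]:
        raise ValueError("speech and rest must have equal trial counts")
    X = np.concatenate([Xs, Xr])                # (n, T, F)
    y = np.r_[np.ones(len(Xs), int), np.zeros(len(Xr), int)]
    n, T, F = X.shape
    r = int(neighborhood)
    acc = np.zeros((T, F))
    if r == 0:
        acc = _lda_cv_cells(
            X.reshape(n, T * F, 1), y, folds, repetitions, seed
        ).reshape(T, F)
    else:
        # interior cells share the full window shape -> one batched call
        if T > 2 * r and F > 2 * r:
            from numpy.lib.stride_tricks import sliding_window_view

            V = sliding_window_view(X, (2 * r + 1, 2 * r + 1), axis=(1, 2))
            Ti, Fi = V.shape[1], V.shape[2]
            Xin = V.reshape(n, Ti * Fi, (2 * r + 1) ** 2)
            acc[r : r + Ti, r : r + Fi] = _lda_cv_cells(
                Xin, y, folds, repetitions, seed
            ).reshape(Ti, Fi)
        interior = np.zeros((T, F), bool)
        interior[r : T - r, r : F - r] = (T > 2 * r) and (F > 2 * r)
        for t in range(T):
            for f in range(F):
                if interior[t, f]:
                    continue
                t0, t1 = max(0, t - r), min(T, t + r + 1)
                f0, f1 = max(0, f - r), min(F, f + r + 1)
                Xc = X[:, t0:t1, f0:f1].reshape(n, 1, -1)
                acc[t, f] = _lda_cv_cells(Xc, y, folds, repetitions, seed)[0]
    return ClassificationMap(
        accuracy=acc,
        times=np.arange(T, dtype=float) if times is None else np.asarray(times),
        freqs=np.arange(F, dtype=float) if freqs is None else np.asarray(freqs),
        cv={"folds": folds, "repetitions": repetitions, "seed": seed,
            "neighborhood": r},
    )


# ---------------------------------------------------------------------------
# Frequency generalisation
# ---------------------------------------------------------------------------

def frequency_generalization(
    tf_speech: TrialTF | np.ndarray,
    tf_rest: TrialTF | np.ndarray,
    folds: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    time_features: bool = True,
    freqs: np.ndarray | None = None,
) -> GeneralizationMatrix:
    """Train the classifier at one frequency, test at every frequency.

    The feature vector of a frequency is its full within-epoch time course
    of power (``time_features=False`` uses the time-averaged scalar
    instead).  Held-out trials are matched between train and test
    frequencies (same folds), so the diagonal equals per-frequency
    self-decoding.
    """
    if isinstance(tf_speech, TrialTF):
        freqs = tf_speech.freqs if freqs is None else freqs
        Xs, Xr = tf_speech.power, (tf_rest.power if isinstance(tf_rest, TrialTF) else tf_rest)
    else:
        Xs, Xr = tf_speech, tf_rest
    if Xs.shape[0] != Xr.shape[0]:
        raise ValueError("speech and rest must have equal trial counts")
    X = np.concatenate([Xs, Xr])                # (n, T, F)
    if not time_features:
        X = X.mean(axis=1, keepdims=True)
    y = np.r_[np.ones(len(Xs), int), np.zeros(len(Xr), int)]
    n, T, F = X.shape
    Xcells = np.transpose(X, (0, 2, 1))         # (n, F, T): cells = freqs
    acc = np.zeros((F, F))
    n_folds = 0
    for tr, te in _folds(y, folds, repetitions, seed):
        w, bias = _lda_fit_cells(Xcells[tr], y[tr])       # w: (F, T)
        scores = np.einsum("ntg,ft->nfg", X[te], w) - bias[:, None]
        acc += ((scores > 0).astype(int) == y[te][:, None, None]).mean(axis=0)
        n_folds += 1
    return GeneralizationMatrix(
        accuracy=acc / n_folds,
        freqs=np.arange(F, dtype=float) if freqs is None else np.asarray(freqs),
        cv={"folds": folds, "repetitions": repetitions, "seed": seed,
            "time_features": time_features},
    )


# ---------------------------------------------------------------------------
# Group statistics on accuracy maps
# ---------------------------------------------------------------------------

def _signed_rank_parts(d: np.ndarray):
    """Per-cell pieces of the Wilcoxon signed-rank statistic, zeros excluded.

    d: (subjects, cells).  Returns (ranks_within_nonzero, pos, neg, mu, sigma)
    where ranks are zero for zero differences, so W+ = sum(ranks * pos) and a
    sign flip moves an entry between the pos and neg terms.
    """
    S = d.shape[0]
    nonzero = d != 0
    n_eff = nonzero.sum(axis=0)
    # zeros pushed below every nonzero value, then re-based
    absd = np.where(nonzero, np.abs(d), -np.inf)
    ranks = stats.rankdata(absd, axis=0) - (S - n_eff)
    ranks = np.where(nonzero, ranks, 0.0)
    mu = n_eff * (n_eff + 1) / 4.0
    sigma = np.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0)
    return ranks, (d > 0), (d < 0), mu, sigma


def _signed_rank_z(d: np.ndarray) -> np.ndarray:
    """Vectorised Wilcoxon signed-rank z (normal approximation) per cell.

    d: (subjects, cells...) differences; zero differences are excluded as in
    the exact test; cells with no nonzero difference get z = 0.
    """
    shape = d.shape[1:]
    ranks, pos, _, mu, sigma = _signed_rank_parts(d.reshape(d.shape[0], -1))
    W = (ranks * pos).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (W - mu) / sigma
    z[~np.isfinite(z)] = 0.0
    return z.reshape(shape)


def _cluster_masses_2d(z: np.ndarray, z_crit: float):
    """Signed suprathreshold clusters (4-connectivity) and their |z| masses."""
    clusters = []
    for sign in (1, -1):
        mask = sign * z > z_crit
        lab, nlab = ndimage.label(mask)
        for k in range(1, nlab + 1):
            sel = lab == k
            clusters.append({"sign": sign, "cells": sel,
                             "mass": float(np.abs(z[sel]).sum())})
    return clusters


def group_stats_accuracy(
    maps: np.ndarray,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Cluster-corrected group test of accuracy maps against chance (0.5).

    Per cell, accuracy - 0.5 is tested with a Wilcoxon signed-rank statistic;
    the permutation null randomly swaps each subject's obtained value with
    its null value (a sign flip of the difference); clusters are formed at
    p < alpha (|z| above the normal quantile) and their masses compared with
    the permutation distribution of the maximum cluster mass, FDR-corrected
    across clusters.
    """
    maps = np.asarray(maps, float)
    S = maps.shape[0]
    if S < 2:
        raise ValueError("group statistics require at least 2 subjects")
    if S < 5:
        logger.warning("group_stats_accuracy: %d subjects gives a %d-element "
                       "flip universe; p-values are coarse", S, 2 ** S)
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is small for cluster inference")
    d = maps - 0.5
    shape = d.shape[1:]
    dc = d.reshape(S, -1)
    z_obs = _signed_rank_z(dc).reshape(shape)
    z_crit = stats.norm.isf(alpha / 2.0)

    ranks, pos, neg, mu, sigma = _signed_rank_parts(dc)
    rng = np.random.default_rng(seed)
    signs = sign_flips(n_perm, S, rng)             # identity pattern first
    flips = (1.0 - signs) / 2.0                    # 0 = keep, 1 = swap
    n_perm = len(flips)
    Wp = (1 - flips) @ (ranks * pos) + flips @ (ranks * neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        Zp = (Wp - mu) / sigma
    Zp[:, sigma == 0] = 0.0
    Zp = Zp.reshape(n_perm, *shape)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _cluster_masses_2d(Zp[i], z_crit)
        null_max[i] = max((c["mass"] for c in cl), default=0.0)

    clusters = _cluster_masses_2d(z_obs, z_crit)
    for c in clusters:
        c["p"] = float((null_max >= c["mass"]).mean())
    if clusters:
        from statsmodels.stats.multitest import multipletests

        rej, q, *_ = multipletests([c["p"] for c in clusters], alpha=alpha,
                                   method="fdr_bh")
        for c, r, qq in zip(clusters, rej, q):
            c["significant"], c["q"] = bool(r), float(qq)
    mask = np.zeros(shape, bool)
    for c in clusters:
        if c["significant"]:
            mask |= c["cells"]
    return ClusterResult(mask=mask, zmap=z_obs, clusters=clusters)
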