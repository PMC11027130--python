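"""Representational similarity analysis linking kinematic profiles to
time-frequency neural data.

The logic: trials are ordered along a kinematic profile (velocity-vs-
amplitude or stiffness-vs-duration) and cut into equal-count partitions.
Euclidean distances between partition mean coordinates give the behavioural
representational dissimilarity matrix (RDM).  For every pair of partitions,
cross-validated LDA classification of their MEG trials at each time-frequency
point gives a neural RDM per (t, f) — partitions whose neural patterns are
harder to tell apart are representationally closer.  Rank-correlating the
behavioural RDM with the neural RDMs over partition pairs yields an RSA
time-frequency map per subject; group inference runs band-averaged
cluster-based sign-flip permutation tests (FDR-corrected across clusters and
bands) on a 1 s window centred on the movement onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

# evaluation bands: mu and beta sensorimotor rhythms, plus a high-gamma band
# dominated by movement artifact that serves as a negative control
DEFAULT_BANDS = {"mu": (8.0, 12.0), "beta": (13.0, 30.0), "gamma": (60.0, 80.0)}

PROFILE_AXES = {
    "stiffness_duration": ("duration", "stiffness"),
    "velocity_amplitude": ("amplitude", "velocity"),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Equal-count partition of trials along a kinematic profile."""

    assignment: np.ndarray       # (n_trials,) partition index per trial
    means_raw: np.ndarray        # (P, 2) partition means, raw coordinates
    means_std: np.ndarray        # (P, 2) partition means, z-scored coordinates
    n_partitions: int

    def trials_in(self, p: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == p)


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    matrix: np.ndarray
    kind: str                    # "behavioural" | "neural"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if np.any(m < -1e-12):
            raise ValueError("RDM entries must be non-negative")
        self.matrix = m

    @property
    def vector(self) -> np.ndarray:
        """Lower-triangle entries (the 45 pairs for 10 partitions)."""
        i, j = np.tril_indices(self.matrix.shape[0], -1)
        return self.matrix[i, j]


@dataclass
class RSAMap:
    """Behavioural-neural RDM correlation per time-frequency point."""

    correlation: np.ndarray      # (times, freqs/bands) in [-1, 1], NaN = undefined
    times: np.ndarray
    freqs: np.ndarray
    model: str = ""
    method: str = "spearman"

    def __post_init__(self) -> None:
        finite = self.correlation[np.isfinite(self.correlation)]
        if finite.size and np.any(np.abs(finite) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class ClusterReport:
    clusters: list[dict] = field(default_factory=list)
    band_series: dict = field(default_factory=dict)   # band -> (mean, t) arrays
    n_missing: int = 0

    @property
    def any_significant(self) -> bool:
        return any(c["significant"] for c in self.clusters)

    def significant(self, band: str | None = None) -> list[dict]:
        return [c for c in self.clusters
                if c["significant"] and (band is None or c["band"] == band)]


# ---------------------------------------------------------------------------
# Partitioning and behavioural RDM
# ---------------------------------------------------------------------------

def partition_profile(points: np.ndarray, n_partitions: int = 10) -> PartitionScheme:
    """Order trials along a profile's dominant axis and cut equal-count blocks.

    The ordering axis is the first principal direction of the z-scored (x, y)
    cloud; blocks are contiguous with counts equal to within one trial.
    Partition means are stored both on raw coordinates and on z-scored
    coordinates (so mm and s scales are commensurable downstream).
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    if n < 2 * n_partitions:
        raise ValueError(f"need >= {2 * n_partitions} trials for "
                         f"{n_partitions} partitions, got {n}")
    sd = pts.std(axis=0, ddof=0)
    Z = (pts - pts.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    proj = Z @ Vt[0]
    if proj @ Z[:, 0] < 0:  # orient along increasing first coordinate
        proj = -proj
    order = np.argsort(proj, kind="stable")
    assignment = np.empty(n, int)
    for p, block in enumerate(np.array_split(order, n_partitions)):
        assignment[block] = p
    means_raw = np.vstack([pts[assignment == p].mean(axis=0)
                           for p in range(n_partitions)])
    means_std = np.vstack([Z[assignment == p].mean(axis=0)
                           for p in range(n_partitions)])
    occupancy = np.bincount(assignment)
    logger.info("partition_profile: %d partitions, %d-%d trials each",
                n_partitions, occupancy.min(), occupancy.max())
    return PartitionScheme(assignment=assignment, means_raw=means_raw,
                           means_std=means_std, n_partitions=n_partitions)


def behavioral_rdm(scheme: PartitionScheme, standardize: bool = True) -> RDM:
    """Pairwise Euclidean distances between partition mean coordinates.

    By default distances are computed on per-axis z-scored coordinates so
    that the two profile axes (e.g. mm and s) contribute commensurably;
    ``standardize=False`` uses the raw partition means.
    """
    means = scheme.means_std if standardize else scheme.means_raw
    return RDM(matrix=squareform(pdist(means)), kind="behavioural")


# ---------------------------------------------------------------------------
# Neural RDM
# ---------------------------------------------------------------------------

def _lda_cv_pairs_scalar(
    X: np.ndarray, y: np.ndarray, folds: int, repetitions: int, seed: int,
) -> np.ndarray:
    """Cross-validated scalar-feature LDA accuracy, batched over pairs x cells.

    X: (pairs, n, C) with a common label vector y and common stratified
    folds across pairs.  With one feature the shrinkage-LDA decision reduces
    to the class-mean midpoint rule, so only means are needed; this is the
    same classifier as ``classify_cv`` restricted to d=1 (asserted in the
    test suite).
    """
    from .tf_decoding import _folds

    acc = np.zeros(X.shape[::2])            # (pairs, C)
    n_folds = 0
    for tr, te in _folds(y, folds, repetitions, seed):
        Xtr, ytr = X[:, tr], y[tr]
        m0 = Xtr[:, ytr == 0].mean(axis=1)  # (pairs, C)
        m1 = Xtr[:, ytr == 1].mean(axis=1)
        score = (X[:, te] - 0.5 * (m0 + m1)[:, None]) * (m1 - m0)[:, None]
        acc += ((score > 0).astype(int) == y[te][None, :, None]).mean(axis=1)
        n_folds += 1
    return acc / n_folds


def neural_rdm(
    power: np.ndarray,
    scheme: PartitionScheme,
    folds: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    mode: str = "rectified",
) -> np.ndarray:
    """Pairwise-partition LDA dissimilarity at every time-frequency point.

    For each of the P(P-1)/2 partition pairs, cross-validated classification
    of their trials runs at each (t, f) with that point's power as the
    feature (all pairs evaluated in one batched pass sharing the stratified
    fold pattern; partitions are trimmed to a common trial count).
    Dissimilarity is max(accuracy - 0.5, 0) by default (``mode="rectified"``);
    ``mode="absolute"`` uses |accuracy - 0.5|, the
    distance-between-accuracy-scores variant.  Returns (P, P, times, freqs)
    with a zero diagonal.
    """
    if mode not in ("rectified", "absolute"):
        raise ValueError("mode must be 'rectified' or 'absolute'")
    X = np.asarray(power, float)
    n, T, F = X.shape
    if n != len(scheme.assignment):
        raise ValueError("power trials do not match the partition scheme")
    P = scheme.n_partitions
    occupancy = np.bincount(scheme.assignment, minlength=P)
    m = int(occupancy.min())
    if m < folds:
        raise ValueError(f"partition with fewer than {folds} trials")
    members = np.vstack([scheme.trials_in(p)[:m] for p in range(P)])  # (P, m)
    ii, jj = np.tril_indices(P, -1)
    idx = np.concatenate([members[jj], members[ii]], axis=1)          # (pairs, 2m)
    Xp = X.reshape(n, T * F)[idx]                                     # (pairs, 2m, C)
    y = np.r_[np.zeros(m, int), np.ones(m, int)]
    acc = _lda_cv_pairs_scalar(Xp, y, folds, repetitions, seed)
    diss = (np.maximum(acc - 0.5, 0.0) if mode == "rectified"
            else np.abs(acc - 0.5))
    out = np.zeros((P, P, T, F))
    out[ii, jj] = out[jj, ii] = diss.reshape(-1, T, F)
    return out


# ---------------------------------------------------------------------------
# RSA correlation map
# ---------------------------------------------------------------------------

def rsa_correlate(
    behavioural: RDM,
    neural: np.ndarray,
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    method: str = "spearman",
    model: str = "",
) -> RSAMap:
    """Correlate the behavioural RDM with the neural RDM at each (t, f).

    Rank correlation (Spearman) by default; Pearson by flag.  Cells where the
    neural dissimilarities have zero variance are undefined and stored NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    P = behavioural.matrix.shape[0]
    if neural.shape[:2] != (P, P):
        raise ValueError("partition count mismatch between RDMs")
    i, j = np.tril_indices(P, -1)
    b = behavioural.vector
    Nv = neural[i, j].reshape(len(b), -1)       # (pairs, cells)
    if method == "spearman":
        b = stats.rankdata(b)
        Nv = stats.rankdata(Nv, axis=0)
    b = b - b.mean()
    Nc = Nv - Nv.mean(axis=0)
    sb = np.sqrt(b @ b)
    sn = np.sqrt((Nc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (b @ Nc) / (sb * sn)
    corr[~np.isfinite(corr)] = np.nan
    T, F = neural.shape[2], neural.shape[3]
    corr = corr.reshape(T, F)
    return RSAMap(
        correlation=corr,
        times=np.arange(T, dtype=float) if times is None else np.asarray(times),
        freqs=np.arange(F, dtype=float) if freqs is None else np.asarray(freqs),
        model=model, method=method,
    )


def band_average(power_or_map: np.ndarray, freqs: np.ndarray,
                 bands: dict[str, tuple[float, float]] = DEFAULT_BANDS) -> np.ndarray:
    """Average the last (frequency) axis into named bands (stacked last)."""
    freqs = np.asarray(freqs, float)
    out = []
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside the frequency axis")
        out.append(np.nanmean(power_or_map[..., sel], axis=-1))
    return np.stack(out, axis=-1)


def rsa_subject_map(
    power: np.ndarray,
    params: pd.DataFrame,
    times: np.ndarray,
    model: str = "stiffness_duration",
    n_partitions: int = 10,
    folds: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    method: str = "spearman",
    mode: str = "rectified",
) -> RSAMap:
    """Single-subject RSA map from trial power and kinematic parameters.

    ``power`` is (trials, times, freqs-or-bands); ``params`` holds one row
    per trial with the kinematic parameters; ``model`` selects the profile
    (stiffness_duration or velocity_amplitude).
    """
    xcol, ycol = PROFILE_AXES[model]
    points = params[[xcol, ycol]].to_numpy()
    scheme = partition_profile(points, n_partitions)
    brdm = behavioral_rdm(scheme)
    nrdm = neural_rdm(power, scheme, folds, repetitions, seed, mode)
    return rsa_correlate(brdm, nrdm, times=times, model=model, method=method)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _perm_t(X: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t statistics of sign-flipped one-sample tests.  X: (S, T), flips: (P, S)."""
    S = X.shape[0]
    m = flips @ X / S
    sx2 = (X ** 2).sum(axis=0)
    var = np.maximum(sx2[None, :] - S * m ** 2, 0.0) / (S - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(var / S)
    t[~np.isfinite(t)] = 0.0
    return t


def _runs(mask: np.ndarray):
    """Contiguous True runs of a 1-D mask as (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(idx[::2], idx[1::2]))


def rsa_group_stats(
    maps: np.ndarray,
    times: np.ndarray,
    band_names: tuple[str, ...] = ("mu", "beta", "gamma"),
    window: tuple[float, float] = (-0.5, 0.5),
    n_perm: int = 500,
    alpha: float = 0.05,
    statistic: str = "t",
    seed: int | None = 0,
) -> ClusterReport:
    """Band-wise cluster-based sign-flip permutation test on group RSA maps.

    ``maps`` is (subjects, times, bands) of band-averaged correlations.
    Evaluation is restricted to ``window`` (default the 1 s epoch centred on
    movement onset).  Per band and timepoint a one-sample sign-flip test
    against zero forms clusters at p < alpha; each cluster's |t| mass is
    compared with the permutation null of the maximum cluster mass (each
    permutation re-thresholded against the full permutation set); cluster
    p-values are FDR-corrected across clusters and bands.  Signed clusters
    are reported — pre-movement positive and post-movement negative
    associations are distinct findings.
    """
    if statistic not in ("t", "wilcoxon"):
        raise ValueError("statistic must be 't' or 'wilcoxon'")
    maps = np.asarray(maps, float)
    if maps.ndim != 3:
        raise ValueError("maps must be (subjects, times, bands)")
    S, _, B = maps.shape
    if S < 2:
        raise ValueError("group statistic undefined for a single subject")
    if B != len(band_names):
        raise ValueError("band_names length must match the band axis")
    times = np.asarray(times, float)
    sel = (times >= window[0]) & (times <= window[1])
    tsel = times[sel]
    rng = np.random.default_rng(seed)
    from .tf_decoding import sign_flips
    flips = sign_flips(n_perm, S, rng)              # distinct patterns, identity first
    n_perm = len(flips)

    band_series: dict = {}
    band_T: dict = {}
    n_missing = 0
    # cluster-mass null: per permutation the maximum mass over signs, runs AND
    # bands (a global max statistic, so "any significant cluster anywhere" is
    # controlled at alpha before the FDR step, which only tightens it)
    null_max = np.zeros(n_perm)
    for b, name in enumerate(band_names):
        X = maps[:, sel, b]
        missing = ~np.isfinite(X)
        n_missing += int(missing.sum())
        X = np.where(missing, 0.0, X)               # undefined cells excluded as 0
        if statistic == "t":
            Tmat = _perm_t(X, flips)                # (n_perm, Tw)
        else:
            from .tf_decoding import _signed_rank_z
            Tmat = np.vstack([
                _signed_rank_z(flips[i][:, None] * X) for i in range(n_perm)
            ])
        # per-timepoint permutation p for each permutation row (incl. observed)
        Pmat = stats.rankdata(-np.abs(Tmat), method="max", axis=0) / n_perm
        for i in range(n_perm):
            forming = Pmat[i] < alpha
            for sign in (1, -1):
                for lo, hi in _runs(forming & (sign * Tmat[i] > 0)):
                    null_max[i] = max(null_max[i],
                                      float(np.abs(Tmat[i, lo:hi]).sum()))
        band_T[name] = (Tmat[0], Pmat[0])
        band_series[name] = {"mean": maps[:, sel, b].mean(axis=0), "t": Tmat[0],
                             "times": tsel}
    clusters: list[dict] = []
    for name in band_names:
        t_obs, p_obs = band_T[name]
        forming = p_obs < alpha
        for sign in (1, -1):
            for lo, hi in _runs(forming & (sign * t_obs > 0)):
                mass = float(np.abs(t_obs[lo:hi]).sum())
                clusters.append({
                    "band": name, "sign": sign,
                    "onset_ms": float(tsel[lo] * 1e3),
                    "offset_ms": float(tsel[hi - 1] * 1e3),
                    "mass": mass,
                    "p": float((null_max >= mass).mean()),
                })
    if clusters:
        from statsmodels.stats.multitest import multipletests

        rej, q, *_ = multipletests([c["p"] for c in clusters], alpha=alpha,
                                   method="fdr_bh")
        for c, r, qq in zip(clusters, rej, q):
            c["significant"], c["q"] = bool(r), float(qq)
    if n_missing:
        logger.info("rsa_group_stats: %d undefined correlation cell(s) excluded",
                    n_missing)
    return ClusterReport(clusters=clusters, band_series=band_series,
                         n_missing=n_missing)
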