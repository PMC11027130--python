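"""Cross-device temporal alignment and epoching.

The articulograph and the MEG acquisition run on independent clocks; both
record the speech acoustics, so the clock offset is recovered as the peak of
the normalized cross-correlation between the two acoustic channels (computed
on their rectified, low-passed envelopes to be robust to waveform mismatch
between microphones).  A single global lag is assumed — sessions are short
enough that clock drift is negligible.  Articulatory landmarks are then
mapped into MEG sample indices and the sensor data is filtered (zero-phase
4th-order Butterworth band-pass plus mains notch) and segmented into
event-locked epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LagEstimate:
    """Signed lag (samples) and peak normalized cross-correlation."""

    lag: int
    correlation: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if abs(self.correlation) > 1.0 + 1e-9:
            raise ValueError("normalized correlation must lie in [-1, 1]")


@dataclass
class EventList:
    """Event sample indices (MEG timebase) with labels, sorted, in-bounds."""

    samples: np.ndarray
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        order = np.argsort(self.samples, kind="stable")
        self.samples = np.asarray(self.samples)[order].astype(int)
        self.labels = np.asarray(self.labels)[order]


@dataclass
class Epochs:
    """Event-locked segments: trials x channels x samples."""

    data: np.ndarray
    times: np.ndarray          # s relative to the event
    events: np.ndarray         # retained event samples
    sfreq: float
    filter_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("epoch window must contain time zero")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


# Epoching presets: speech decoding uses 4 s epochs about the bilabial-closure
# opening onset (later truncated to 3 s to trim spectral edge effects); the
# localiser uses 15 s epochs spanning the preceding trial set, the rest
# period and the current trial set; button press uses -0.5..+1 s.
EPOCH_PRESETS = {
    "speech": {"window": (-2.0, 2.0), "truncate": (-1.5, 1.5)},
    "localiser": {"window": (-10.0, 5.0)},
    "button": {"window": (-0.5, 1.0)},
}


# ---------------------------------------------------------------------------
# Lag estimation
# ---------------------------------------------------------------------------

def _envelope(x: np.ndarray, fs: float, cutoff: float = 20.0) -> np.ndarray:
    env = np.abs(np.asarray(x, float))
    if cutoff < fs / 2:
        sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
        env = signal.sosfiltfilt(sos, env)
    return env


def estimate_lag(
    acoustic_ref: np.ndarray,
    acoustic_other: np.ndarray,
    sfreq: float,
    max_lag: int | None = None,
    use_envelope: bool = True,
    corr_floor: float = 0.2,
) -> LagEstimate:
    """Clock offset between two co-recorded acoustic channels.

    Both signals must share ``sfreq`` (resample first).  The returned lag L
    is the shift maximising the normalized cross-correlation within
    +/- max_lag, with ties broken toward the smallest |L|; positive L means
    ``acoustic_other`` leads, i.e. other[n] aligns with ref[n + L].  A peak
    correlation below ``corr_floor`` sets the low-confidence flag.
    """
    a = np.asarray(acoustic_ref, float)
    b = np.asarray(acoustic_other, float)
    if use_envelope:
        a, b = _envelope(a, sfreq), _envelope(b, sfreq)
    a = a - a.mean()
    b = b - b.mean()
    c = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(len(a), len(b), mode="full")
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return LagEstimate(lag=0, correlation=0.0, low_confidence=True)
    c = c / denom
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        c, lags = c[keep], lags[keep]
    best = np.max(c)
    ties = np.flatnonzero(c >= best - 1e-12)
    lag = int(lags[ties[np.argmin(np.abs(lags[ties]))]])
    low = best < corr_floor
    if low:
        logger.warning("estimate_lag: peak correlation %.3f below floor %.2f",
                       best, corr_floor)
    return LagEstimate(lag=lag, correlation=float(min(best, 1.0)), low_confidence=low)


# ---------------------------------------------------------------------------
# Landmark mapping
# ---------------------------------------------------------------------------

def map_landmarks(
    times_s: np.ndarray,
    lag: int,
    sfreq_meg: float,
    n_samples: int,
    labels: np.ndarray | str = "BC_opening_onset",
) -> EventList:
    """Convert articulatory-clock event times to MEG sample indices.

    sample = round(t * sfreq_meg) + lag.  Out-of-bounds events are dropped
    and counted.
    """
    times_s = np.asarray(times_s, float)
    samples = np.round(times_s * sfreq_meg).astype(int) + int(lag)
    if isinstance(labels, str):
        labels = np.full(len(samples), labels, dtype=object)
    labels = np.asarray(labels)
    keep = (samples >= 0) & (samples < n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("map_landmarks: %d event(s) outside the recording dropped",
                    n_dropped)
    return EventList(samples=samples[keep], labels=labels[keep], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Filtering and epoching
# ---------------------------------------------------------------------------

def _filter_recording(
    data: np.ndarray, sfreq: float,
    bandpass: tuple[float, float] | None, notch: float | None,
) -> tuple[np.ndarray, dict]:
    prov: dict = {}
    out = np.asarray(data, float)
    if bandpass is not None:
        lo, hi = bandpass
        if lo <= 0:
            sos = signal.butter(4, hi, btype="low", fs=sfreq, output="sos")
        else:
            sos = signal.butter(4, [lo, hi], btype="band", fs=sfreq, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1)
        prov["bandpass"] = (lo, hi)
    if notch is not None:
        b, a = signal.iirnotch(notch, Q=30.0, fs=sfreq)
        out = signal.filtfilt(b, a, out, axis=-1)
        prov["notch"] = notch
    prov["design"] = "butterworth-4 zero-phase (two-pass)"
    return out, prov


def epoch(
    data: np.ndarray,
    sfreq: float,
    events: EventList | np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    bandpass: tuple[float, float] | None = (0.0, 100.0),
    notch: float | None = 50.0,
    truncate: tuple[float, float] | None = None,
) -> Epochs:
    """Zero-phase filter then segment a recording about event samples.

    Events whose window exceeds the recording are dropped; fewer than 2
    retained events is an error.  ``truncate`` optionally trims the filtered
    epochs to an inner window (e.g. 4 s epochs cut to 3 s to discard
    time-frequency edge effects).
    """
    X = np.atleast_2d(np.asarray(data, float))
    samples = events.samples if isinstance(events, EventList) else np.asarray(events, int)
    Xf, prov = _filter_recording(X, sfreq, bandpass, notch)
    i0 = int(round(window[0] * sfreq))
    i1 = int(round(window[1] * sfreq))
    n = X.shape[-1]
    keep = [s for s in samples if s + i0 >= 0 and s + i1 <= n]
    if len(keep) < 2:
        raise ValueError(f"only {len(keep)} event(s) fit the epoch window; need >= 2")
    if len(keep) < len(samples):
        logger.info("epoch: dropped %d event(s) at the recording edges",
                    len(samples) - len(keep))
    trials = np.stack([Xf[:, s + i0 : s + i1] for s in keep])
    times = (np.arange(i0, i1)) / sfreq
    ep = Epochs(data=trials, times=times, events=np.asarray(keep, int),
                sfreq=sfreq, filter_provenance=prov)
    if truncate is not None:
        sel = (ep.times >= truncate[0]) & (ep.times <= truncate[1] + 1e-12)
        ep = Epochs(data=ep.data[:, :, sel], times=ep.times[sel], events=ep.events,
                    sfreq=sfreq, filter_provenance=prov)
    return ep


def sample_rest_events(
    rest_intervals: np.ndarray,
    n_events: int,
    sfreq: float,
    window: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | int | None = None,
    lag: int = 0,
    require_full_window: bool = False,
) -> EventList:
    """Epoch-reference time points drawn uniformly from inter-trial rest.

    ``rest_intervals`` is (k, 2) start/stop times in seconds (articulatory
    clock).  By default only the reference point itself must fall in a rest
    interval — the epoch window may extend beyond it, as when rest epochs
    are cut from short inter-trial respites; ``require_full_window=True``
    additionally demands that the whole window fit inside the interval.
    The count is matched to the number of speech trials so that the two
    classes are balanced.
    """
    rng = np.random.default_rng(rng)
    margin_lo = -window[0] if require_full_window else 0.0
    margin_hi = window[1] if require_full_window else 0.0
    usable = []
    for lo, hi in np.asarray(rest_intervals, float):
        lo2, hi2 = lo + margin_lo, hi - margin_hi
        if hi2 > lo2:
            usable.append((lo2, hi2))
    if not usable:
        raise ValueError("no rest interval can accommodate the epoch window")
    lengths = np.array([hi - lo for lo, hi in usable])
    probs = lengths / lengths.sum()
    times = np.empty(n_events)
    which = rng.choice(len(usable), size=n_events, p=probs)
    for i, k in enumerate(which):
        lo, hi = usable[k]
        times[i] = rng.uniform(lo, hi)
    samples = np.round(times * sfreq).astype(int) + int(lag)
    return EventList(samples=samples,
                     labels=np.full(n_events, "rest_reference", dtype=object))
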