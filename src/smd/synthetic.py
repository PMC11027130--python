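"""Synthetic articulatory and MEG-like sessions with recoverable ground truth.

The generator emulates the experimental design the pipeline is built for:
reiterated disyllabic nonword productions (/ipa/ vs /api/) in ~12 s breath
groups ("trial sets") separated by rest, tracked by articulator coils, with a
concurrently recorded MEG-like multichannel session containing a focal
cortical source whose beta (and optionally mu) rhythm desynchronises during
speech and rebounds at rest, movement-locked broadband (>50 Hz) artifact, and
an acoustic envelope channel recorded on both devices with a known clock lag.

Movement primitive
------------------
Each opening or closing movement is a raised-cosine half-cycle,
x(t) = A/2 (1 - cos(pi t / D)).  Its kinematics are closed-form:
peak velocity A pi / (2 D), stiffness (= peak velocity / amplitude)
pi / (2 D), and 10%/90% amplitude-level crossings at fractions
acos(0.8)/pi ~ 0.2048 and ~0.7952 of D.  Jittering amplitudes and durations
across cycles therefore yields a near-linear amplitude/peak-velocity profile
and a 1/D (curvilinear, plateauing) stiffness/duration profile — the two
kinematic laws the downstream analysis is meant to recover.

For /ipa/ the bilabial closure falls on the descending limb of the
tongue-body gesture; for /api/ on the ascending limb (the two utterances are
phase-reversed mirror images).

Every generated quantity (landmark times, per-cycle kinematic parameters,
device lag, source location, applied coupling) is recorded in a GroundTruth
object so that each downstream stage has an exact oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .beamforming import Leadfield
from .kinematics import RAISED_COSINE_F10, RAISED_COSINE_F90, ArticulatoryTrack

# shortest physically plausible single movement (s); configs implying faster
# half-cycles are rejected as non-physical
MIN_MOVEMENT_DURATION = 0.04


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Trial-wise coupling of a kinematic parameter to pre-movement band power.

    Single-trial band-limited source amplitude in ``band`` is multiplied by
    (1 + gain * z_i) in a window starting ``onset_lead_ms`` before each
    opening-movement onset and lasting ``duration_ms``, where z_i is the
    trial's kinematic parameter mapped monotonely onto [-1, 1].
    """

    parameter: str = "stiffness"     # stiffness | duration | amplitude | velocity
    gain: float = 0.5
    onset_lead_ms: float = 90.0
    duration_ms: float = 300.0
    band: tuple[float, float] = (18.0, 22.0)

    def __post_init__(self) -> None:
        if self.parameter not in ("stiffness", "duration", "amplitude", "velocity"):
            raise ValueError(f"unknown coupling parameter {self.parameter!r}")


@dataclass
class SimulationConfig:
    """Experimental parameters of a simulated session.

    Defaults follow the protocol the pipeline targets: 10 trial sets of 12 s
    reiterated productions (about 10 cycles per normal-rate set) separated by
    5 s of rest, 1 kHz MEG sampling, beta 13-30 Hz with 50% event-related
    desynchronisation during speech.  Amplitude/duration dispersions are
    generator choices (the protocol does not fix speaker-specific
    distributions): amplitudes vary substantially across productions while
    durations are comparatively stable (speech isochrony), which is what
    makes the amplitude/peak-velocity profile close to linear.
    """

    sampling_rate_track: float = 250.0      # Hz, articulograph position rate
    sampling_rate_meg: float = 1000.0       # Hz
    n_trial_sets: int = 10
    trial_set_duration: float = 12.0        # s
    inter_trial_interval: float = 5.0       # s of rest between trial sets
    cycle_rate_normal: float = 10.0 / 12.0  # cycles/s -> ~10 productions / 12 s
    cycle_rate_faster: float = 1.0          # cycles/s -> ~12 productions / 12 s
    rate_condition: str = "normal"          # "normal" | "faster"
    amplitude_mean: float = 10.0            # mm
    amplitude_sd: float = 2.0               # mm
    duration_jitter: float = 0.06           # lognormal sigma on movement durations
    utterance: str = "ipa"                  # "ipa" | "api"
    device_lag: int = 120                   # MASK->MEG clock offset, MEG samples
    n_sensors: int = 64
    grid_shape: tuple[int, int, int] = (5, 5, 5)
    grid_spacing: float = 4.0               # mm
    source_location: int | None = None      # grid index; None = central point
    source_amplitude: float = 2.0           # source signal SD in sensor units
    beta_band: tuple[float, float] = (13.0, 30.0)
    mu_band: tuple[float, float] = (8.0, 12.0)
    mu_gain: float = 0.0                    # mu source amplitude relative to beta
    erd_depth: float = 0.5                  # fractional beta suppression in speech
    artifact_gain: float = 2.0              # movement artifact amplitude, sensor units
    artifact_duration: float = 0.15         # s per burst
    coupling: CouplingSpec | None = None
    noise_sd: float = 1.0                   # sensor white noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_rate_track", "sampling_rate_meg", "cycle_rate_normal",
                     "cycle_rate_faster", "trial_set_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.utterance not in ("ipa", "api"):
            raise ValueError("utterance must be 'ipa' or 'api'")
        if self.rate_condition not in ("normal", "faster"):
            raise ValueError("rate_condition must be 'normal' or 'faster'")
        period = 1.0 / self.cycle_rate
        if period < 2 * MIN_MOVEMENT_DURATION * math.exp(2 * self.duration_jitter):
            raise ValueError(
                f"non-physical config: cycle period {period * 1e3:.0f} ms is shorter "
                f"than two minimum-duration movements "
                f"({2 * MIN_MOVEMENT_DURATION * 1e3:.0f} ms plus jitter headroom)"
            )

    @property
    def cycle_rate(self) -> float:
        return (self.cycle_rate_normal if self.rate_condition == "normal"
                else self.cycle_rate_faster)

    @property
    def session_duration(self) -> float:
        """Rest, then alternating trial sets and rests, ending in rest."""
        return (self.n_trial_sets * (self.trial_set_duration + self.inter_trial_interval)
                + self.inter_trial_interval)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class AcousticChannel:
    """Synthetic acoustic envelope (not audio): bursts time-locked to closures."""

    time: np.ndarray
    data: np.ndarray
    sfreq: float


@dataclass
class GroundTruth:
    """Oracle record of everything the generator did.

    ``cycles`` has one row per movement cycle with the trial set, analytic
    landmark times t1..t4 (10/90% crossings), extremum times, and the
    closed-form kinematic parameters of the opening and closing movements.
    """

    cycles: pd.DataFrame
    trial_set_windows: np.ndarray        # (n_sets, 2) start/stop times, s
    config: SimulationConfig
    device_lag: int | None = None        # MEG samples (set by the MEG stage)
    source_index: int | None = None
    source_orientation: np.ndarray | None = None
    coupling_applied: CouplingSpec | None = None
    coupling_z: np.ndarray | None = None  # per-opening-movement modulation in [-1,1]

    @property
    def opening_onsets(self) -> np.ndarray:
        """BC opening-movement onset times (t1 landmarks), s, articulatory clock."""
        return self.cycles["t1"].to_numpy()


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named substream of the config seed (stable across runs and stages)."""
    import hashlib
    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Articulatory session
# ---------------------------------------------------------------------------

def _draw_cycles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample per-cycle amplitudes/durations and lay out the session timeline."""
    rows = []
    half = 0.5 / config.cycle_rate
    starts = []
    t0 = config.inter_trial_interval
    for k in range(config.n_trial_sets):
        starts.append(t0)
        t = t0
        ci = len(rows)
        while True:
            d_open = half * math.exp(rng.normal(0.0, config.duration_jitter))
            d_close = half * math.exp(rng.normal(0.0, config.duration_jitter))
            d_open = max(d_open, MIN_MOVEMENT_DURATION)
            d_close = max(d_close, MIN_MOVEMENT_DURATION)
            if t + d_open + d_close > t0 + config.trial_set_duration:
                break
            amp = rng.normal(config.amplitude_mean, config.amplitude_sd)
            amp = max(amp, 0.25 * config.amplitude_mean)
            rows.append(
                dict(trial_set=k, cycle=len(rows) - ci, t_start=t,
                     d_open=d_open, d_close=d_close, amplitude=amp)
            )
            t += d_open + d_close
        t0 += config.trial_set_duration + config.inter_trial_interval
    df = pd.DataFrame(rows)
    # analytic landmarks and kinematics of the raised-cosine primitive
    df["t_max"] = df.t_start + df.d_open
    df["t_end"] = df.t_max + df.d_close
    df["t1"] = df.t_start + RAISED_COSINE_F10 * df.d_open
    df["t2"] = df.t_start + RAISED_COSINE_F90 * df.d_open
    df["t3"] = df.t_max + RAISED_COSINE_F10 * df.d_close
    df["t4"] = df.t_max + RAISED_COSINE_F90 * df.d_close
    df["peak_velocity_open"] = df.amplitude * math.pi / (2.0 * df.d_open)
    df["peak_velocity_close"] = df.amplitude * math.pi / (2.0 * df.d_close)
    df["stiffness_open"] = math.pi / (2.0 * df.d_open)
    df["stiffness_close"] = math.pi / (2.0 * df.d_close)
    windows = np.array([[s, s + config.trial_set_duration] for s in starts])
    return df, windows


def _bc_waveform(t: np.ndarray, cycles: pd.DataFrame, baseline: float) -> np.ndarray:
    """Bilabial-aperture magnitude: raised-cosine open/close cycle train."""
    x = np.full_like(t, baseline)
    for row in cycles.itertuples():
        sel = (t >= row.t_start) & (t < row.t_max)
        x[sel] = baseline + row.amplitude / 2.0 * (
            1.0 - np.cos(np.pi * (t[sel] - row.t_start) / row.d_open))
        sel = (t >= row.t_max) & (t < row.t_end)
        x[sel] = baseline + row.amplitude / 2.0 * (
            1.0 + np.cos(np.pi * (t[sel] - row.t_max) / row.d_close))
    return x


def _cycle_phase(t: np.ndarray, cycles: pd.DataFrame) -> np.ndarray:
    """Continuous cycle phase theta in [0, 2pi): 0 at cycle start, pi at the peak."""
    theta = np.zeros_like(t)
    for row in cycles.itertuples():
        sel = (t >= row.t_start) & (t < row.t_max)
        theta[sel] = np.pi * (t[sel] - row.t_start) / row.d_open
        sel = (t >= row.t_max) & (t < row.t_end)
        theta[sel] = np.pi + np.pi * (t[sel] - row.t_max) / row.d_close
    return theta


def simulate_articulatory_session(
    config: SimulationConfig,
) -> tuple[dict[str, ArticulatoryTrack], AcousticChannel, GroundTruth]:
    """Generate coil tracks, an acoustic envelope and their ground truth.

    Tracks: upper lip (UL) / lower lip (LL) whose x-y distance is the BC
    gesture, tongue body (TB) / nasal reference (NAS) whose x-y distance is
    the TB gesture, plus fixed fiducial coils (nose, left_ear, right_ear)
    already in the occlusal frame.  The acoustic channel is an envelope with
    one burst per /p/ closure (offset of each closing movement).
    """
    rng = _rng_for(config, "articulatory")
    cycles, windows = _draw_cycles(config, rng)
    fs = config.sampling_rate_track
    t = np.arange(0.0, config.session_duration, 1.0 / fs)

    bc = _bc_waveform(t, cycles, baseline=2.0)
    theta = _cycle_phase(t, cycles)
    phi = -np.pi / 2.0 if config.utterance == "ipa" else np.pi / 2.0
    a_tb = config.amplitude_mean
    in_speech = np.zeros_like(t, bool)
    for lo, hi in windows:
        in_speech |= (t >= lo) & (t < hi)
    tb = 15.0 + a_tb / 2.0 * (1.0 - np.cos(theta + phi))
    tb[~in_speech] = 15.0 + a_tb / 2.0 * (1.0 - math.cos(phi))

    zeros = np.zeros_like(t)
    ll = np.column_stack([zeros, zeros, zeros])
    ul = np.column_stack([0.6 * bc, 0.8 * bc, zeros])
    nas = np.column_stack([np.full_like(t, 60.0), np.full_like(t, 0.0), np.full_like(t, 40.0)])
    tbp = nas.copy()
    tbp[:, 0] -= 0.6 * tb
    tbp[:, 1] -= 0.8 * tb

    tracks = {
        "UL": ArticulatoryTrack("UL", t, ul),
        "LL": ArticulatoryTrack("LL", t, ll),
        "TB": ArticulatoryTrack("TB", t, tbp),
        "NAS": ArticulatoryTrack("NAS", t, nas),
        "nose": ArticulatoryTrack("nose", t, np.tile([60.0, 0.0, 0.0], (len(t), 1))),
        "left_ear": ArticulatoryTrack("left_ear", t, np.tile([0.0, 40.0, 0.0], (len(t), 1))),
        "right_ear": ArticulatoryTrack("right_ear", t, np.tile([0.0, -40.0, 0.0], (len(t), 1))),
    }

    # acoustic envelope: Gaussian burst at each closure offset (/p/ release)
    env = np.zeros_like(t)
    sigma = 0.03
    for t4 in cycles["t4"]:
        sel = np.abs(t - t4) < 5 * sigma
        env[sel] += np.exp(-0.5 * ((t[sel] - t4) / sigma) ** 2)
    acoustic = AcousticChannel(time=t, data=env, sfreq=fs)

    truth = GroundTruth(cycles=cycles, trial_set_windows=windows, config=config)
    return tracks, acoustic, truth


# ---------------------------------------------------------------------------
# Leadfield
# ---------------------------------------------------------------------------

def make_leadfield(
    n_sensors: int = 64,
    grid_shape: tuple[int, int, int] = (5, 5, 5),
    grid_spacing: float = 4.0,
    head_radius: float = 80.0,
    seed: int | np.random.Generator | None = 0,
) -> Leadfield:
    """Magnetic-dipole leadfield on a regular grid under a sensor hemisphere.

    Sensors are laid out on an upper hemisphere of ``head_radius`` * 1.25 mm
    (Fibonacci spacing with a small seeded jitter) measuring the radial field
    component; gains follow the magnetostatic dipole law
    B(r) ~ (q x (r_s - r)) / |r_s - r|^3.  Coincident grid points are flagged
    in metadata (duplicated columns); duplicate sensor positions raise.
    """
    rng = np.random.default_rng(seed)
    n = n_sensors
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = 0.15 + 0.85 * (i + 0.5) / n               # upper hemisphere
    az = 2 * np.pi * i / golden
    r_sens = head_radius * 1.25
    sens = np.column_stack([
        np.sqrt(1 - z ** 2) * np.cos(az), np.sqrt(1 - z ** 2) * np.sin(az), z
    ]) * r_sens
    sens += rng.normal(0.0, 0.5, sens.shape)
    d = np.linalg.norm(sens[:, None] - sens[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-6:
        raise ValueError("degenerate geometry: duplicate sensor positions")

    nx, ny, nz = grid_shape
    ax = [(np.arange(m) - (m - 1) / 2.0) * grid_spacing for m in (nx, ny, nz)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel() + head_radius * 0.3])

    diffs = sens[:, None, :] - grid[None, :, :]           # (S, P, 3)
    dist3 = np.linalg.norm(diffs, axis=-1) ** 3           # (S, P)
    # near-radial sensor orientations with realistic mounting scatter (a
    # perfectly radial array would be blind to radial dipole components)
    nhat = sens / np.linalg.norm(sens, axis=1, keepdims=True)
    nhat = nhat + rng.normal(0.0, 0.05, nhat.shape)
    nhat /= np.linalg.norm(nhat, axis=1, keepdims=True)
    gain = np.empty((n, grid.shape[0], 3))
    eye = np.eye(3)
    for k in range(3):
        cr = np.cross(np.broadcast_to(eye[k], diffs.shape), diffs)  # q x (r_s - r)
        gain[:, :, k] = np.einsum("spj,sj->sp", cr, nhat) / dist3
    gain *= 1e4  # convenient numeric scale

    meta: dict = {}
    dg = np.linalg.norm(grid[:, None] - grid[None, :], axis=-1)
    np.fill_diagonal(dg, np.inf)
    dup = np.argwhere(dg < 1e-9)
    if len(dup):
        meta["degenerate_point_pairs"] = [tuple(p) for p in dup[dup[:, 0] < dup[:, 1]]]
    return Leadfield(grid=grid, gain=gain, spacing=grid_spacing,
                     sensor_positions=sens, metadata=meta)


# ---------------------------------------------------------------------------
# MEG session
# ---------------------------------------------------------------------------

@dataclass
class SensorRecording:
    """Multichannel MEG-like recording with an embedded acoustic channel."""

    data: np.ndarray       # (n_channels, n_samples)
    sfreq: float
    acoustic: np.ndarray   # (n_samples,) auxiliary acoustic envelope channel
    first_sample_time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _narrowband_noise(n: int, fs: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    lo, hi = band
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / max(y.std(), 1e-12)


def _smooth_gate(gate: np.ndarray, fs: float, ramp: float = 0.2) -> np.ndarray:
    w = signal.windows.hann(max(int(ramp * fs), 3))
    return signal.fftconvolve(gate, w / w.sum(), mode="same")


def _coupling_z(values: np.ndarray) -> np.ndarray:
    """Monotone map of a kinematic parameter onto [-1, 1] (rank-linear)."""
    order = np.argsort(np.argsort(values))
    n = len(values)
    if n < 2:
        return np.zeros(n)
    return 2.0 * order / (n - 1.0) - 1.0


def simulate_meg_session(
    config: SimulationConfig,
    leadfield: Leadfield,
    truth: GroundTruth,
    acoustic: AcousticChannel | None = None,
) -> tuple[SensorRecording, GroundTruth]:
    """Project a speech-locked oscillatory source into sensor space.

    The target grid point carries band-limited beta (and optionally mu)
    activity whose amplitude drops by ``erd_depth`` during trial sets and
    rebounds between them; broadband >50 Hz artifact bursts with a fixed
    random sensor topography are injected at movement onsets; when coupling
    is configured, single-trial power in the coupling band, in a window
    starting ``onset_lead_ms`` before each opening-movement onset, is a
    monotone function of that trial's kinematic parameter.  The acoustic
    envelope is embedded with ``device_lag`` samples of clock offset relative
    to the articulatory session.
    """
    if leadfield.n_sensors != config.n_sensors:
        raise ValueError(
            f"leadfield has {leadfield.n_sensors} sensors, config expects "
            f"{config.n_sensors}")
    rng = _rng_for(config, "meg")
    fs = config.sampling_rate_meg
    lag = int(config.device_lag)
    n_samples = int(round(config.session_duration * fs)) + abs(lag)
    # MEG sample n corresponds to articulatory-clock time (n - lag) / fs
    t_art = (np.arange(n_samples) - lag) / fs

    src_idx = (config.source_location if config.source_location is not None
               else leadfield.n_points // 2)
    orientation = rng.standard_normal(3)
    orientation /= np.linalg.norm(orientation)

    in_speech = np.zeros(n_samples, bool)
    for lo, hi in truth.trial_set_windows:
        in_speech |= (t_art >= lo) & (t_art < hi)
    erd_env = _smooth_gate(
        np.where(in_speech, 1.0 - config.erd_depth, 1.0), fs)

    source = _narrowband_noise(n_samples, fs, config.beta_band, rng) * erd_env
    if config.mu_gain > 0:
        source = source + config.mu_gain * (
            _narrowband_noise(n_samples, fs, config.mu_band, rng) * erd_env)

    coupling_z = None
    if config.coupling is not None and config.coupling.gain != 0.0:
        cp = config.coupling
        param_col = {
            "stiffness": "stiffness_open", "duration": "d_open",
            "amplitude": "amplitude", "velocity": "peak_velocity_open",
        }[cp.parameter]
        values = truth.cycles[param_col].to_numpy()
        coupling_z = _coupling_z(values)
        gate = np.zeros(n_samples)
        lead = cp.onset_lead_ms / 1e3
        dur = cp.duration_ms / 1e3
        for t1, z in zip(truth.cycles["t1"], coupling_z):
            sel = (t_art >= t1 - lead) & (t_art < t1 - lead + dur)
            gate[sel] = cp.gain * z
        carrier = _narrowband_noise(n_samples, fs, cp.band, rng)
        source = source + carrier * erd_env * (1.0 + _smooth_gate(gate, fs, 0.05))

    g = leadfield.gain[:, src_idx, :] @ orientation      # (n_sensors,)
    data = np.outer(g / np.linalg.norm(g), config.source_amplitude * source)
    data += config.noise_sd * rng.standard_normal(data.shape)

    if config.artifact_gain > 0:
        # speech-movement muscle artifact is high-rank (many independent
        # motor units): independent >50 Hz bursts on every sensor, so a
        # beamformer cannot spatially null it
        sos = signal.butter(4, 50.0, btype="high", fs=fs, output="sos")
        nb = int(config.artifact_duration * fs)
        win = signal.windows.hann(nb)
        for t1 in truth.cycles["t1"]:
            i0 = int(round(t1 * fs)) + lag
            if i0 < 0 or i0 + nb > n_samples:
                continue
            burst = signal.sosfiltfilt(
                sos, rng.standard_normal((config.n_sensors, nb)), axis=-1)
            data[:, i0:i0 + nb] += config.artifact_gain * burst * win

    if acoustic is None:
        ac = np.zeros(n_samples)
    else:
        ac = np.interp(t_art, acoustic.time, acoustic.data, left=0.0, right=0.0)

    recording = SensorRecording(data=data, sfreq=fs, acoustic=ac)
    truth_out = replace(
        truth, device_lag=lag, source_index=src_idx,
        source_orientation=orientation,
        coupling_applied=config.coupling, coupling_z=coupling_z,
    )
    return recording, truth_out


# ---------------------------------------------------------------------------
# Reduced-scale generator for decoding/RSA statistical studies
# ---------------------------------------------------------------------------

def simulate_trial_band_power(
    n_trials: int = 150,
    n_times: int = 50,
    time_range: tuple[float, float] = (-1.5, 1.5),
    bands: tuple[str, ...] = ("mu", "beta", "gamma"),
    coupling_band: str = "beta",
    coupling_gain: float = 0.0,
    coupling_parameter: str = "stiffness",
    onset_lead_ms: float = 90.0,
    coupling_duration_ms: float = 300.0,
    noise_sigma: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Per-trial band-power matrices with optional kinematic coupling.

    Emulates the band-averaged virtual-sensor spectrograms of epoched speech
    trials at reduced resolution, for statistical studies of the RSA chain
    (error-rate and parameter-recovery simulations): log-normal baseline
    power, plus — when ``coupling_gain`` > 0 — a multiplicative modulation
    (1 + gain * z_i) of ``coupling_band`` power in the window
    [-onset_lead, -onset_lead + duration] around the movement onset at t=0,
    with z_i a monotone [-1, 1] map of the trial's kinematic parameter.

    Returns (power (trials x times x bands), per-trial kinematic parameters,
    time axis in s).
    """
    rng = np.random.default_rng(rng)
    times = np.linspace(*time_range, n_times)
    durations = 0.18 * np.exp(rng.normal(0.0, 0.35, n_trials))
    amplitudes = np.maximum(rng.normal(10.0, 1.5, n_trials), 2.0)
    params = pd.DataFrame({
        "duration": durations,
        "amplitude": amplitudes,
        "stiffness": math.pi / 2.0 / durations,
        "velocity": amplitudes * math.pi / (2.0 * durations),
    })
    power = np.exp(noise_sigma * rng.standard_normal((n_trials, n_times, len(bands))))
    if coupling_gain != 0.0:
        b = bands.index(coupling_band)
        z = _coupling_z(params[coupling_parameter].to_numpy())
        lead = onset_lead_ms / 1e3
        eps = 1e-9
        sel = (times >= -lead - eps) & (times < -lead + coupling_duration_ms / 1e3 - eps)
        power[:, sel, b] *= (1.0 + coupling_gain * z)[:, None]
    return power, params, times
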