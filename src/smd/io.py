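"""Formats, configuration, seeding and pipeline orchestration.

Tracks, gestures and movement tables travel as TSV; sensor sessions with
their leadfield, events and ground truth live in a versioned HDF5 container;
configurations are YAML and are echoed into every output for provenance.
All randomness flows from one root seed, fanned out into named per-stage
substreams so stages can be re-run independently yet reproducibly; every
pipeline run emits exactly one JSON manifest recording the config snapshot,
seeds and input/output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import alignment, beamforming, kinematics, rsa, synthetic, tf_decoding
from .kinematics import ArticulatoryTrack
from .synthetic import CouplingSpec, GroundTruth, SensorRecording, SimulationConfig

logger = logging.getLogger(__name__)

CONTAINER_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the root seed."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(root_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(root_seed, stage))


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def write_tracks(path: str | Path, tracks: dict[str, ArticulatoryTrack]) -> None:
    """TSV with a time_s column then <coil>_x/_y/_z mm columns (lossless)."""
    cols = {"time_s": next(iter(tracks.values())).time}
    for name, tr in tracks.items():
        for k, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = tr.position[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tracks(path: str | Path) -> dict[str, ArticulatoryTrack]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("malformed track file: missing column 'time_s'")
    t = df["time_s"].to_numpy()
    names = []
    for c in df.columns:
        if c.endswith("_x"):
            names.append(c[:-2])
    tracks = {}
    for name in names:
        for ax in "xyz":
            if f"{name}_{ax}" not in df.columns:
                raise ValueError(f"malformed track file: missing column '{name}_{ax}'")
        pos = df[[f"{name}_{ax}" for ax in "xyz"]].to_numpy()
        tracks[name] = ArticulatoryTrack(name, t, pos)
    if not tracks:
        raise ValueError("malformed track file: no coil columns found")
    return tracks


def write_events(path: str | Path, events: alignment.EventList, sfreq: float) -> None:
    pd.DataFrame({
        "sample": events.samples,
        "time_s": events.samples / sfreq,
        "label": events.labels,
    }).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> alignment.EventList:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time_s", "label"):
        if col not in df.columns:
            raise ValueError(f"malformed event file: missing column '{col}'")
    return alignment.EventList(samples=df["sample"].to_numpy(int),
                               labels=df["label"].to_numpy())


# ---------------------------------------------------------------------------
# Config (YAML)
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def dict_to_config(d: dict) -> SimulationConfig:
    d = dict(d)
    if d.get("coupling") is not None:
        cp = dict(d["coupling"])
        if "band" in cp and cp["band"] is not None:
            cp["band"] = tuple(cp["band"])
        d["coupling"] = CouplingSpec(**cp)
    for key in ("beta_band", "mu_band", "grid_shape"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return dict_to_config(yaml.safe_load(fh) or {})


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_container(
    path: str | Path,
    recording: SensorRecording,
    leadfield: beamforming.Leadfield,
    truth: GroundTruth,
    events: alignment.EventList | None = None,
) -> None:
    """Versioned hierarchical container: /sensors, /leadfield, /events, /truth."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CONTAINER_SCHEMA_VERSION
        g = f.create_group("sensors")
        g.create_dataset("data", data=recording.data)
        g.create_dataset("acoustic", data=recording.acoustic)
        g.attrs["sfreq"] = recording.sfreq
        g = f.create_group("leadfield")
        g.create_dataset("gain", data=leadfield.gain)
        g.create_dataset("grid", data=leadfield.grid)
        g.attrs["spacing"] = leadfield.spacing
        if leadfield.sensor_positions is not None:
            g.create_dataset("sensor_positions", data=leadfield.sensor_positions)
        if events is not None:
            g = f.create_group("events")
            g.create_dataset("sample", data=events.samples)
            g.create_dataset("label", data=np.array(events.labels, dtype="S32"))
        g = f.create_group("truth")
        for col in truth.cycles.columns:
            g.create_dataset(f"cycles/{col}", data=truth.cycles[col].to_numpy())
        g.create_dataset("trial_set_windows", data=truth.trial_set_windows)
        if truth.device_lag is not None:
            g.attrs["device_lag"] = truth.device_lag
        if truth.source_index is not None:
            g.attrs["source_index"] = truth.source_index
        if truth.source_orientation is not None:
            g.create_dataset("source_orientation", data=truth.source_orientation)
        if truth.coupling_z is not None:
            g.create_dataset("coupling_z", data=truth.coupling_z)
        f.create_dataset("config", data=yaml.safe_dump(config_to_dict(truth.config)))


def read_container(path: str | Path):
    """Load a session container; returns (recording, leadfield, truth, events)."""
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise OSError(f"cannot open container {path}: file missing, truncated or "
                      f"not HDF5") from err
    with f:
        version = f.attrs.get("schema_version")
        if version != CONTAINER_SCHEMA_VERSION:
            raise ValueError(
                f"container schema version {version!r} does not match reader "
                f"version {CONTAINER_SCHEMA_VERSION!r}")
        config = dict_to_config(yaml.safe_load(f["config"][()].decode()))
        recording = SensorRecording(
            data=f["sensors/data"][()], sfreq=float(f["sensors"].attrs["sfreq"]),
            acoustic=f["sensors/acoustic"][()],
        )
        lf = beamforming.Leadfield(
            grid=f["leadfield/grid"][()], gain=f["leadfield/gain"][()],
            spacing=float(f["leadfield"].attrs["spacing"]),
            sensor_positions=(f["leadfield/sensor_positions"][()]
                              if "sensor_positions" in f["leadfield"] else None),
        )
        cycles = pd.DataFrame(
            {k: f[f"truth/cycles/{k}"][()] for k in f["truth/cycles"]})
        truth = GroundTruth(
            cycles=cycles, trial_set_windows=f["truth/trial_set_windows"][()],
            config=config,
            device_lag=(int(f["truth"].attrs["device_lag"])
                        if "device_lag" in f["truth"].attrs else None),
            source_index=(int(f["truth"].attrs["source_index"])
                          if "source_index" in f["truth"].attrs else None),
            source_orientation=(f["truth/source_orientation"][()]
                                if "source_orientation" in f["truth"] else None),
            coupling_z=(f["truth/coupling_z"][()]
                        if "coupling_z" in f["truth"] else None),
        )
        events = None
        if "events" in f:
            events = alignment.EventList(
                samples=f["events/sample"][()],
                labels=np.array([s.decode() for s in f["events/label"][()]]),
            )
    return recording, lf, truth, events


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    root_seed: int
    stage_seeds: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: str = ""
    package_version: str = ""

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
    skip: tuple[str, ...] = (),
    virtual_sensor_source: int | None = None,
    searchlight_freqs: np.ndarray | None = None,
    rsa_model: str = "stiffness_duration",
    n_partitions: int = 10,
) -> RunManifest:
    """Run simulate -> kinematics -> align -> localize -> decode -> rsa.

    Per-stage skips are honoured (``skip=("localize",)`` with
    ``virtual_sensor_source`` extracts the virtual sensor at a given grid
    index instead of the pseudo-T peak).  Any stage failure raises with a
    stage-tagged message.  Outputs (TSV tables, JSON reports, one manifest)
    land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.replace(seed=seed)
    root_seed = config.seed
    manifest = RunManifest(
        config=config_to_dict(config), root_seed=root_seed,
        stage_seeds={s: stage_seed(root_seed, s)
                     for s in ("simulate", "align", "decode", "rsa")},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "simulate"
    try:
        tracks, acoustic, truth = synthetic.simulate_articulatory_session(config)
        lf = synthetic.make_leadfield(config.n_sensors, config.grid_shape,
                                      config.grid_spacing,
                                      seed=stage_seed(root_seed, "leadfield"))
        recording, truth = synthetic.simulate_meg_session(config, lf, truth, acoustic)
        write_tracks(out / "tracks.tsv", tracks)
        write_container(out / "session.h5", recording, lf, truth)
        manifest.stages_run.append(stage)

        stage = "kinematics"
        bc = kinematics.compute_gesture(tracks["UL"], tracks["LL"], "xy", "BC")
        cycles = kinematics.detect_movements(bc, min_amplitude=0.3 * config.amplitude_mean)
        records = [r for c in cycles for r in kinematics.compute_kinematics(bc, c)]
        records, n_excluded = kinematics.exclude_outliers(records)
        va, sd = kinematics.build_profiles(records)
        kinematics.records_to_frame(records).to_csv(out / "movements.tsv",
                                                    sep="\t", index=False)
        manifest.outputs["n_movements"] = len(records)
        manifest.outputs["n_excluded"] = n_excluded
        manifest.outputs["velocity_amplitude_r"] = va.fit["r"]
        manifest.stages_run.append(stage)

        stage = "align"
        mask_ac = np.interp(np.arange(recording.n_samples) / recording.sfreq,
                            acoustic.time, acoustic.data, left=0.0, right=0.0)
        lag = alignment.estimate_lag(recording.acoustic, mask_ac, recording.sfreq,
                                     max_lag=int(recording.sfreq))
        opening = [r for r in records if r.movement_type == "opening"]
        events = alignment.map_landmarks(
            np.array([r.onset_time for r in opening]), lag.lag, recording.sfreq,
            recording.n_samples)
        write_events(out / "events.tsv", events, recording.sfreq)
        manifest.outputs["estimated_lag"] = lag.lag
        manifest.outputs["true_lag"] = truth.device_lag
        manifest.stages_run.append(stage)

        stage = "localize"
        if stage in skip:
            src = (virtual_sensor_source if virtual_sensor_source is not None
                   else truth.source_index)
        else:
            onsets = alignment.EventList(
                samples=np.round(truth.trial_set_windows[:, 0]
                                 * recording.sfreq).astype(int) + truth.device_lag,
                labels=np.full(len(truth.trial_set_windows), "speech_trialset_onset",
                               dtype=object))
            loc_window = (-min(config.inter_trial_interval, 10.0),
                          min(5.0, config.trial_set_duration))
            ep = alignment.epoch(recording.data, recording.sfreq, onsets,
                                 window=loc_window, bandpass=(0.0, 100.0),
                                 notch=50.0)
            preset = beamforming.PRESETS["speech"]
            baseline = (max(loc_window[0] + 0.5, -5.0), -0.5)
            tmap = beamforming.pseudo_t_map(
                ep.data, ep.times, recording.sfreq, lf,
                active_windows=preset["active_windows"],
                baseline_window=baseline, band=preset["band"])
            # speech suppresses beta: the source is the most negative pseudo-T
            src = int(np.argmin(tmap.values))
            pd.DataFrame(np.column_stack([lf.grid, tmap.values]),
                         columns=["x", "y", "z", "pseudo_t"]).to_csv(
                out / "pseudo_t.tsv", sep="\t", index=False)
            manifest.stages_run.append(stage)
        manifest.outputs["source_index"] = int(src)
        manifest.outputs["true_source_index"] = truth.source_index

        stage = "decode"
        ep = alignment.epoch(recording.data, recording.sfreq, events,
                             window=(-2.0, 2.0), bandpass=(0.0, 100.0),
                             notch=50.0, truncate=(-1.5, 1.5))
        rest = alignment.sample_rest_events(
            _rest_intervals(truth), ep.n_trials, recording.sfreq, (-2.0, 2.0),
            rng=stage_rng(root_seed, "rest-events"), lag=truth.device_lag)
        ep_rest = alignment.epoch(recording.data, recording.sfreq, rest,
                                  window=(-2.0, 2.0), bandpass=(0.0, 100.0),
                                  notch=50.0, truncate=(-1.5, 1.5))
        n_trials = min(ep.n_trials, ep_rest.n_trials)
        cov = beamforming.compute_covariance(ep.data, ep.times, recording.sfreq)
        w, ori = beamforming.beamformer_weights(cov, lf.gain[:, src, :])
        freqs = (np.arange(4.0, recording.sfreq / 2 - 5.0, 2.0)
                 if searchlight_freqs is None else np.asarray(searchlight_freqs))
        decim = max(int(recording.sfreq // 50), 1)
        tf_s = beamforming.virtual_sensor_tf(
            np.einsum("c,tcs->ts", w, ep.data[:n_trials]), recording.sfreq,
            freqs, decim=decim)
        tf_r = beamforming.virtual_sensor_tf(
            np.einsum("c,tcs->ts", w, ep_rest.data[:n_trials]), recording.sfreq,
            freqs, decim=decim)
        cmap = tf_decoding.tf_searchlight(tf_s, tf_r, neighborhood=1,
                                          seed=stage_seed(root_seed, "decode"))
        _write_map(out / "accuracy_map.tsv", cmap.accuracy,
                   ep.times[::decim], freqs)
        manifest.outputs["searchlight_max_accuracy"] = float(cmap.accuracy.max())
        manifest.stages_run.append(stage)

        stage = "rsa"
        params = kinematics.records_to_frame(opening).rename(
            columns={"peak_velocity": "velocity"})
        n_use = min(len(params), tf_s.shape[0])
        if n_use >= 5 * n_partitions:  # every partition must support 5-fold CV
            bands = rsa.band_average(tf_s[:n_use], freqs)
            rmap = rsa.rsa_subject_map(
                bands, params.iloc[:n_use], ep.times[::decim], model=rsa_model,
                n_partitions=n_partitions, seed=stage_seed(root_seed, "rsa"))
            _write_map(out / "rsa_map.tsv", rmap.correlation, rmap.times,
                       np.arange(bands.shape[-1]))
            manifest.stages_run.append(stage)
        else:
            logger.warning("rsa: too few trials (%d) for %d partitions; skipped",
                           n_use, n_partitions)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    for p in sorted(out.glob("*")):
        if p.name != "manifest.json":
            manifest.outputs.setdefault("checksums", {})[p.name] = file_checksum(p)
    manifest.save(out / "manifest.json")
    return manifest


def _rest_intervals(truth: GroundTruth) -> np.ndarray:
    """Inter-trial-set rest intervals (s, articulatory clock)."""
    cfg = truth.config
    w = truth.trial_set_windows
    rests = [(0.0, w[0, 0])]
    for k in range(len(w) - 1):
        rests.append((w[k, 1], w[k + 1, 0]))
    rests.append((w[-1, 1], cfg.session_duration))
    return np.asarray(rests)


def _write_map(path, values, rows, cols) -> None:
    pd.DataFrame(values, index=np.asarray(rows),
                 columns=np.asarray(cols)).to_csv(path, sep="\t",
                                                  index_label="time_s")
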