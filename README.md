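# smd — speech-motor decoding from concurrent articulography and MEG

`smd` implements an analysis pipeline for experiments that track speech
articulator movements (lip, tongue and jaw coils of an MEG-compatible
articulograph) *simultaneously* with whole-head MEG, during reiterated
nonword speech (/ipa/, /api/ produced continuously in ~12 s breath groups).
It is written for speech motor control researchers who want to test whether
kinematic structure measured at the articulators is encoded in the mu
(8–12 Hz) and beta (13–30 Hz) rhythms of speech motor cortex.

The pipeline has four phases, each usable on its own:

1. **Kinematics** (`smd.kinematics`) — occlusal-frame transform, gestural
   signals as 2-D inter-coil distances (bilabial closure BC, tongue-body
   constriction TB), segmentation of opening/closing movements with
   sub-sample 10 %/90 % landmarks, and the classical kinematic parameters:
   amplitude *A*, duration *D*, peak velocity *v*, stiffness *k = v/A*.
   Across movements these obey two lawful profiles — *v* ≈ linear in *A*,
   and *k* a curvilinear, plateauing function of *D* — which serve as the
   behavioural models downstream.
2. **Alignment & beamforming** (`smd.alignment`, `smd.beamforming`) —
   cross-correlation of the two devices' acoustic channels recovers the
   clock lag; events are epoched (zero-phase Butterworth 0–100 Hz + 50 Hz
   notch); a SAM-style beamformer with optimized dipole orientation maps the
   pseudo-T contrast

       T = (P_active − P_baseline) / (2 σ² ‖w‖²),   w = C⁻¹l / (lᵀC⁻¹l)

   over a source grid (speech suppresses beta, so the speech motor source is
   the pseudo-T *minimum*), with omnibus sign-flip permutation thresholding
   at the group level and "virtual sensor" source time series.
3. **Time–frequency MVPA** (`smd.tf_decoding`) — per-trial Morlet
   spectrograms of the virtual sensor; a searchlight shrinkage-LDA
   classification of speech vs rest at every (time, frequency) point
   (5 folds × 5 repetitions); frequency generalisation (train at one
   frequency, test at another) to separate genuine rhythm structure from
   >50 Hz movement artifact; Wilcoxon/sign-flip cluster statistics.
4. **RSA** (`smd.rsa`) — trials partitioned into 10 equal blocks along a
   kinematic profile; behavioural RDM = distances between partition means;
   neural RDM = pairwise-partition classification accuracy per
   time–frequency point; their Spearman correlation, band-averaged and
   cluster-tested across subjects, asks *when* and *in which rhythm* the
   kinematic structure is encoded.

Because the paradigm's recordings are not public, `smd.synthetic` generates
complete articulatory + MEG sessions from a raised-cosine movement primitive
(closed-form kinematics: v = Aπ/2D, k = π/2D, 10/90 % crossings at 0.2048 D
and 0.7952 D) with phase-reversed /ipa/ vs /api/ coordination, beta
event-related desynchronisation, movement-locked broadband artifact, a known
device lag, and optional trial-wise coupling between a kinematic parameter
and pre-movement beta power — every generated quantity is recorded as ground
truth, so each stage has an exact oracle. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

Run the whole chain on a synthetic session (6 trial sets of 12 s at the
normal rate, 32 sensors, 4 mm-style grid, seeded):

```python
import numpy as np
from smd import SimulationConfig, io

cfg = SimulationConfig(n_trial_sets=6, trial_set_duration=12.0,
                       inter_trial_interval=6.0, sampling_rate_track=250.0,
                       sampling_rate_meg=250.0, n_sensors=32,
                       grid_shape=(4, 4, 4), seed=21, noise_sd=0.5,
                       source_location=30)
manifest = io.run_pipeline(cfg, "out/", n_partitions=8,
                           searchlight_freqs=np.arange(6.0, 100.0, 6.0))
print(manifest.outputs)
```

prints (seed 21):

```
n_movements 105            # opening+closing movements kept
n_excluded 5               # amplitude/duration outliers ("speech errors")
velocity_amplitude_r 0.963 # linearity of the velocity-amplitude profile
estimated_lag 120          # acoustic cross-correlation lag, samples
true_lag 120               # generator ground truth: recovered exactly
source_index 30            # pseudo-T extremum on the grid
true_source_index 30       # generator ground truth: localised exactly
searchlight_max_accuracy 0.894
```

The movement table, pseudo-T map, accuracy map and RSA map land in `out/` as
TSV, together with a JSON manifest recording the config, seeds and output
checksums. The same stages are exposed on the command line
(`smd simulate | kinematics | align | localize | decode | rsa | run`).

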