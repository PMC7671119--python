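# vromm

Marker-based videogrammetry and external-marker muscle strain analysis for
suction-feeding biomechanics.

## The problem

Suction-feeding fishes expand the mouth cavity in tens of milliseconds by
elevating the neurocranium and retracting/depressing the hyoid apparatus
and pectoral girdle. Measuring which muscles actually shorten to power
this motion normally requires X-ray methods (fluoromicrometry). Video
Reconstruction of Moving Morphology (VROMM) instead tracks small markers
sutured to the skin with two or three synchronized high-speed light
cameras, reconstructs their 3D trajectories, and — where the skin is
tightly coupled to the underlying muscle — estimates muscle strain from
the distance between markers spanning the muscle.

This package implements that full measurement chain, for biomechanists
working with multi-camera marker data:

- **Cameras** — 11-parameter DLT calibration from control points and
  linear multi-view triangulation (`vromm.cameras`).
- **Rigid bodies** — SVD (Kabsch) pose fitting for marker sets grouped by
  bone, a best-fit moving *body plane* from ≥ 5 trunk markers, and the
  standard tracking-precision metric: the SD over time of pairwise
  marker-to-marker distances within one rigid body (`vromm.rigid_body`).
- **Kinematics** — an anatomical coordinate system (ACS) parented to the
  body plane (+X rostral, +Y left, +Z dorsal) decomposing urohyal and
  cleithrum motion into retraction (−ΔX) and depression (−ΔZ), and a
  joint coordinate system (JCS) giving neurocranial elevation relative to
  the body plane, all zeroed on a pre-strike baseline and timed relative
  to peak gape (`vromm.kinematics`).
- **Strain** — muscle length L(t) as 3D inter-marker distance, strain
  s(t) = 100·(L_i − L(t))/L_i in % of the pre-strike length L_i
  (shortening positive), and instantaneous shortening velocity
  v(t) = −d(L/L_i)/dt in L_i·s⁻¹ from a zero-phase low-pass filtered
  normalized length (`vromm.strain`).
- **Validation** — per-trial OLS regression of external (skin-marker)
  strain on an internal reference: the slope against the ideal 1 is the
  method's *accuracy* (skin slip attenuates strain multiplicatively), the
  residual RMSE its *precision*; plus mean-of-means pooling across
  individuals, one-way ANOVA, and peak-vs-elevation correlations
  (`vromm.validation`).
- **Synthetic strikes** — a generator producing strikes with exact ground
  truth (raised-cosine kinematic pulses, a rigid neurocranium, a
  multiplicative skin-slip model linking external to internal strain) and
  a pinhole DLT camera rig to render noisy 2D observations, so every
  stage is testable without any recorded video (`vromm.synthetic`).
- **Pipeline** — file-based orchestration (CSV/YAML dialects) and a thin
  CLI: `vromm simulate`, `vromm run`, `vromm validate`
  (`vromm.pipeline`, `vromm.cli`).

## Worked example

Simulate a strike (7.2% peak sternohyoideus strain, skin-slip coupling
0.90, 0.3 px tracking noise), render it through three cameras, and run the
complete file-based pipeline:

```sh
python examples/03_trial_kinematics_and_strain.py
```

```
            variable unit     peak  peak_frame  latency_ms
  urohyal_retraction   mm 2.551183          50         0.0
  urohyal_depression   mm 3.513529          50         0.0
cleithrum_retraction   mm 1.545276          49        -2.0
cleithrum_depression   mm 1.062991          50         0.0
           elevation  deg 7.947843          50         0.0

sh: peak strain 6.42% of L_i at +16.0 ms after peak gape, peak shortening velocity 4.33 L_i/s
epaxial: peak strain 3.72% of L_i at +14.0 ms after peak gape, peak shortening velocity 2.47 L_i/s
```

The excursion peaks recover the simulated amplitudes (urohyal 2.5 mm
retraction / 3.5 mm depression, cleithrum 1.5 / 1.0 mm, elevation 8°)
within the tracking noise; the recovered SH strain is the simulated 7.2%
attenuated by the 0.90 skin-slip coupling (≈ 6.5%), peaking ~15 ms after
peak gape as configured. The other examples cover camera calibration
(`01`), reconstruction precision (`02`), and the external-vs-internal
method validation (`04`), each printing what its numbers mean.

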