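# Methods

## Camera model and reconstruction

Each camera is an 11-parameter direct linear transformation (DLT) from
world coordinates (mm) to pixels:

    u = (L1·X + L2·Y + L3·Z + L4) / (L9·X + L10·Y + L11·Z + 1)
    v = (L5·X + L6·Y + L7·Z + L8) / (L9·X + L10·Y + L11·Z + 1)

Calibration multiplies the equations through by the denominator and
solves the resulting linear system by least squares; it requires at least
6 control points and rejects (near-)coplanar configurations, for which
the 11-parameter model is rank-deficient. Triangulation stacks two linear
equations per observing camera and solves the 3×3 (or overdetermined)
system; frames seen by fewer than two cameras are *missing*, not errors,
and frames whose design matrix condition number exceeds 10⁶
(near-parallel rays) are flagged low-confidence. Refraction through water
and lens distortion are not modelled; over a small working volume the
linear DLT absorbs them approximately, and the synthetic cameras are
ideal pinholes that need neither. Triangulation is purely linear (no
iterative refinement): at the sub-pixel noise levels relevant here the
refinement gain is far below the tracking noise.

## Rigid bodies and the body plane

Marker sets grouped by bone are fitted per frame with the orthogonal
Procrustes / Kabsch solution (SVD with a reflection guard, det R = +1),
minimizing Σ‖R·ref + t − obs‖². Frames with fewer than 3 visible markers
are missing; collinear visible markers are flagged degenerate. All
markers are weighted equally. The pose residual is the RMS *per-point*
misfit (mm); under iid coordinate noise σ its expectation follows
degrees-of-freedom counting, E[RMS²] = σ²(3M − 6)/M for M markers.

The body plane is the same fit applied to ≥ 5 trunk markers, with the
reference configuration first re-expressed in an anatomical frame: +X is
the rostro-caudal principal axis of the marker cloud (signed toward the
first-listed, conventionally rostral-most, marker), +Z the direction
orthogonal to X closest to a dorsal hint vector, +Y completing a
right-handed (left-lateral) set. The fitted pose therefore *is* the
moving anatomical coordinate system (ACS).

Tracking precision is the SD over frames of each within-body pairwise
marker distance (true distances are constant), averaged over pairs.
Gap-filled frames are excluded from the precision metric — interpolation
deflates the SD artificially. Interior gaps up to a configurable length
(default 5 frames) are filled by cubic-spline interpolation per
coordinate; edge gaps are never extrapolated.

## Kinematics

Excursions: marker world positions are re-expressed in the per-frame ACS,
so whole-body swimming motion cancels; retraction = −(X − X̄_baseline) and
depression = −(Z − Z̄_baseline), both positive during suction expansion.
Elevation: the relative rotation R_bodyᵀ·R_neuro is referenced
*multiplicatively* to its quaternion mean over the baseline window — this
cancels the arbitrary orientation of the neurocranium's reference
configuration exactly — and decomposed in Z-Y-X Euler order (configurable;
for near-planar pitching the Y angle is insensitive to the order). The Y
angle in degrees is the elevation, dorsal rotation positive; |elevation| >
89° flags gimbal proximity. The baseline window defaults to the first 20
frames (40 ms at 500 fps), shared between kinematics and strain so that
excursion baselines and L_i refer to the same pre-strike epoch.

Peak gape — the time origin for all latencies — is either supplied in the
events file or detected as the global maximum of the jaw-marker-pair
distance after a light zero-phase Savitzky–Golay smooth (quadratic,
9 frames); ties resolve to the earliest frame.

## Strain and shortening velocity

Muscle length is the 3D distance between the two markers spanning the
muscle; L_i is its mean over the baseline window; strain is
100·(L_i − L)/L_i in % (shortening positive); velocity is the negated
central-difference derivative of the normalized length, in L_i·s⁻¹.

The normalized length is low-pass filtered once (4th-order Butterworth,
zero-phase via forward–backward filtering so peak *timing* is unbiased)
and both strain and velocity derive from the filtered series. Two reasons:
central differences amplify tracking noise, and the per-trial peak strain
is a maximum over ~100 noisy frames, which is biased upward on the raw
series (about +0.33% strain at 0.3 px pixel noise in the default
two-camera geometry). The default cutoff is 50 Hz at 500 fps: strike
transients of tens of ms have spectral content below ~40 Hz and pass
essentially unattenuated (< 0.02% strain error on the default pulse),
whereas a 25 Hz cutoff would clip the pulse peak by ~0.9% strain —
biasing exactly the quantities being reported. Filtering is off-switchable
(`filter_cutoff_hz=None`), and all machine-precision closure statements
below are made with it off.

## Validation statistics

For each paired trial, external strain is regressed on internal strain by
OLS (intercept free by default, configurable to forced-zero; a free
intercept is robust to baseline offsets between methods). Accuracy is the
slope over the ideal slope 1; precision is the residual RMSE in % strain.
Trials are pooled as the mean of per-trial slopes (not one pooled
regression), with SEM across trials; the underestimation margin is
100·(1 − mean accuracy). Series are compared at identical frames with no
time-warping — the two methods share the video clock. Group comparisons
use the classical one-way fixed-effects ANOVA, and summaries across
heterogeneous individuals use the unweighted mean of per-individual means
("mean of means") with SEM across individuals; the homogeneous
pooled-across-trials mean ± SEM is reported alongside. Peak excursions are
correlated against peak elevation with Pearson's r.

## The synthetic strike generator

The generator emulates a ~20 cm surfperch-like suction strike filmed at
500 fps for 200 ms by 1024×1024 px cameras about 65 cm away: a rigid
4-marker neurocranium, a 5-marker body plane, single urohyal / cleithrum /
postcleithrum / epaxial markers, and a jaw pair whose distance peaks
exactly at peak gape (real trials without jaw markers supply the event in
a file instead). Every kinematic variable follows a raised-cosine pulse —
smooth, bounded, analytic peak location and derivative. Defaults: 8°
elevation; urohyal retraction/depression 2.5/3.5 mm and cleithrum 1.5/1.0
mm (urohyal excursions exceed cleithrum excursions, urohyal depression >
retraction, cleithrum retraction > depression — the observed suction
pattern); peak SH strain 7.2% and epaxial strain 3.9% of initial lengths
(L_i 15 and 12 mm), peaking 15 ms after peak gape; kinematic pulse width
80 ms; strain pulse width 46 ms, at which 7.2% strain yields a peak
shortening velocity of ≈ 4.9 L_i·s⁻¹, the physiologically observed rate.

Skin slip — imperfect mechanical coupling between skin markers and the
underlying muscle — is modelled as a pure multiplicative strain
attenuation, L_ext(t) = L_i·(1 − α·s_int(t)/100) with α ∈ (0, 1], default
0.90. This is a phenomenological model chosen because empirical
attenuation is observed to be approximately multiplicative; no mechanism
(viscoelastic skin, fibre-angle change) is modelled. The external marker
at the muscle's caudal end is placed along a fixed direction at exactly
L_ext(t), so downstream strain recovery has a closed-form truth.

Neurocranial elevation rotates about the body-plane Y axis through a
fixed pivot, so the JCS recovers the set amplitude exactly; urohyal and
cleithrum displacements are applied along the body-plane −X and −Z axes,
so ACS excursions recover theirs. Rendering projects markers through the
DLT rig, flags points behind a camera as missing, and adds iid Gaussian
pixel noise (default 0.3 px) and optional dropout; all randomness comes
from a single seed.

What the generator does **not** emulate: refraction and lens distortion,
marker detection/occlusion structure of real video, asymmetric or
multi-phase strike profiles, body bending (the trunk is rigid), and any
mechanistic skin dynamics. Passing tests therefore demonstrate the
correctness and noise behaviour of the *estimators*, not the biological
fidelity of real tracking data.

## Numerical choices and degenerate inputs

- Peak/tie rule everywhere: earliest frame of the global maximum.
- A strain-peak lag of 15 ms at 500 fps falls between frames (7.5
  frames); sampled peaks are then up to ~0.011% strain below the
  continuous maximum and latencies quantize to 14/16 ms.
  Machine-precision closure tests use an on-grid 16 ms lag; noisy
  recovery tests keep 15 ms with frame-level tolerances.
- Missing data policy: < 2 camera views → missing 3D frame; < 3 visible
  markers → missing pose frame; missing frames in a strain series are
  bridged by linear interpolation only inside the low-pass filter and
  restored to NaN afterwards.
- Simulation sizes in tests and the acceptance script (10–20 replicate
  strikes, 100-frame trials, 1000–2000 Monte-Carlo replicates) were
  chosen so Monte-Carlo standard errors sit well below the tolerances
  being asserted.

## Known limitations

- The linear DLT degrades with strong refraction (underwater filming
  through flat ports); a refractive camera model is out of scope.
- The body plane assumes a rigid trunk; body bending during a strike
  leaks into excursions and elevation.
- Strain from two skin markers measures the chord of the muscle, not
  fascicle strain; the skin-slip factor is muscle- and species-specific
  and must be established against an internal reference method before
  external tracking is used quantitatively.
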