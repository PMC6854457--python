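# Methods

`opmbeam` implements a complete source-localisation analysis for wearable
OPM-MEG theta-power experiments, together with a synthetic-session generator
that provides ground truth for validating every stage.  This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic world does and does not capture.

## Forward model

The head is a homogeneous conducting sphere.  The external magnetic field of
a current dipole **Q** at position **r₀** (relative to the sphere centre) is
the closed-form solution

    B(r) = μ₀ / (4π F²) · ( F (Q × r₀) − ((Q × r₀) · r) ∇F ),
    F = a (r a + r² − r₀·r),   a = |r − r₀|,

which is exact for any sphere radius and conductivity profile with spherical
symmetry.  Two consequences shape the pipeline:

* **Silent radial sources.**  Dipoles parallel to the radius (and any dipole
  at the centre) produce no external field.  The lead field at each candidate
  source therefore uses a two-column *tangential* basis; the radial direction
  is excluded by construction, keeping the orientation optimisation
  well-posed.  The implementation detects the silent family explicitly
  (|Q × r₀| ≤ 1e−12 |Q||r₀|) and returns an exact zero.
* **No individual anatomy.**  A realistically meshed single-shell model would
  add nothing here: the synthetic world *is* a sphere, so the analytic
  solution is exact, and the beamformer/statistics chain is agnostic to how
  the lead fields were produced.

Tests verify radial silence (1e−15 absolute on unit moments), linearity
(1e−12 relative), rotational equivariance (1e−9), and agreement with an
independent implementation obtained by symbolically differentiating the
magnetic scalar potential (Q × r₀ · r)/(4πF) with sympy (1e−10 relative).

## Synthetic sessions

The generator emulates a three-participant wearable-OPM experiment: 21
radially oriented scalp magnetometers on a Fibonacci cap 6.5 mm above a
9 cm sphere (the inferior cap below z = −0.4 r is excluded, mimicking
scanner-cast coverage), plus four reference magnetometers clustered ~10 cm
behind the head whose sensitive axes span x/y/z with one duplicated axis at a
1.2 cm offset.  Sessions are epoched 3 s trials at 1200 Hz in two conditions,
"scene" (imagery) and "counting" (baseline).

**Source.**  A fixed current dipole at (36, −8, −16) mm — 0.45·r deep,
right-lateral-anterior, the depth and laterality of the anterior hippocampus —
with a tangential orientation drawn once per participant.  Its moment is
band-limited 4–8 Hz Gaussian noise, rescaled so each trial's sample SD equals
the condition amplitude exactly: 30 nAm during counting, 0.7 × 30 = 21 nAm
during scenes.  The scene condition therefore carries a theta *power*
decrease of factor 0.49 — trial-power contrast ratio ≈ 2 — which is the
direction and rough magnitude of hippocampal theta suppression the analysis
is designed to detect.  30 nAm is a plausible equivalent moment for sustained
deep theta; weaker settings shade continuously into non-detection, and the
default is chosen so that the synthetic study is decisively detectable, as
the real experiment was.

**Interference.**  Environmental interference is a time-varying uniform
field u(t) (3 dof, 100 pT per component) plus a linear gradient g(t)
(3 dof, 20 pT/m), each a low-pass Gaussian process (2nd-order Butterworth,
corner 1 Hz, zero phase, standardised then scaled).  Every channel sees
orientation · (u + G(p − c)), so scalp and reference arrays receive coherent
interference — the property synthetic gradiometry exploits.  The amplitudes
and corner frequency describe the *residual* field inside a shielded room
after nulling coils driven from the reference array have cancelled the
uniform field and gradients: what remains is drift-dominated (well below the
theta band) and small.  The three gradient dof are a fixed subspace of the
symmetric traceless gradient tensor (xx−yy, xy, xz); four reference channels
cannot identify more, and reference hardware reports three gradient
components.

**Noise and geometry.**  White sensor noise of 2.45e−13 T per sample
(10 fT/√Hz at 1200 Hz) is added everywhere.  Each participant's scalp
sensors and source position receive 1 mm Gaussian jitter — the registration
accuracy of scanner-cast OPM — so participants share one grid (identity
"normalisation") but differ slightly in true source location.  Reference
positions are fixed room furniture and are not jittered.

**Trial accounting.**  Completed / self-rated-successful / artefact-removed
counts per condition default to the wearable sessions' bookkeeping
(45/35/0 + 45/45/0; 75/68/7 + 75/75/6; 48/45/0 + 48/48/0).  Only successful,
artefact-free trials are usable; trial numbers are then equated across
conditions by a seeded uniform subsample of the larger condition, giving
35 / 61 / 45 analysed trials per condition for the three participants.
Artefacts are bookkeeping only — no artefact waveforms are injected, because
the analysis consumes artefact removal purely as counts.

**What the generator does not emulate.**  Head motion, cardiac/ocular
artefacts, sensor gain errors and cross-talk, the auditory cue structure and
inter-trial intervals, line noise, and non-spherical anatomy.  Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under its stated assumptions, not robustness to every artefact of real
recordings.  The ±1.5 nT hardware dynamic range is represented by an optional
clipping check (`clipping_fraction`), not by physical modelling.

## Preprocessing

Baseline correction subtracts each trial-channel's whole-epoch mean (no
within-epoch baseline window exists in this design; any constant is
annihilated by the band-pass anyway).  Synthetic gradiometry regresses each
scalp trace, per trial, on an intercept plus all reference traces by ordinary
least squares and keeps the residual — a projection, hence idempotent and
variance-non-increasing, with residuals orthogonal to the references within
each trial.  Design-matrix columns are rescaled to unit norm before solving
so that the rank decision reflects genuine collinearity rather than the
10-orders-of-magnitude difference between the intercept and tesla-scale
reference columns; a genuinely rank-deficient design falls back to the
minimum-norm solution with a warning.

The analysis band is isolated with a 5th-order Butterworth band-pass (4–8 Hz)
applied forward and backward (zero phase, squared magnitude response), with
odd-symmetric padding of ten periods of the low band edge.  The filter's
impulse response decays on the 1/bandwidth scale (~0.4 s), so the default
solver padding of a few dozen samples leaves visible edge transients; ten
low-edge periods bound the mid-band edge error at roughly 2 % on 3 s epochs.

## Beamformer

The data covariance is pooled over all samples of all trials of both
conditions (whole-trial window, per-trial means removed), then regularised by
diagonal loading C + λ·mean(diag C)·I.  At each voxel the source orientation
u maximises unit-gain output power over the tangential plane — the
eigenvector of A = Lᵀ C⁻¹ L with the smallest eigenvalue, computed in closed
form for the 2×2 problem and verified against an exhaustive angle search.
Weights are the unit-gain LCMV solution w = C⁻¹l / (lᵀC⁻¹l) with l = L·u.
Per-trial source power is wᵀ C_t w with C_t the centred per-trial covariance
(identical to the variance of the projected trace, but far cheaper across
many voxels).

**Regularisation default λ = 0.2.**  With light loading (λ = 0.05) the
adaptive beamformer partially cancels the source whenever the assumed lead
field is slightly wrong — here the truth sits off-grid and the orientation is
estimated — and the cancellation deepens as source power grows, capping the
measured condition contrast at ~1.8 instead of the injected 2.04 and the
peak F statistic at a third of its attainable value.  λ = 0.2 suppresses the
cancellation with no measurable cost in localisation error on this array
(41/42 peaks within 6 mm over 14 studies during development).  The value is
exposed in the analysis config.

**Statistics.**  Trial powers are log-transformed (power is right-skewed;
the two-group machinery assumes approximate normality) and compared with a
two-sample t (scene − counting, so negative t = theta decrease) with
df = n₁ + n₂ − 2, and F = t².  Voxels with zero within-group variance but
differing means receive a +inf sentinel; identical samples give F = t = 0.
Calibration is verified empirically: the F test's type-I error at α = 0.05
sits inside the 99 % binomial interval over 2000 null simulations of
band-limited-noise trial powers.

## Group inference

Participant F maps are smoothed with a 9 mm FWHM Gaussian (σ = FWHM/2.3548),
restricted to the in-mask volume with kernel renormalisation over the mask
(normalised convolution: constants are preserved exactly at boundaries), then
converted to upper-tail F probabilities.  Smoothing precedes the p
conversion; the order is fixed.  The conjunction statistic is the voxelwise
*maximum* p across participants, a valid (conservative) test of the null
that *no* participant shows an effect — the appropriate question for a
proof-of-capability study.  Multiplicity is controlled with the
Benjamini–Hochberg step-up at q = 0.005 over all in-mask voxels (BH rather
than the more conservative Benjamini–Yekutieli, matching standard voxelwise
FDR practice).  Clusters are maximal 6-connected (face-adjacent) components
of the significance mask; each cluster reports its peak statistic voxel, with
ties broken towards the lowest linear index, in mm world coordinates.  The
statistic reported at conjunction peaks is the minimum smoothed F across
participants — the monotone counterpart of the maximum p.

The default source grid is a 30³ cube of 3 mm voxels centred on the head
(±43.5 mm, entirely inside the sphere), covering the deep/central volume that
contains the simulated source; grid size and spacing are configurable.

## Bootstrap stability

Per participant, trials are resampled with replacement *independently within
each condition* (the alternative — joint resampling — would let condition
counts drift from their equated values), and the full
covariance → orientation → weights → power → F chain is rerun per replicate;
100 replicates per participant by default.  Each of 500 conjunction draws
picks one replicate image per participant uniformly at random, reruns
smoothing → p → conjunction → BH-FDR (the threshold is re-estimated in each
conjunction rather than frozen at the original analysis's value), and records
the binary significance mask.  The stability map is 100 × the mean of these
masks — exactly, by construction — and its argmax marks the most reliably
significant voxel.

## Reproducibility and problem sizes

Every stochastic stage draws from a named child of a single study seed
(numpy `SeedSequence` spawning), so identical (config, seed) pairs give
bit-identical sessions, maps and files.  The test suite and the acceptance
script run the default three-participant study (35/61/45 analysed trials per
condition, 27 000-voxel grid) for end-to-end checks, a scaled-down high-SNR
study (20 trials per condition, 45 nAm) for peak-recovery and bootstrap
stability checks with 25 bootstrap replicates × 100 conjunctions, and
2000-replicate null simulations for statistical calibration; these sizes are
the package's chosen desk-scale defaults and are all configurable.

## Known limitations

* The conducting-sphere forward model is exact only for the simulated world;
  real heads need a realistic volume conductor.
* Four reference channels cannot cancel a full linear-gradient field; the
  residual after regression grows with the gradient amplitude, and the
  beamformer absorbs only its low-rank spatial structure.
* The maximum-p conjunction is conservative and, with a single focal effect,
  the BH threshold is strict; detection at q = 0.005 depends on the weakest
  participant's map.
* Bootstrap stability percentages are sensitive to the replicate counts; at
  the reduced desk-scale counts the argmax is stable but the percentage
  values themselves are noisy.
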