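# opmbeam

Scalar LCMV beamformer source localisation for wearable OPM-MEG theta-power
experiments, with a fully ground-truthed synthetic study.

## The problem

Optically-pumped magnetometers (OPMs) are cryogen-free magnetic field sensors
worn on the scalp, close enough to the head to detect activity in deep
structures such as the hippocampus — but, being magnetometers rather than
gradiometers, they are highly sensitive to environmental interference.  A
canonical experiment contrasts theta-band (4–8 Hz) power between a
hippocampal-dependent condition (imagining novel scenes) and a baseline
(mental counting) across a handful of participants, asking whether a wearable
array can localise the resulting theta *decrease* to the hippocampus.

`opmbeam` implements that analysis end to end, driven by a synthetic-data
generator whose ground truth (source position, per-condition power,
interference components) makes every stage testable:

1. **Synthetic sessions** — ~21 scalp magnetometers plus a 4-sensor reference
   array behind the head; 3 s epochs at 1200 Hz; a band-limited deep theta
   source whose amplitude drops by factor 0.7 during scene trials; structured
   interference (uniform field + linear gradient) seen coherently by both
   arrays; white sensor noise; per-participant geometry jitter; the trial
   accounting (completed / successful / artefact-removed / analysed) of a
   three-participant study.
2. **Preprocessing** — baseline correction; *synthetic gradiometry* (per-trial
   OLS regression of reference channels out of scalp channels); 5th-order
   bidirectional Butterworth band-pass, 4–8 Hz.
3. **Beamformer** — scalar linearly-constrained minimum-variance spatial
   filter on a conducting-sphere forward model (Sarvas closed form), with the
   max-power source orientation per voxel:

       u  = argmin eig( Lᵀ C⁻¹ L ),      w = C⁻¹ l / (lᵀ C⁻¹ l),   l = L u,

   pooled whole-trial covariance over both conditions, diagonal loading
   λ·mean(diag C)·I.  Per-trial band power wᵀC_t w is log-transformed and
   compared between conditions voxelwise: signed t (scene − counting) and
   F = t².
4. **Inference** — 9 mm Gaussian smoothing, F→p conversion, maximum-p
   conjunction across participants (rejects "no participant shows an
   effect"), Benjamini–Hochberg FDR at q < 0.005, 6-connected cluster/peak
   reports, and a bootstrap-conjunction stability map (resample trials with
   replacement per participant, redraw conjunctions, report per-voxel
   significance percentages).

## Worked example

```python
import numpy as np
from opmbeam import RunConfig, run_study, bootstrap_stability

cfg = RunConfig(seed=1)               # default three-participant study
study = run_study(cfg)

print(study.accounting[["participant", "analysed"]].to_string(index=False))
for pr in study.participants:
    peak_world, peak_f = pr.f_map.peak()
    err = np.linalg.norm(peak_world - pr.ground_truth.source_position) * 1e3
    print(f"P{pr.index + 1}: peak F = {peak_f:.1f}, "
          f"localisation error = {err:.1f} mm")
sig = study.significance_mask.masked_values
print(f"conjunction (q < 0.005): {int(sig.sum())} significant voxels, "
      f"{len(study.clusters)} cluster(s)")
c = study.clusters.clusters[0]
print(f"peak at ({c.peak_world_mm[0]:.0f}, {c.peak_world_mm[1]:.0f}, "
      f"{c.peak_world_mm[2]:.0f}) mm, min-F = {c.peak_value:.1f}")
```

prints

```
 participant  analysed
           1        35
           2        61
           3        45
P1: peak F = 169.3, localisation error = 2.2 mm
P2: peak F = 442.4, localisation error = 1.3 mm
P3: peak F = 269.4, localisation error = 2.1 mm
conjunction (q < 0.005): 181 significant voxels, 1 cluster(s)
peak at (38, -8, -17) mm, min-F = 61.4
```

The analysed-trial counts follow from the session bookkeeping (usable =
successful − artefact-removed, equated across conditions).  Each
participant's F map peaks within a few mm of that participant's true source
at (36, −8, −16) mm (± 1 mm registration jitter), the conjunction survives
whole-volume FDR at q < 0.005 in a single cluster containing the true source,
and every significant voxel shows t < 0 — a theta power decrease during
scene imagery, the direction the generator injected.

The same pipeline is scriptable from the shell:

```bash
opmbeam run-all --seed 7 --outdir out/   # NIfTI maps, TSV tables, JSON log
```

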