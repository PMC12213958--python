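# erpsource

Simulation and multimodal analysis of **subsequent source-memory effects**
in event-related EEG: an end-to-end, fully testable pipeline from planted
cortical sources to group-level ROI statistics.

During memory encoding, scalp EEG differs between items whose episodic
context (the "source") is later remembered versus forgotten — the
subsequent memory effect (SME). Two components carry it in children: an
early frontal positivity (**P2**, 120–250 ms) and a sustained late slow
wave (**LSW**, 1100–1500 ms). Localizing these effects requires a forward
head model, an inverse solution, and region-of-interest statistics — a long
chain in which every stage can silently fail. `erpsource` rebuilds that
chain on synthetic data with *known ground truth*, so each stage is checked
against an independent oracle:

- **Synthetic studies** (`erpsource.simulate`): multi-subject, two-condition
  epoched EEG (−100…1500 ms at 512 Hz, 64 channels) with Gaussian-bump P2
  and logistic-onset LSW sources planted in named medial-temporal and
  fMRI-constrained ROI masks, 1/f + white sensor noise, high-amplitude
  artifact trials, and per-subject latency jitter.
- **Forward model** (`erpsource.forward`): analytic potentials for a current
  dipole in N concentric conducting shells (default brain/CSF/skull/scalp,
  0.33/1.79/0.01/0.43 S/m). Per degree *n* the potential is a Legendre
  series whose transfer gains follow from 2×2 interface conditions; for
  equal conductivities it collapses to the closed-form homogeneous-sphere
  solution, which serves as the test oracle. Fiducial-based rigid
  (Umeyama) montage alignment is included.
- **Preprocessing & ERP analysis** (`erpsource.preprocess`, `erpsource.erp`):
  zero-phase 0.1–30 Hz FIR filtering, ±200 µV trial rejection, bad-channel
  detection with Perrin spherical-spline interpolation (max 8 bad
  channels), average reference, collapsed-localizer window suggestion,
  per-subject P2 windows (median of per-trial frontal peak latencies),
  component re-baselining, and a 2 (condition) × 3 (coronal) × 3 (sagittal)
  within-subject ANOVA with Tukey-corrected estimated-marginal-mean
  contrasts.
- **eLORETA inverse** (`erpsource.inverse`): the weighted minimum-norm
  solution with self-consistent 3×3 weight blocks
  `W_j = (K_jᵀ M K_j)^{1/2}`, `M = pinv(K W⁻¹ Kᵀ + α c H)` — exact
  localization of noiseless point sources at α = 0. Current-density (CDR)
  scores are the per-sample moment-vector norms averaged over the component
  window, aggregated per ROI.
- **Group inference** (`erpsource.stats`): paired t-tests per ROI with
  Benjamini–Hochberg FDR applied separately per hemisphere × mask family ×
  component.
- **Pipeline + CLI** (`erpsource.pipeline`, `erpsource` console command):
  staged orchestration with a JSON manifest (parameters, SHA-256 hashes,
  wall times, warnings), bit-exact caching, and deterministic per-subject
  seeding.

## Worked example

Run the built-in demo study (12 subjects, 20 trials per condition, planted
correct > incorrect effects: P2 in the left caudal parahippocampal and
orbital-frontal patches, LSW in the left entorhinal and left rostral
parahippocampal patches):

```sh
erpsource run-all --seed 7 --out demo_run
```

```
forward: 1.091 s, 0 warning(s)
simulate: 12.468 s, 0 warning(s)
preprocess: 25.979 s, 0 warning(s)
erp: 5.405 s, 0 warning(s)
inverse: 1.141 s, 0 warning(s)
stats: 0.102 s, 0 warning(s)
report: 0.01 s, 0 warning(s)
```

`demo_run/report/summary.md` then reads:

```
- planted P2 effect in left caudal PhG: recovered
- planted P2 effect in OFG: recovered
- planted LSW effect in left EC: recovered
- planted LSW effect in left rostral PhG: recovered
- significant ROIs total: 35
- significant reversed-direction ROIs: 0
```

and `demo_run/stats/report.md` lists the per-ROI contrasts, e.g.

```
## LSW / MTL_atlas
- left EC: t(11) = 6.48, p = 0.0000, q = 0.0000 (source_correct > source_incorrect)
```

All four planted ROI/component pairs are recovered with the planted
direction and no reversed effects. Note that many *non*-planted ROIs are
also significant: a distributed inverse on a coarse grid spreads a strong
focal effect over neighboring cortex (spatial leakage), which is exactly
why ROI-constrained hypotheses are used in this kind of analysis — see
`docs/methods.md` for the resolution discussion.

Library use mirrors the CLI:

```python
from erpsource.config import default_config
from erpsource.pipeline import Pipeline

pipe = Pipeline(default_config(out_dir="demo_run", seed=7))
pipe.run_all()
```

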