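# Methods

This note documents the models, numerical choices and known limitations of
`erpsource`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Head model and forward solution

The head is modeled as N concentric spherical shells, each homogeneous and
isotropic. The default is four shells — brain 0.33, CSF 1.79, skull 0.01,
scalp 0.43 S/m, radii 8 / 8.5 / 9 / 10 cm — standard literature
conductivity values; the shell count, radii and conductivities are all
config-exposed. This geometry replaces subject-specific finite-element
meshes (which require individual MRIs) with a model that admits an exact
series solution, so the forward code can be verified rather than trusted.

For a current dipole at radius b inside the innermost shell, the potential
at the scalp is

    V = 1/(4π σ₁ R²) Σₙ gₙ (b/R)^{n−1} [ n m_r Pₙ(cos γ) + m_t Pₙ¹(cos γ) ]

with R the outer radius, m_r / m_t the radial/tangential moment components
relative to the electrode direction, and gₙ a per-degree gain obtained by
solving the 2×2 interface conditions (continuity of potential and of radial
current density) per shell plus the insulating scalp boundary. For equal
conductivities gₙ = (2n+1)/n and the series sums in closed form via
generating-function identities; that closed form is implemented separately
(`homogeneous_sphere_potential`) and used as the oracle — the acceptance
suite requires agreement to 1e-6 relative error over 100+ random
dipole/electrode configurations (observed: ~4e-15).

Numerical choices: radii are normalized by R before solving the per-degree
systems so powers stay O(1); the series is truncated at L = 60, which for
sources at eccentricity ≤ 0.8 · r_inner (with electrodes on a strictly
larger outer shell, the effective expansion ratio is ≤ ~0.64) leaves a
relative tail below 1e-8 (checked against L = 120). Electrodes are
projected radially onto the outer shell before evaluation, as the analytic
solution requires on-sphere sensors. A dipole exactly at the origin is
handled by the degree-1 limit. Lead fields are average-referenced by the
explicit centering matrix H = I − (1/n)·11ᵀ; every column sums to zero to
1e-9 by construction, and the loader re-verifies this invariant.

Units are fixed package-wide: meters, S/m, nA·m for moments, µV for
potentials (1 nA·m through 1 S/m at 1 m yields 1e-3 µV).

## Montage, source grid and ROI masks

Electrodes are placed on a deterministic Fibonacci spiral over the upper
scalp (default 64, polar angles ≤ 115°) and partitioned into the 3 × 3
coronal (frontal/central/posterior) × sagittal (left/middle/right) cluster
scheme by position terciles. The default 64 carry a 10-10-style label set;
labels are cosmetic, the analysis uses positions and cluster assignments.

The source space is a cubic lattice (default pitch 1.2 cm for the demo;
3 mm reproduces a realistic grid pitch at ~51k points) clipped to a
spherical "grey-matter" band, by default 0.6–0.95 of the innermost radius —
deep/subcortical positions and ocular sources are deliberately excluded.
Hemisphere labels come from the lateral coordinate with a midline band of
half a grid step, which makes the left/right split unambiguous and
testable.

Two synthetic ROI families are grown by nearest-neighbor accretion around
fixed anatomical seed directions: a bilateral medial-temporal family
(rostral/caudal parahippocampal, lateral/medial posterior parahippocampal,
entorhinal, temporal-insular patches; 6 names × 2 hemispheres) and a
6-region "fMRI-constrained" group-mask family (left IPL/SPL, IOG, left
ITG, left IFG, FuG, OFG). Masks are disjoint within a family and
deterministic given the seed. These are geometric stand-ins: they carry
the right names, laterality and approximate location, not real anatomy.

## Synthetic studies

The generator emulates a two-condition (subsequent source correct /
incorrect) encoding study: epochs −100…1500 ms at 512 Hz, balanced trial
counts (default 40 per condition). Source time courses are

- **P2**: a Gaussian bump (FWHM 60 ms) at a per-subject latency drawn once
  as nominal (180 ms) + N(0, 20 ms), clipped to 120–250 ms;
- **LSW**: a logistic onset centered at 1100 ms with 40 ms slope, rising to
  a plateau held through 1500 ms — a plateau-like late positivity.

Each planted source is radial, with condition amplitudes in nA·m. The
between-subject effect structure is explicit: per subject, the condition
amplitude difference is (amp_correct − amp_incorrect) + N(0, τ), so the
planted paired effect size is d = Δ/τ in source-amplitude units (the demo
and recovery ladders use Δ = 30, τ = 37.5, i.e. d = 0.8). Trial-to-trial
amplitudes jitter multiplicatively (CV 0.1). Sensor noise is white
(σ = 2 µV) plus spectrally shaped 1/f noise (σ = 2 µV, exponent 1);
trial-averaged component SNR at these defaults is roughly 5–10, a
moderate, realistic regime. A configured fraction of trials receives a
slow half-sine, frontally weighted drift of 350 µV — exactly
round(fraction × n_trials) trials, so rejection counts are testable. All
randomness derives from (master seed, subject index) via SeedSequence
spawning, making whole studies byte-reproducible.

What the generator does *not* emulate: realistic cortical folding or
orientation maps, ocular/muscle artifact physiology, heteroscedastic or
non-stationary noise, behavioral responses, or age structure. Passing
tests therefore demonstrate the correctness of the *machinery* (forward
model, inverse, statistics) under a known truth — not that real pediatric
EEG meets these assumptions.

## Preprocessing

Order: bad-channel detection → spherical-spline interpolation → zero-phase
band-pass → amplitude rejection → average reference → inclusion rules.

Bad channels are flagged by flatline variance (< 1e-12 µV², relative to an
otherwise live recording) or a robust z-score (median/MAD) of log-variance
above 5; more than 8 bad channels excludes the subject. Interpolation is a
classical spherical spline (order m = 4, 50 Legendre terms, ridge 1e-5)
with the constant-offset constraint, so constant fields are reproduced
exactly and a held-out channel of a smooth dipolar field is recovered to a
few percent.

The band-pass is a linear-phase windowed-sinc (Hamming) FIR at 0.1–30 Hz,
applied by FFT convolution with mirror padding and group-delay
compensation — symmetric inputs stay symmetric to 1e-9. The 0.1 Hz low
edge nominally implies ~17k taps at 512 Hz; on epoched data the length is
capped at the epoch length (819 taps), which relaxes the low-edge
transition but is immaterial for 1.6 s epochs where the high-pass is
essentially DC removal. Trials with any |sample| > 200 µV are dropped;
subjects with fewer than 10 surviving trials in either condition (config)
are excluded.

## ERP components and scalp statistics

Component windows are 50 ms long (config; a 150 ms variant is supported).
The P2 window is individual: per trial, the frontal-cluster mean's argmax
latency within 120–250 ms (earliest sample on ties); the window centers on
the lower median of those latencies — the lower median is a deterministic
choice for even trial counts, and "median of per-trial peak latencies" was
chosen over "latency of the median-amplitude trial" as the more robust
reading. The LSW window is fixed at 1200 ms for all subjects (1175–1225
default). A collapsed localizer (grand average over all trials,
conditions and subjects) suggests ranges without condition bias.

Re-baselining subtracts the mean over a short pre-component window — P2:
130–140 ms, LSW: 610–620 ms. The P2 baseline lying *inside* the P2 search
range is a quirk of the quantification convention this reproduces; it is
implemented exactly as specified and flagged here.

Cluster means feed a balanced 2 × 3 × 3 within-subject ANOVA computed from
an explicit full-factorial sum-of-squares decomposition (each effect
tested against its subject interaction). Only condition-involving effects
are reported. No sphericity correction is applied by default — the
condition factor has 1 df — with Greenhouse–Geisser adjusted dfs available
via `sphericity_correction="gg"`. The decomposition is verified against
both a loop-based summation oracle and `statsmodels` AnovaRM to 10
significant figures. Post hoc condition contrasts use estimated marginal
means per cell with the pooled condition-involving error stratum
(df = 9(n−1)); with k = 2 means the Tukey studentized-range p equals the
unadjusted two-sided t p exactly, which the implementation exploits and
the tests verify against the studentized-range distribution (itself
validated against direct numerical integration).

## eLORETA and CDR

Weights are iterated from W_j = I: M = pinv(Σ K_j W_j⁻¹ K_jᵀ + α c H) with
c = trace/n_channels, then W_j ← (K_jᵀ M K_j)^{1/2} (symmetric square
root via eigendecomposition), until the maximum relative Frobenius change
is below 1e-6 (max 100 iterations; non-convergence warns and returns the
best iterate). Pseudo-inverses use an eigenvalue floor of 1e-12 relative.
α defaults to 0.05 (as a fraction of the mean sensor-space eigenvalue) for
noisy data and 0 for noiseless property tests; the fixed point is
scale-invariant in the lead field (the operator scales as 1/c), which the
tests assert.

The defining property — noiseless point sources localized exactly at
α = 0 — is verified on a ~520-point grid: ≥ 95% of interior sources must
put the CDR peak on the true grid point (observed: 100%).

CDR is computed norm-then-average: the Euclidean norm of the 3-vector
moment at each window sample, then the arithmetic mean across samples —
matching "magnitudes of the dipole moment vectors … average source
strength". The inverse is applied to condition-specific trial-averaged
ERPs (not single trials), re-baselined per component. Raw ROI means are
used for inference; no normalization is applied (a log transform can be
layered by the caller).

## Group inference

Per ROI: classical paired t across subjects on condition CDR means
(df = n − 1; zero-variance differences are flagged degenerate, not
silently zeroed). BH FDR runs independently within each correction family
= hemisphere × mask family × component: the bilateral MTL family is
corrected per hemisphere, the fMRI-constrained group masks as one set.
Tests are two-sided despite directional hypotheses, since reversed scalp
effects are a real possibility the analysis must be able to report.

## Calibration and recovery (replicate studies)

Replicate ladders use deliberately coarse settings — 32 channels, 2 cm
grid (~190 points), 3-point ROI patches, 10–12 trials per condition — so
that hundreds of full simulate→preprocess→ERP→inverse→stats runs fit in a
test budget; geometry, lead field and inverse operator are computed once
and shared. These sizes are the package's choice of desk-scale problem,
stated here so results are interpreted at that scale.

- **Null calibration** (no condition effect, active sources present,
  n = 12): across 200 replicates the ANOVA condition effect rejects within
  the 95% binomial band around 5%, and the per-family ROI false discovery
  proportion averages ≤ 0.05 + Monte-Carlo tolerance (0.02).
- **Recovery** (d = 0.8 planted in left EC + left rostral PhG for LSW and
  left caudal PhG + OFG for P2, n = 20): across 50 replicates each planted
  ROI/component pair is recovered at q < 0.05 in ≥ 80% of runs, with no
  significant reversed-direction ROI in ≥ 95% of runs.

## Known limitations

- **Spatial leakage**: a distributed linear inverse at ~100–800 grid
  points spreads focal effects widely; in effect-present demos most ROIs
  reach significance, with the planted ROIs carrying the strongest
  statistics. The pipeline is therefore validated on *recovery* (planted
  ROI significant, direction correct, nulls calibrated), not on exclusive
  selectivity — mirroring why a priori ROI constraints matter in practice.
- The spherical head and radial sources ignore real conductivity
  anisotropy, skull inhomogeneity and cortical orientation structure.
- The printed group statistics of real developmental studies depend on
  unreleased participant data and are not reproduction targets here; the
  package reproduces the *procedure* and validates it on synthetic truth.
- Single-trial source estimation, beamformers and mixed-effects age
  models are out of scope.
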