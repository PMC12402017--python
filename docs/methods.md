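# Methods

This note records the models, conventions and parameter choices behind
`aquadom`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Data model and conventions

An EEM is stored with rows = excitation and columns = emission,
everywhere. The standard acquisition grid is excitation 230–450 nm in
5 nm steps (45 points) and emission 250–550 nm in 1 nm steps
(301 points). Wavelengths and frequencies are floats; grid-equality
checks use an absolute tolerance of 1e-9 nm (relative 1e-9 for
frequencies). CSV payloads carry no metadata; units, dilution factor
and replicate number live in a JSON sidecar (`<file>.meta.json`), so
the CSVs stay readable by any spreadsheet or plotting tool. Wide EEM
CSVs are fixed to the rows-=-excitation orientation; the reader never
guesses or transposes.

## EEM conditioning

The chain is blank subtraction → scatter excision → dilution
back-correction → QSU normalization.

*Scatter excision.* Cells within ±15 nm of the first-order Rayleigh
line (em = ex), ±15 nm of the second-order line (em = 2·ex), or
±10 nm of the water Raman line (1/λem = 1/λex − 3400·10⁻⁷ nm⁻¹,
i.e. a 3400 cm⁻¹ wavenumber shift) are excised. Two modes:

- **mask** — cells are flagged and excluded from every downstream
  computation (indices refuse to read masked cells; MCR excludes them
  from residuals).
- **interpolate** — each excised cell is filled by 1-D linear
  interpolation along the emission axis between its nearest unmasked
  neighbors. A gap touching a grid edge has no bracketing pair; it is
  anchored on a virtual zero at the responsible scatter-line center
  (em = ex on the blue side, em = 2·ex on the red side), because
  fluorescence vanishes at the excitation line. The anti-Stokes region
  em ≤ ex is set to zero. Early development used plain edge clamping
  (nearest-value extension); that manufactures flat plateaus across the
  below-Rayleigh region which the trilinear model happily fits as a
  spurious short-wavelength component, so the anchored scheme replaced
  it.

*Inner-filter screening.* Handled by dilution, not by an
absorbance-based correction formula: a sample whose A254 exceeds the
threshold (default 0.05, 1 cm path; the boundary value itself is
acceptable) is flagged with the smallest power-of-two dilution that
brings A254 to or below the threshold. The EEM of a diluted sample is
multiplied back by its dilution factor afterwards.

*QSU normalization.* Division by the recorded raw-count intensity of
the 0.01 mg/L quinine sulfate standard at ex 350 / em 450 nm, so that
standard reads 1 QSU. Normalizing twice is an error.

*Blank subtraction.* Element-wise, clipped at zero (non-negativity is
required by the downstream factorization); masks are unioned.

## Fluorescence indices

All four are intensity ratios, hence invariant to global scaling:

| index | convention | definition |
|---|---|---|
| FI | McKnight | I(ex 370, em 470) / I(ex 370, em 520) |
| HIX | Ohno, normalized | Σ I(ex 255, em 435–480) / [Σ(300–345) + Σ(435–480)] |
| BIX | Huguet | I(ex 310, em 380) / I(ex 310, em 430) |
| Peak C/T | Coble windows | max(ex 320–360 × em 420–480) / max(ex 270–280 × em 330–350) |

The conventional HIX excitation of 254 nm is off the 5 nm grid; the
nearest grid point (255 nm) is used without interpolation. The
normalized HIX form (bounded in [0, 1]) is the default; the classic
high/low ratio is available via `IndexWindows(hix_normalized=False)`.
Peak C and Peak T are window *maxima*, not fixed cells, since the
peaks denote regions. Every wavelength is overridable through
`IndexWindows`. Indices on mask-mode EEMs raise rather than silently
read an excised cell.

## MCR-ALS with the trilinearity constraint

The K sample matrices are concatenated vertically into
`D_aug` (K·45 × 301) and modeled as `D_aug = A S_em` with
`A = [S_ex C_1; …; S_ex C_K]`. One ALS iteration:

1. solve `S_em ≥ 0` given `A` by exact active-set NNLS per column
   (scipy's implementation; exact KKT solutions keep the unconstrained
   ALS monotone, unlike clip-after-solve);
2. rescale `S_em` rows to peak 1, compensated in `A` (model unchanged);
3. solve `A ≥ 0` given `S_em` by NNLS per row;
4. trilinearity: refold each component's column of `A` into a
   45 × K block and replace it with its best rank-one approximation
   (leading singular triplet, signs fixed into the nonnegative orthant,
   negative residuals clipped at zero). This forces a common excitation
   profile with per-sample scales — the constraint that removes the
   rotational ambiguity of the plain bilinear model.

Convergence: relative change in lack of fit (100·√(rss/tss)) below
1e-6 per iteration, or 200 iterations. Masked cells are handled by
expectation-style imputation — they start emission-interpolated and are
replaced by the model estimate each iteration, which has the same fixed
point as 0/1-weighted least squares but keeps the NNLS subproblems
exact.

*Initialization.* ALS with overlapping components has genuine local
minima, observed even on noise-free synthetic stacks. The default is
therefore a small multi-start: purest rows of `D_aug` (SIMPLISMA-style
selection of the most distinct measured emission spectra — markedly
more robust here than purest columns, because the excitation profiles
are strongly collinear), purest columns, and two seeded random starts;
the fit with the lowest lack of fit wins. All starts are deterministic
given the seed.

*SIMPLISMA.* Purity of a column is std/(mean + offset) with offset =
5% of the largest column mean, weighted by the determinant of the
correlation-around-origin (cosine) submatrix of the already-selected
columns — so mutually orthogonal pure columns are selected exactly.
Ties break to the lowest index.

*Rank estimation.* A component is significant when its individual
share of the squared singular-value spectrum is ≥ 1 − threshold
(default threshold 0.999, i.e. a 0.1% share). For exact-rank data this
coincides with the cumulative-variance rule; under measurement noise
the cumulative rule counts the long tail of noise singular values and
grossly overestimates, which is why the share rule is used.

*Normalization and ordering.* `S_ex` columns and `S_em` rows peak at
1; all magnitude lives in the contribution matrix `C` (the "relative
concentration contributions"). Components are sorted by descending
total contribution ΣC — per-component "% variance" is not reported
because the components are non-orthogonal and such shares overlap;
ΣC and the fit history are exported instead.

## PCA and the EIS block

PCA is computed by SVD of the preprocessed matrix (deterministic and
exact at these sizes; no NIPALS). `explained_i = σᵢ²/Σσ²·100` over all
components; kept scores are `U Σ`, loadings `V` with the sign
convention that each loading's largest-magnitude entry is positive
(score signs are convention-dependent, so cluster structure rather
than raw signs is what tests compare). Autoscaling divides by the
n−1 sample standard deviation — material at n = 5 — and refuses
zero-variance columns.

EIS Bode-phase spectra are interpolated in log10(frequency) onto a
common 500-point log-spaced grid over 0.1 Hz–20 kHz (phases
themselves are not transformed), optionally smoothed with the
in-package Savitzky–Golay filter: least-squares polynomial per point,
0th order and 15-point window by default, edges handled by shrinking
the window symmetrically (so order 0 is a centered moving average
everywhere). The design matrix rows are ordered sample-major then by
replicate; replicate score rows are averaged before fusion.

## Fusion

The fused table covers the EIS-measured subset (blank + 4 rivers; the
9-river default reproduces the R3/R5/R6/R9 + DOM-free design) with the
fixed column contract [Temp, pH, Cond | EISpc1, EISpc2 | uv254 | FI,
HIX, BIX, PeakC/PeakT | C1..Cnc] — 3+2+1+4+nc columns, 16 for two EIS
PCs and six fractions. Index replicate means enter the table; MCR
contributions enter as raw C-row values, not renormalized per sample.
The global PCA autoscales the table and exports scores and loadings on
common axes for a biplot. A configuration flag in the pipeline allows
fusing all samples with the EIS block omitted (fusion is skipped with
a warning when no EIS spectra exist at all).

## Synthetic campaign generator

The generator emulates a small mountain-river survey: 9 rivers along
an altitude-like DOM gradient plus a DOM-free Milli-Q blank.

*Fluorophores.* Six Gaussian components (in wavelength, not
wavenumber — adequate at this grid resolution) at the canonical peak
positions (ex/em): 340/474, 350/430, 320/399 (humic-like) and
300/354, 280/338, 270/294 nm (protein-like), σ_ex 20 nm and σ_em
30 nm, each with a secondary UV excitation shoulder at half amplitude
(250 nm for the humics, 242/235 nm for the protein-like families —
real fluorophore families differ in shoulder position, and identical
shoulders would make the excitation factor needlessly degenerate).

*Contributions.* Each component follows its own structured river
pattern: terrestrial humics rise steeply downstream (load^1.3,
load^1.0), microbial humic material is ubiquitous (0.25 + 0.75·load),
the two tryptophan-like fractions peak at specific
anthropogenically-impacted rivers (Gaussian hotspots at gradient
positions 0.35 and 0.70), and the tyrosine-like fraction tracks
microbial activity (load^0.9). On top sits lognormal river-to-river
scatter with σ = 0.45 (~±50%, the magnitude real campaigns show).
This linear independence of the contribution patterns is not a
convenience: the essential uniqueness of the trilinear model *requires*
variation in the sample mode, and a survey in which all fractions
co-varied perfectly would not be resolvable by any method. Base
amplitudes (10, 9, 8, 3.5, 4.5, 3 QSU) keep the humics dominant.

*Measurement model.* Scatter ridges with Gaussian cross-sections
(Rayleigh σ 4 nm at amplitude 3× the sample maximum, second order 1×,
Raman σ 3 nm at 0.5×), i.i.d. Gaussian noise with σ defaulting to 1%
of the stack's maximum intensity, clipped at zero. The full campaign
generator additionally adds a constant dark-count offset of 4σ so
measured counts stay strictly positive as on a real detector (the bare
stack generator used by the recovery benchmark adds none). EIS spectra
come from a single-dispersion Cole element
Z(ω) = R_s + R_ct/(1 + (iωτ)^α) with conductivity mapping inversely
to R_s and DOM load lowering α (broader dispersion), two replicates
with 0.5% parameter scatter; UV spectra are exponential CDOM curves
pinned to uv254, which rises linearly with load while conductivity
rises as load^1.5 from 1.7 µS/cm (blank) toward ~1625 µS/cm.

*What it does not emulate.* Inner-filter nonlinearity, turbidity and
temperature effects on fluorescence, instrument drift, wavelength
calibration error, and the device physics behind the EIS response.
Passing recovery tests therefore demonstrates the correctness of the
decomposition machinery under a known trilinear truth — not that six
components is the right model for any particular river system.

## The recovery benchmark and a known limitation

`aquadom.experiments.recovery_experiment` generates the ten-sample
stack (1% noise, scatter ridges), excises scatter (anchored
interpolation), fits trilinearity-constrained MCR-ALS with nc = 6, and
scores each resolved component against the generator by the cosine of
concatenated, per-mode unit-normalized (excitation, emission) profiles
after optimal assignment.

On noise-free, scatter-free stacks the decomposition is exact
(R² = 100, all cosines 1.0) — the trilinear-consistency property. At
the benchmark's realistic noise level the humic components and the
strong tryptophan fractions are recovered with cosines ≳ 0.98 and
band maxima on or within a grid step of the generated positions, and
R² stays above 99.

The weakest, tyrosine-like component (270/294 nm) is the documented
exception: its emission peak lies inside the merged Rayleigh+Raman
excision zone for its main excitation band (the water Raman line at
ex 270 nm falls at ~297 nm), so most of the rows that excite it
strongly carry no direct observation of its peak. Its profile cosine
plateaus around 0.87–0.94 and its recovered emission maximum sits
~5–10 nm blue of the generated 294 nm, consistently across seeds.
Refitting from a truth-initialized start reproduces the same optimum,
so this is an identifiability limit of the measurement-plus-excision
design, not an optimizer artifact — and it mirrors the real difficulty
of resolving tyrosine-like fluorescence near the Raman band. The
acceptance tests assert the idealized recovery bounds and the
tyrosine clauses fail by these documented margins.

## Numerical choices

- NNLS: scipy's active-set solver per row/column (exact KKT).
- Rank-one projection: leading SVD triplet, sign fixed by the sum of
  the left factor, negatives clipped.
- Degenerate components (all-zero after clipping) stay at zero; the
  normalization guards against division by zero.
- Convergence tolerance 1e-6 (relative lack-of-fit change); monotone
  descent holds exactly only with the trilinearity constraint off.
- PCA sign convention: largest-|entry| loading positive; stable across
  runs and platforms.
- All randomness flows from a single integer seed per experiment;
  derived seeds stay below 2³¹.

## Problem sizes

The default campaign is 10 samples of 45 × 301 EEMs (the augmented
matrix is 450 × 301), 10 EIS spectra of 500 points, and a 5 × 16
fused table; a full pipeline run or recovery benchmark takes seconds
on a single CPU, so the test suite exercises the complete stack at
full size rather than down-scaled toys.
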