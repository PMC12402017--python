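# aquadom

Chemometric characterization of dissolved organic matter (DOM) in
natural waters from three instrumental blocks — excitation–emission
matrix (EEM) fluorescence, UV–Vis absorption, and electrochemical
impedance spectroscopy (EIS) — plus in-situ physicochemical sensing,
fused into a single multivariate picture of a sampling campaign.

It is written for water-quality and environmental-chemistry groups who
run small river surveys (a handful of samples, a few techniques) and
want a reproducible, scriptable pipeline instead of a pile of ad-hoc
spreadsheets: read the spectra, condition the EEMs, compute the
standard DOM indices, resolve the underlying fluorophores, and relate
everything to the impedance and sensor data.

## What it computes

**EEM conditioning.** Blank subtraction, first/second-order Rayleigh
and water-Raman scatter excision (masking or physically anchored
interpolation), inner-filter screening by dilution against an A254
threshold, dilution back-correction, and quinine-sulfate-unit (QSU)
normalization, on the standard acquisition grid (excitation 230–450 nm
in 5 nm steps, emission 250–550 nm in 1 nm steps; 45 × 301 points).

**Fluorescence indices.** FI (McKnight; em 470/520 at ex 370), HIX
(Ohno's normalized 0–1 form at ex 255), BIX (Huguet; em 380/430 at
ex 310), and the Peak C / Peak T window-maximum ratio (Coble windows),
with replicate means ± sd.

**MCR-ALS with a trilinearity constraint.** The K sample EEMs
`D_k` (45 × 301) are stacked and factored as

    D_k = S_ex C_k S_em^T + E_k ,   k = 1..K

with common excitation profiles `S_ex` (45 × nc), common emission
profiles `S_em` (nc × 301), and diagonal per-sample contribution
matrices `C_k`. Alternating least squares under non-negativity (exact
active-set NNLS) plus a per-component rank-one constraint across the
sample mode makes the decomposition essentially unique (PARAFAC-like).
Fit quality is the explained variance
`R² = 100·(1 − Σ(d−d̂)²/Σd²)`.

**EIS Bode-phase PCA.** Phase spectra (500 points, 0.1 Hz–20 kHz,
log-spaced) are Savitzky–Golay smoothed (0th order, 15-point window),
assembled sample-major × replicate into a 10 × 500 matrix,
mean-centered and decomposed by SVD-based PCA.

**Multi-block fusion.** For the EIS-measured sample subset, a 5 × 16
table [temperature, pH, conductivity | 2 EIS PC scores | uv254 |
4 indices | 6 MCR contributions] is autoscaled and decomposed by a
global PCA whose biplot separates DOM-poor from DOM-rich waters.

**Synthetic campaign generator.** Every stage is testable without any
instrument: a seeded generator emulates a 10-sample campaign (9 rivers
along an altitude-like DOM gradient plus a DOM-free blank) with six
Gaussian fluorophores at the canonical humic-like and protein-like
peak positions, scatter ridges, Cole-element EIS responses, and
co-varying uv254/conductivity — with the ground truth stored for
recovery scoring.

## Worked example

Run the whole pipeline on a simulated campaign:

```sh
$ aquadom run --outdir run5 --seed 5
pipeline complete -> run5
MCR r2 = 98.89% (6 components)
global PCA: PC1 51%, PC2 28% (total 78%)
```

`run5/` then contains the conditioned inputs, `indices.csv` (per-sample
index table), `mcr_result.json` (resolved profiles and contributions),
`eis_pca.json`, `fused_table.csv` (5 × 16), and the global-PCA biplot
data. The MCR R² of 98.89% says the six-component trilinear model
reproduces essentially all structured variance of the simulated stack;
PC1 of the fused model orders samples by DOM load, placing the
DOM-free blank and the highest-DOM river at opposite extremes.

The same thing from Python, scoring against the generator truth:

```python
>>> from aquadom.experiments import recovery_experiment
>>> out = recovery_experiment(seed=1)
>>> round(out.result.r2, 2)
99.45
>>> sorted(out.component_maxima())[:2]
[('C1', 340.0, 473.0), ('C2', 350.0, 433.0)]
```

i.e. the terrestrial humic component is recovered with its main
excitation band at 340 nm and emission maximum within 1 nm of the
generated 474 nm peak.

## Layout

```
src/aquadom/
  io_formats.py    CSV/JSON readers and writers, canonical containers
  synthetic.py     campaign generator with stored ground truth
  preprocess.py    EEM conditioning chain
  indices.py       FI / HIX / BIX / Peak C/T
  mcr.py           MCR-ALS with the trilinearity constraint
  pca.py           PCA, Savitzky-Golay, EIS design matrix
  fusion.py        fused table, global PCA, pipeline orchestration
  experiments.py   the recovery benchmark
  cli.py           `aquadom` command-line interface
docs/methods.md    model, conventions, parameter choices, limitations
```
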