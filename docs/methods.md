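# Methods

This note records the models, conventions, and design choices behind
`dnpmas`, and what the synthetic-data tests do and do not demonstrate.

## Unique-pair labeling design (`seqdesign`)

A "unique pair" is an ordered, adjacent dipeptide occurring exactly once
in the primary sequence.  Counting uses overlapping windows of step 1,
so a sequence of length L contributes L−1 ordered dipeptides and the
counts always sum to L−1.  Ordering matters physically: the ¹³C label
sits on the first residue, the ¹⁵N label on the second, and the
CO(i)→N(i+1) one-bond transfer is directional — "MV" unique with "VM"
repeated still yields one clean filtered signal.

Choices made where practice is genuinely open:

* **Scrambling-prone residues are flagged, never removed.**  Whether
  transaminase-mediated isotope scrambling disqualifies a site depends
  on the expression system, so exclusion is advisory.  A suggested set
  {N, D, Q, E} ships as `SUGGESTED_SCRAMBLING_PRONE`; the default
  exclusion set is empty.
* **Homopairs** (XX) are reported with `is_homopair=True`: one residue
  type would have to carry both labels, which is chemically possible
  (¹³C,¹⁵N-labeled amino acid) but changes the filtering logic, so the
  caller decides.
* Positions are 1-based, matching residue numbering conventions.
* Nucleotide FASTA input is accepted and translated (frame 1, standard
  code, stop at the first stop codon), since expression constructs are
  usually archived as DNA.

The pair finder is validated against a regex-lookahead brute-force tally
on 1,000 random sequences of lengths 2–500.

## Relaxation fitting (`relaxfit`)

Models:

* saturation recovery  I(t) = A·(1 − e^(−t/T₁))
* Hahn-echo decay      I(t) = A·e^(−t/T₂)
* J-modulated echo     I(t) = A·e^(−t/T₂)·cos(πJt),  J fixed at
  50.7 Hz (one-bond CO–Cα coupling) during fitting.

The time variable is the **total** echo evolution time t = 2τ; curve
files declare `time_convention: total|tau` and τ values are doubled on
read.  The modulated model is fit in **signed** form — the sign
inversion past the cosine zero at t = 1/(2J) ≈ 9.86 ms is information,
and magnitude processing is not assumed.  Finite-pulse corrections are
not applied.

Numerics: deterministic initialization (A from the intensity extremum, T
from a log-linear regression on the envelope, excluding points where
|cos πJt| < 0.3), then Levenberg–Marquardt least squares.  95% confidence
half-widths come from the linearized covariance at the optimum scaled by
the Student-t quantile with n−2 degrees of freedom; a residual bootstrap
(`bootstrap_ci`) is available when n is small.  Simulated coverage of
the linearized intervals is ≥ 90% over 500 replicates at 2% noise (the
suite asserts exactly this).  Degenerate inputs (all-zero intensities,
non-convergence) return a result flagged `converged=False` rather than
raising, so pipelines can report rather than crash; the pipeline stage
itself converts an unconverged fit into a numerical-failure exit.

The homogeneous linewidth is FWHM = 1/(πT₂); the ratio of observed
linewidth (ppm converted to Hz via an explicitly supplied nucleus
frequency in MHz — no default magnet is assumed) to this value
diagnoses inhomogeneous broadening, with a configurable flag threshold
of 10.

## DNP figures of merit (`dnpmetrics`)

* ε = I_on/I_off at equal scans and recycle delay (≥ 5·T₁ for a
  quantitative ratio; mismatches warn).
* P = (I_sample/I_reference)/(1 − loss) on microwave-off spectra of
  equal analyte amounts; `loss` compensates known sample loss and must
  lie in [0, 0.5).  Depolarization is 1 − P.
* S = ε·P/√T₁ in s⁻⁰·⁵.  T₁ is the microwave-on value where available;
  the radical-free reference, which has none, uses its microwave-off T₁.
  Polarization is accepted as percent or fraction (values > 1.5 are
  treated as percent; up to 1.2 is a legitimate fraction).
* Optimal recycle delay: 1.3 × T₁ (the analytic optimum for
  signal-to-noise per unit time under exponential recovery is ≈ 1.26 T₁).
* Noise-normalized intensity: spectra accumulated for equal wall time at
  different recycle delays carry different scan counts; dividing by
  √n_scans equalizes noise, and the series is pinned to a chosen
  reference value so it can be compared with computed sensitivities.

The bundled `KR2_DDM_SCREEN` (seven samples: radical-free, 5/10/20 mM
AMUPol and AsymPol-POK on the microbial rhodopsin KR2 in DDM micelles)
stores only measured parameters; sensitivity is always derived at run
time.  Recomputing S from the stored parameters reproduces the
measured sensitivity column to ±0.1 s⁻⁰·⁵ for the radical-free and
AMUPol rows.  The AsymPol-POK rows deviate by up to ~2 s⁻⁰·⁵: their T₁
values are sub-second and rounded to one decimal, and S ∝ T₁^(−1/2)
amplifies that rounding (e.g. 74·0.83/√1.0 = 61.4 vs a recorded 62.9,
consistent with an unrounded internal T₁ just below 1.0 s).  Tests
therefore check the AsymPol rows at the looser tolerance; forcing them
to printed precision would assert more than the stored inputs contain.

`rank_conditions` orders sample records by S, or by the **heuristic**
score S·√(T₂/T₂,ref) (`T2_weighted`) that makes the
sensitivity-versus-coherence-lifetime compromise explicit.  The weighted
criterion is labeled a heuristic in all outputs: it is a design aid, not
a measured quantity.  `estimate_scans` is likewise an estimator only;
real spectrometers round scan counts to phase-cycle multiples by rules
not modeled here (the recorded screen counts differ from
floor(time/1.3T₁) by up to ~25%).

## Ensemble shifts and line shapes (`ensembleshift`)

Histograms use a default bin width of 0.2 ppm (configurable) with edges
snapped to integer multiples of the bin width, so different ensembles of
one site bin identically.  Densities are piecewise constant and
integrate to 1.

Secondary-structure propensity windows for methionine (≥ 20% propensity,
derived from joint chemical-shift/structure database statistics):

| atom | helical (ppm) | non-helical (ppm) |
|------|---------------|-------------------|
| Cα   | 56 – 60       | 53 – 57.5         |
| CO   | 176.5 – 179   | 173 – 177         |

The windows overlap (Cα on 56–57.5 ppm), so helical and non-helical
area fractions are reported independently and may sum past 1.  Negative
spectral intensities (noise) are clipped at zero for area computations
only.

**Bimodality** is decided by fitting 1- and 2-component Gaussian
mixtures: two modes are reported only when the 2-component fit wins on
BIC *and* the component means are ≥ 2× the larger component SD apart.
The double guard replaces visual judgment conservatively; on 200
unimodal synthetic ensembles of 5,000 frames the false-positive rate is
≤ 5% (asserted in the suite), while a 50/50 mixture of components 1 ppm
apart with 0.2 ppm SDs is detected at 25,000 frames with component means
recovered to < 0.05 ppm.

**Comparison with experiment** resamples the histogram density and the
(clipped, area-normalized) spectrum onto a common uniform grid at a
quarter of the finer resolution and reports the overlap coefficient
Σ min(p,q)·Δppm — symmetric, 1 iff identical on the grid — and the
spectrum/histogram 10–90 inter-percentile width ratio.  Because
experimental intensity scaling against an MD histogram is arbitrary,
only normalized densities are ever compared.  A width ratio > 1 means
the frozen line is broader than the simulated ensemble, i.e. the sample
contains conformational heterogeneity on timescales the trajectory does
not reach.

**Re-referencing**: when a spectrum declares a reference peak (e.g.
glycerol 64.78 ppm or a detergent sugar carbon at 105.2 ppm vs DSS), the
axis is shifted so the nearest local maximum lands on the reference
value; the original axis is preserved.  Axes are stored ascending; the
NMR display convention (descending) is a rendering concern.

## Synthetic data (`synthetic`)

Each generator takes a spec dataclass with a seed and uses its own
`numpy` `default_rng` — no global state — so identical specs give
bit-identical output.  Ground-truth parameters are attached to every
product, and noiseless outputs match their closed forms to ≤ 1e-10
relative error; each downstream estimator recovers the generative truth
on its matching noiseless input to within 1e-6.

What the generators emulate, and what they do not:

* Sequences are i.i.d. draws (optionally composition-biased); real
  protein sequences have local composition structure, so the generator
  is a worst case for dipeptide statistics, not a model of any protein.
* Decays are single-exponential plus **additive Gaussian noise** — no
  multi-exponential relaxation, no spin dynamics, no rf imperfections.
  No noise model is known for the reference spectra; Gaussian noise is
  an assumption recorded as such.
* Shift ensembles are Gaussian mixtures; real per-frame predictions are
  skewed and autocorrelated across frames.
* Spectra are sums of ideal Gaussian/Lorentzian peaks; no baseline,
  phase, or apodization artifacts.

Passing the suite therefore demonstrates correctness of the estimators
under these idealized conditions, not robustness to every instrumental
artifact.

A saturation-recovery "infinite" delay is whatever longest delay the
caller requests; generators never append delays silently.

## Problem sizes

The suite uses the problem sizes the analyses are designed around:
25,000-frame ensembles for bimodality power, 5,000-frame ensembles × 200
replicates for the false-positive rate, 500 replicate fits for CI
coverage, and 1,000 random sequences for the pair-finder oracle.  The
full suite runs in well under a minute of compute-dominated time on one
core.

## Known limitations

* No modeling of DNP physics: enhancement, polarization, and T₁ are
  empirical inputs, never predicted from radical concentration, field,
  or MAS rate.
* No chemical-shift prediction: per-frame shift tables are consumed as
  produced by upstream predictors.
* No spectral deconvolution, 2D processing, or vendor raw formats.
* The bimodality decision is limited to 1 vs 2 modes by design.
* `fit_echo_decay` assumes the declared time convention is correct;
  a τ-vs-2τ mix-up halves or doubles T₂ undetectably.
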