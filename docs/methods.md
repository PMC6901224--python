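# Methods

## The measurement model

Linear-mode MALDI-TOF profiling of unfractionated serum records, per
acquisition of 800 laser shots, an intensity trace on an m/z grid:

    y_i(x) = s(x) + r_i(x),        x = m/z

where `s(x)` is the sample's signal — protein/peptide peaks on a smooth
chemical background — and `r_i(x)` is high-frequency noise, independent
between acquisitions with zero mean and finite variance (no Gaussian
assumption is needed for the averaging law, though the simulator draws
Gaussian noise).  Averaging `n` aligned acquisitions leaves the signal
untouched and shrinks the noise standard deviation by `1/sqrt(n)`.
Everything the package quantifies — noise level, observable peak count,
feature CV, concordance, information content, enrichment detectability —
is a consequence of that law plus the instrument's finite resolution.

## Simulator (`deepmaldi.simulate`)

The generator emulates the serum profiling conditions the analysis was
designed for; its defaults are the study conditions, not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| grid | 3,000–30,000 Da, Δ = 1 Da | uniform m/z axis; real TOF digitizers are uniform in time, but all processing here is defined in m/z, so a uniform m/z grid is the minimal faithful model |
| n_peaks | 200 | protein peaks per reference sample, centers uniform over the grid interior |
| amp_range | 1–10⁴ (log-uniform) | peak abundances span about four orders of magnitude, the dynamic range deep averaging makes observable in serum |
| resolving_power R | 700 | peak width σ_w(m) = m / (2.355·R); constant R makes FWHM grow linearly with m/z and yields on the order of 800 barely-resolvable peak slots over the range — the qualitative peak-crowding regime |
| noise_sigma | 1.0 | per-point noise sd of one 800-shot acquisition, in the same arbitrary units as amplitudes |
| jitter_scale | 10⁻⁴ | per-acquisition affine miscalibration x → a·x + b, with a−1 and b/m_mid ~ N(0, jitter_scale); matches the affine correction the alignment stage fits |
| baseline | 200·exp(−d/3000) + 20·exp(−d/15000), d = m/z − 3000 | smooth non-negative chemical background, intense at low mass |

The raw-spectrum generator evaluates the clean signal directly at the
warped coordinates `a·x + b` rather than warping and resampling — the
two are mathematically identical and direct evaluation has no
interpolation error.  Cohorts share one peak template with lognormal
between-sample amplitude variation (CV 15% by default); planted
peak–protein correlations use a Gaussian copula with latent Pearson
r = 2·sin(π·ρ/6) to hit a Spearman target ρ.

What the simulator does *not* model: ion suppression, detector
saturation, isotope envelopes, time-uniform digitization, batch/plate
effects, and any realistic distribution of serum peak positions or the
true baseline shape (neither is publicly available in quantitative form).  Passing tests therefore
demonstrate the internal consistency and statistical laws of the
pipeline, not agreement with any particular instrument's absolute peak
counts or CV values.

## Preprocessing (`deepmaldi.preprocess`)

Order is fixed: align raw spectra → average → subtract background →
re-align averages → normalize → integrate features.

* **Calibration points** — peaks detected at SNR ≥ 3 in more than half
  of the pool, clustered across spectra within max(1 Da, 300 ppm) and
  reported at cluster medians.
* **Alignment** — detected peaks are matched to calibration points
  within the same tolerance; if ≥ 60% of calibration points match, an
  affine correction `x_true = a·x_obs + b` is least-squares fitted and
  the spectrum linearly resampled onto the common grid; otherwise the
  spectrum is returned as an `Excluded` record, never dropped silently.
  The affine family is the minimal model a calibration-point fit
  determines and matches standard linear-TOF recalibration.
* **Averaging** — arithmetic mean of a random subset drawn without
  replacement, seeded; `n_shots = 800 × n_raw`.
* **Background** — the lower convex hull of the (m/z, intensity) point
  set, computed by a monotone-chain scan and interpolated between hull
  vertices; the global hull (rather than a segment-wise variant) is the
  implemented assumption.  Collinear points are kept as vertices so an
  exactly affine spectrum subtracts to zero.  Residuals are clipped at
  zero.
* **Normalization** — division by the summed intensity over
  [6100, 7500] ∪ [8500, 10700] ∪ [13300, 16400] Da (inclusive
  boundaries).
* **Feature integration** — sum of intensities at grid points inside
  each feature's [left, right] boundary, inclusive on both ends; a grid
  point on a shared boundary counts in both features (boundaries are
  deliberately wide to tolerate width variation and small shifts).

## Noise estimation and peak detection (`deepmaldi.noise`)

Noise is fluctuation with wavelength much smaller than a peak width.
It is isolated as the residual of Savitzky-Golay smoothing
(window 29, order 8) and estimated robustly within an m/z window of
relative width 0.08:

    sigma_hat = (P50 − P25) / (sqrt(2)·erfinv(1/2)) ≈ (P50 − P25) / 0.6745

which reproduces σ exactly for Gaussian residuals while ignoring
outliers (real peak structure leaking into the residual).  Percentiles
use linear interpolation between order statistics; windows are truncated
at grid edges and require ≥ 50 points; a negative raw estimate clamps to
zero with a warning.  The estimator inherits a small downward bias
(~9%) because smoothing absorbs part of the noise — a property of the
residual-based procedure itself, common to both axes of any scaling fit,
hence invisible to the exponent.

The smoothing kernel is built from a local polynomial least-squares fit
on abscissae scaled to [−1, 1]: at order 8 the standard unscaled solve
is ill-conditioned enough to leave a ~5×10⁻⁸ kernel normalization error,
while the scaled fit reproduces polynomials up to degree 8 to machine
precision.  Edges are handled by refitting the edge window's polynomial.

Peak detection takes local maxima of the smoothed, background-subtracted
spectrum with apex SNR ≥ cutoff, at least 3 grid steps apart, subject to
two artifact guards chosen here as design decisions:

1. topographic prominence ≥ cutoff·σ̂ — rejects noise wiggles riding on
   the flank of an intense neighbour, which pass a pure apex-intensity
   test;
2. prominence ≥ 2× the local maximum |smoothing residual| within one
   smoothing window — rejects the small ringing sidelobes a high-order
   polynomial filter leaves beside peaks much sharper than its window.
   For white noise this guard sits near 5σ and is inactive at the usual
   counting cutoffs (SNR ≥ 10).

FWHM is measured by linear interpolation of half-maximum crossings; a
crossing not reached before the signal rises again (overlapping
neighbour) flags the width as unreliable (`None`) rather than guessing,
and a crossing that runs off the grid edge is an error.

## Reproducibility metrics (`deepmaldi.metrics`)

* CV per feature over K replicate runs of one sample,
  `100·sd/mean` with the unbiased (K−1) denominator (no convention is
  standard here; the choice shifts constants only).
* Concordance of two runs: per-feature Pearson R and regression slope
  of run B on run A; summary is the median of (1−R).  Undefined
  quantities (constant features) are flagged and excluded, never
  imputed; summaries report exclusion counts.
* Information content per feature, in bits:
  `S_j = log2( sd(f(:,j,:)) / mean_i sd(f(i,j,:)) )` — total variability
  over technical variability; the spectrum total is the sum over
  features.  The total in bits is the implemented reading of the
  "analytical information content" axis, which is not otherwise
  specified.
* Power-law fits are OLS of log y on log x.

## Enrichment analysis (`deepmaldi.psea`)

For each feature: Spearman correlation against every panel protein
(average ranks for ties; constant columns flagged NaN), then a weighted
running-sum enrichment score over proteins ranked by decreasing ρ —
in-set proteins advance the sum proportionally to |ρ|^w (default w = 1;
w = 0 gives the classic unweighted KS form), out-of-set proteins
decrement it uniformly, and the score is the signed extremum.  The
exact running-sum convention differs between published enrichment
tools; this weighted variant is the module's largest assumption and is
exposed as a config field.  Ranking ties are resolved by rounding
ρ to 12 decimals (so mathematically tied correlations tie numerically)
then by panel order.  If all in-set correlations are exactly zero the
in-set steps fall back to uniform.

P-values compare |ES| (associations are reported unsigned) with the
null obtained by permuting feature values across samples —
`(1 + hits)/(1 + n_perm)` for Monte-Carlo (default 499 permutations,
seed mandatory), or the exact fraction over the full permutation group
when the sample count is ≤ 7.  BH adjustment is applied per process
across features by default (matching per-process feature counts), with
a global-scope flag.  Note one statistical property a user should know:
sample permutation preserves inter-protein correlation, so a tightly
correlated protein set has a genuinely heavy-tailed null — with a small
panel a perfectly enriched set may not be able to reach very small
p-values because a few percent of permutations also rank the whole
correlated block on top.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scaling-law experiments
at sizes chosen as realistic desk-scale study conditions: the noise-law
fit uses a 1,000-spectrum pool on the full 3–30 kDa grid with averages
of 1–1,000 raw spectra; the CV-law fit uses 20 independent replicate
averages at 4 shot levels spanning 2,400–240,000 shots (the low end of the range
over which replicate CVs are typically reported), 100 features on the strongest peaks,
repeated over 3 independent reference samples and fitted jointly — the
repetition tames the common-mode noise that windowed normalization
shares across all features of a replicate, which otherwise leaves the
fitted exponent with a sampling sd of about 0.05.  The fitted CV
exponent magnitude comes out near 0.52–0.56 rather than exactly 0.5:
at the lowest shot level the convex hull hugs the noise floor and its
fluctuations add a small super-`1/sqrt(n)` CV contribution — a real
property of the processing chain, and the kind of curvature replicate
CV-vs-shots tables commonly show at their low end.

Degenerate inputs are errors, not guesses: empty feature intervals,
non-positive normalization constants, unmatched alignment, constant
features in correlation screens, p-values outside (0, 1].

## Known limitations

* No batch/plate correction; pools are treated as exchangeable.
* No vendor raw formats or mzML; spectra travel as 2-column text.
* Absolute instrument-specific quantities (peak-count plateaus,
  specific median CVs, information-content curves, per-process feature
  counts) depend on real serum composition and instrument noise floors
  and are out of the test surface; only their directions and scaling
  laws are asserted.
* Peak-to-protein identity assignment is out of scope by design; the
  enrichment module exists precisely to avoid needing it.
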