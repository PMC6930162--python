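# Methods

This note documents the models, defaults and numerical choices behind
`sigprof`, and what the synthetic-data generators do and do not emulate.

## Trace model and preprocessing

A trace is one cell's fluorescence series on a strictly increasing time grid
(seconds), raw (`F`) or baseline-normalized (`dff`).  ΔF/F is
`(F − F₀)/F₀` with `F₀` the mean over the baseline window; the default
window is every sample strictly before the stimulus, which uses all
pre-stimulus data (the window length is configurable — assays with drifting
baselines may prefer a short window just before the stimulus).  A baseline
mean ≤ 0 is rejected as non-physical rather than normalized through.

Kinetic fits operate on the post-stimulus sub-trace with time re-origined so
the first retained sample is t = 0.  Alignment at the stimulus time (not the
per-cell peak) is the default: it is deterministic and identical across
cells, whereas peak alignment couples the fit origin to noise; peak
alignment remains available (`peak_align=True`) for sensitivity analysis.
Traces with grid gaps are rejected at load, never interpolated, because
clustering requires a common grid.

Quality control retains a cell iff its maximum **post-stimulus** ΔF/F is at
or above 0.2 (the boundary value is retained; the filter's purpose is to
remove cells without a positive response to the stimulus, so pre-stimulus
excursions cannot rescue a flat response).  In the bundled pipeline the
filter is applied to cAMP (bPAC) data before any analysis; the Ca²⁺
clustering scenario runs unfiltered, since its blunted-response profile
family lives partly below 0.2 and is a population of scientific interest
there, not an artifact.

## Kinetic models

**Exponential transient** `ΔF/F = α·e^(−θt)`: α is the signaling amplitude
(unitless ΔF/F), θ the clearance rate (s⁻¹).  Fit by bounded least squares
(`scipy.optimize.least_squares`), α ∈ (0, 10], θ ∈ [1e−5, 5] s⁻¹,
tolerances 1e−12, at most 500 function evaluations.  Initialization is
deterministic: α₀ = trace maximum; θ₀ from an ordinary regression of
ln(ΔF/F) on t over samples with ΔF/F > 0.05.

**Logistic decay** `ΔF/F = α/(1+β·e^(−θt))`: the printed form increases for
θ > 0, so the biologically relevant branch — decay from ≈α back toward
baseline — has θ < 0 and β < 1.  θ is fit unconstrained in [−5, 5] and a fit
is accepted only if the fitted curve decreases over the window and its
half-life `t½ = ln(β)/θ` is positive and inside the observation window.  β
is optimized on a log scale (ln β ∈ [−50, 50]) for conditioning;
(β₀, θ₀) come from a logit regression `ln(α₀/y − 1) ≈ ln β − θt` over the
mid-range samples, falling back to the raw half-crossing time.  A trace
whose terminal mean (last max(3, n/10) samples) stays at or above 90% of its
peak is rejected up front ("no decay observed").

Failed fits return `converged=False` with a reason and are excluded from all
downstream statistics but counted in the run log; they are never silently
dropped nor reported with garbage parameters.  The closed-form t½ is
verified in the test suite against bisection on the fitted curve (≤ 1e−9 s).

## Profile clustering and the PBM index

Traces are clustered as raw ΔF/F vectors on the common post-stimulus grid.
Per-trace z-normalization is off by default — the profile families differ
chiefly by amplitude, which z-scoring would erase — but is available as a
flag.  k-means (Euclidean, Lloyd) runs 25 seeded restarts per candidate K,
keeping the lowest within-cluster sum of squares; cluster labels are
re-ordered by ascending centroid mean so profile numbering is stable.
Candidate K = 2…7 are scored with

    PBM(K) = ((1/K) · (E₁/E_K) · D_K)²,

E₁ = Σᵢ‖xᵢ − x̄‖, E_K = Σᵢ‖xᵢ − c(i)‖, D_K = maxⱼₗ‖cⱼ − cₗ‖, and the
maximizing K is selected, ties broken toward smaller K.  Conditions being
compared are pooled before clustering; per-condition profile fractions are
then pure lookups of the pooled assignments (never a re-fit), reported per
well with mean ± SD across wells.

PBM behaves as designed only when within-cluster spread is dominated by
noise rather than by a continuous parameter gradient: on small noiseless
sets the index keeps improving as the parameter continuum is chopped finer,
so selected K on such fixtures is not meaningful.

## Statistics

* Empirical CDFs are right-continuous; evaluation at q returns the fraction
  of values ≤ q.  CDF comparisons are descriptive; a two-sample
  Kolmogorov–Smirnov test is provided as an explicit extension.
* Condition comparisons use two-tailed pooled-variance t-tests on
  **well-level** summaries (N = wells), avoiding pseudo-replication from
  per-cell units.  Zero pooled variance with equal means gives t = 0, p = 1
  by convention; with different means the result is flagged degenerate.
* The stress–signaling relationship is the Pearson correlation (with the
  least-squares line) between per-cell stress score and maximum Ca²⁺ ΔF/F;
  |R| < 0.1 is flagged weak.
* Parameter distributions are summarized by quantiles and Gaussian KDEs
  (Silverman bandwidth; a constant sample gets a zero density and its
  quantiles), with a dip-test p-value as a bimodality report.

### Dip test of unimodality

No dip-test implementation exists in the dependency stack, so the statistic
is computed in-package directly from its definition: the minimum over
unimodal CDFs U of sup|Fₙ − U|.  A unimodal CDF is convex before its mode
and concave after, with at most one atom, at the mode.  The implementation
binary-searches the smallest band half-width ε admitting a
convex-then-concave nondecreasing CDF inside [Fₙ − ε, Fₙ + ε]; band
feasibility splits the sample at a mode either between data points or at a
data point (whose atom absorbs the jump), and each branch reduces to a
greatest-convex-minorant check that is monotone in the split index, hence
binary-searchable.  42 bisection steps give ~1e−13 precision.  p-values are
Monte Carlo against uniform null samples of the same size (default 100
draws, cached per sample size) — the standard calibration for this test.
The statistic is validated against closed forms (equally spaced samples give
1/(2n); two balanced atoms give 0.25) and against an independent
linear-programming oracle at small n.

## Image quantification

Nuclei are segmented on the red (expression) channel: global Otsu threshold,
connected components, minimum area 20 px at the default rendering scale;
coordinates are 0-based (row, col), areas in pixels.  A blank image yields
an empty mask.  Per-nucleus mean red/green and the green/red ratio are
measured on the mask.  The stressed flag compares mean nuclear green to a
threshold: a user-supplied value, or automatically Otsu on the pooled
per-nucleus means when that distribution is bimodal, else 3× the background
green (median outside the mask).  Bimodality is a dip test (p < 0.05) plus a
2-fold class-separation gate on the Otsu split: per-nucleus means are
quantized by the integer pixel area of each nucleus, and without the gate
the dip test fires on that fine structure in homogeneous frames, letting
Otsu split a single population.  Percent stressed is 100·n_dual/n_red per
image; time courses are per-image population statistics with no nucleus
tracking.  No declumping/watershed is attempted beyond what the
non-overlapping synthetic nuclei require, and no illumination correction is
applied.

## Synthetic data

The generators emulate the experiments' statistical structure with known
ground truth (family label, true α/θ/β/t½, stress flag), which is carried
beside every data set and never consumed by analysis code.

* **Ca²⁺** (2-s cadence, stimulus at 100 s, 300 s total): flat baseline
  noise, then `α·e^(−θ(t−t_stim))` + Gaussian noise (sd 0.05 ΔF/F).  Four
  families with α in [0.05, 0.25], [0.3, 0.6], [0.9, 1.4], [1.8, 2.5].  The
  per-family θ bands ([0.085, 0.095], [0.02, 0.03], [0.035, 0.045],
  [0.055, 0.065] s⁻¹) were chosen so the four families are genuinely
  distinct in raw-trace space — a fast-clearing blunted spike, a sustained
  blunted response, a slow full response, a moderately clearing large
  response: amplitude alone cannot separate the two blunted families, whose
  absolute ΔF/F difference is below the wide families' internal spread.
* **cAMP** (20-s cadence, pulse at 100 s, 900 s post-pulse): baseline, rise
  at the pulse, then the decreasing logistic with β = e^(θ·t½).  Families
  share one amplitude band (1.4–1.9 ΔF/F: the bPAC pulse drives every cell
  to a similar peak) and differ in kinetics: half-lives 60–120 s (rapid),
  180–300 s (intermediate), 420–600 s (delayed), with steepness bands
  keeping |θ|·t½ ≳ 3 so each trace starts near its plateau.  A two-family
  variant pairs rapid with delayed.
* **Stress–signaling coupling**: log-normal stress scores s; max ΔF/F =
  0.2 + slope·e^(−s) + ε (slope 1.8, ε sd 0.2), a monotone-decreasing map so
  noiseless pairs are negatively correlated.
* **Images**: nuclei as 2-D Gaussian spots (σ = 4 px) on constant background
  100, red amplitude 3000 on every nucleus, green 2500 on exactly
  round(frac·n) of them; centers rejection-sampled at least 8σ apart (error
  if unpackable); 16-bit channels; optional Poisson noise, off by default.
  Label masks are disks of radius 2σ.

What the generators do **not** emulate — and hence what passing tests do not
show about real data: photobleaching, baseline drift, motion, cell-to-cell
optical cross-talk, touching/overlapping nuclei, illumination gradients,
segmentation errors from irregular nuclear morphology, and correlated
(non-Gaussian) noise.  Family parameters are stand-ins spanning the
qualitative response classes, not estimates of any measured cell population.

## Problem sizes

The test suite and the acceptance script run cluster-count recovery at
~800 cells × 20 seeds per scenario, parameter recovery at 200 traces per
model, and image statistics at 50 nuclei × 10 seeds per stressed fraction —
sizes at which the population structure is well resolved while a full run
completes in minutes on one core.

## Known limitations

* The PBM selection is only as meaningful as the Euclidean raw-trace
  representation; amplitude-dominated data can mask kinetic structure (use
  `znorm=True` to explore shape-only clustering).
* The logistic fit rejects traces whose half-life falls outside the
  observation window; very slow decays therefore need a longer acquisition,
  not extrapolation.
* The minimal segmenter assumes non-overlapping, roughly circular nuclei;
  it does not claim equivalence with pipeline-grade segmentation of real
  micrographs.
* Dip-test p-values are Monte Carlo (default 100 draws): resolution is
  ~0.01, adequate for α = 0.05 decisions, not for reporting precise small p.
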