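# Methods

## Model and assumptions

The enrichment procedure treats the two compartment profile blocks as
related by a single affine systematic distortion on the log2 scale. The
working assumptions are:

* expression values are complete, finite, post-normalisation log2
  intensities (missing values are a load error, never imputed);
* only a small fraction of probesets is compartment-specific, so the bulk
  of both sorted aggregate profiles traces the same underlying curve and a
  line fitted to each captures their relative base level and dynamic range;
* enrichment of interest is one-sided (glomerular over-representation);
  the mean + k·SD rule selects only the upper tail of the difference
  distribution.

### Choice of abscissa for the sorted line fits

The fits are computed against the shared 1-based rank after sorting.
Absolute slopes therefore depend on the x-units, but both quantities that
enter the adjustment map — the slope *ratio* and the intercept
*difference* — are invariant to any common positive rescaling of the
abscissa (both OLS slopes scale by the same factor; both intercepts are
evaluated at the same origin). This invariance is asserted numerically in
the test suite, and it is why the calibration is well-defined even though
rank units are arbitrary. Ties in the sort key are broken by probeset ID
with a stable sort, making the fit deterministic.

### Selection rule

The threshold is `mean(d) + k·SD(d)` computed over **all** probesets in a
single pass (no iterative trimming), with the sample (n−1) standard
deviation and a strict `>` at the boundary. `k = 2` by default. A constant
difference vector (SD = 0) raises an explicit degenerate-input error rather
than silently selecting nothing. For Gaussian differences the rule selects
the one-sided tail mass beyond two SDs, ≈ 2.275%; with ~22k probesets the
enriched subset inflates the SD slightly, so the realised null fraction
sits just above that value.

### Probeset → gene collapse

Unannotated probesets are dropped and redundant ones (several probesets,
one symbol) collapsed to the first occurrence in selection order. The
accounting identity `selected = genes + dropped + collapsed` holds on every
input and is property-tested. Gene counts are annotation-release-dependent
by design; the package takes the annotation as input.

## Parameters that matter

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| `n_probesets` | — | 22,283 | HG-U133A array scale |
| `n_samples_per_compartment` | — | 6 | paired living-donor design |
| `baseline_mean` / `baseline_sd` | log2 | 7.0 / 2.0 | conventional spread of RMA-summarised intensities; configurable since the true empirical spread is platform/lab-dependent |
| `noise_sd` | log2 | 0.3 | standard Gaussian approximation of microarray measurement noise |
| `distortion` (a\*, b\*) | —, log2 | (0.9392425, 1.17905) | magnitude of a realistic between-block affine offset |
| `enriched_fraction` | — | 0.03 | "small subset" of compartment-specific genes |
| `enrichment_effect` | log2 | 2.0 | a 4-fold enrichment, typical of strong compartment markers |
| `k` (selection) | SD units | 2 | the mean + 2·SD criterion |
| DDD `alpha` | — | 0.05 | per-cluster one-sided Fisher level, uncorrected by default |
| Ct plausible range | cycles | 5–40 | brackets real-time PCR runs |

## What the generators emulate — and what they do not

`simulate_compartment_pair` draws per-probeset true levels
μ_i ~ N(baseline_mean, baseline_sd²), adds the enrichment effect to a known
random subset on the glomerular side only, and produces the
tubulointerstitial samples as `(μ_i − b*)/a*` plus noise — the *inverse* of
the downstream adjustment direction, so a perfect calibration recovers
(a\*, b\*) and parameter recovery is the natural end-to-end test. One seed
governs a scenario; sub-generators draw from independent spawned streams,
so output is bit-identical under a fixed seed.

Not emulated: probe-level effects, chip spatial artifacts, batch structure
beyond the single affine distortion, heavy-tailed or intensity-dependent
noise, and correlated probesets. Passing tests therefore demonstrate the
pipeline's arithmetic and its statistical behaviour under the stated
Gaussian/affine model, not robustness to every failure mode of real arrays.
Likewise the library-count generator draws exact multinomials with uniform
base cluster frequencies, and the Ct generator uses a shared per-gene
baseline with i.i.d. Gaussian cycle noise and fold-1 reference genes by
construction.

## Numerical and design choices

* **OLS, not robust fitting**, for the sorted line fits; fits are checked
  against a closed-form normal-equations oracle to 1e-9.
* **Adjustment direction** is fixed tubulointerstitium → glomeruli; the
  CLI `calibrate --swap-direction` flag reverses it with a warning.
* **Averaging of the two passes** is the componentwise arithmetic mean of
  the two adjustment maps (slope with slope, intercept with intercept).
* **DDD test statistic**: one-sided Fisher's exact test on the
  (cluster, rest) × (pool A, pool B) table, computed via the vectorised
  hypergeometric survival function (mathematically identical); verified
  against exhaustive hypergeometric summation. The classic tool's exact
  significance procedure is not published, so this is the package's own
  documented choice. Zero counts are replaced by 0.5 in the reported
  frequency ratio only — p-values always use the true counts. No
  multiple-testing correction by default; Benjamini–Hochberg is a flag.
* **ΔΔCt**: per-sample ΔCt against the arithmetic mean of the reference
  Cts (geometric mean available); group ΔΔCt from group means. Group
  p-values delegate to the Mann–Whitney U test.
* **Gene symbols** are compared case-insensitively after upper-casing; no
  alias or identifier mapping is attempted, so overlap counts inherit any
  nomenclature drift between input lists.
* **Synthetic reference lists** (`regged.synthetic_lists`): the published
  supplementary gene lists this package's comparison stage was designed
  around are not redistributable, so deterministic synthetic stand-ins with
  the published sizes and overlap structure (six genes common to all five
  datasets; 38/9/17 cross-list overlaps; 17 markers covered) are generated
  in code. They exercise the set arithmetic exactly; they carry no biology
  beyond the handful of real symbols they pin.

## Problem sizes used in tests

Unit tests run at a few hundred to a few thousand probesets; the
acceptance-level properties run at the full design scale (22,283 probesets,
6+6 samples) with 20 seeds for the recovery and sensitivity checks, 50
seeds for the DDD false-positive budget, and exhaustive table enumeration
(pool totals ≤ 12 each, plus random tables with combined total ≤ 500) for
the Fisher oracle. These sizes make the whole suite run in well under a
minute while keeping the Monte-Carlo error bands meaningful.

## Known limitations

* The affine model is a first-order correction; curvature between the two
  sorted profiles (e.g. saturation at high intensity) is not modelled.
* The mean + k·SD rule has no per-gene variance moderation and no FDR
  control; it is an aggregate-profile outlier cut, reported as such.
* Calibration operates on aggregate profiles, not per sample, so
  sample-level variability enters only through the profile means.
* One reported reference figure for the adjustment arithmetic is
  internally inconsistent with its own printed inputs (the intercept
  difference of the printed fits is 1.2122, not 1.3022); the package
  computes the arithmetic faithfully and the discrepancy surfaces as an
  honest test failure against the reported figure.
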