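# Methods

## The statistic

For a categorical variable with k categories, let E_i be the share of
category i in a *reference* sample and O_i its share in a *scoring* sample.
The Population Stability Index is

    PSI = Σ_{i=1}^{k} (O_i − E_i) · ln(O_i / E_i).

Each term is a product of two factors with the same sign, so every
per-category contribution is non-negative and PSI = 0 exactly when the two
distributions coincide. The statistic is symmetric in its arguments, and on
the proportion scale it equals the Jeffreys divergence,
KL(O‖E) + KL(E‖O) — an identity the test suite asserts to 1e-12.

### The two conventions

The scorecard-monitoring literature computes PSI on proportions (shares
summing to 1); the interpretation cut-offs 0.1 and 0.25 come from that
scale. Published breakdown tables for aggregated registry data, however,
often tabulate *percentage* columns and multiply percentage-point
differences by the log-ratio. Because the log-ratio is scale-invariant,
the percent-convention total is exactly 100× the proportion-convention
total. Both conventions are first-class here:

- `convention="percent"` (default) reproduces percentage-column breakdown
  tables cell for cell, including totals far above 1 (the packaged example
  peaks at 2.96);
- `convention="proportion"` is the interoperable form for comparison with
  other drift metrics and with the 0.1/0.25 thresholds' original scale.

Interpretation bands are applied to the score in its computed convention
(so a percent-scale 2.96 is "significant" against 0.25); the thresholds
live in an `InterpretationPolicy` and are configurable. Boundary values
belong to the higher band (0.1 → moderate, 0.25 → significant).

Breakdown rows store the difference as reference−scoring and the log-ratio
as ln(reference/scoring), matching the sign conventions of printed
breakdown tables; the contribution is unaffected by the ordering.

## Zero counts and smoothing

ln(O/E) is undefined when either share is zero. When a comparison pair
contains any zero count (typically after union-alignment of mismatched
category sets), a pseudo-count of 0.5 is added to *every* category of
*both* samples before normalising, and the resulting vectors are flagged
`smoothed`. Smoothing both sides keeps the treatment symmetric and the
distortion O(k/N); a warning is logged. The packaged registry table
contains no zeros, so its results involve no smoothing.

## Companion chi-square analysis

Each pair of samples forms a k×2 contingency table. The Pearson statistic
with pooled-margin expected counts is computed by
`scipy.stats.chi2_contingency` with no continuity correction anywhere,
including 2×2 sex tables — correction is a small-sample device and these
tables have N in the hundreds of thousands; the choice is recorded in the
report metadata. Degrees of freedom are k−1; p-values are the upper tail.

Multiplicity over the m pairwise comparisons within one variable's family
(m = C(#samples, 2) = 21 for seven years, configurable) is handled by
Bonferroni division of the nominal levels 0.05/0.01/0.001. Star
annotations use the full-precision thresholds; displayed thresholds are
truncated toward zero at two significant digits (0.05/21 → "0.0023"),
matching common figure-note style.

Effect size is Cramér's V = √(χ²/(N·min(r−1, c−1))) without bias
correction, banded small (≤0.2), moderate (≤0.6), large (>0.6). V is
scale-free: doubling every cell doubles χ² but leaves V unchanged.

The point of running both arms on the same pairs: with registry-scale N,
nearly every chi-square test is significant even after adjustment while
every V is tiny — statistical significance has decoupled from practical
difference. PSI bands, which do not sharpen with N, stay interpretable.

## Binning

PSI needs categories, so record-level numeric variables are discretised
first. Bins are left-closed/right-open with the final bin right-closed
(the age-group style "60–64"); a value on an interior edge goes to the
higher bin; out-of-range values are clipped to the terminal bins with a
warning, so bin counts always sum to the input size. `equal_width` spans
[min, max]; `quantile` uses empirical i/k quantiles with duplicate edges
collapsed (tied data are the norm in EHR-style variables) rather than
raised. The default k = 10 follows common drift-monitoring practice; no
principled universal choice exists, bin choice demonstrably moves PSI, so
the scheme is an explicit, JSON-serialisable object surfaced in reports.

## Synthetic data generator

The generator emulates aggregated registry tables: multinomial counts over
k categories for a reference sample (true shares p) and a scoring sample
(true shares q), with

    q_i ∝ p_i · exp(δ · z_i),   z_i ~ N(0, 1) i.i.d.

The log-normal share perturbation was chosen over a Dirichlet because
δ = 0 gives q = p *exactly* (a clean null) and the expected divergence
grows monotonically with δ. `generate_yearly_table` chains the
perturbation into a random walk across samples, mimicking gradual
year-on-year drift. One `numpy` Generator per spec; identical seeds give
bit-identical tables.

Under the null, the sampled proportion-scale PSI is not zero but noise
with mean ≈ (k−1)(1/n_ref + 1/n_scor) (delta-method limit, accurate when
expected cell counts are large). With k = 5 and n = 1,000 per sample that
is 0.008 — two orders of magnitude below the 0.1 band — which the test
suite verifies by Monte Carlo (2,000 replicates, within 10%).

What the generator does *not* emulate: real incidence dynamics, registry
coverage changes, correlated drift across variables, or overlapping
category groups (as cancer-site groups in the packaged table are). Green
simulation tests therefore certify the statistics' sampling behaviour
under clean multinomial sampling, not fidelity to cancer epidemiology.

## Problem sizes and numerics

The packaged analysis is exact and runs in well under a second: 3
variables × C(7,2) = 63 comparisons on tables of ~240k–310k patients per
year. Simulation defaults (200 replicates per grid point; 2,000 for the
null-calibration check at n = 1,000) were chosen so the whole suite
completes in a few seconds while keeping Monte-Carlo error inside the
stated tolerances. All internal arithmetic is double precision with
`math.fsum` for totals; rounding to two decimals happens only at
presentation. Percent-vs-proportion agreement is asserted at 1e-9
relative; identities (symmetry, Jeffreys, loop-oracle) at 1e-12 absolute.

## Known limitations

- PSI here is univariate; concatenated multivariate PSI needs record-level
  data, out of scope by design.
- No sampling distribution or p-value is attached to PSI itself; bands are
  conventions, not tests.
- The 0.1/0.25 cut-offs are tied to the proportion scale's tradition but
  the package applies them in the computed convention by design; users
  comparing against the wider PSI literature should use
  `convention="proportion"`.
- Quantile binning on heavily tied data can collapse to fewer bins than
  requested (logged); an all-tied variable cannot be binned at all.
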