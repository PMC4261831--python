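# Methods

This note records the models, conventions and numerical choices behind
`sedtriad`, in the order the pipeline runs them.

## Sediment quality guideline quotients

Each analyte's quotient is its mean concentration divided by the marine
probable effects level (PEL). The class quotient is the arithmetic mean
over the analytes of that class; the total quotient pools **all**
PEL-bearing analytes into one mean rather than averaging the class
means — with a clean reference sediment, averaging class means would
let a near-zero organics class halve an otherwise meaningful total.
The metalloid arsenic is scored with the metals; selenium has no PEL
and is skipped (with a log message), as is any analyte absent from the
guideline table. Classification uses strict thresholds at 0.1 and 1.0
with boundary values assigned to the moderate bin: a sediment exactly
at a threshold has already reached the level that defines the more
precautionary class's lower edge, and the moderate bin is the
conservative choice at both edges.

The PEL constants ship as a versioned CSV (`data/pel_marine.csv`);
alternative guideline families (TEL, ERL/ERM, freshwater) are a
user-supplied table, not a bundled variant.

## Dose–response model

Responses are normalized before fitting: viability to percent of the
solvent-control absorbance, %DNA in tail to the highest mean %tail
measured across the experiment set (about 30% in practice — comet
tails never approach 100%, so the observed study maximum stands in for
the maximal effect). The fitted curve is the two-parameter log-logistic

    f(x) = upper / (1 + (x/EC50)^b)

with `lower = 0` and `upper` fixed by the normalization (100 or 1.0);
the sign of `b` encodes direction. Two free parameters are the fewest
consistent with pre-normalized data; richer families (Weibull, hormesis,
free asymptotes) are deliberately out of scope.

Numerics: the fit runs on `(log EC50, b)` via least squares
(`scipy.optimize.curve_fit`). Starting values are deterministic — EC50
from linear interpolation of the dose bracket crossing half-response
(geometric mid-range of the tested doses when no bracket exists),
`b = ±1` by direction. The dose-0 control anchors the asymptote
directly rather than entering as log(0). The 95% CI is the delta-method
interval on log EC50, back-transformed, matching the symmetric
"± 95% CI" reporting convention; a profile-likelihood interval would be
a reasonable alternative but is not implemented.

A series is flagged **non-estimable** (rendered "–") instead of raising
when the optimizer fails, the fitted EC50 leaves the tenfold extension
of the tested dose range `[min dose/10, 10 × max dose]`, the maximum
observed normalized effect stays below 0.5, or the fitted slope
contradicts the declared direction. An EC50 extrapolated beyond the
data is not a reportable estimate; downstream, "–" is treated as "no
measurable effect at the tested doses".

## Comet statistics

The condition endpoint is the mean %tail pooled over all nucleoids of
all gels and replicates (the reported summary), but hypothesis tests
default to replicate means as the experimental unit: the ~100 nucleoids
of a condition share a culture and a gel run and are not independent.
Nucleoid-level testing remains available for exploratory work.
Kruskal–Wallis H uses the standard tie correction; post-hoc
comparisons against the dose-0 control are Dunn rank tests with the
pooled-rank tie-corrected standard error and Bonferroni adjustment
(the literature's "multiple-comparison adaptation" names no specific
procedure; Dunn + Bonferroni is the standard rank-based choice).
Net FPG damage is the FPG-minus-buffer difference of condition means;
negative values are reported, not clipped — they are informative for
QC, and clipping would bias aggregate summaries upward.

## Integrated Biomarker Response

For each biomarker the station means are standardized to `Y`, flipped
to `Z` for biomarkers that decrease under stress, and shifted to
partial scores `S = Z + |min Z|`, so the least-stressed station scores
exactly zero. Star-plot areas between consecutive biomarkers are
`A_i = S_i S_{i+1} sin(2π/k)/2` with wraparound, and the station's IBR
is their sum; no division by the biomarker count is applied, so values
are comparable only within a fixed panel.

Two standardizations: `across_station_means` uses mean and sample SD of
the station means alone; `pooled_total` (default) divides by
`sqrt(mean within-station variance + population variance of the means)`
— the dispersion of the underlying individuals, frequency-weighted when
station sizes are given and equal-n otherwise. The pooled form damps
biomarkers whose between-station differences are small relative to
their biological variability, which is the behaviour wanted when the
panel mixes noisy enzyme activities with stable ratios.

Conventions that the IBR literature leaves open, fixed here:

* **Directions** default to increases-with-stress for every biomarker
  except GSH/GSSG (reduced glutathione is consumed under oxidative
  stress, so the ratio falls).
* **Star order** defaults to the input row order. The IBR is invariant
  to rotations and reversals of that order but not to arbitrary
  permutations; `order_sensitivity` reports the spread over sampled
  permutations so users can judge how much their ordering choice
  matters.
* **Per-species scores** partition the global star: a species' score is
  the sum of the `A_i` whose leading vertex belongs to it. They are not
  species-local stars — a two-biomarker species (clam) would otherwise
  always score zero, since a 2-vertex star is degenerate
  (`sin(π) = 0`; the code warns and returns 0 for such stars).

On the bundled three-station panel these conventions give a reference
IBR of 0.01 (2 dp) and the area ordering south > north > reference,
with clam and fish peaking in the south and cuttlefish in the north.

## Lines-of-evidence integration

Endpoints are min–max normalized per column; a constant column maps to
all zeros and missing cells become 0 after normalization (missing means
"no measurable signal" here, mirroring the "–" convention; it is logged).
EC50s enter as potencies `1 − minmax(EC50)` over estimable entries so
the most potent extract scores 1; non-estimable entries and the
degenerate single-estimate case score 0. Sites cluster on Euclidean
distance, endpoints on `d = 1 − Spearman R` (range [0, 2]; constant
profiles get distance 1 with a warning), both complete linkage through
`scipy.cluster.hierarchy`; the test suite checks the merge heights
against an exhaustive brute-force agglomeration oracle. IDW uses power
2 by default (configurable), planar coordinates (estuary extents are
far below the scale where geodesy matters), exactness at data points
and boundedness by the input range. Field biomarkers sampled from
fishing grounds rather than sediment stations are attached to a
representative site through an explicit site→area map (the reference
animals to site R).

## Synthetic data generator

The generator emulates the study design, not just array shapes:

* **Chemistry**: per-analyte lognormal draws (CV 0.15) around a
  reference baseline times class multipliers. The default archetypes
  put the reference total quotient below 0.1 and the four impacted
  sites between 0.1 and 1, with the northern pair PAH-heavy and the
  southern pair metal-leaning.
* **Dose–response**: the dose grid {0, 5, 10, 25, 50, 100, 200}
  mg SEQ/mL; truth EC50s of order 80–360 mg SEQ/mL with slope 2 and a
  maximal %tail of 30, so fixtures sit on the scale of the real assay
  tables. Nucleoid noise is truncated normal (SD 8 %tail, bounds
  [0, 100]) — truncation was chosen over a beta model for transparency,
  at the cost of a small mean bias near the bounds. FPG-treated series
  divide the truth EC50 by 2.5.
* **Biomarkers**: lognormal individuals (shape 0.6, matching the large
  CVs of field panels; 12 individuals per station, a typical field
  sample) around station medians patterned on the bundled panel. The
  GSH/GSSG ratio is built per individual from GSHt and GSSG draws as
  GSH/(GSSG/2), so its noise is the propagated noise of its parts.
* All draws derive from one seed through CRC-keyed independent streams,
  so each component is reproducible regardless of what else was drawn.

What passing simulation tests do **not** show: the generator has no
spatial autocorrelation in chemistry, no toxicokinetics linking
chemistry to the dose–response truth, and independent biomarkers within
an individual — conclusions about real data with those structures need
their own checks.

The `stress_gradient_config` scenario exists for parameter-recovery
studies: clam/fish biomarkers roughly double per step along
reference < north < south while cuttlefish peaks in the north, giving
a truth-level IBR ranking with a wide margin (≈1.9 vs ≈3.6 vs 0).
Under the default panel-like truth the two impacted areas differ by
only ~20% in truth IBR, so their ranking is genuinely ambiguous at
field sample sizes — a property of that scenario, not an estimator
defect.

## Problem sizes used in the checked simulations

Estimator calibration runs 500 seeded series (6 doses + control,
triplicate, Gaussian noise SD 0.10 on the normalized scale) for EC50
error and CI coverage; 2000 seeded null sets (3 groups × 20) for the
Kruskal–Wallis level; 200 seeded bundles for IBR ranking recovery; and
200 random ≤5-leaf matrices for the clustering oracle. These sizes give
Monte-Carlo standard errors comfortably below the margins being
checked.

## Known limitations

* The published organic/total quotients of the contaminated sites drew
  on congener-level inputs not carried in the summary chemistry table;
  only the recomputable cells are asserted.
* The published global IBR values for the impacted areas (2.10, 2.72)
  come from per-individual data and an unstated star order; this
  package reproduces the reference value and all orderings, and
  documents its own conventions instead of chasing those two numbers.
* Delta-method CIs undercover mildly at very steep slopes or sparse
  dose placement; profile likelihood would be the upgrade path.
* IDW surfaces are convention-bound (power, grid); they are validated
  by exactness/boundedness properties, not against published rasters.
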