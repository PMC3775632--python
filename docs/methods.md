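# Methods

## Model

A bidirectional signature partitions a pathway's (or regulator's)
transcriptional program into an *activated* gene list $A$ and an
*inhibited* gene list $I$.  Given a per-gene signal vector $x$ — one
sample's expression values, or fold-changes between two conditions —
the signature's activity is scored by treating $\{x_g : g \in A\}$ and
$\{x_g : g \in I\}$ as replicate observations from two populations and
testing whether the first sits above the second.  The assumptions are
deliberately minimal: genes within a list are taken as exchangeable
observations (no network topology, no per-gene weights), and the test
statistic's sign carries direction (positive = activation).  This also
means correlated genes within a list are over-counted as independent
replicates — p-values are anti-conservative to the extent that
signature genes are co-regulated beyond the planted mean shift, which
is one reason the cohort modes re-test significance at the level of
per-sample scores rather than leaning on single-profile p-values.

## Test statistics

* **t (default)** — two-sample t, activated minus inhibited.  The
  default flavor is Welch (unequal variances, Welch–Satterthwaite
  degrees of freedom): the two lists usually differ in size and
  spread.  A pooled-variance flavor is available for comparability
  with classical implementations; every output header records which
  was used.  P-values are two-sided throughout; direction lives in the
  statistic's sign.
* **Mann–Whitney U** — reported as the normal-approximation z with
  midranks, tie-corrected variance, and a 0.5 continuity correction,
  signed so that positive = activation.  U itself is unsigned and
  scale-dependent; the z puts all three methods on one signed scale
  for box plots and ROC curves.
* **Kolmogorov–Smirnov** — D computed on an integer ECDF grid
  ($D = c/(n_1 n_2)$ with $c$ an integer, so no floating-point
  tolerance enters), signed by the direction of the median difference
  (falling back to the mean difference on a median tie, then 0).  The
  p-value is exact for tie-free samples with $n_1 n_2 < 10{,}000$,
  by lattice-path counting, and the classical Kolmogorov asymptotic
  $Q\!\left(\sqrt{n_1 n_2/(n_1+n_2)}\,D\right)$ otherwise.

**Degenerate inputs.**  If both sides have zero variance the t is
undefined: equal constants give statistic 0, p = 1; unequal constants
fall back to the Mann–Whitney z for both statistic and p, and the row
is flagged `degenerate_variance`.  No infinity ever reaches the
downstream ANOVA or ROC.

## Multiple testing

Across signatures, `bh` is the Benjamini–Hochberg step-up adjustment.
`storey` multiplies the BH values by an estimate of the null
proportion $\hat\pi_0$: the λ-grid estimator on λ = 0.05…0.95 (step
0.05), smoothed with a cubic polynomial and evaluated at λ = 0.95,
clipped to (0, 1].  Below 20 p-values the smoother is unstable and
$\hat\pi_0 = 1$ is used (Storey then coincides with BH).

## Cohort modes

In 2-D mode each sample column is scored independently (gene matching
resolved once per signature against the shared row index).  Group
structure is then assessed on the per-sample statistics:

* **ANOVA** — one-way fixed effects, requiring ≥ 2 groups with ≥ 2
  samples each.  With exactly two groups this equals a pooled t-test
  (F = t²) but is reported as ANOVA; the equality is itself a test in
  the suite.  Samples without a group label stay in the score matrix
  but are excluded from ANOVA and classification.
* **Box summaries** — five-number summaries with linear-interpolation
  (type 7) quartiles, the dominant convention in scientific plotting
  stacks; recorded in output metadata.  A group's box is colored red
  when its median statistic exceeds +2 and green below −2 — ±2 being
  the usual "roughly p < 0.05" landmark for a t statistic.
* **Classifier** — triggered when the label set is exactly
  {positive, negative} (any other binary labeling must be mapped
  explicitly; no guessing).  The ROC sweeps all thresholds with higher
  score ⇒ predicted positive (an `invert` flag serves
  inhibition-oriented signatures); AUC is the trapezoid area, which
  equals the tie-adjusted pair-counting probability — an identity the
  tests verify to 1e-12.  Threshold accuracy uses the strict rule
  score > cutoff, cutoff defaulting to 2.

## Signatures and their construction

Gene symbols are upper-cased so matching is case-insensitive (human
vs mouse symbol conventions).  A gene appearing on both sides of one
signature is removed from both, with a warning: the two lists must
form independent populations for the two-sample logic to hold.
Signature files round-trip losslessly in a native long format
(`name TAB UP|DOWN TAB gene,gene,...`) and in GMT, where `*_UP`/`*_DN`
(also `_DOWN`, and the GO-style "positive regulation"/"negative
regulation" phrases) are paired into one bidirectional signature and
unpaired sets are reported and dropped.

Construction from a differential-expression table keeps genes with
fold-change > threshold (activated) or < −threshold (inhibited) at
FDR < threshold, strict inequalities, defaults |FC| > 2, FDR < 0.05.
The consensus builder requires |FC| > 1.5 and p < 0.05 in *every*
input table with a consistent fold-change sign.  Two fold-change
dialects are auto-detected: signed linear values, or pure ratios
(down-regulation in (0,1), converted to −1/x).  Duplicate gene rows
keep the smallest p-value (probe collapse favoring the strongest
probe).  The ≥ 10 genes-per-side filter is applied at exact
boundaries.

## Input dialects

Signal tables are tab-delimited, first column gene symbols.  A second
header row is treated as group labels exactly when every data cell in
it is non-numeric — no magic keywords.  Mode resolves from shape:
1 data column → 1-D, several → 2-D, 2-D with labels
{positive, negative} → classifier.  Duplicate gene rows collapse by
mean (logged); non-finite values are dropped with counts logged; a
non-numeric cell is an error naming its row and column.  RPKM input
can be transformed as log2(RPKM + 0.1), the offset taming
low-coverage genes.

## Synthetic data

The generators plant known structure and return a truth record
sufficient to score every downstream stage.  Effects are expressed in
within-gene noise-SD units so power statements are dimensionless.
Profile scenarios: activation (A up by +effect, I down by −effect),
inhibition (mirrored), mixed (both lists up together — the trap case
where membership-only enrichment fires but the bidirectional statistic
correctly stays near zero), and null.  Cohorts share per-gene
baselines (SD 1.0) across samples so columns resemble correlated
expression profiles; positive samples carry the activation pattern.
Noise is Gaussian by default — chosen so the t statistic's analytic
expectations are checkable — with a standardized t(3) switch to
exercise the rank/ECDF methods under heavy tails.  What these
simulations do *not* emulate: gene–gene correlation beyond the shared
baseline, platform artifacts, count-distribution effects in RNA-Seq,
or annotation errors in real signatures; passing them shows the
machinery is calibrated and powered under its own assumptions, not
that any particular biological signature is valid.

Validation problem sizes (used by the test suite and
`scripts/acceptance.py`): null calibration with 25 genes per side over
10,000 replicates and 500 null cohorts for the AUC center; power and
the mixed trap with 50+50 genes at effect 2 over 500 replicates;
cohort recovery with 40+40 signature genes, 120 background genes,
10+10 samples at effect 1 over 200 replicates (accuracy at the +2
cutoff measured at effect 2 over 100).

## Numerical and design choices

* Statistics are computed from explicit formulas; scipy/statsmodels
  equivalents and base R (`t.test`, `wilcox.test`, `ks.test`, `aov`,
  `p.adjust`) serve as independent cross-checks in the tests
  (statistics to 1e-9, p-values to 1e-6).
* Ranks use midranks with tie-corrected variance; BH is the step-up
  running minimum, clipped to [0, 1].
* The KS exact p holds the path-counting bound in integers, so tied
  ECDF steps cannot flip the strict/non-strict boundary.
* KDE density plots use Silverman's rule; a constant-valued side gets
  a bandwidth floor (max of 1e-6 and one grid step) and renders as a
  narrow spike rather than crashing.
* Result tables carry a `#` metadata header (version, configuration,
  conventions such as t flavor and quartile type) and re-parse
  losslessly; identical configuration and input yield byte-identical
  TSVs.  The output prefix is excluded from the header so the same
  analysis written to two locations stays byte-comparable.
* Seeded streams derive from a root seed plus a CRC32-tagged purpose
  string, so scenario components are independent and reproducible
  across processes.

## Known limitations

* Within-list gene–gene correlation is not modeled; single-profile
  p-values are optimistic for tightly co-regulated signatures.
  The cohort-level ANOVA over per-sample scores is the recommended
  inference route, mirroring how the method is meant to be used.
* The KS asymptotic branch uses the classical Kolmogorov limit, which
  for moderate samples can differ from refined approximations by a
  few percent; the exact branch covers the regime where this matters
  most.
* Signatures require both sides to be non-empty (and, by default,
  ≥ 10 genes each): purely unidirectional gene sets are out of scope
  by design — a membership-style enrichment tool is the right
  instrument there.
* No permutation-based p-values, no network topology, no curated
  regulator database: the method's scope is exactly the two-list
  comparison.
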