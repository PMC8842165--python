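# Methods

## Scope and data model

`cftrscreen` implements the computational path of a pooled two-hybrid
interaction screen and its follow-up assays: read quantification,
candidate calling, artifact (frequent-flier) filtering, interactome
comparison, high-content siRNA traffic-screen scoring, and the
functional-assay statistics. Raw sequencing and imaging inputs are
represented by a synthetic-data module with explicit ground truth; the
statistical machinery is identical whether the inputs are simulated or
real.

## Read-to-ORF assignment

Reads are assigned by exact k-mer voting against the prey ORF reference
(default k = 31, a standard pseudo-alignment length at which random
31-mers essentially never collide between ORF-scale sequences). Each
k-mer unique to one ORF votes for it; a read is counted iff all its
unambiguous k-mers agree and at least one exists. Reads that are too
short, match nothing, carry only shared k-mers, or vote for two ORFs are
discarded and tallied, so `assigned + discarded = total` always holds.
Matching is forward-strand only by default: prey cassettes are amplified
with cassette-specific primers in a fixed orientation, so
reverse-complement lookup is an explicit opt-in rather than a default.
No mismatch tolerance is attempted — exact matching keeps the stage
deterministic and verifiable against a brute-force substring oracle, at
the cost of discarding reads with sequencing errors (the simulator emits
error-free reads, so recovery there is exact). CPM is counts × 10⁶ /
column library size; zero-library columns become zero with a warning.

## Candidate calling

An ORF is removed iff its count is below `min_count` (default 3) in
*every* replicate — i.e. kept when at least one replicate reaches the
threshold. The same per-replicate threshold defines "detected in" for
the replicate-overlap report. This literal reading makes the
dual-replicate overlap a strict subset of the candidate list, which is
what the reported overlap percentages (e.g. 209 of 224) require.
Percentages are rounded half-to-even at integer precision (one decimal
for the shared-of-union figure). Single-replicate tables are rejected
unless the caller passes an explicit flag.

## Frequent-flier detection (rank products)

Within each control screen, CPMs are ranked descending (rank 1 =
highest; ties get average ranks, which conserves rank sums). A prey's
rank product is the geometric mean of its per-screen ranks. The null is
generated by independently permuting each screen's rank column;
p(prey i) is the fraction of iterations in which the randomized rank
product *at position i* is ≤ the observed rank product of prey i. The
per-position comparison is the standard rank-product formulation and the
only reading that yields one p-value per prey; the ≤ comparison makes
the fully-tied degenerate case return p = 1 rather than 0. Division is
by the plain iteration count (no +1/+1 correction) by default, so a
Monte-Carlo p can be exactly 0; both the strict-inequality and the
add-one corrections are config toggles. P-values are BH-adjusted (via
`scipy.stats.false_discovery_control`) and preys at adjusted p ≤ α
(default 0.05) are flagged. α = 0 disables flagging outright, since
adjusted p = 0 is reachable. Zero-CPM preys receive (tied-last) ranks —
no imputation. Fewer than two control screens is rejected: the rank
product is a multi-screen consensus.

The permutation engine works on log-rank sums in chunked, vectorized
form (~1 s per 10,000 iterations at 1,000 preys × 9 screens) and is
validated against an exhaustive-enumeration oracle that iterates all
(n!)^s joint column permutations on tiny instances. Exact ties of log
sums across permutations are compared with a 10⁻⁹ tolerance because the
same multiset of floats summed in a different order can differ in the
last ulp.

## Interactome comparison

Plain set algebra after flier removal: shared, per-bait unique, union.
The edge list has one row per (bait, prey) with category shared /
a-only / b-only, sorted by (bait, prey) so re-export is byte-identical.
Note: 46 shared interactors over a 447-prey union is 10.3% at one
decimal; the package reports the computed value.

## Traffic-screen scoring

Images are rejected when they have fewer than 100 cells, a focus metric
below threshold, or negligible reporter expression. The
negligible-expression default is the 10th percentile of the
negative-control (siNeg1) wells' expression per plate/replicate; an
absolute threshold can be supplied instead (the per-cell exclusion used
upstream by the original imaging pipeline is modelled at image level
here). A well's value is the median of its valid image medians. The
Z-score references the median of the 5×5 window centred on the well
(truncated at plate edges, centre included; excluding the centre is a
toggle). The scale is the plate-level robust SD, 1.4826 × MAD of the
local residuals: a 25-well local MAD is noisy and frequently zero under
ties, so the plate-level estimator is the default, with
`neighborhood_mad` and `neg_control_sd` as alternatives. Zero scale
yields Z = 0. Negative-control wells set QC thresholds; centring is
spatial, not control-based. Per-siRNA scores are medians across valid
wells over all replicates, with the number of contributing replicates
reported; hits are Z > +1 / Z < −1, and gene calls are
enhancer/inhibitor/ambiguous/none depending on the directions in which
the gene's siRNAs pass.

The local-median reference removes smooth spatial trends exactly when
they are locally linear (the 5×5 median of a plane equals its centre for
interior wells) and approximately otherwise; it does not protect against
effects spatially clustered at the window scale, which would be absorbed
into the reference.

## Functional assays

- **FLIPR**: F₀ is the mean of all pre-agonist scans (≥4 by protocol);
  using only the last scan is a toggle. Maximum F/F₀ is the post-agonist,
  pre-inhibitor maximum over F₀. F₁/F₋inh is the last pre-inhibitor scan
  over the post-inhibitor minimum. Multiple read points per whole-well
  scan are averaged per scan on load. Both metrics are invariant under
  positive rescaling of the trace. Non-positive F₀ or F₋inh is an error.
- **Normalization and testing**: values are divided by the control-group
  mean (per-run control, not per-plate); conditions are compared with the
  control by a two-sided unpaired t-test, pooled-variance Student by
  default with a Welch toggle, starred at 0.05/0.01/0.001.
- **Swelling AUC**: trapezoidal integral of (relative area − 100) from
  t = 0 (stimulation) to 60 min; shrinkage contributes negatively; a
  series ending early integrates to its last point with a warning.
- **Ussing**: Ieq(t) = Vte(t)/Rte(t); in mV over Ω·cm² this is
  µA·cm⁻² after a factor 1000. The forskolin delta is the median
  post-forskolin Ieq (up to any inhibitor event) minus the median
  baseline Ieq, where the baseline window starts after the amiloride
  event when present (ENaC block); window edges are event-defined rather
  than fixed-width by default.
- **Western blot**: band intensities are divided by the lane's calnexin
  and expressed as fold change versus the mean of the baseline
  condition. A one-way ANOVA runs across conditions; pairwise
  comparisons versus baseline use Welch t-tests with BH adjustment.
  This substitutes for a Dunnett post hoc: Dunnett's multivariate-t
  quantiles are out of proportion to the role the comparison plays here,
  and the substitution is recorded in the output metadata
  (`tests.attrs["posthoc"]`). Conditions with a single sample are
  reported with p = NaN rather than tested.

## Synthetic-data generator

- **Screen counts** are negative-binomial (mean μ, size = `dispersion`;
  variance μ + μ²/size) — the standard overdispersed model for pooled
  sequencing counts, and the overdispersion is what makes the
  rank-product null non-trivial. Background preys have mean `base_mean`
  (default 2), a bait's true interactors `base_mean × enrichment_fold`
  (default 50×, modelling post-sort enrichment), fliers
  `base_mean × flier_fold` (default 100×) in every screen. Two technical
  replicates and nine control screens by default. Control screens also
  draw their own screen-specific enriched preys so they resemble real
  screens of unrelated baits. Reads are error-free forward-strand
  substrings at uniform offsets; sequencing error is out of scope by
  design (the assignment stage is exact-match).
- **Plates**: per-image value = B·g(r,c)·(1 + e·cv) + N(0, B·cv) with
  B = 1,000, cv = 0.05, and g a smooth gradient (default a plane with
  ±`gradient_amplitude`; sinusoidal optional). Effects `e` are therefore
  in units of the per-image noise SD; the well summary (median of 4
  images) has a smaller noise SD, so a +3 effect exceeds +3 well-level
  robust SDs — conservative for power checks. QC failures are injected
  at rate `qc_fail_rate`, uniformly over three modes (low cell count,
  out of focus, near-zero expression). Column 1 carries siNeg1;
  consecutive test wells pair into two siRNAs per gene.
- **Traces**: baseline (5 scans at 100 RFU), linear rise to
  baseline × (1 + amplitude) after the agonist event, linear decay to
  peak × (1 − drop) after the inhibitor event, plus optional Gaussian
  noise. Event times are explicit columns — the operator knows the
  addition times, so they are never inferred from the signal.
- The generators do **not** model FACS gating physics, transfection
  efficiency, PCR amplification bias (beyond the NB dispersion knob),
  cell segmentation, or plate-to-plate batch structure. Passing tests
  therefore demonstrate the correctness and calibration of the
  statistical machinery under the stated noise models, not performance
  on the full artifact spectrum of real screens.

## Problem sizes and numerical choices

Calibration checks run at 1,000 preys × 9 screens × 10,000 permutation
iterations (null uniformity, spike-in recovery over 20 seeds), ~67
plate simulations for ≥1,000 spiked wells at 4 replicates, and 10,000
null repeats for t-test calibration — sizes at which the Monte-Carlo
error of each check is well below its tolerance. The documented
production default for permutation p-values is 100,000 iterations.
Library sizes and dispersions of real screens are not published for
this workflow; both are free config parameters, with defaults chosen to
give realistic per-prey counts (a few reads background, hundreds for
enriched preys).

## Known limitations

- Exact matching discards error-containing reads; on real FASTQ data the
  assignment rate will be lower than the simulator's 100%.
- The rank-product permutation null treats screens as exchangeable
  columns; systematic library-composition differences between control
  screens are not modelled.
- The published adjusted-p cutoff that produced a specific flier count
  for the original dataset is not reported; α = 0.05 is the package
  default, exposed in config.
- The traffic-screen scale estimator and the centre-well window question
  are open choices in the original method description; both are config
  toggles with the defaults above.
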