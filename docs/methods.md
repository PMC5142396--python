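# Methods

## Occupancy model

Clone picking after library transformation is modelled as sampling with
replacement: each of *n* picks lands on library member *i* independently
with probability *w_i* (uniform 1/N by default). The recovery count of a
designated member is therefore Binomial(n, w_i), giving the multiplicity
pmf, the coverage probability `1 − (1 − 1/N)^n`, and — by linearity of
expectation under uniform weights — the expected multiplicity spectrum
`N · P(X = m)`. The model ignores finite-population effects on the colony
plate (a picked colony is not removed from the pool of genotypes, which is
what "with replacement" asserts) and treats transformation, plating and
picking bias only through the aggregate weight vector.

Two deliberately distinct quantities: `multiplicity_pmf` is a per-member
probability, while the *relative occurrence* reported from a sequenced
campaign divides the count of members seen exactly *m* times by the number
of picks *n*. They have different denominators; campaigns compare them only
heuristically, and the package never conflates them. At the study design
point (n = 66, N = 148) the binomial pmf rounds to 0.287 / 0.063 / 0.009 /
0.001 for m = 1..4; note that the Poisson(n/N) approximation differs in the
third decimal at m = 2 (0.064).

## Screening simulator

One campaign is *n* categorical draws from the weight vector. Replicate *i*
of a study uses the dedicated substream `default_rng([seed, i])`, so adding
replicates never perturbs earlier ones and any replicate can be regenerated
in isolation. Summaries report min/mean/max member counts per multiplicity;
the mean converges to the closed-form spectrum at the usual 1/√R rate.
Overdispersed member abundance (after pooled cloning) is modelled by a
symmetric Dirichlet weight draw with a single concentration knob; smaller
concentrations inflate repeat hits.

## Assay reduction

Traces are reduced by ordinary least squares of A410 on time. r² is defined
as 0 for a constant trace (no explainable variance). An optional
leading-lag trim drops initial points by maximizing r² over trailing
windows of ≥ 5 points; the default uses every point. The blanked slope is
converted with ε = 15 cm²/µmol and a path length d. The well path length is
a property of fill volume and geometry, not the instrument; the default
0.58 cm corresponds to 200 µL in a cylindrical approximation of a 96-well
plate, it is configurable, and every measurement records the d used.
Volumes default to 20 µL sample + 180 µL reagent. Non-positive blanked
slopes are reported as activity 0 with a `below_detection` flag, never as
negative activities, matching how activity tables floor at 0.0. U/mL equals
kU/L numerically (1 µmol·min⁻¹·mL⁻¹ = 1000 µmol·min⁻¹·L⁻¹); both unit
labels are accepted on input. Dilution factors are required inputs, never
inferred.

## Phenotyping

Replicates aggregate to the arithmetic mean and sample SD (n−1; 0 for a
single value). Relative activity is 100 × mean / max(mean) *within one
host's series*; normalization is idempotent and scale-invariant, and the
argmax row gets exactly 100.0. Ranking is descending by mean with
lexicographic tie-break. Repeated isolates of one SP are kept as separate
records (as screening tables list them), with an explicit collapse-by-mean
mode for cross-host pairing.

Classification against a reference panel uses interval overlap: entry
candidate iff `|activity − mean| ≤ k·s` with `s = sqrt(sd_panel² +
sd_clone²)` (quadrature combination; the two error sources are
independent). Default k = 2, chosen because at that width a well-separated
top secretor is a safe singleton call while strains ~1 combined SD apart
form ambiguity sets — the qualitative pattern of known-insert control
experiments. If no interval contains the clone, the nearest entry by
standardized distance is returned flagged `nearest_only`.
Distinguishability groups are the transitive closure of pairwise interval
overlap (`|m_i − m_j| ≤ k(sd_i + sd_j)`).

The packaged reference panel is *synthetic* (filename says so): the control
experiment it is shaped after prints no numeric panel values, so the panel
encodes only the qualitative geometry (top strain separated, two strains
overlapping, empty vector near zero).

## Cross-host comparison

Host series are paired per SP after collapse-by-mean (a per-clone mode
exists; which convention published scatter plots use is not stated).
Pearson is computed on the relative values, Spearman on mid-ranks, both via
scipy; zero-variance series yield an explicitly "undefined" summary rather
than NaN surprises. Concordance labels: discordant when floored relatives
differ by more than 4-fold (floor 2 percentage points keeps ratios finite
for SPs dead in one host), otherwise concordant_high if both ≥ 50%, else
concordant_low. These defaults reproduce the verbal labels of the motivating
campaign (YwfM discordant toward the actinobacterial host, Bpr concordant
high) without contradicting any printed number. Swapping hosts exchanges
the two discordant labels and fixes the concordant ones.

On the packaged table the collapsed pairing gives Pearson r ≈ 0.57,
Spearman ρ ≈ 0.63. Both are inflated by the ~26 SPs inactive in *both*
hosts (the lower-left corner of the scatter); among active SPs the
transfer is poor, as the 10 discordant labels show. No significance test is
attached: with 40 pairs the interesting claim is the effect size and the
discordant set, not a p-value.

## Synthetic campaigns

The generator emulates the study shape: N = 148 members, 66 picks,
replicate activities spanning ~0–13 U/mL. True activities come either from
resampling the packaged table's activity multiset ("fixture" mode — ties
occur, as repeated isolates do in reality) or LogNormal(µ = 1.08,
σ = 1.05), fitted once to the log of the positive fixture means. Replicate
noise is multiplicative Gaussian, `a(1 + N(0, cv))` truncated at 0
(default cv 0.15, within the CV range the fixture's ± columns imply), and
trace noise is additive Gaussian on absorbance. Picks reuse the simulator's
sampler and substream, so a generated campaign's multiplicity spectrum *is*
a simulator draw. Trace slopes are the exact algebraic inverse of the assay
conversion, so the zero-noise end-to-end identity (truth → traces → assay →
ranks) holds to machine precision.

What the generator does not emulate: growth curves and harvest triggering,
substrate depletion or product inhibition in the assay, plate position
effects, or mechanistic transformation bias (only the aggregate weight
vector). Passing tests therefore validate the campaign *arithmetic*, not
robustness to those real-world effects.

The top-rank recovery check (does the pipeline rank the truly best picked
SP first?) uses lognormal truths: the fixture multiset contains exact ties
and 0.1 U/mL near-ties at the top, which make "the best SP" ill-conditioned
as an oracle at replicate cv = 0.1. With distinct lognormal truths, 66
picks, 8 replicates and cv = 0.1, the measured recovery rate is ≈ 0.96–0.97
over 200 campaigns (exact true ties count as success).

## Numerical choices

* Comparisons to values printed at fixed precision round half away from
  zero to the printed number of decimals (`round_half_away`); Python's
  banker's rounding would mis-handle .5 boundaries.
* Library weights must be non-negative and unit-sum within 1e-9; pmf
  normalization and pick conservation are asserted at the same tolerance.
* `required_picks` uses the closed-form logarithm for a starting point and
  settles the integer boundary by direct evaluation, so the returned n is
  exactly minimal even when floats sit on the threshold.
* Degenerate inputs fail loudly: empty replicate lists, all-zero
  normalization series, traces with < 3 points or non-increasing times,
  unknown units, coverage targets ≥ 1.

## Problem sizes

Default analysis and test sizes are chosen to keep every run on a laptop
scale: 10⁴ replicate campaigns for simulation summaries, 10⁵ for the
Monte-Carlo frequency check (MC SE ≈ 0.0014 on a probability of 0.287), 200
campaigns for recovery rates, 100 seeded traces for assay round-trips.

## Known limitations

* The transcribed activity table lists 64 rows although the campaign
  sequenced 66 clones, and its multiplicity census (24/9/6/1) matches the
  published relative occurrences only at m = 2; the fixture ships as
  transcribed with this caveat attached rather than "repaired".
* Absolute means in the fixture are printed at one decimal; relative
  activities recomputed from them can deviate from the printed relative
  column by up to ~0.4 percentage points on rows whose unrounded means end
  near .x5.
* The occupancy model has no without-replacement (hypergeometric) variant;
  the with-replacement urn is the stated sampling picture.
* Classification offers only the interval-overlap rule; no ANOVA/Tukey
  battery is provided, matching screening practice where the decision is
  "sequence or not".
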