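# Methods

## Scope and data model

`xover` analyzes testcross genotype matrices: each progeny carries one
parental state per SNP marker, revealing a single gamete of an F1
meiosis. The coordinate backbone is a physical marker map (strictly
increasing bp positions per chromosome, ≥ 2 markers each); marker order
is taken from physical positions throughout — no multipoint re-ordering
is performed, appropriate when genetic and physical orders are known to
agree. All on-disk and in-memory interval coordinates are 0-based
half-open (BED convention); human-readable reports are 1-based
inclusive where stated.

## Crossover calling

After discarding individuals with any missing call (counts logged), a
crossover is recorded wherever two adjacent markers disagree within an
individual. The event is localized to its marker interval and given a
point position at the interval's physical midpoint — the unbiased point
choice given that two-state data localize exchanges only to intervals.
The count is minimal: an even number of exchanges inside one interval
is invisible, and an odd number ≥ 3 is recorded as one. Consequently
called ≤ true per gamete always, with equality once marker spacing
falls below the minimum true inter-crossover distance.

Per-marker 1:1 segregation is checked by χ² = (a−b)²/(a+b) on the two
state counts (1 df, missing excluded); distorted markers are flagged
and reported but not removed by default (removal is a CLI option),
since a well-behaved panel is expected to segregate 1:1.

Per-meiocyte rates double the per-gamete totals (each testcross progeny
is one of the two reciprocal meiotic products): mean = 2 · total / n.
The bundled published counts for twelve *Brassica* hybrid populations
reproduce their reported means under this arithmetic for ten of twelve
rows; for the remaining two (the single-C09 *B. oleracea* addition and
the *B. oleracea* allotriploid) the recomputed values are 21.6 and 29.0
against reported 21.8 and 29.1 — the package reports the recomputed
arithmetic and does not force the published cells. The related
"percent of variation explained" figure for the single C09 addition
computes to 51.7% here.

## Genetic maps and comparisons

Interval recombination fraction r = recombinants/n maps to
centimorgans by Kosambi, d = 25 ln((1+2r)/(1−2r)), defined on
0 ≤ r < 0.5; an interval at r ≥ 0.5 (possible in tiny samples) is
flagged, its distance reported undefined and excluded from totals with
a warning. Chromosome/genome lengths are sums of interval distances.

Between-population heterogeneity per interval is a 2×2 Pearson χ²
(1 df) without continuity correction, threshold 5% per interval. At
chromosome and genome scales a Bonferroni threshold of
0.05/(intervals at that scale) applies, and two populations are
declared different at a scale iff at least one interval is significant
at the corrected threshold. A single pooled genome-scale statistic
would be an alternative reading; the per-interval Bonferroni rule is
the default because it uses exactly the stated correction and divisor.
Letter groups (compact letter display) sort populations by total cM
descending and assign letters greedily so two populations share a
letter iff their comparison is non-significant.

Two regressions are provided: per-chromosome mean crossovers vs.
marker-covered Mbp (OLS; R² and p reported — for simple OLS the F-test
p equals the slope t-test p, so `scipy.stats.linregress` backs both),
and relative interval recombination rate (%) vs. relative distance to
the nearest centromere edge (%), with rates normalized to sum to 100%
per chromosome and distances scaled by arm length. A constant
predictor raises a degenerate-design error; a constant response
returns slope 0, R² = 0 by convention.

## KL divergence framework

KL(P, Q) = Σᵢ Pᵢ ln(Pᵢ/Qᵢ) in nats (natural-log plug-in), with
0·ln 0 := 0. An occupied-P bin facing an empty-Q bin is an explicit
infinite-divergence error, never a silent cap; an optional
0.5-per-bin pseudocount is available but off by default, since the
method as specified uses the raw plug-in.

**Landscapes.** Crossover point positions, as fractions of chromosome
physical length, are binned into 10 equal bins (bin k is
[k/10, (k+1)/10), the last bin closed; a crossover exactly on an edge
goes right). Pooling chromosomes concatenates relative positions.
P is compared to the flat landscape Q = 1/10:

* *flatness p-value* — every crossover is repositioned uniformly;
  10⁴ such randomizations (configurable) give the null KL
  distribution; p = (# null ≥ observed)/n. Uniform positions are drawn
  directly as uniform bin indices — an exact shortcut for a binned
  statistic.
* *ordering test* — per population, 10⁴ bootstrap resamples of
  individuals (each individual's full crossover set travels with it;
  zero-crossover resamples are redrawn and logged). Pairwise, the i-th
  replicates of the two independent streams are paired by index and
  the reversals of the observed ordering counted: raw p = k/B,
  Bonferroni-multiplied by the number of pairs performed, letters at
  adjusted 5%. Index-pairing of independent streams is a choice the
  procedure's description leaves open.
* *pairwise landscape KL* — KL(P_A, Q_B) between two observed
  landscapes (asymmetric; both directions can be reported), with a
  percentile CI (2.5/97.5%) from jointly resampling both populations.
  Replicates hitting an empty-Q bin are redrawn and counted. The CI of
  this plug-in statistic sits high relative to the point estimate
  (resampling adds noise on both sides), so it brackets the typical
  between-replicate divergence rather than the point value.

**Interference.** For each gamete × chromosome with ≥ 2 crossovers, the
distances between successive crossovers are computed in genetic units —
each event's cM position interpolates linearly to its interval midpoint
on the population's own Kosambi map — and normalized by chromosome
genetic length ("genetic" is the primary reading; relative-physical is
available for sensitivity analysis). Distances never span chromosomes;
pooling concatenates distance lists. The no-interference reference Q
pools the binned distances of 10⁴ shuffles, each shuffle permuting the
pooled per-chromosome position multiset over individuals with
per-individual counts fixed — the only shuffle variant that preserves
the landscape exactly (same multiset) while removing within-gamete
correlations. p = fraction of single shuffles S with
KL(P_S, Q) ≥ KL(P, Q). The bootstrap ordering of interference strength
recomputes both P and a shallower Q (default 100 shuffles) per
replicate — a full 10⁴ × 10⁴ nesting is computationally pointless, as
the replicate noise dominates — with a pseudocount on the shallow Q
since it can leave bins empty.

## Synthetic meiosis

The generator emulates the statistical structure of testcross data
with known truth:

* **Crossover number/interference** — stationary gamma renewal along
  the bivalent's genetic length: gaps i.i.d. Gamma(shape ν, mean 1/2
  Morgan), i.e. 2 crossovers per Morgan; ν = 1 is Poisson
  (no interference), larger ν spaces events more evenly. Stationarity
  via burn-in from −5 Morgans (bias < 10⁻⁶ for ν ≤ 20), avoiding the
  length-biased first-interval formula. No obligate-crossover rule is
  imposed: the analyses never condition on ≥ 1 crossover and the
  Poisson-limit checks require its absence.
* **Chromatid thinning** — each bivalent crossover is kept with
  probability 1/2 (one gamete carries two of four chromatids), in the
  Housworth–Stahl spirit: one interference parameter on the bivalent,
  dilution to the gamete by thinning.
* **Landscape** — a Marey warp given as piecewise-linear anchors
  (physical fraction → cumulative genetic fraction). Presets: "flat"
  (identity) and "distal" (anchors (0,0), (0.25,0.45), (0.5,0.5),
  (0.75,0.55), (1,1): 90% of the genetic length in the distal halves,
  a crossover-suppressed middle).
* **Genotyping** — founder state Bernoulli(1/2) per chromosome, state
  flips at each crossover, markers read off at their physical
  positions. No genotyping error, segregation distortion, or
  homeologous exchange is simulated; real data add those noise layers,
  so passing tests demonstrate correctness of the statistics, not
  robustness to assay artifacts.

Defaults mirror the emulated study where it states conditions:
populations of 100–450 gametes, 10 chromosomes, markers every ~1.5 Mbp
(16 intervals per 25 Mbp chromosome). Genetic length defaults to
1 Morgan per chromosome (≈ 2 crossovers per bivalent, the biological
norm); no quantitative interference strength is published for these
genotypes, so ν is a free test parameter, not a calibrated estimate.

## Numerical and experimental-design choices

* All randomized stages draw from named substreams of one user seed
  (`SeedSequence([seed, crc32(stage), …])`), so changing one stage's
  depth never perturbs another's draws, and every result is exactly
  reproducible under a fixed seed.
* Resampling loops are vectorized in blocks (≈ 512 replicates; 2·10⁶
  elements for shuffles) to bound memory at a few tens of MB.
* Marker density matters for the interference statistics. Called
  events sit at interval midpoints, so a shuffle can co-place two
  crossovers at one midpoint (distance 0) while called data never can,
  and same-interval double crossovers are invisible; at ~1.5 Mbp
  spacing this discretization inflates the nominal 5% rejection of the
  no-interference null to roughly 30%. The calibration and power
  experiments therefore use dense maps (200 intervals/chromosome),
  where the measured null rejection is ≈ 6%. Interference inference on
  sparse maps should be read as anti-conservative.
* The flatness calibration experiment uses marker grids whose interval
  count is a multiple of the bin count (40 intervals → 10 bins), so
  interval midpoints never straddle bin edges and the binned null is
  exactly multinomial-flat.
* Experiment sizes in the test suite and acceptance script (e.g. 200
  null populations of n = 200 at 10³ randomizations; 50 replicates of
  distal-vs-flat at n = 300; 30–50 replicates of ν = 8 vs ν = 1 at 10³
  shuffles) are chosen to make the binomial noise of the measured rates
  small against the asserted margins while keeping a laptop-scale run.

## Known limitations

* Two-state testcross genotypes only; no F2 three-state support, no
  imputation, no singleton smoothing.
* The minimal-count contract undercounts multiple exchanges within one
  interval; per-meiocyte means are therefore lower bounds at sparse
  marker spacing.
* No gamma-model maximum-likelihood estimate of interference strength
  and no coefficient of coincidence; the KL-to-shuffle-null statistic
  orders populations but its magnitude depends on sample size (it
  shrinks toward 0 as n grows under the null).
* Compact letter displays use a greedy insert-absorb assignment;
  for the 2–12 populations typical here it reproduces the pairwise
  significance relation exactly in all tested configurations.
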