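# Methods

`coalabc` re-creates, at desk scale and on fully synthetic data, the
demographic-inference workflow used to study the historical relationships
among four Indigenous Australian community samples — Tiwi (TIW), Galiwin'ku
(GAL), Titjikala (TIJ) and Yarrabah (YAR) — together with Highland Papua New
Guinea (PNG) and an African-like outgroup (OUT).  The real cohort is held
under restricted governance; nothing here touches it.  Instead, the package
simulates cohorts with the same statistical structure, computes the same
summary-statistic suite, and runs the same style of likelihood-free
inference, so that every step of the analysis is exercised and testable.

## The demographic model

A history is a rooted binary tree of population splits with
piecewise-constant diploid effective sizes, optional continuous migration
bands and admixture pulses.  Conventions:

- Time is continuous, in generations before present; "present" is the
  sampling time of all populations.  One generation defaults to 28.7 years
  (so that 1,636 generations is 47 ka); configurable.
- `N_e` is the diploid effective size; a pair of lineages within a
  population coalesces at rate `1/(2N_e)` per generation.
- Migration is parameterized backward in time: a band `(source → dest,
  rate m)` means a lineage currently in `dest` traces its ancestry to
  `source` with probability `m` per generation.  A pulse moves each lineage
  of the receiving population to the donor with the pulse proportion, at a
  single time.

Seven candidate topologies over the four Australian samples (PNG always the
first population to branch off, the outgroup at a fixed 3,000 generations)
are kept in a catalog.  Scenarios 4–6 place Tiwi as the outgroup to the
other Australian groups; scenarios 1–2 contain a (TIW,GAL) clade.  The
topologies of scenarios 3 and 7 are not pinned down by the primary analysis,
so the catalog defaults them to the remaining distinct rooted shapes
(Galiwin'ku-outgroup and Yarrabah-outgroup respectively) and makes all seven
strings configurable.

Split times and ancestral sizes are keyed by the sorted leaf set of the
clade they subtend (`T_TIJYAR`, `T_GALTIJYAR`, `T_AU`, `T_AUPNG`), which is
well defined for every topology in the catalog.

### Priors

| parameter | prior | rationale |
|---|---|---|
| `T_AUPNG` | uniform 800–3,000 gen | brackets ~23–86 ka; covers the inferred 27–64 ka interval |
| inner split times | uniform 0–parent (nested) | parent drawn first, child uniform below it: every draw is a valid tree without rejection loops |
| `NE_*` | log-uniform 500–30,000 | spans the inferred sizes (1,500–10,000) with an order of magnitude on either side |
| `M_PNG_*` | log-uniform 1e-6–1e-3 /gen | "limited" migration; upper end ≈ strong contact; includes the calibrated 2e-4 |
| `YAR_PULSE_PROP` | uniform 0–0.1 | includes the inferred 1.8% |
| `YAR_PULSE_TIME` | uniform 3–7 gen | the modelled window for recent contact |

When a prior draw produces an extremely young Yarrabah split (younger than
the pulse time), the pulse has no effect pathway and is omitted from the
built model rather than failing the draw.

### The calibrated scenario-4 fixture

The point calibration used throughout the tests encodes the best-supported
history: AU–PNG split at 1,636 generations, then Tiwi (1,207), Galiwin'ku
(1,069) and a Titjikala–Yarrabah split (897); ancestral Australia at
`N_e` 2,000 between the AU–PNG and Tiwi splits (≈12,000 years);
pre-reduction sizes 7,000 (TIW) and 10,000 (GAL) with a recent epoch
(200 generations ≈ 5,700 years) at 1,500 and 2,000; TIJ 2,000, YAR 10,000,
PNG 5,000.  Two elements are calibrated to qualitative findings rather than
printed numbers:

- **PNG contact bands.**  The shared-drift gradient (northern communities
  share strongly and significantly more drift with PNG than Titjikala)
  requires post-split gene flow.  The fixture uses 2e-4 /generation into
  TIW and GAL (≈20% cumulative PNG-derived lineage ancestry over their
  post-split history, consistent with the substantial Papuan ancestry
  fractions reported for those communities) and 5e-5 into YAR, whose recent
  contact is carried by the pulse (1.8%, 3–7 generations) instead.
- **Recent Galiwin'ku size.**  Only Tiwi's recent size (1,500) is printed;
  GAL's recent epoch is set to 2,000, within the reported recent range.

## Coalescent simulation

Simulation is delegated to msprime (the simulator the original analysis
used); genealogies are tskit tree sequences.  Loci are unlinked,
internally non-recombining, and double as the jackknife blocks.  Mutations
follow the infinite-sites model; continuous positions are floored onto a
1-based integer grid (collisions, ~1e-4 of sites, drop the later site).
Defaults: 100 loci × 100 kb at μ = 1.25e-8 /bp/gen (a human-typical rate).

Genealogies for the loci of one dataset come from a single msprime
replicate stream (an order of magnitude cheaper than one simulation call
per locus); per-locus mutation streams are derived from the dataset seed by
counter.  A dataset is exactly reproducible from its seed; individual loci
are not independently re-simulable, a trade we accept for throughput.

Pair coalescence times are read directly from the simulated trees
(`tskit.Tree.tmrca`), with per-locus pair subsampling to bound cost.

## Summary statistics

Allele frequencies are computed per site from called haplotypes; a site is
usable for a statistic when every involved population has ≥2 called
haplotypes.  With `p̂` the derived-allele frequency and
`h = p̂(1−p̂)·n/(n−1)`:

- `F2(A,B) = (p̂_A−p̂_B)² − h_A/n_A − h_B/n_B`
- `F3(C;A,B) = (p̂_C−p̂_A)(p̂_C−p̂_B) − h_C/n_C`
- `F4(A,B;C,D) = (p̂_A−p̂_B)(p̂_C−p̂_D)` (no bias term needed)

Estimates are means over usable sites; standard errors come from a
delete-one weighted block jackknife over loci (weights ∝ usable sites per
block, Busing-style variance), `Z = estimate/SE`.  `|Z| > 3` rejects
cladeness for `F4(O, PNG; X, Y)`; `Z < −3` flags admixture for
`F3(target; A, B)`.  Outgroup F3 is reported unnormalized; the ordering
analyses it feeds are normalization-invariant.

FST uses the Hudson-type ratio-of-sums estimator, optionally ascertained on
sites polymorphic in a chosen panel.  Tajima's D uses the standard
constants, restricted per population to sites at full call rate so that a
single sample size applies; S = 0 yields NaN, never 0.

Counting statistics: four mutually exclusive sharing classes from the
presence pattern of the derived allele across populations/continents; the
minor-allele-count spectrum in a fixed subsample of 5 diploids, minor
defined by pooled global frequency (ties resolve to the ancestral allele);
per-individual heterozygous-site counts with optional rescaling by the
individual's unmasked fraction; rare-allele sharing (global count ≤ 5) per
individual pair with optional rescaling by the pair's joint unmasked
fraction; nested discovery curves (1..n, averaged over replicates) and
novel-variant-by-continent curves after pre-sampling the other continents.

Under missing data, rarity for the sharing matrix is classified by the
call-rate-adjusted count (`count/called × total haplotypes`; identical to
the raw count on complete data).  The raw-count rule applied to a masked
dataset deflates counts and promotes common variants into the rare class,
which would make masked-then-rescaled sharing structurally biased relative
to unmasked truth.  For masked/unmasked comparisons at desk-scale sample
sizes a fixed variant set (`rare_sites=`) should additionally be supplied,
because conditioning on both members of a pair being called shifts the
adjusted count of exactly the variants they share.

### The ABC summary vector

One row per simulated dataset, fixed schema: all 10 outgroup-F3
`F3(O; A, B)`, all 30 `F4(O, A; B, C)` combinations over the five study
populations, the 2nd and 3rd central moments of each across blocks
(unweighted over per-locus values), and per-population Tajima's D, π and S
— 135 entries.  An undefined per-population D (S = 0, essentially never at
the default scale) is recorded as 0 to keep the schema dense.

## ABC inference

The reference table holds (scenario, prior draw, summary vector) rows; each
row's random stream is derived from (seed, scenario, row index), so tables
are reproducible and extendable chunk-wise.  Summaries are centered and
scaled by table median and MAD (robust to the heavy-tailed moment
summaries); zero-MAD dimensions are dropped with a warning.

Two model-choice engines share one posterior interface:

- **Rejection** (the transparent core): Euclidean distance in normalized
  summary space, keep the nearest `⌈tolerance·rows⌉` rows (default 0.5%),
  Epanechnikov weights; model probabilities are weighted acceptance
  fractions under equal 1/7 priors.  Exactly testable against a brute-force
  distance sort.
- **Random forest** (the route the original analysis used): a forest on the
  table's summaries augmented with linear-discriminant axes; the posterior
  is the class-probability vote for the observed vector.  Consistently the
  stronger engine here and the default for power experiments.

Group probabilities (defaults: scenarios 4–6, scenarios 1–2) are sums of
member probabilities; group Bayes factors are posterior odds divided by
prior odds.  Pairwise Bayes factors are probability ratios (equal priors).

Parameter posteriors come from the weighted accepted draws of one
scenario: weighted median (midpoint convention) and the shortest interval
holding 95% of the weighted mass (two-pointer scan over sorted draws).
An optional weighted local-linear regression adjustment on the normalized
summaries is available and off by default.

### Desk-scale configuration and what it can and cannot show

Reference-table rows and pseudo-observed datasets use 8/8/7/8/8 diploids
plus 4 outgroup diploids and 40 loci × 100 kb (≈4 Mb, ~6,000 SNVs) at
2,000 rows per scenario — against the original's 50,000 simulations and
chromosome-scale data.  The table builds in ≈12 minutes on one CPU;
the full-default 100-locus configuration would roughly triple that.

Parameter recovery at this scale is well behaved: the AU–PNG split time is
recovered with ≈15–20% median relative error and 95% HPD coverage at or
near 1 (the posterior is prior-dominated enough to be conservative, never
anti-conservative, in our experiments).

Model choice is a different matter.  The calibrated history's
topology-separating internal branches are short: 138 generations at
`N_e` 2,000 separate scenario 4 from the (TIW,GAL)-clade scenarios, 172
generations separate it from scenarios 5–6.  The corresponding expected F
contrasts (~1e-3) are of the same order as their desk-scale sampling noise
(σ ≈ 3e-3 at 40 loci, scaling as loci^-1/2), so no classifier can separate
the scenarios reliably from one 4 Mb dataset: the random-forest out-of-bag
recall for scenario-4 rows is ≈0.35 at 40 loci and barely improves (≈0.39)
at 120 loci, and calibrated-point top-rank rates are ≈0.26 (rejection) to
≈0.45 (forest) against a 1/7 chance level.  The forest does, however, shift
posterior mass toward the correct scenario (≈2× its prior) and toward the
correct group (scenarios 4–6), mirroring the original study's emphasis on
grouped evidence over a single topology.  Conclusions about
single-topology resolution at full scale cannot be drawn from desk-scale
runs; the reporting therefore includes the group-level posterior.

## Cohort emulation and masking

`emulate_cohort` simulates the calibrated scenario-4 history at the study's
sample sizes (34/17/7/31 Australian diploids, 25 PNG, small outgroup
panel), then applies ancestry-mask missingness: per-individual masked
fractions are Beta-distributed (means per population are order-of-magnitude
defaults — e.g. 0.12 for Yarrabah, 0.02–0.03 elsewhere — exposed in the
profile precisely because the empirical distribution is derivable only from
the restricted data).  Masked spans have exponential lengths (mean 5% of a
locus, emulating multi-megabase local-ancestry tracts at locus scale), are
placed uniformly without overlap via a stick-breaking construction that
hits the requested fraction exactly (±1 bp), and set both haplotypes of the
individual to missing — the diploid masking rule.  Individuals masked
above 95% are flagged (the original pipeline dropped such individuals).

What the emulation does *not* reproduce: real local-ancestry tract-length
distributions and their correlation along chromosomes, reference-panel
errors in ancestry assignment, sequencing/genotyping error, relatedness
within communities, and recombination within loci.  Passing tests show the
statistical machinery (masking footprint, rescaling, complete-case
handling) is correct, not that real masked data would behave identically.

## I/O

Datasets are exchanged as plain text: minimal VCF 4.2 (one contig per
locus, phased diploid GT, `.|.` for missing; unphased GT accepted on read,
phase ignored), a popmap TSV (sample, population, continent), and 4-column
BED mask tracks (contig, 0-based half-open interval, sample).  Reading
validates structure line-by-line first (column counts, 1-based positive
positions) so parse errors carry line numbers, then parses with cyvcf2.
A write/read round trip is bit-exact on genotypes, positions, labels and
masks.

## Numerical choices and degenerate inputs

- Global minor-allele ties (pooled frequency exactly 0.5) resolve to the
  ancestral allele code 0, deterministically.
- Jackknife SE of identical block values is 0 and the Z score is NaN
  (undefined marker), never infinite.
- The rCCR denominator needs ≥20 exposed pairs per bin (configurable);
  bins failing that are NaN.  Isotonic smoothing (non-decreasing toward the
  past) precedes crossing-time extraction; raw curves are retained.
  Crossing times interpolate linearly between the geometric bin midpoints
  of the first straddling pair, scanning oldest → youngest.
- Degenerate uniform priors (low = high) return the point value.
- HPD of a degenerate posterior collapses to a point and is flagged.

## Test and script problem sizes

The test suite runs entirely from seeds — no fixture files.  Closed-form
coalescent checks use 2,000–10,000 replicates; the F4 null uses 100
replicate datasets; the drift gradient 50 replicates of 600 loci; rCCR
calibration 10 replicate curves of ≥15,000 pairs; the ABC experiments share
one 2,000-rows-per-scenario table.  `scripts/acceptance.py` recomputes the same
quantities at reduced sizes (500-row tables, 20–60 replicates) to fit a
single short run, and reports each with the problem size used.
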