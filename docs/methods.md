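# Methods

## Scope and data model

The package operates on phased tetrad tables: each spore carries a vector of
parental-origin calls (`P`/`M`, `-` for missing) over an ordered marker map.
It does not infer phase from sequencing, model octads/dyads, or perform
image analysis; gel modules start from background-corrected densitometry
numbers.

An interval is any ordered pair of loci on one chromosome (identity is the
pair in map order; non-adjacent pairs are allowed). Per-chromatid breakpoint
counting, by contrast, always walks adjacent loci in map order.

## Scoring policy

Interval tallies admit only tetrads that are four-spore viable, fully called
at both interval loci, and 2:2 at both. The strict default additionally
excludes tetrads showing gene conversion (3:1, 1:3, 4:0, 0:4) at *any* other
fully-called locus; `RELAXED_POLICY` confines the conversion check to the
interval loci themselves. The strict default mirrors the usual definition of
a clean four-spore-viable mapping dataset while the relaxed flag supports
sensitivity checks; loci that cannot be assessed (missing calls elsewhere)
never disqualify a tetrad on their own. Unscorable tetrads are counted
separately so that tallies always conserve the input
(`PD + TT + NPD + unscorable = n_input`).

## Estimators and tests

**Perkins distance.** `cM = 100 (TT/2 + 3 NPD)/n`. The SE treats each tetrad
as an i.i.d. score x ∈ {0, ½, 3}: `se = 100 · sd(x)/√n` with the sample
(n−1) variance. The underlying no-chromatid-interference assumption is the
same one the simulator implements.

**Papazian expectation and NPD ratio.**
`E[fNPD] = ½(1 − fTT − (1 − 3fTT/2)^{2/3})`, undefined for fTT > 2/3 (the
inner base turns negative; at exactly 2/3 the expectation is 1/6). The ratio
NPD_obs/NPD_exp is reported "n.d." with a low-NPD flag when no NPDs were
observed — at low NPD counts the statistic is not robust. Two SE
propagations are exposed: the default Poisson form `√NPD_obs / NPD_exp`
(expectation held fixed) and a delta-method variant that adds the sampling
variance of fTT through the formula's derivative. Published tables of this
kind are consistent with the Poisson form in some rows but not all, so
neither is treated as canonical.

**Adjacent-interval interference ratio.** Partition by the reference
interval's class (PD vs TT ∪ NPD), map the test interval in each partition,
and form `ratio = cM_REC / cM_PD`. Positive interference is *called* only
when three conditions hold at level alpha (default 0.05, two-tailed): the
chi-square test on the two partitions' (PD, TT, NPD) distributions rejects,
the normal test on the map-distance difference
(`z = Δ cM / √(se₁² + se₂²)`) rejects, and the ratio is below 1. Empty
partitions yield an explicitly diagnosed undefined result.

**Chi-square layout.** The 2×3 table is collapsed to 2×2 by pooling NPD into
TT whenever any expected NPD cell is below 5 (NPDs are rare and the test is
unreliable on sparse cells); Pearson statistic without continuity
correction; all-zero columns are dropped and a table with fewer than two
informative columns raises a degenerate-table error.

**Random-spore distance.** `cM = 100 r/t` with the binomial SE
`100 √((r/t)(1 − r/t)/t)` (interpreting the conventional printed SE formula
as including the square root).

**Rounding.** Map distances to 1 decimal, ratios to 2 decimals,
percent-of-reference to the nearest integer, all half-away-from-zero and
applied only in reporting functions (`report_cm`, `report_ratio`,
`report_percent`) and output writers, never internally.

## Simulator

**Crossover placement.** Events on each bivalent follow a stationary gamma
renewal process on the genetic scale with rate 2 events/Morgan — so the
expected recombinant-chromatid fraction per Morgan is 1, matching the map
definition, since each event involves two of four chromatids. Inter-event
distances are Gamma(ν, scale = 1/(2ν)); the interference shape ν is the
tunable strength (ν = 1 is exactly a homogeneous Poisson process; larger ν
under-disperses event counts and suppresses nearby doubles). The first event
is drawn from the equilibrium forward-recurrence distribution,
`F_e(t) = 2t·S(t) + F_{ν+1}(t)` (S and F gamma survival/CDF at the same
scale), sampled by inverse transform on a cached 4096-point grid, so the
process is stationary and the event rate is exactly 2/Morgan for every
shape. `obligate_crossover` rejection-samples until a chromosome has at
least one event. Chromosome length is taken as the span of its markers.

**Chromatid choice and genotype propagation.** Each event picks one
chromatid per homolog uniformly and independently (no chromatid
interference — the assumption beneath both the Perkins correction and the
Papazian expectation). A spore chromatid is the path from a centromere
through the crossover junctions, so the genotype at a locus composes the
junction transpositions proximal to it *in path order*; the implementation
realizes this by applying distal exchanges first. The ordering matters: the
naive proximal-first segment swap composes the transpositions backwards and
induces a spurious dependence of an interval's class on crossovers outside
it, which a Poisson-cohort independence check catches immediately.

**Analytic oracle.** For an interval of x Morgans under ν = 1, the class
probabilities are computed exactly: the event count is Poisson(2x) and,
conditional on k events, the class follows the Markov chain over
{PD, TT, NPD} with uniform non-sister chromatid choice
(PD→TT always; TT→PD/TT/NPD with ¼/½/¼; NPD→TT always), summed over k to
convergence (Poisson tail below 1e-15, renormalized). This reproduces
`P_TT = (2/3)(1 − e^{−3x})` and is consistent with the Papazian expectation
to machine precision, which the test suite asserts at 1e-9.
`expected_perkins_cm(x)` gives the estimator's exact expectation, including
its small downward bias from triple-and-higher crossover classes — parameter
-recovery tests compare against this, not against 100x.

**Gene conversion.** Applied after crossover placement, independently per
locus with probability `conversion_rate` per meiosis: one uniformly chosen
chromatid's call is flipped, producing 3:1 or 1:3 segregation. Conversion
tracts (co-conversion of neighbours) are out of scope.

**Viability.** Two layered processes: independent random spore death with
probability `p_random_spore_death`, and, for each chromosome with zero
crossovers, meiosis-I nondisjunction with probability
`p_nondisjunction_if_no_crossover`. The default `mi_lethal` mode marks all
four spores dead (two disomic, two nullisomic — a 0-sv outcome); the milder
`nullisomic_only` mode kills only the randomly oriented pole pair receiving
zero copies (a 2-sv outcome). This viability model is a synthetic stand-in:
the biology links spore death to crossover-less chromosomes, but no
quantitative model is established, so recovery tests treat these parameters
as generating knobs only. Dead spores are written with all calls missing.

**Determinism.** One seeded `numpy` generator per cohort; the draw order is
fixed (per chromosome: placement, then per-event chromatid choices; then
conversion per locus; then viability), and the truth sidecar serializes the
parameters, seed and every realized event, so identical (params, seed) give
byte-identical outputs.

**What the simulator does and does not emulate.** It reproduces the
statistical structure the tetrad statistics consume — interval class
frequencies, interference via event spacing, conversion as isolated non-2:2
loci, viability classes. It does not model DSBs or molecular intermediates,
crossover homeostasis, chromatid interference, centromere effects, conversion
tracts, or marker-specific genotyping error; passing tests therefore
validate the estimators under the stated model assumptions, not the full
complexity of real meiotic data.

## Problem sizes in the test suite

Distributional checks run at cohort sizes chosen to make 3·Monte-Carlo-SE
bounds decisive: 20,000 tetrads for class-frequency calibration (intervals
of 0.05–0.4 Morgans), 50 seeds × 5,000 tetrads per condition for
interference detection power and false-call rate (adjacent 0.2-Morgan
intervals, shapes 10 and 1), and 40×500 / 24×5,000 / 4×50,000 tetrads for
estimator recovery, where the 2% mean-accuracy bound is asserted at the
sizes whose sampling floor is below 2%.

## Known limitations

* Perkins SEs assume independent tetrads; partition SEs in the
  adjacent-interval analysis ignore the (weak) dependence induced by
  conditioning on the reference class.
* The Papazian expectation is undefined above fTT = 2/3; cohorts near
  saturation should be mapped with more closely spaced markers instead.
* The delta-method NPD-ratio SE treats fTT and NPD_obs as independent,
  which overstates variance slightly for small n.
* Map-function conversion (Haldane/Kosambi) and gamma-shape *estimation*
  from data are deliberately absent; the simulator's shape parameter is a
  generative control, not a fitted quantity.
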