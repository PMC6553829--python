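# Methods

## Model and assumptions

The framework is the classical deterministic single-locus multi-allele
viability model: an effectively infinite diploid population, random mating,
discrete non-overlapping generations, Hardy–Weinberg genotype frequencies at
birth, and selection through genotype viability alone. Fitness is
interpreted as the effectiveness of pathogen recognition: 0 = not viable,
1 = protected against everything. There is no mutation, no drift, no
invasion dynamics — the model asks only which subset of an initial allele
pool a fitness matrix can maintain, and at what proportions.

Allele proportions evolve as `p_i' = p_i (F p)_i / (pᵀ F p)` for a symmetric
fitness matrix `F`. Population mean fitness is nondecreasing along these
trajectories, and at a stable polymorphic equilibrium the marginal fitnesses
of all surviving alleles are equal. The equilibrium solver exploits this:
solve `F x = 1`, drop every allele with `x_i ≤ 0`, repeat on the reduced
matrix until all entries are positive, then normalize. When the final
principal submatrix is nonsingular this equilibrium is unique and globally
attracting from interior states, which is why a (numerically) singular final
submatrix is reported as `status="singular"` and treated by the sweep as a
discard-and-redraw event.

## Fitness models

With intrinsic merits `w_i` (homozygote fitness, the diagonal of `F`):

* symmetric overdominance `f_ij = 1 (i≠j)` retains all alleles forever and
  serves only as a limiting case in tests;
* AO `f_ij = w_i + w_j − w_i w_j` — the subtracted product is the *expected*
  recognition overlap of two independent alleles. Persistence of all `k`
  alleles is equivalent to `min w_i > ((k−1)/k)·ŵ` with `ŵ` the harmonic
  mean; the AO survivor set is always the top interval of merits above a
  cutoff;
* DAA `f_ij = |P_i ∪ P_j| / lS` over binary recognition patterns — AO's
  discount replaced by the realized overlap `|P_i ∩ P_j| / lS`. For random
  patterns the expected DAA heterozygote fitness equals the AO value, so AO
  is the mean-field limit of DAA; the models differ through the variance and
  correlation structure of the realized overlaps.

Patterns are stored as boolean vectors so unions/intersections are
elementwise; pairwise intersection counts are computed as a single-precision
matrix product (exact below 2^24, far above any `lS` used here).

## Numerical choices

* Linear solves use an LU factorization; singularity is declared when the
  1-norm reciprocal condition number falls below `sqrt(eps) ≈ 1.5e-8`,
  a robust floating-point proxy for "determinant zero". An exactly singular
  intermediate submatrix (zero pivot) is likewise reported singular.
* Elimination removes *all* nonpositive-`x` alleles per round; one-at-a-time
  removal is available as a flag for sensitivity checks. A cycle guard
  returns `status="degenerate"` if a survivor set recurs (never observed).
* The time-stepping validator declares convergence when the marginal-fitness
  spread of alleles above the extinction-prune threshold (default `1e-12`)
  falls below `1e-11`; at that tolerance it reproduces the linear-solve
  equilibria to ~11 decimals and is used as an independent oracle in tests.
* Merits are quantized to the pattern grid (`m_i = round(lS·w_i)`,
  round-half-to-even; floor/ceil available as options) and **both** models
  are built from the quantized merits `m_i/lS`, so paired AO/DAA comparisons
  see identical inputs and merit-range ties can be decided by exact
  equality. Quantization error is at most `1/(2·lS)`.

## Scenario generation

A scenario is `(w_min, w_max, n_ini, f)`. The pattern length is the smallest
`lS` with at least `f·n_ini` representable merits in the range:
`lS = ceil(f·n_ini / (w_max − w_min))`. Merits are kept inside the open
range by the margin `ε = (w_max − w_min)/(2·n_ini)`: Random draws uniformly
on `[w_min+ε, w_max−ε]`, Fixed uses `n_ini` evenly spaced values on the same
closed interval (scenario 62: 0.005, 0.015, …, 0.995). Each allele's pattern
is a uniform random `m_i`-subset of the `lS` positions. Every repeat derives
its generator from a `SeedSequence` of (base seed, scenario, experiment,
repeat, redraw attempt), so results are bitwise reproducible and independent
of execution order.

The generator emulates the abstract epitope-set picture only: sites are
exchangeable and alleles are drawn independently. Real MHC data have linkage
between sites, phylogenetic correlation between alleles, and mutation —
none of which is modeled, so passing tests demonstrate properties of the
selection mechanism, not predictions for any particular locus.

## Metrics

At each stable equilibrium: number of survivors `n_equil`; merit range
`r_equil` (max − min quantized merit among survivors); overdominance
`h̄ = (w̄_het − w̄_hom)/w̄_hom`, with class means weighted by Hardy–Weinberg
genotype frequencies renormalized within the heterozygote and homozygote
classes (plain unweighted class means available via a flag — which weighting
the comparison should use is a genuinely open choice; weighted is the
default because the statistic is defined "at equilibrium"); per-allele
`h_i = (w_het,i − w_ii)/w_ii` with partner-frequency weights; recognition
overlap `g_ij = |P_i ∩ P_j|/lS`, per-allele average
`g_i = Σ_{j≠i} p_j g_ij / (1−p_i)` (the self-pair is excluded — the
`1/(1−p_i)` factor is exactly the renormalization of the partner weights),
and the population-weighted mean `ḡ = Σ p_i g_i`. A single-survivor
equilibrium has no heterozygotes, so `h̄` and `g_i` are NaN there.

## Experiments and aggregation

The sweep crosses 80 scenarios with a paired design: per repeat one allele
set is generated and both models are solved on it. Repeat schedules follow
the published counts (10,000 / 10,000 / 2,000 / 500 / 100 repeats for
n_ini = 50…1000; a reduced overlap schedule is also provided), scalable by a
global factor. Singular draws are redrawn — whole allele set in Random,
patterns only in Fixed (Fixed merits are deterministic) — with the redraw
count logged; more than 50 consecutive failures aborts the repeat with a
diagnostic (never observed in practice).

Per-scenario aggregates report means and maxima of `n_equil` and `r_equil`
per model, the fractions of repeats in which DAA's range (and count) exceeds /
trails / ties AO's, and overlap summaries (mean ḡ, mean minimum `g_i`,
1/2/5/10% percentiles). Pooled fractions are reported both as the unweighted
mean of per-scenario fractions (primary — repeat counts differ per scenario)
and as raw iteration pooling, since either reading of a cross-scenario
summary is defensible.

## Desk-scale defaults

The packaged default sweep (used by `scripts/acceptance.py` and the
acceptance tests) runs all 80 scenarios of both experiments at 1% of the
full repeat schedule with a floor of 3 repeats per scenario — about 3,500
paired repeats per experiment. The floor exists because the n_ini = 1000
scenarios would otherwise contribute single-repeat indicator variables to
the pooled fraction; three repeats keeps the pooled sampling error near two
percentage points. At this scale a full two-experiment reproduction takes on
the order of ten minutes on one core; the largest single cost is the
pattern-product for scenarios with `lS = 10^5` and 1000 alleles.

## Known limitations

* Only viability selection in an infinite population: no drift, so
  "vanishing" alleles reach zero only asymptotically; finite-population
  behavior is out of scope (the experiment layer is the natural hook point
  for a Wright–Fisher wrapper).
* When the final submatrix is singular, multiple or boundary equilibria may
  exist; the package reports the discard signal rather than attempting an
  eigenanalysis.
* Random fitness matrices can possess several stable boundary equilibria,
  in which case the elimination procedure and the time-stepping dynamics may
  settle on different (occasionally even invadable) survivor sets of nearly
  equal population fitness. The solver deliberately reports the procedure's
  answer — the `eliminations` log makes the path auditable — and the
  oracle-equivalence tests fall back to checking that the dynamics reach at
  least the procedure's population fitness when the sets differ.
* "Sites" are exchangeable abstract epitope sets; no sequence, binding
  affinity, or pathogen dynamics.
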