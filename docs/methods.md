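# Methods

This note documents the models and algorithms implemented in
`aroidnet`, the choices made where the design was genuinely open, and
what the test suite does and does not establish.

## Data model

An `InteractionWeb` is a non-negative integer matrix of insects (rows)
by host plants (columns); cell a_ij counts individuals of insect i
reared from host j, with grand total m, row totals k_i and column
totals d_j. Insects are placed on rows because every species-level
metric here (d′, hub scores, niche overlap) is phrased from the
consumer side. A `RecordTable` holds long-format per-sampling-unit
records (host, elevation, unit, species, count); one infructescence is
one sampling unit, and aggregating records over units reproduces a web
exactly.

## Reconstruction of the survey web

The survey publishes, for each host, the percentage of its individuals
contributed by each insect species (two decimals), plus exact
per-species totals and the grand total of 16,120. The integer matrix
behind that presentation is recovered in two steps:

1. **Host totals.** Solve min_c ‖P c/100 − t‖² subject to c ≥ 0 and
   Σc = 16,120, where P is the percentage matrix and t the species
   totals. The equality constraint is enforced by a heavily weighted
   penalty row inside a non-negative least-squares solve, followed by
   an exact rescaling. The system is strongly over-determined (34
   equations, 8 unknowns) and well-posed here because every host has
   at least one "signature" species found nowhere else; for webs with
   proportionally identical columns the column totals are not
   identifiable and no solver could recover them.
2. **Integer rounding.** Each species row is rounded by largest
   remainder so its sum equals the exact printed total; support is
   restricted to cells with positive percentage. Row totals are exact
   by construction; host totals absorb the rounding slack (< 1 per
   host). Before rounding, the worst per-species residual on the
   survey table is under 2 individuals; reconstruction aborts with a
   residual report when any residual exceeds `max_abs_residual`
   (default 5 individuals — loose enough for two-decimal rounding
   noise on totals of this magnitude, tight enough to reject
   inconsistent tables).

The printed sampling-effort and IFA tables disagree slightly on
per-host infructescence counts (77 vs 73 for *D. oerstedii*, 19 vs 9
for *R. wendlandii*). Each fixture reproduces its own table verbatim;
IFA reproduction uses the IFA table's denominators, and no
reconciliation is attempted.

## Specialization (H2′, d′)

H2 = −Σ p_ij ln p_ij with p_ij = a_ij/m (all entropies in nats).
H2′ = (H2max − H2)/(H2max − H2min), where the extremes are over integer
tables with the observed marginals. Exact integer extremes are a hard
combinatorial problem; we compute them as the best of several
principled fills:

- **Minimum (concentration):** greedy assignment of
  min(remaining row, remaining column) to the pair of largest
  remaining marginals, plus a variant that first consumes exactly
  equal row/column marginals into single saturated cells.
- **Maximum (evenness):** floors of the proportional expectation
  k_i d_j/m with remaining units distributed either toward the largest
  expectation deficit or by water-filling (smallest current count
  first), each refined by greedy 2×2 cycle moves (marginal-preserving
  unit transfers) until no move increases entropy.

On every instance small enough to enumerate exhaustively (all 2×2
margins with m ≤ 12, all 3×2 and 3×3 families tested, ~3,000 margin
sets) these fills attain the true extremes; for larger webs they are
heuristics, as in the standard implementations of this index. H2′ is
clipped to [0, 1] and defined as 0 when H2max = H2min.

d_i = Σ_j p′_ij ln(p′_ij/q_j) with p′_ij = a_ij/A_i and q_j = d_j/m.
d_max packs A_i into the rarest resources first, capped by the column
marginals; d_min is the closest-to-proportional integer allocation;
ties break by column order so results are reproducible.
d′ = (d − d_min)/(d_max − d_min), clipped to [0, 1].

## Niche overlap

The survey names only "NO"; we fix it to Morisita–Horn similarity,
C = 2Σx_i y_i / [(Σx_i²/X² + Σy_i²/Y²) X Y], averaged (unweighted) over
all unordered pairs of insect rows — the default abundance-based
overlap of the standard network software. Pairs are never excluded:
every insect in a trimmed web has positive total. This choice
reproduces the printed full-network value (0.21).

## Modularity

Barber's bipartite Q is maximized by weighted label propagation:
rows start in singleton modules, columns then rows repeatedly adopt
the label with the largest summed null-corrected weight
(B = A − k dᵀ/m), ties to the lowest module id, sweeps in index order;
converged partitions are refined by the single best Q-increasing
module merge, and propagation and merging alternate until Q stops
improving. Propagation is monotone in Q, so termination is guaranteed.
The restart wrapper mixes the deterministic singleton start,
uniform-random row labelings, and coarse starts with c = 2…min(dims)
initial modules, keeping the best Q; all randomness flows from one
seed. On small random webs (≤ 4+5 nodes, m ≤ 12) the wrapper with 20
restarts always matched brute-force enumeration over all joint
partitions. On the reconstructed survey web it finds Q ≈ 0.535 with 6
modules, against a printed 0.523 — within the tolerance expected from
two-decimal percentage rounding and optimizer differences.

## Null models

The Patefield algorithm draws tables from the fixed-margins
(multivariate hypergeometric) law by filling cells row by row, each
cell a hypergeometric draw conditioned on the remaining marginals.
Ensembles default to n = 100 draws; Z = (obs − mean)/sd with the
"highly significant" flag at |Z| ≥ 2, and the empirical p-value uses
(1 + b)/(1 + n) so p is never 0 at n = 100. A statistic conserved by
the marginals (e.g. m itself) yields a flagged undefined Z rather than
an exception. Both Z and p are reported because the survey states the
Z ≥ 2 rule but annotates tables with p < 0.05; we do not assert which
generated its asterisks.

## Diversity

Jackknife-1 over sampling units: S_jack1 = S_obs + Q1(m−1)/m with Q1
the species found in exactly one unit; completeness = 100·S_obs/S_jack1.
The phrase "jackknife based on abundance" is ambiguous, so the
abundance variant (Q1 = species with exactly one individual) is
available via `variant="abundance"`; neither variant is asserted to
reproduce the printed 43.3 expected species, which cannot be checked
without the raw records. Accumulation curves average cumulative
richness over seeded random unit orderings.

Bray–Curtis decomposition follows Baselga: with A = Σ min(x_i, y_i),
B = Σx − A, C = Σy − A: d_BC = (B+C)/(2A+B+C),
balanced = min(B,C)/(A+min(B,C)), gradient = d_BC − balanced; the
multi-site form replaces A, B, C by sums over all site pairs.
Additivity holds to 10⁻¹² by construction.

## IFA and guild testing

IFA = rf·ra·100. With raw records, rf and ra come from exact unit and
individual counts. For reproducing the printed scores, rf is taken
from the printed table and ra from the printed percentages/100; the
recomputed values agree with the printed ones to ≤ 0.06, consistent
with two-decimal input rounding (the printed values were evidently
computed from unrounded inputs).

G = 2Σ O ln(O/E) on the guild × host table, Williams correction
q = 1 + (NΣ1/R_i − 1)(NΣ1/C_j − 1)/(6N(r−1)(c−1)), p from the
chi-square upper tail of G/q at df = (r−1)(c−1). Zero cells contribute
nothing; zero marginals are rejected rather than silently collapsed.
The guild map follows the species-level table (22 phytophages, 8 mixed,
2 saprophages, 2 mycetophages), which is the only assignment consistent
with 34 species.

## Synthetic surveys

The generator emulates the survey design: hosts × elevations sampling
units, a dominance-skewed species-abundance distribution, planted
insect/host blocks, and elevational turnover.

- **Dominance** uses deterministic lognormal quantiles assigned to
  species in a seeded shuffle, so the shape of the rank-abundance
  curve is a property of σ, not of the seed. The default σ = 2.0 makes
  the four most abundant species hold roughly three quarters of the
  individuals, the dominance regime of the survey (74.5%).
- **Block structure:** each insect spends probability κ inside its
  planted host block, 1 − κ spread uniformly outside; κ = 1 yields a
  block-diagonal web whose optimal Q is 1 − Σ f_b² (f_b the block mass
  fractions), and recovered Q and H2′ increase monotonically with κ.
- **Turnover:** species are laid out along the gradient and each
  stratum sees a window shifted by τ window-widths per step: τ = 0
  gives identical pools, τ = 1 disjoint adjacent pools (pure balanced
  dissimilarity). Richness loss with elevation arises from the
  declining unit counts (123/94/33 in the reference configuration).
- Individuals are allocated by one multinomial over
  (species, host, stratum) cells weighted by abundance × preference ×
  sampling effort, then split across units by symmetric multinomials;
  everything is reproducible from the configuration seed.

The generator does **not** emulate phenology, within-infructescence
tissue partitioning, spatial autocorrelation of units, or
detection/rearing failure. Passing tests on synthetic data therefore
establish estimator correctness under the stated sampling model, not
robustness to those field realities.

## Pipeline and reproducibility

`run_full_analysis` expands one global seed into fixed per-stage seeds
via `SeedSequence.spawn` under a fixed key order, so adding a stage
never changes earlier stages' draws; reports are deterministic given
(input, seed, settings). Null ensembles inside the pipeline use a
light 3-restart schedule for the modularity statistic to keep 100
draws inexpensive; the headline Q always uses the full restart budget.

## Problem sizes used in the test suite

Enumeration-backed checks run on all 2×2 margin families with m ≤ 12
plus 3×2/3×3 families with m ≤ 7 (and known hard regression cases);
Patefield law checks use 10⁴ draws on enumerable margins; the
concentration-monotonicity check averages 20 seeds per κ on
12-insect × 6-host communities of 800 individuals. These sizes were
chosen to make the brute-force oracles exact while keeping the suite
quick to run.

## Known limitations

- The H2 extremes and d′ extremes are exact only where enumeration
  confirms them; for large margins they are best-of-heuristics, so H2′
  could in principle be slightly mis-standardized (any error shrinks
  H2′'s denominator contributions equally in practice).
- Label propagation is a local optimizer; global optimality is only
  guaranteed where brute force verified it.
- The reconstructed survey web is exact in its row sums but carries
  ±rounding uncertainty in individual cells; all survey-level results
  quote tolerances that absorb it.
- The elevation-stratified webs of the original survey are not
  reproducible from printed data and are deliberately out of scope.
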