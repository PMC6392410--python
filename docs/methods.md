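# Methods

## The network and its construction

The unit of observation is a species-level visitation record: one
hummingbird species seen taking nectar at one plant species, flagged by
whether the plant is native to the New World. Records are aggregated into a
*qualitative* (binary) matrix of plant families (rows) by hummingbird clades
(columns): a single record anywhere in a family–clade pair sets the cell to
1. Visitation counts compiled across heterogeneous sources are not
comparable, so no quantitative matrix is attempted. Two matrices are built
from the same records — all plants, and native plants only — with the native
filter applied at the record level *before* aggregation, so a family stays
in the native matrix as long as any native member was visited. All-zero rows
and columns are dropped at build time: families never visited and clades
never recorded are not nodes, and every downstream metric assumes positive
degrees.

Node ordering is part of the measurement. Degree ordering (descending link
count, alphabetical tie-break for determinism) is used for the conventional
nestedness score; an externally supplied order — typically a phylogenetic
tip sequence read from a Newick file — can be frozen instead, which turns
NODF into a test of whether phylogeny *per se* arranges the matrix nestedly.

## Nestedness (NODF)

For an ordered pair of rows (u above v), the paired term is 0 if
degree(u) ≤ degree(v) — the decreasing-fill condition is strict, so
equal-degree pairs contribute nothing — and otherwise
100·|ones(u) ∩ ones(v)|/degree(v). Column pairs are scored identically and
the total pools all pairs. Scores are kept at full precision internally and
rounded to 3 decimals only at the interface. Sorted-mode NODF is invariant
to any permutation of the input; fixed-mode NODF can only be lower, because
sorting maximizes the decreasing-fill indicator.

## Null models and standardized effect sizes

Three binary null models bracket the constraint spectrum:

- **ER** reassigns the observed number of 1s uniformly among all cells.
- **CE** fills cell (i, j) independently with probability
  ½(row fill_i + column fill_j), conserving each node's generalization level
  in expectation.
- **FF** conserves both margin vectors exactly, sampled by curveball trades
  (default 5× the link count), which is the modern uniform sampler for the
  margin-fixed ensemble; the historical swap-based samplers target the same
  ensemble but with an unstated schedule.

ER and CE can produce empty rows/columns, on which NODF is undefined; such
draws are rejected and resampled (cap 1000, then an error suggesting the
matrix is too sparse). The ensemble summary reports
SES = (observed − null mean)/null sd and an upper-tail empirical p with the
add-one correction (1 + #{null ≥ obs})/(1 + n), which avoids p = 0
artifacts; a zero-variance ensemble yields SES = 0 with a warning rather
than a division error. On nested matrices the null means order
ER < CE < FF, mirroring the constraint ordering.

## Modularity, consensus, and node roles

The bipartite matrix is viewed as a unipartite graph (one node per family
and per clade, one edge per 1-cell) and partitioned by maximizing
Newman–Girvan modularity M = Σ_s [l_s/L − (d_s/2L)²]. This deliberately
follows the classical unipartite treatment of pollination webs rather than
bipartite-specific (Barber-type) modularity; the docs flag the latter as the
modern alternative.

The optimizer is simulated annealing over single-node moves plus one merge
and one split proposal per temperature step (defaults: T₀ = 1/n, geometric
cooling 0.995, n² node proposals per step, stop at T₀/1000 — all
configurable because no canonical schedule exists). Every run ends with a
deterministic polish: alternating best-single-move passes, best-pair merge
passes, per-module Kernighan–Lin splits, and a whole-graph Kernighan–Lin
pass that applies locked best moves and keeps the best prefix. The polish
makes each run a strict local optimum over a rich move class; with a handful
of optional basin-hopping kicks (`SASchedule.kicks`) the optimizer matched
the exhaustive-partition optimum on every random graph of ≤ 8 nodes we
enumerated (500 graphs). Runs are deterministic under a seeded generator.

Because module labels are arbitrary across runs, repeated-run consensus uses
pairwise co-membership frequencies: the highest-M run is the reference; each
reference module's *core* is the subset of members that co-occur in every
run (falling back to the most coherent member); and a node is assigned to
its reference module only when its mean co-membership with the core exceeds
the threshold (default 0.9, the ">90 % of runs" rule). Unstable nodes are
reported as unassigned.

Node roles use the standardized within-module degree z (population sd within
the module; z = 0 when the sd vanishes) and the participation coefficient
c = 1 − Σ_t (k_{i,t}/k_i)², classified at the conventional cutoffs z = 2.5
and c = 0.62 (ties fall to the low side): peripheral, connector, module hub,
network hub. Significance of modularity compares the mean M over consensus
runs against M re-optimized on ER and FF null matrices; negative SES
(observed less modular than chance) is reported as such.

## Degree-distribution model selection

P(k) is fit on its natural scale (not log–log) by nonlinear least squares to
the exponential, power-law, and truncated power-law forms, with the
power-law exponent initialized from the log–log slope and the cutoff from
max k. Model choice is by the least-squares AIC n·ln(RSS/n) + 2p with RSS
floored at 1e−12 to keep the criterion finite for numerically perfect fits.
The original study's fitting package and objective are unknown, so the AIC
values themselves are not comparable across implementations; what is stable,
and what the tests check, is that data generated from each model family is
attributed to its generator in the majority of replicates, and that the
truncated form never fits worse than the pure power law it nests.

## Biogeography and the niche-conservatism GLM

Each species carries Nearctic/Neotropical/Austral presence flags, lat/elev
extremes, and the geographic center of its clade's radiation (North vs South
America). Clade summaries report region percentages over the clade's full
species count and mean ± sd (n−1 convention) of the four extremes; the
clade's latitudinal/elevational *range* is defined as the difference of
clade means, not the mean of species ranges — the published table's
arithmetic forces this convention. Southern latitudes are negative. Island
(Caribbean) species carry no mainland-region flag; they stay in the table
and count in denominators but score 0 in the GLM response.

The response is 1 when a species occupies ≥ 2 of the three regions. Fits use
binomial GLMs (IRLS via statsmodels, tolerance 1e−8) with logit and probit
links; South America is the reference level, so the exponentiated logit
coefficient is directly the northern odds ratio. Term significance is the
likelihood-ratio (deviance-difference) chi-square; the Wald chi-square is
also reported because the two differ in finite samples. Post-hoc pairwise
clade comparisons are Wald tests on coefficient contrasts with Bonferroni
adjustment over all pairs tested (28 for 8 clades). Overdispersion is the
Pearson χ²/df ratio, flagged above 1.5, with the caveat that the ratio is
weakly informative for strictly binary responses. Complete separation (a
clade with all-0 or all-1 outcomes) produces a warning and a divergent
coefficient rather than a silent failure.

## Synthetic data generator

`generate_records` emulates a compiled continental data set: by default 292
bird species in 9 clades and 1287 plant species in 100 families (Zipf-like
group sizes), with a species-level fill of 0.012 (~4500 records). Structure
enters through a latent-generalism model — species i and j interact with
probability ∝ exp(η(u_i + v_j)) for uniform latent scores, so η = 0 is
unstructured and larger η increasingly nested — and through block structure:
with n_blocks > 0, off-block probabilities are multiplied by
(1 − block_affinity). A bisection step calibrates the overall scale to the
target fill; realized fill is kept within ±10 % by rejection, since exact
fill would distort the probabilistic structure. `generate_biogeo` draws
multi-region occupancy per species from its clade center's odds, so the GLM
has a known true odds ratio (default ratio 9 between centers, matching the
study's reported effect size).

What the generator does *not* emulate: sampling effort and source
heterogeneity, spatial autocorrelation, phylogenetic signal in the latent
scores, and the correlation between a species' range size and its detection.
Passing tests therefore demonstrate that the estimators recover the
structure they target under clean sampling, not that the field data satisfy
those assumptions. A further caveat specific to aggregation: clade×family
cells saturate when groups are large, which dampens the η and block dials at
the aggregated level; the dial tests measure structure on the species-level
matrix (`records_to_species_matrix`) where it is injected.

## Study reconstruction

The species-level compilation and the per-species biogeography table exist
only as document supplements, so `hummnet.reconstruct` builds *synthetic*
stand-ins constrained by every published aggregate. The native matrix starts
from a family-degree distribution (26·1, 19·2, 12·3, 9·4, 7·5, 5·6, 5·7,
4·8, 13·9 — 100 families, 385 links, 13 fully connected families, three
clades above 50 families) arranged as a perfect staircase. A staircase's
margins are conjugate partitions and admit exactly one realization, which
would make the margin-fixed (FF) ensemble degenerate; so for every family of
degree 4–8 the last 1 is relocated to a random lower-rank clade, preserving
all family degrees and the three leading clade degrees while breaking
margin-uniqueness. Five exotic-only families and 15 exotic links in three
otherwise-native families bring the full matrix to 105 families and 409
links. Floral syndromes split 14/36/50 % among native families, assigned by
descending degree (ornithophilous families are the observed generalists).

The biogeography table realizes 292 species across the nine published clade
sizes with region-flag compositions that reproduce, exactly: 38 Nearctic
(3 exclusive + 35 shared), 270 Neotropical, 27 Austral (4 exclusive + 23
partial), 58 multi-region species, and 15 island species with no mainland
flag. Per-species diversification centers follow clade centers except for 16
northern-origin species inside southern clades, arranged so the
success × center table is (33, 31; 24, 203) — the closest integer table to
the published odds ratio (9.004 vs 9.080) and LR chi-square (45.997 vs
46.114) consistent with the 58 published successes. Latitude/elevation
extremes are deterministic placements matching each clade's published means
and sds (island species sit at the clade mean). One published value is
corrected: the Topazes minimum-latitude mean is used as −18.000 because the
printed positive sign contradicts the same row's range column
(3.333 − (−18.000) = 21.333).

Reconstruction limitations: the matrix is *a* matrix with the published
margins, not the published matrix, so point values that depend on the full
cell pattern (the empirical NODF of 70.680, the modularity of 0.189, the
negative modularity SES) are not reproduced — only their directional
properties are (fixed-order NODF < sorted NODF; no significant modularity on
unstructured matrices at the study's density profile; null means ordered
ER < CE < FF). Likewise the per-clade GLM recovers a clade effect of similar
magnitude (LR chi 23.2 vs 21.9 on 7 df) but its pairwise contrasts are
weaker than published, because the reconstruction spreads successes more
evenly within clades than the real data.

## Problem sizes and numerical choices

Test and analysis runs use scaled-down replicate counts chosen as the
package's own defaults for desk-scale verification: 200 null replicates per
model for the nestedness ensembles (the published analysis used 1000), 10
annealing runs and 20 + 20 null networks for modularity (vs 50 and
100 + 100), 1000 trials × 99 replicates for the ER type-I calibration, 500
replicates at n = 300 species for odds-ratio CI coverage, and exhaustive
partition enumeration up to 8 nodes (Bell(8) = 4140 partitions). Stage seeds
derive from a master seed by hashing (seed, stage name), so stages are
reproducible and independent. Ties in degree ordering break alphabetically;
equal-degree NODF pairs contribute 0; z with zero within-module sd is 0; the
add-one correction bounds empirical p away from 0; RSS is floored at 1e−12
in the AIC.
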