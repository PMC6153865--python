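# Methods

## Data model

A deployment is one lander drop: id, depth (m), position, date, duration
on the seabed (h), camera orientation, and optional per-deployment
environmental summaries (current cm s⁻¹, temperature °C, salinity PSU).
A species observation ties a taxon to a deployment with N_max (≥ 1),
t_arr (min) and % images. Absence is encoded by the absence of the row;
the assembled community matrix zero-fills the gaps, so a cell is zero
exactly when the species was never seen there. The method cannot
distinguish "absent" from "present but not detected", and no such
distinction is attempted. Rows are ordered by increasing depth (ties by
id); taxon names are matched case-insensitively after whitespace
normalisation, with no synonym resolution.

The bundled fixture encodes the eight Ionian deployments (532–5111 m) and
their 25 species observations over 14 taxa. The source table's column
assignment is typographically ambiguous for several single-entry rows;
the fixture follows the assignment most consistent with the survey's
results narrative (the gulper shark at all three shallow deployments with
counts 1–3; the shrimp *Acanthephyra eximia* in every deployment below
1000 m, peaking at 4204 m with N_max 29; the grenadier as the only fish of
the three deepest deployments, arriving after 174 min at 5111 m) and
records a provenance note for every inferred cell. Where two source tables
disagree on deployment 5's depth (1841 vs 1823 m) the fixture uses
1823 m, the value carried by the species table the matrix is built from.

## Resemblance

Abundances are square-root transformed by default — strong enough to damp
the dominant species, weak enough to retain count information in a
low-count data set — and compared by Bray–Curtis similarity on the 0–100
scale. Two all-zero samples have undefined similarity: the default is a
hard error, with an explicit opt-in (`zero_pairs="zero"`) that defines
S = 0, used internally by permutation nulls where column shuffles can
empty a row. Rank machinery uses mid-ranks throughout, with ties detected
at an absolute tolerance of 1e−9 on dissimilarity; the tied plateau at
S = 0 produced by disjoint assemblages is expected and handled exactly.

## Clustering and SIMPROF

Clustering is agglomerative group-average (UPGMA) linkage on similarities,
with deterministic tie-breaking (first pair in current cluster order).
Group-average linkage admits no inversions, so fusion similarities
decrease monotonically toward the root; this is asserted property-style on
random matrices.

SIMPROF tests a set of ≥ 3 samples for internal structure. The observed
profile is the ordered vector of off-diagonal similarities; the null
permutes each taxon column independently across samples. The statistic π
is the summed absolute deviation of the observed profile from the mean of
1000 null profiles; significance comes from 999 further null profiles,
with p = (#{π_perm ≥ π_obs} + 1)/(999 + 1). A node of fewer than 3 samples
is *untestable*, a distinct state from non-significant. Group delimitation
applies SIMPROF top-down the dendrogram: a child is tested only if its
parent rejected homogeneity; terminal (non-significant or untestable)
nodes become the reported groups. Seeds for child tests are spawned
deterministically from the user's seed.

## ANOSIM

One-way ANOSIM uses R = (r̄_B − r̄_W)/(M/2) on the mid-ranked
dissimilarities of all M = n(n−1)/2 pairs. When the number of distinct
label assignments (the multinomial coefficient) is at most 10⁵, all are
enumerated and p = #(R_perm ≥ R_obs)/n_distinct with the observed
assignment included — for the bundled 3-vs-5 split this is an exact test
over C(8,3) = 56 assignments. Larger problems fall back to 9999
Monte-Carlo relabelings with the observed statistic added to numerator and
denominator. The exact path is deterministic and seed-independent.

## SIMPER

For each within-group pair, the per-species similarity share
100·2·min(y_ij, y_ik)/Σᵢ(y_ij + y_ik) is computed; shares sum exactly to
the pair's Bray–Curtis similarity, so the per-species averages sum exactly
to the group's average similarity (asserted at 1e−9). Reported per group:
average (transformed) abundance with zeros included, average similarity
contribution, percent and cumulative percent contribution, sorted
descending. Singleton groups are skipped with a warning. Only within-group
decomposition is implemented; between-group SIMPER is out of scope.

## LINKTREE

The linkage tree is grown divisively. At each node, candidate splits are
all midpoints between consecutive ordered unique values of each abiotic
variable among the node's samples; constant columns contribute none. Each
candidate is scored by R_local, the two-group ANOSIM R computed on the
node's own mid-ranked dissimilarities, and by B%, the difference between
mean between-group and mean within-group dissimilarity measured on the
*global* ranks rescaled to 0–100, which makes split strengths comparable
across the tree. The split maximising R_local wins; ties go to the larger
B%, then to the alphabetically first variable. Recursion stops on SIMPROF
non-significance, node size below `min_split_size` (default 3, the
smallest testable set; split-off singletons terminate immediately), or no
admissible candidate. A split on any strictly monotone transform of a
variable yields identical partitions (thresholds move, memberships do
not). This is a reimplementation in the spirit of published linkage-tree
methods, not a numeric bit-match of any proprietary software; B% values
are internally consistent but not comparable across implementations. All
abiotic variables are always offered as candidates — a tree "driven solely
by depth" is an output, never an input constraint.

## Arrival-time regression and ANCOVA

log₁₀(t_arr in minutes) is regressed on depth by OLS (≥ 3 points).
Arrival times are recorded at one-image-interval resolution (1 min);
zeros are rejected rather than jittered — floor raw times at one interval
upstream. Basin comparison is a sequential (type-I) ANCOVA with depth
entered first, then location, then the depth × location interaction,
computed from explicit nested OLS fits (the generic type-I ANOVA of the
underlying fitting library reorders categorical terms ahead of covariates,
which would change the decomposition). A noise-free input drives the
residual variance to zero and is flagged as degenerate rather than
reporting an unbounded F. Bundled as constants are the published basin
lines: Atlantic a = 0.0386, b = 0.000331 (n = 83) and Eastern
Mediterranean a = 0.892, b = 0.000200 (n = 28).

## Odour-plume density inversion

With t_arr in seconds, r = t_arr/(1/V_f + 1/V_w) and A = 10⁶/(3r²) fish
km⁻², assuming the first arriver is the nearest fish, alerted by a plume
advected at V_w and swimming at V_f (both 0.05 m s⁻¹ by default — the
package does not couple them to measured deployment currents, though both
are free parameters). The minute→second seam is owned by
`density_at_depth`. The implied density line is log₁₀(A) =
6 − log₁₀3 − 2(log₁₀60 + a − log₁₀(1/V_f + 1/V_w)) − 2b·depth; its slope
is always −2b, which reproduces the published density regressions from
the arrival regressions to three decimals.

## Synthetic generators

All generators are pure functions of (config, seed).

* **Plume simulator.** Fish are a homogeneous Poisson field at the
  configured density over a circular arena; squared distances of uniform
  points in a disc are uniform on (0, R²), so the nearest-fish distance is
  drawn exactly, and π·r² is exponential with mean 1/λ (asserted by a
  Kolmogorov–Smirnov test at 10⁴ replicates). The config validates that an
  empty arena has probability < 10⁻⁶; empties are redrawn and logged. The
  inversion's constant 3 is kept as the model's convention although the
  Poisson geometry gives π: densities recovered from mean r² therefore run
  ≈ 4.7 % high (π/3), a bias the recovery test quantifies inside its 5 %
  + Monte-Carlo tolerance rather than silently corrects.
* **Arrival generator.** Depths uniform on 500–5000 m (spanning both
  basins' survey ranges); log₁₀(t_arr) = a + b·depth + N(0, σ), σ = 0.2 by
  default (a visually representative scatter for such data), floored at
  1 min. Default point counts are the published 83 + 28.
* **Community generator.** Each species occupies a depth band with
  expected abundance decaying toward the band edges; counts are negative
  binomial (dispersion k = 5 by default, so tests face realistic
  overdispersion; k = ∞ gives Poisson). The study-condition config places
  8 samples at the fixture depths with two disjoint five-species guilds
  split at 1000 m and mean abundance 8 at band centre (matching the
  fixture's low-count regime); the unstructured variant spans every
  species across all depths and is the type-I null. Nuisance abiotic
  columns (latitude, longitude, duration) are drawn independently of
  community structure, giving variable-selection tests a defined
  false-variable baseline.

What the generators deliberately do not emulate: plume fluid dynamics and
current anisotropy, staged arrival behaviour (necrophages before
necrophagivores), seasonal or inter-basin productivity gradients, and
observation error in species identification. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
the models' own assumptions, not robustness to every feature of field
data.

## Simulation sizing

Operating-characteristic suites use 500 unstructured matrices for
SIMPROF/ANOSIM type-I error (nominal 5 % within ±3 points), 200
simulations for LINKTREE boundary recovery (≥ 95 %) and ANCOVA power at
the published effect sizes (≥ 80 %), and 10⁴ plume replicates for density
recovery. Within simulations SIMPROF runs 100 mean-profile and 99 test
permutations — the p-value grid (multiples of 1/100) keeps the 5 % level
exact while holding the whole suite to well under a minute per study.
Fixture-level analyses use the full 1000/999 defaults.

## Known limitations

* Table-derived fixtures inherit the source's typographic ambiguities;
  provenance notes flag every inferred cell, and two printed SIMPER
  averages (3.29 and 1.33) are not reproducible from any reading of the
  source abundance table (the matrix gives 3.20 and 1.30) — treated as a
  source inconsistency, not tuned around.
* The raw arrival records behind the published basin regressions are not
  public; their printed F statistics and R² are covered by power
  simulation at the published effect sizes, not by re-derivation.
* Bray–Curtis is the only resemblance measure; two-way/nested ANOSIM and
  between-group SIMPER are not implemented.
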