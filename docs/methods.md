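# Methods

`snailheat` links mitochondrial population structure of land-snail
populations to their cellular and biochemical heat-stress responses.  The
pipeline has two arms — a genetic arm operating on aligned COI sequences and
a physiological arm operating on per-individual biomarkers — joined by a
multivariate regression tree that asks whether genetic structure predicts
mean stress response.  This note records the models, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Genetic arm

### Haplotypes and K2P distances

Sequences are assumed pre-aligned, equal-length, and indel-free (a fixed
protein-coding COI fragment, 700 bp by default); no aligner is included and
unequal lengths are a hard error (an optional trim window is available).
Haplotypes are exact string equivalence classes by default (`strict`: an N
is a fifth symbol, so determinism is preserved); the `match_N` policy lets
an N match any base, joining an individual to the first compatible haplotype
in input order — opt-in permissiveness for chromatogram consensus sequences.

Pairwise divergence uses the Kimura 2-parameter model,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with P and Q the transition and transversion proportions over sites where
both sequences are unambiguous (**pairwise deletion**; gaps are treated like
N).  Pairwise deletion maximizes per-pair information at this scale, and the
choice is stated here because diversity tables depend on it.  Inputs with
1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 are refused as saturated rather than silently
clamped.

### Statistical-parsimony network

Haplotypes are joined agglomeratively in order of increasing mutational
distance d = 1, 2, …, limit; a join at distance d inserts d − 1 degree-2
intermediate nodes along one shortest mutational path (sites mutated
left-to-right along the alignment — every shortest path is equally
parsimonious, so the choice is arbitrary and pinned).  Ties in join order
resolve lexicographically by haplotype id.  Clusters never join beyond the
connection limit, so the component count is the cryptic-lineage screen.

The connection limit is the largest step count j whose probability of
parsimony is at least the confidence level (default 95%).  The probability
model pinned here is the uniform multiple-hit model: conditional on j
mutational events over m exchangeable sites, the events are homoplasy-free
exactly when they strike j distinct sites,

P(j; m) = ∏_{i=0}^{j−1} (m − i)/m,

treating any repeated hit (back, parallel, or onward substitution) as a
parsimony violation.  For m = 700 and 95% confidence the limit is 8 steps.
Published statistical-parsimony programs use related but not identical
estimators and their realized limits can differ by a few steps; an integer
`--connection-limit` override is provided for exact mimicry of another
program's limit.  The synthetic haplotypes are at most 3 steps apart, so
network topology is insensitive to this choice there.

### Diversity and divergence indices

* **Nucleotide diversity π** — mean K2P distance over all n(n−1)/2
  within-population pairs.  The reported SD is, by default, the square root
  of the Nei (1987)-style total variance

  Var(π) = (n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π²,

  the estimator used by standard population-genetics software (L =
  alignment length); a plain sample SD of the pairwise distances is
  available via `sd_estimator="sample"`.  π of a population equals the mean
  of its pairwise K2P submatrix — tested as a cross-module invariant.
* **Nei pairwise F_ST** — the pooled-frequency (G_ST-type) form on
  haplotype frequency vectors p, q: H_S = 1 − (Σp² + Σq²)/2,
  H_T = 1 − Σp̄² with p̄ = (p+q)/2, F_ST = (H_T − H_S)/H_T, defined as 0
  when H_T = 0.  No sample-size bias correction is applied; the estimator
  is non-negative by concavity, so no clamping is needed.
* **Morisita–Horn divergence H_MH** — haplotypes treated as species:
  overlap C = 2Σxᵢyᵢ / ((d_x + d_y)XY) with d_x = Σxᵢ²/X², divergence
  1 − C.  Both divergence indices depend only on relative frequencies and
  lie in [0, 1].

Report tables print π to 4 decimals, F_ST to 3, H_MH to 2 (diagonal π±SD,
H_MH above, F_ST below).

### Ordination

Classical scaling (PCoA): B = −½·J·(D∘D)·J with J the centering projector;
coordinates are eigenvectors scaled by √eigenvalue for the leading positive
eigenvalues (3 axes for H_MH, 2 for F_ST by default — exactly the
explanatory variables used downstream).  Divergence matrices need not be
Euclidean; negative eigenvalues are dropped with a logged warning (the
Cailliez additive correction is available behind a flag but is off by
default, matching common classical-scaling behavior).  If fewer positive
axes exist than requested, the remainder are zero-padded and warned about —
a constant column is harmless downstream because trees cannot split on it.
Axis signs are fixed by forcing each axis's largest-magnitude loading
positive, making runs bit-reproducible.

## Physiological arm

Biomarkers per individual: relative Hsp70 level (blot optical volume over
an internal standard; n = 10 per population × temperature) and three
semi-quantitative 1–5 histopathology scores (tubules, digestive cells,
calcium cells; 1 = control status, 3 = reaction, 5 = destruction; n = 8).
Exposure temperatures are 25 (control), 33, 38, 40, 43, 45, 48 °C.

Aggregations: mean assessment value (MAV ± sample SD) per cell type;
per-temperature Hsp70 group means as a percentage of the 25 °C control
mean (control ≡ 100%); the temperature of maximum induction (control
excluded from the argmax; ties go to the lower temperature, logged); and
the digestive/calcium integrity ratio (< 1 ⇒ digestive cells in better
condition; bounded in [0.2, 5] by the score floor and ceiling).

**Rank-sum tests.**  Each exposure group is compared against the control
with a two-sided Mann–Whitney rank-sum test.  Because 1–5 scores tie
heavily and the groups are small (8–10), the p-value is computed by exact
enumeration of the permutation distribution of the rank-sum statistic
(midranks; the two-sided tail is symmetric about the null mean) whenever
C(n₁+n₂, n₁) ≤ 250,000 — which covers every design cell.  The tie-corrected
normal approximation with continuity correction is the large-sample
fallback only; at these group sizes its error against the exact
distribution can reach ≈0.1 in p, which is why it is not the default.
All-identical pooled data return p = 1 with a warning.

**Bonferroni tiers.**  Hsp70 comparisons run at the six non-control
temperatures (m = 6); histology at 33/40/43/48 °C (m = 4; 38 and 45 °C are
compared for Hsp70 only).  Tier boundaries 0.05/m, 0.01/m, 0.001/m are
applied as half-open intervals at reporting precision (4, 4, and 5 decimal
places), e.g. m = 6 ⇒ 0.0083 / 0.0017 / 0.00017 with the boundary
inclusive.  Both m values are configurable.

**ANOVA + letters.**  Across-population comparison at one temperature
(typically 40 °C, where induction maxima differ most): one-way ANOVA F,
then Tukey–Kramer HSD pairwise p-values from the studentized-range
distribution with the unequal-n correction, rendered as a compact letter
display by insert-and-absorb (groups sharing a letter are not significantly
different at 0.05).  If every group mean is identical the F statistic is
defined as 0 with p = 1 rather than 0/0.

## Multivariate regression trees

Responses per temperature: population means of Hsp70 and the three MAVs —
four variables on incommensurate scales, so columns are standardized to
unit variance by default (raw-scale flag provided; both modes are
reported).  Explanatory variables: π, H_MH axes 1–3, F_ST axes 1–2.

Fitting is greedy best-first binary partitioning: candidate splits are
midpoints between consecutive sorted unique values of each explanatory
variable; the chosen split maximizes the reduction in total within-node sum
of squared Euclidean distances to node centroids.  Ties resolve to the
lowest variable index, then the lowest split value.  Recursion stops at
`min_node_size` (default 2), `max_depth` (default 3), or zero achievable
reduction — the only sensible values at n = 7 populations.  Splits are
rank-based, so the fit is invariant to population order and to positive
affine rescaling of any explanatory variable; at n ≤ 8 the greedy first
split provably equals exhaustive search (tested).

Tree size is selected by v-fold cross-validation with the fold count
clamped to n.  At the study scale (n = 7 < 10 folds) this is leave-one-out,
which is deterministic — the nominal "1000 repetitions" collapse to one,
and this is logged rather than hidden, since repeated random 10-fold CV is
under-determined at n = 7.  Relative error is the summed held-out squared
distance to the assigned leaf centroid over the total response SS; its SE
across per-population contributions gives the selection rule.  The default
rule is **1-SE** (smallest tree within one SE of the minimum), the
convention of the original multivariate-tree software; plain minimum-CV is
a flag.  Under pure-noise responses the 1-SE rule returns the root-only
tree in ≈99% of simulated replicates; under a strong planted two-cluster
signal it selects ≥ 2 leaves essentially always.

Reported per temperature: first-split R² = (SS_root − SS_left −
SS_right)/SS_root; the CV error of the selected size; the leaf-group
topology in Newick (left sibling = low side of the split; multi-member
leaves as parenthesized comma lists; a well-formed form with outer
parentheses and semicolon plus a display form without); and the Pearson
correlation between the primary split variable and each response —
Hsp70 as +/−, each MAV mapped to "i" (negative correlation: higher
divergence, lower damage, improved condition) or "d" (deteriorated), with
zero-variance inputs flagged "undefined" instead of given a sign.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes,
with planted ground truth, so the full pipeline is testable without any
download.

*Sequences.*  7 populations × 20 sequences of 700 bp from 6 haplotypes: a
hub haplotype and mutants one step away (one of them two steps), all
transitions at ≤ 7 distinct sites (> 99% of columns invariant; the
realized haplotype set uses 6).  Per-population haplotype counts are
multinomial draws from Dirichlet-jittered base frequencies (concentration
150).  Archetypes: population 7 is monomorphic (hub only ⇒ π = 0
downstream); population 4 is divergent, with base frequencies
(0.15, 0.05, 0.025, **0.70**, 0.0375, 0.0375) concentrating mass on an
otherwise-rare haplotype so its mean pairwise F_ST and H_MH exceed every
other population's; the remaining populations use
(0.66, 0.24, 0.03, 0.01, 0.03, 0.03), giving global dominant-haplotype
frequencies of roughly 64% and 18%.  Both dominant haplotypes are
guaranteed present in every polymorphic population, and every planted
haplotype occurs at least once (top-ups never touch the monomorphic
population).  A frequency-level model is sufficient — the downstream
indices consume only haplotype counts — so no coalescent or
substitution-model simulation is attempted.

*Physiology.*  Three heat-response archetypes drive per-temperature
profiles: `moderate` (percent-of-control peaking at 145% at 40 °C),
`high` (165%), and `flat` (≈104% peak — the divergent population), all
declining at ≥ 43 °C.  The moderate and high peaks sit inside the
125–145% / 155–195% bands that define the archetypes; they were placed at
the band edges nearest each other so that the flat population, not the
moderate/high contrast, is the dominant outlier at 40 °C — the pattern the
tree analysis is designed to detect.  Individual Hsp70 levels are
truncated-at-zero Gaussians around the profile (relative SD 0.12; group
size 10).  Histology scores discretize a latent damage curve plus Gaussian
noise (SD 0.6) into categories 1–5; control groups sit near category 1–2
and 48 °C groups near 4–5; the flat population holds a good condition to
40 °C and collapses above it; calcium-cell curves sit slightly below
digestive-cell curves at ≥ 40 °C (calcium cells planted as more heat
resistant).  Curve parameters live in `SimulationConfig`, not code.

The same seed reproduces every dataset byte for byte; the sequence and
physiology streams are independently seeded so either can be regenerated
alone.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: realistic sequence evolution (no
transition/transversion rate structure beyond all-transition planted
mutations, no rate heterogeneity), within-individual measurement
replicates, blot-level normalization noise, population-specific Hsp70 base
levels, and any genuine mechanistic coupling between genotype and
physiology — the genetic/physiological association exists only because the
divergent population is also assigned the flat strategy.  Recovery rates
measured on synthetic data (e.g. the 40 °C primary split placing the
divergent population on the minority side in ≈93% of seeds) therefore
validate the machinery, not the biological effect size.

## Reported problem sizes

Tests and the acceptance script run the full design (7 × 20 sequences,
7 × 7 temperature cells) per seed and use 100 generator seeds for recovery
rates; oracle-equivalence checks run on randomized instances with n ≤ 8,
where exhaustive enumeration is feasible.

## Known limitations

* The parsimony-probability model is a pinned approximation (see above);
  realized connection limits from other software can differ by a few steps.
* The F_ST estimator is the pooled-frequency form without sample-size bias
  correction; other estimators (and the π ± SD estimator choice) will give
  slightly different tables on the same data.
* At n = 7 populations, cross-validated size selection has large variance
  (the CV errors reported alongside trees make this visible), and
  `min_node_size = 2` means a single population can never form a leaf
  alone — "isolating" a population means placing it on the minority side
  of a split.
* Wilcoxon/Bonferroni machinery assumes independent groups; repeated
  measures or tub effects are outside the model.
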