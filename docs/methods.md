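# Methods

This note documents the statistical procedures implemented in
`microcohort`, the choices made where the methods literature leaves room,
and what the synthetic cohorts do and do not establish about real data.

## Data model and clinical derivations

The central object is a samples × taxa matrix in `counts` mode
(non-negative integers) or `relative` mode (rows summing to 1 within
1e-9), with one taxonomy lineage per taxon. Lineages accept both
Greengenes-style `k__/p__/.../g__` prefixes and plain semicolon-delimited
strings; uninformative tokens ("uncultured", empty) are unassigned. A rank
that is unassigned forces all lower ranks unassigned, with one pragmatic
exception at parse time: an uninformative *intermediate* token sitting
above a properly named deeper rank is replaced by an
`<parent>_incertae_sedis` placeholder so the deeper assignment survives —
this mirrors how rank-collapse tools treat gappy lineages.

Collapsing to a rank sums counts over taxa sharing a name at that rank and
drops taxa unassigned there; a taxon unassigned at genus but assigned at
phylum therefore still contributes to phylum-level analyses. Relative
abundances are recomputed (renormalized) after any discard, so each
analysis rank works on a proper composition.

Rare-taxon filtering keeps taxa whose mean relative abundance across
samples is at least the threshold (default 0.1%); the boundary is kept
because the exclusion rule is "strictly less than". The filter is
idempotent and decided on the full composition before any renormalization.

Derived clinical variables: BMI, FMI, and FFMI divide a mass in kg by
height squared in metres; HOMA-IR multiplies fasting insulin (mU/L) by
fasting plasma glucose (mmol/L) and divides by 22.5. Glucose arrives in
mg/dL and is converted by the standard clinical factor 18.0. With the
cohort means FI = 14.5 mU/L and FPG = 82.6 mg/dL this yields 2.96, i.e.
3.0 at one decimal.

## Diversity

Shannon entropy uses the natural log by default; the base is an explicit
parameter because conventions differ (QIIME reports log2). Simpson is the
Gini–Simpson form 1 − Σ pᵢ² (the quantity usually labelled "Simpson" in
microbiome reports); the dominance Σ pᵢ² is also emitted. Chao1 is the
classic estimator S_obs + F1²/(2 F2), falling back to
S_obs + F1(F1−1)/2 when no doubletons exist; a bias-corrected variant sits
behind a flag. Chao1 requires integer counts because singleton/doubleton
counts are undefined otherwise.

PCoA double-centres −½D² (Gower) and eigendecomposes; coordinates are
eigenvectors scaled by √λ for positive eigenvalues only. Negative
eigenvalues (possible because Bray–Curtis is non-Euclidean) are reported
but excluded from both the coordinates and the proportion-explained
denominator.

ANOSIM ranks all n(n−1)/2 dissimilarities with average ranks on ties and
computes R = (r̄_between − r̄_within)/(M/2). The p-value is one-sided
(large R). With two groups and at most 10,000 distinct label arrangements
the arrangement distribution is enumerated exactly and p is the exact
fraction with R_perm ≥ R_obs (the observed labelling included); otherwise
p = (1 + count)/(B + 1) over B random relabelings, B = 999 by default and
configurable, since published analyses rarely state their B.

## Composition

The two-group test is the Wilcoxon rank-sum (Mann–Whitney): exact
enumeration when both groups have ≤ 10 observations and the pooled data
are tie-free, otherwise the tie-corrected normal approximation with 0.5
continuity correction. The switch point keeps exact enumeration cheap and
lets brute-force arrangement oracles verify it.

The compositional screen addresses the unit-sum constraint: a change in
one taxon's absolute abundance moves every relative abundance. For each
unordered taxon pair the per-sample additive log-ratio
log((cᵢ + 1)/(cⱼ + 1)) is compared between groups by rank-sum; each
taxon's m−1 pair p-values are BH-adjusted at 0.05 and Wᵢ counts the
rejections. A taxon is flagged when Wᵢ ≥ ⌈0.7(m−1)⌉. The pseudocount 1,
per-taxon BH family, and 0.7 threshold are the method's customary
defaults. W is reported rather than any per-taxon p-value, because the
procedure does not produce one. With the pseudocount the W statistic is
only approximately invariant to per-sample scaling; with pseudocount 0 on
strictly positive counts the invariance is exact (and is tested).

The F/B ratio is computed per sample from phylum-level relative
abundances; samples with zero Bacteroidetes are flagged undefined and
excluded from group tests.

## Associations

Spearman rho is the Pearson correlation of average ranks. Unadjusted
p-values come from permutation: the clinical variable is shuffled while
the taxon vector stays fixed, with full enumeration when n! ≤ 10,000
(then p is the exact fraction of permutations at least as extreme, the
identity included) and otherwise p = (1 + count)/(B + 1) over B = 5,000
shuffles. BH runs over one family per screen grid (all taxa × all
variables at a rank), matching an "overall FDR" interpretation; cells with
fewer than 10 pairwise-complete observations are excluded from the family
and flagged.

A resolution caveat: with B shuffles the smallest attainable permutation
p-value is 1/(B + 1), so in a grid of m cells a lone true association can
never clear BH at level α unless m/(B + 1) ≤ α·k for the k cells at the
floor — with 5,000 shuffles and ~2,000 cells, at least 8 cells must hit
the floor jointly. Screens expecting only a handful of real signals
should either restrict the variable list or raise B.

Partial Spearman rank-transforms x, y, and the covariates, projects the x
and y ranks onto the covariate ranks plus intercept, and correlates the
residuals. The p-value uses the t approximation with n − k − 2 degrees of
freedom; a permutation variant on the residuals sits behind a flag. This
matches the conventional partial-rank-correlation implementations (it is
cross-checked against pingouin in the tests).

CCA standardizes both blocks and takes the SVD of the whitened
cross-covariance Sxx^(−1/2) Sxy Syy^(−1/2); singular values are the
canonical correlations, back-transformed singular vectors the weights.
Component k is tested with Bartlett's chi-square approximation to Wilks'
Λₖ = Π_{i≥k}(1 − rᵢ²): χ² = −(n − 1 − (p+q+1)/2) ln Λₖ on
(p−k+1)(q−k+1) degrees of freedom. A canonical correlation of exactly 1
collapses Λ to 0 and is flagged degenerate. Block membership (dietary,
lifestyle, body composition, metabolic) is configuration, not code.

## Cooccurrence networks

Presence is value > 0 after the rare filter (configurable threshold; the
detection definition is a modelling choice, not something count data pin
down). For every genus pair with margins a, b and copresence count k out
of N samples, the Jaccard index is k/(a+b−k) and both inclusive
hypergeometric tails are computed: P(X ≥ k) flags copresence, P(X ≤ k)
mutual exclusion. Inclusive tails are conservative and agree exactly with
arrangement enumeration. The Bonferroni family is all tested pairs × two
tails (a one-tail-family variant sits behind a flag); edges with adjusted
p ≤ 0.05 are retained and signed by the winning tail. Edge display
strength is J for copresence and 1 − J for exclusion.

Network clustering is the average local clustering coefficient with
degree-< 2 nodes contributing 0, signs ignored. The null model draws
uniform G(n, m) graphs with matched node and edge counts (default
R = 10,000; p = (1 + #{C_null ≥ C_obs})/(R + 1)); degree-preserving
rewiring is available behind a flag because the null choice materially
changes the reference distribution.

Intra-phylum comparison collects the Jaccard indices of all tested genus
pairs within a phylum in each cohort and applies a two-sided rank-sum
test. Comparing retained-edge counts instead would be an alternative
reading; the Jaccard-value comparison uses strictly more of the data.

## Synthetic cohorts

The generator emulates a two-cohort paediatric study: 164 cases with full
clinical metadata, 45 controls with counts only. Seventy real gut genus
names are allocated to five phyla; within-phylum mean abundances come from
a symmetric Dirichlet(0.7) draw (fixed by a catalogue seed and blended
70/30 toward uniform so no catalogue member is vanishingly rare), scaled
by cohort-specific phylum budgets — Firmicutes-dominant with depleted
Bacteroidetes and Actinobacteria in the case template, Firmicutes and
Bacteroidetes balanced in the control template.

Per sample: sequencing depth is log-normal (median 20,000 reads, log-sd
0.4); genus proportions are Dirichlet around the cohort template with
concentration 300; presence/absence comes from correlated latent Gaussians
thresholded at each genus's detection probability
(clip(1 + 0.12 log10(mean), 0.15, 0.98)); counts are multinomial over the
masked, renormalized proportions. The concentration is deliberately high:
at low concentration, near-zero Dirichlet draws dominate zero-generation
and the latent mask cannot impose its correlation structure, so planted
pairs would not achieve their tetrachoric correlation in the realized
presence pattern. The cost is less compositional overdispersion than real
stool data show; the benefit is that the planting contract actually holds.

Planted structure is all recorded in a truth object serialized with every
dataset. The default study plants ten copresence pairs at latent
correlation 0.8 in the case cohort only (the planted correlation matrix is
checked for positive definiteness and repaired by eigenvalue clipping with
a warning if planting makes it infeasible). Six of the ten close two
latent triangles so that the recovered case network is genuinely clustered
— average clustering near 0.43 against a G(n,m) null p < 0.001 — mirroring
the densely clustered case networks such studies report, while the control
cohort yields essentially no edges.

Clinical variables use normal marginals for mean ± SD quantities (e.g.
HDL-C 51.2 ± 9.6 mg/dL), log-normal marginals matched to median (Q1, Q3)
for right-skewed ones (screen time, sedentary hours, exercise, ALT,
fasting insulin), and Bernoulli for sex (0.59 male) and acanthosis
nigricans (0.80). Fat mass and fat-free mass derive from generated FMI and
FFMI and height, so the derived-variable code path is exercised
consistently. Planted taxon–variable Spearman correlations use a Gaussian
copula: the genus's normal scores are mixed into the variable's latent
with Pearson weight 2 sin(πρ/6) so the realized Spearman matches the
target on fully observed data; zero-inflation attenuates the realized
correlation roughly in proportion to the genus's absence fraction, so
planting targets prevalent genera where fidelity matters.

What passing tests on these cohorts do **not** show: robustness to
sequencing batch effects, taxonomy misassignment, compositional
overdispersion beyond the Dirichlet, longitudinal structure, or real
covariate confounding — none of which the generator simulates.

## Numerical choices and problem sizes

Exhaustive enumeration limits: 10,000 label arrangements (ANOSIM), n! ≤
10,000 (permutation Spearman), both groups ≤ 10 and tie-free (exact
rank-sum). Permutation counts: 5,000 Spearman shuffles, 999 ANOSIM
relabelings, 10,000 random networks by default. Floating-point
comparisons against permutation thresholds use a 1e-12 slack so exact
ties count as "at least as extreme". Symmetry and zero-diagonal of
distance matrices are enforced to 1e-12.

The test suite and the acceptance script run error-rate and recovery
simulations at reduced replicate counts (20–50 seeds, permutation B of
1,000 for null-grid screens, sub-grids of 12 genera × 10 variables) —
sizes chosen so the Monte-Carlo error of the checked proportions stays
well inside the asserted margins while the whole suite remains quick to
run.

## Known limitations

- The hypergeometric model conditions on presence margins; it ignores
  abundance information and any compositional coupling between pairs.
- Bartlett's chi-square for Wilks' Λ is asymptotic; at small n with many
  variables the p-values are approximate.
- The analytic t p-value for partial Spearman treats ranks as data; it is
  the conventional approximation, not an exact permutation test (which is
  available behind a flag).
- The package starts at the taxa table: read QC, denoising, taxonomy
  assignment, phylogenetic (UniFrac) beta diversity, and BIOM-HDF5 binary
  I/O are out of scope.
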