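# microcohort

Statistical comparison of gut-microbiome cohorts from genus/phylum-resolvable
count tables, built for case-control studies of the kind run in paediatric
obesity research: a case cohort with rich clinical metadata (anthropometry,
body composition, diet, activity, fasting blood chemistry) contrasted against
a smaller reference cohort with taxa counts only.

The package covers the full analysis chain:

- **Tables** — TSV feature-table I/O (QIIME2-export style lineage strings),
  collapsing counts to a taxonomic rank, relative abundance, rare-taxon
  filtering (mean relative abundance < 0.1% excluded by default), and derived
  clinical variables: BMI, FMI, FFMI (kg/m²) and
  HOMA-IR = FI [mU/L] × FPG [mmol/L] / 22.5.
- **Diversity** — Shannon *H* = −Σ pᵢ log pᵢ, Gini–Simpson 1 − Σ pᵢ²,
  Chao1 richness; Bray–Curtis dissimilarity
  d(u,v) = 1 − 2 Σ min(uᵢ,vᵢ)/(Σu + Σv); PCoA; ANOSIM
  R = (r̄_between − r̄_within)/(M/2) with exact arrangement enumeration when
  feasible and Monte-Carlo permutation otherwise.
- **Composition** — per-taxon Wilcoxon rank-sum contrasts on relative
  abundances; a compositional differential-abundance screen that tests every
  pairwise additive log-ratio and reports the per-taxon W count (how many of
  a taxon's m−1 ratio tests reject after BH correction); the
  Firmicutes/Bacteroidetes ratio.
- **Associations** — taxa × clinical Spearman screens with permutation
  p-values (5,000 shuffles by default) and Benjamini–Hochberg FDR over the
  whole grid; partial Spearman correlations adjusted for age, sex, and BMI;
  canonical correlation analysis between variable blocks with Bartlett's
  chi-square test of Wilks' Λₖ = Π_{i≥k}(1 − rᵢ²).
- **Cooccurrence** — presence/absence genus networks: Jaccard index
  J = k/(a+b−k), inclusive hypergeometric tails for copresence
  (P(X ≥ k)) and mutual exclusion (P(X ≤ k)), Bonferroni control over all
  pairs × both tails, average clustering coefficient, and a G(n,m)
  random-graph null for network clustering.
- **Synthetic cohorts** — a generator that emulates the two-cohort study
  design (164 cases / 45 controls, cohort-specific phylum composition
  templates, zero-inflated detection via a Gaussian copula with plantable
  copresence/exclusion pairs, clinical marginals with plantable Spearman
  correlations), with every planted feature recorded in a truth object.

## Worked example

```python
import microcohort as mc
from microcohort.core_tables import collapse_taxa, to_relative, derive_clinical

spec = mc.default_spec()
(obese, truth), (nonobese, _) = mc.generate_paired_study(spec, seed=1)

phylum = to_relative(collapse_taxa(obese.table, "phylum"))
print((100 * phylum.data.mean()).round(1).to_string())

net = mc.build_network(collapse_taxa(obese.table, "genus"))
print(f"obese network: {len(net.edges)} edges among "
      f"{net.graph.number_of_nodes()} genera, clustering C = {net.clustering:.3f}")
null = mc.null_network_test(net, r=1000, seed=7)
print(f"clustering vs 1,000 random G(n,m) graphs: p = {null.p_value:.4f}")

meta = derive_clinical(obese.metadata)
print(f"mean HOMA-IR: {meta.data['homa_ir'].mean():.2f}")
```

prints

```
Firmicutes        46.5
Bacteroidetes     36.0
Proteobacteria    14.4
Actinobacteria     2.2
Fusobacteria       0.9
obese network: 10 edges among 14 genera, clustering C = 0.429
clustering vs 1,000 random G(n,m) graphs: p = 0.0010
mean HOMA-IR: 2.92
```

The simulated case cohort reproduces its composition template (Firmicutes
dominant, Bacteroidetes and Actinobacteria depleted relative to the
reference cohort); the cooccurrence screen recovers the ten planted
copresence pairs — two of them latent triangles, hence the high clustering
coefficient that no same-size random graph matches — and the clinical
generator's fasting insulin/glucose marginals put mean HOMA-IR near 3.

## Command line

```bash
microcohort all --table counts.tsv --metadata meta.tsv \
    --reference-table controls.tsv --rank genus --out results/ --seed 7
microcohort simulate --out sim/ --seed 1
```

Subcommands `diversity`, `compare`, `associate`, and `cooccur` run single
stages; a YAML config file (`--config`) can set any pipeline option, with
flags taking precedence. Every output directory contains a `manifest.json`
recording versions, seeds, thresholds, and per-artifact checksums — a
manifest fully determines a rerun.

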