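"""Synthetic cohort generator.

Emulates the data structure of a two-cohort paediatric gut-microbiome
study: an "obese" cohort of 164 children with full clinical metadata and a
"nonobese" reference cohort of 45 children with taxa counts only.  Genus
catalogues are explicitly artificial (real genus names, synthetic
abundances): phylum-level mean compositions follow the cohort templates,
genus means split each phylum's budget by a Dirichlet draw, per-sample
compositions are Dirichlet-multinomial with log-normal sequencing depth,
presence/absence is overlaid by thresholding correlated latent Gaussians
(a Gaussian copula, which makes copresence/exclusion plantable via the
latent tetrachoric correlation), and clinical variables are drawn from
Table-style marginals with plantable Spearman correlations to designated
genera.

Every generated dataset carries a :class:`SyntheticTruth` object recording
exactly what was planted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import (
    AbundanceTable,
    ClinicalMetadata,
    CohortStudy,
    TaxonLineage,
    TEMPLATE_VARIABLES,
)

__all__ = [
    "PlantedPair",
    "PlantedCorrelation",
    "SyntheticSpec",
    "SyntheticTruth",
    "default_spec",
    "generate_cohort",
    "generate_paired_study",
]


# --- genus catalogue -------------------------------------------------------

# real gut genus names grouped by phylum; abundances assigned synthetically
GENUS_CATALOGUE: dict[str, tuple[str, ...]] = {
    "Firmicutes": (
        "Blautia", "Faecalibacterium", "Lactobacillus", "Roseburia",
        "Ruminococcus", "Coprococcus", "Dorea", "Streptococcus",
        "Subdoligranulum", "Agathobacter", "Anaerostipes", "Fusicatenibacter",
        "Lachnospira", "Lachnoclostridium", "Romboutsia", "Veillonella",
        "Dialister", "Megamonas", "Megasphaera", "Holdemanella",
        "Catenibacterium", "Butyricicoccus", "Flavonifractor", "Oscillibacter",
        "Monoglobus", "Peptostreptococcus", "Clostridioides",
        "Erysipelatoclostridium", "Tyzzerella", "Acidaminococcus",
        "Phascolarctobacterium", "Colidextribacter",
        "Eubacterium_coprostanoligenes_group", "Eubacterium_eligens_group",
        "Eubacterium_hallii_group", "Eubacterium_ventriosum_group",
        "Ruminococcus_gnavus_group", "Ruminococcus_torques_group",
        "Ruminococcus_gauvreauii_group", "Christensenellaceae_R-7_group",
        "Lachnospiraceae_NK4A136_group", "Lachnospiraceae_UCG-010",
    ),
    "Bacteroidetes": (
        "Bacteroides", "Prevotella", "Alistipes", "Parabacteroides",
        "Alloprevotella", "Paraprevotella", "Barnesiella", "Odoribacter",
        "Muribaculaceae", "Prevotellaceae_UCG-003", "Butyricimonas",
        "Coprobacter",
    ),
    "Proteobacteria": (
        "Escherichia-Shigella", "Klebsiella", "Enterobacter", "Haemophilus",
        "Sutterella", "Parasutterella", "Bilophila", "Desulfovibrio",
        "Acinetobacter",
    ),
    "Actinobacteria": (
        "Bifidobacterium", "Collinsella", "Eggerthella", "Rothia",
        "Actinomyces",
    ),
    "Fusobacteria": ("Fusobacterium", "Leptotrichia"),
}

# cohort phylum-level mean compositions (renormalized to sum to 1);
# the obese template is Firmicutes-dominated with depleted Bacteroidetes
# and Actinobacteria relative to the nonobese template
OBESE_PHYLUM_MEANS = {
    "Firmicutes": 0.471,
    "Bacteroidetes": 0.344,
    "Proteobacteria": 0.140,
    "Actinobacteria": 0.024,
    "Fusobacteria": 0.010,
}
NONOBESE_PHYLUM_MEANS = {
    "Firmicutes": 0.460,
    "Bacteroidetes": 0.460,
    "Actinobacteria": 0.052,
    "Proteobacteria": 0.027,
    "Fusobacteria": 0.008,
}

# clinical marginals: ("normal", mean, sd) / ("lognormal", mu, sigma of log)
# / ("bernoulli", p).  Log-normal parameters are matched to reported
# median (Q1, Q3); sigma = (ln Q3 - ln Q1) / (2 * 0.6745).
CLINICAL_MARGINALS: dict[str, tuple] = {
    "age_yr": ("normal", 10.4, 2.2),
    "sex": ("bernoulli", 0.59),
    "height_cm": ("normal", 145.0, 11.0),
    "bmi_z": ("normal", 3.2, 1.0),
    "waist_cm": ("normal", 89.7, 10.7),
    "sbp_mmhg": ("normal", 116.0, 10.0),
    "acanthosis": ("bernoulli", 0.80),
    "fmi_kg_m2": ("normal", 11.8, 2.9),
    "ffmi_kg_m2": ("normal", 16.1, 2.1),
    "body_fat_pct": ("normal", 41.7, 5.5),
    "trunk_fmi_kg_m2": ("normal", 5.7, 1.4),
    "vfa_cm2": ("normal", 129.4, 40.3),
    "energy_kcal_d": ("normal", 1450.0, 537.9),
    "fiber_g_per_1000kcal": ("normal", 2.8, 2.0),
    "fat_energy_pct": ("normal", 36.0, 6.0),
    "screen_weekday_h": ("lognormal", np.log(7.0), 1.028),
    "screen_weekend_h": ("lognormal", np.log(8.0), 0.679),
    "sedentary_h": ("lognormal", np.log(4.0), 0.929),
    "exercise_min_wk": ("lognormal", np.log(60.0), 2.45),
    "tc_mg_dl": ("normal", 189.6, 31.7),
    "ldl_c_mg_dl": ("normal", 128.9, 31.6),
    "hdl_c_mg_dl": ("normal", 51.2, 9.6),
    "tg_mg_dl": ("normal", 101.6, 41.8),
    "alt_u_l": ("lognormal", 3.157, 0.716),
    "fpg_mg_dl": ("normal", 82.6, 5.9),
    "fi_mu_l": ("lognormal", 2.365, 0.786),
}

# variables whose draws must stay positive
_POSITIVE_FLOOR = {
    "age_yr": 7.0, "height_cm": 110.0, "waist_cm": 50.0, "sbp_mmhg": 80.0,
    "fmi_kg_m2": 3.0, "ffmi_kg_m2": 10.0, "body_fat_pct": 20.0,
    "trunk_fmi_kg_m2": 1.0, "vfa_cm2": 20.0, "energy_kcal_d": 400.0,
    "fiber_g_per_1000kcal": 0.1, "fat_energy_pct": 10.0,
    "tc_mg_dl": 90.0, "ldl_c_mg_dl": 40.0, "hdl_c_mg_dl": 20.0,
    "tg_mg_dl": 25.0, "fpg_mg_dl": 60.0, "bmi_z": 2.0,
}


@dataclass(frozen=True)
class PlantedPair:
    genus_a: str
    genus_b: str
    latent_corr: float

    def __post_init__(self) -> None:
        if not -1 < self.latent_corr < 1:
            raise ValueError("|latent correlation| must be < 1")


@dataclass(frozen=True)
class PlantedCorrelation:
    genus: str
    variable: str
    rho: float

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError("|planted Spearman| must be < 1")


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated two-cohort study."""

    n_obese: int = 164
    n_nonobese: int = 45
    genus_catalogue: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {p: tuple(g) for p, g in GENUS_CATALOGUE.items()}
    )
    phylum_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "obese": dict(OBESE_PHYLUM_MEANS),
            "nonobese": dict(NONOBESE_PHYLUM_MEANS),
        }
    )
    #: Dirichlet concentration controlling within-cohort compositional
    #: dispersion (smaller = noisier samples).  Kept high enough that a
    #: genus drawn as present rarely falls below one read at the default
    #: depth: detection is then governed by the latent presence mask,
    #: which is what makes planted copresence correlations realizable.
    concentration: float = 300.0
    #: within-phylum genus weights come from a symmetric Dirichlet with
    #: this alpha, drawn once from catalogue_seed
    genus_alpha: float = 0.7
    catalogue_seed: int = 12345
    depth_median: float = 20_000.0
    depth_log_sigma: float = 0.4
    planted_pairs: dict[str, list[PlantedPair]] = field(default_factory=dict)
    planted_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_correlations: dict[str, list[PlantedCorrelation]] = field(
        default_factory=dict
    )
    clinical_marginals: dict[str, tuple] = field(
        default_factory=lambda: dict(CLINICAL_MARGINALS)
    )
    #: cohorts that carry clinical metadata
    with_metadata: tuple[str, ...] = ("obese",)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for label, means in self.phylum_means.items():
            total = sum(means.values())
            if total <= 0:
                raise ValueError(f"cohort {label!r}: non-positive phylum means")
            self.phylum_means[label] = {p: m / total for p, m in means.items()}
        for folds in self.planted_fold_changes.values():
            if any(f <= 0 for f in folds.values()):
                raise ValueError("fold changes must be > 0")

    @property
    def genera(self) -> list[str]:
        return [g for genera in self.genus_catalogue.values() for g in genera]

    @property
    def genus_phylum(self) -> dict[str, str]:
        return {
            g: p for p, genera in self.genus_catalogue.items() for g in genera
        }

    def genus_weights(self) -> dict[str, float]:
        """Within-phylum genus weights (sum to 1 per phylum), drawn once
        from catalogue_seed so every run of a spec shares the catalogue."""
        rng = np.random.default_rng(self.catalogue_seed)
        weights: dict[str, float] = {}
        for phylum, genera in self.genus_catalogue.items():
            w = rng.dirichlet(np.full(len(genera), self.genus_alpha))
            # blend toward uniform so no genus is vanishingly rare within
            # its phylum (every catalogue member stays detectable)
            w = 0.7 * w + 0.3 / len(genera)
            w = w / w.sum()
            weights.update(dict(zip(genera, w)))
        return weights

    def genus_template(self, label: str) -> pd.Series:
        """Cohort genus-level mean composition (fold changes applied,
        renormalized to sum to 1)."""
        if label not in self.phylum_means:
            raise ValueError(f"unknown cohort label {label!r}")
        weights = self.genus_weights()
        means = {}
        for phylum, genera in self.genus_catalogue.items():
            budget = self.phylum_means[label].get(phylum, 0.0)
            for g in genera:
                means[g] = budget * weights[g]
        template = pd.Series(means, dtype=float)
        for genus, fold in self.planted_fold_changes.get(label, {}).items():
            template[genus] *= fold
        return template / template.sum()


@dataclass
class SyntheticTruth:
    """Record of everything planted into one generated cohort."""

    label: str
    seed: int
    genus_template: dict[str, float]
    presence_probs: dict[str, float]
    planted_pairs: list[PlantedPair]
    planted_fold_changes: dict[str, float]
    planted_correlations: list[PlantedCorrelation]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        payload["planted_pairs"] = [PlantedPair(**p) for p in payload["planted_pairs"]]
        payload["planted_correlations"] = [
            PlantedCorrelation(**c) for c in payload["planted_correlations"]
        ]
        return cls(**payload)


def default_spec() -> SyntheticSpec:
    """The default two-cohort study: 164 obese / 45 nonobese samples,
    cohort phylum templates as above, ten planted copresence pairs
    (latent tetrachoric correlation 0.8) in the obese cohort only, and
    three planted genus-clinical Spearman correlations of magnitudes
    typical for such screens.

    Six of the ten pairs close two latent triangles so that the recovered
    obese network is genuinely clustered (high average clustering
    coefficient against the G(n, m) null), mirroring the dense mutualistic
    structure such cohorts show; the remaining four pairs are disjoint.
    """
    pairs = [
        # triangle 1 (Lachnospiraceae-style guild)
        PlantedPair("Blautia", "Dorea", 0.8),
        PlantedPair("Dorea", "Fusicatenibacter", 0.8),
        PlantedPair("Blautia", "Fusicatenibacter", 0.8),
        # triangle 2 (Bacteroidetes guild)
        PlantedPair("Alistipes", "Odoribacter", 0.8),
        PlantedPair("Odoribacter", "Barnesiella", 0.8),
        PlantedPair("Alistipes", "Barnesiella", 0.8),
        # disjoint pairs
        PlantedPair("Roseburia", "Agathobacter", 0.8),
        PlantedPair("Prevotella", "Paraprevotella", 0.8),
        PlantedPair("Lachnospiraceae_NK4A136_group", "Ruminococcus_torques_group", 0.8),
        PlantedPair("Sutterella", "Parasutterella", 0.8),
    ]
    correlations = [
        PlantedCorrelation("Bifidobacterium", "hdl_c_mg_dl", 0.18),
        PlantedCorrelation("Bifidobacterium", "screen_weekday_h", -0.40),
        PlantedCorrelation("Lactobacillus", "fmi_kg_m2", 0.24),
    ]
    return SyntheticSpec(
        planted_pairs={"obese": pairs, "nonobese": []},
        planted_correlations={"obese": correlations, "nonobese": []},
    )


# --- generation ------------------------------------------------------------


def _presence_probability(mean_abundance: np.ndarray) -> np.ndarray:
    """Detection probability as a smooth function of mean abundance:
    abundant genera are nearly always detected, rare ones intermittently."""
    with np.errstate(divide="ignore"):
        logm = np.log10(np.maximum(mean_abundance, 1e-12))
    return np.clip(1.0 + 0.12 * logm, 0.15, 0.98)


def _planted_sigma(genera: list[str], pairs: list[PlantedPair]) -> np.ndarray:
    m = len(genera)
    idx = {g: i for i, g in enumerate(genera)}
    sigma = np.eye(m)
    for pair in pairs:
        for g in (pair.genus_a, pair.genus_b):
            if g not in idx:
                raise ValueError(f"planted pair names unknown genus {g!r}")
        i, j = idx[pair.genus_a], idx[pair.genus_b]
        sigma[i, j] = sigma[j, i] = pair.latent_corr
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() < 1e-10:
        warnings.warn(
            "planted latent correlation matrix not positive definite; "
            "repairing by eigenvalue clipping",
            stacklevel=2,
        )
        vals, vecs = np.linalg.eigh(sigma)
        vals = np.maximum(vals, 1e-8)
        sigma = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def _marginal_ppf(marginal: tuple, u: np.ndarray) -> np.ndarray:
    kind = marginal[0]
    if kind == "normal":
        _, mean, sd = marginal
        return stats.norm.ppf(u, loc=mean, scale=sd)
    if kind == "lognormal":
        _, mu, sigma = marginal
        return np.exp(stats.norm.ppf(u, loc=mu, scale=sigma))
    if kind == "bernoulli":
        _, prob = marginal
        return (u > 1 - prob).astype(float)
    raise ValueError(f"unknown marginal kind {kind!r}")


def _normal_scores(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map a vector to standard-normal scores via mid-ranks; ties (zeros)
    are broken with a tiny random jitter so the scores stay continuous."""
    jitter = rng.normal(0.0, 1e-9, size=values.shape)
    ranks = stats.rankdata(values + jitter)
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _generate_clinical(
    spec: SyntheticSpec,
    label: str,
    rel_abundance: pd.DataFrame,
    rng: np.random.Generator,
) -> ClinicalMetadata:
    n = rel_abundance.shape[0]
    planted = {
        c.variable: c for c in spec.planted_correlations.get(label, [])
    }
    columns: dict[str, np.ndarray] = {}
    for var, marginal in spec.clinical_marginals.items():
        if var in planted:
            corr = planted[var]
            if corr.genus not in rel_abundance.columns:
                raise ValueError(f"planted correlation names unknown genus {corr.genus!r}")
            # Gaussian-copula planting: latent score = mix of the genus's
            # normal scores and noise; Pearson latent r chosen so the
            # resulting Spearman matches the target (r = 2 sin(pi rho / 6))
            z_g = _normal_scores(rel_abundance[corr.genus].to_numpy(), rng)
            r_latent = 2.0 * np.sin(np.pi * corr.rho / 6.0)
            z = r_latent * z_g + np.sqrt(1 - r_latent**2) * rng.standard_normal(n)
            u = stats.norm.cdf(z)
        else:
            u = rng.uniform(size=n)
        values = _marginal_ppf(marginal, u)
        floor = _POSITIVE_FLOOR.get(var)
        if floor is not None:
            values = np.maximum(values, floor)
        columns[var] = values

    h_m2 = (columns["height_cm"] / 100.0) ** 2
    columns["fm_kg"] = columns["fmi_kg_m2"] * h_m2
    columns["ffm_kg"] = columns["ffmi_kg_m2"] * h_m2
    columns["weight_kg"] = columns["fm_kg"] + columns["ffm_kg"]

    df = pd.DataFrame(columns, index=rel_abundance.index)
    types = {v: TEMPLATE_VARIABLES.get(v, "continuous") for v in df.columns}
    return ClinicalMetadata(data=df, var_types=types)


def generate_cohort(
    spec: SyntheticSpec, cohort_label: str, seed: int
) -> tuple[CohortStudy, SyntheticTruth]:
    """Generate one cohort (counts table, optional metadata) plus its truth.

    Per sample: sequencing depth ~ log-normal; genus proportions ~
    Dirichlet around the cohort template; presence/absence from correlated
    latent Gaussians thresholded at each genus's detection probability
    (planted pairs share latent correlation); counts ~ multinomial over the
    masked, renormalized proportions.
    """
    if cohort_label not in spec.phylum_means:
        raise ValueError(f"unknown cohort label {cohort_label!r}")
    rng = np.random.default_rng(seed)
    genera = spec.genera
    m = len(genera)
    n = spec.n_obese if cohort_label == "obese" else spec.n_nonobese

    template = spec.genus_template(cohort_label)
    template = template.reindex(genera)
    alpha = spec.concentration * template.to_numpy()
    alpha = np.maximum(alpha, 1e-3)  # Dirichlet needs strictly positive alpha
    props = rng.dirichlet(alpha, size=n)

    pairs = spec.planted_pairs.get(cohort_label, [])
    sigma = _planted_sigma(genera, pairs)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, m)) @ chol.T
    pi = _presence_probability(template.to_numpy())
    present = z < stats.norm.ppf(pi)

    masked = props * present
    empty = masked.sum(axis=1) <= 0
    if empty.any():
        # force the template-dominant genus present in degenerate samples
        top = int(np.argmax(template.to_numpy()))
        masked[empty, top] = props[empty, top] + 1e-9
    masked = masked / masked.sum(axis=1, keepdims=True)

    depths = np.round(
        rng.lognormal(np.log(spec.depth_median), spec.depth_log_sigma, size=n)
    ).astype(int)
    depths = np.maximum(depths, 500)
    counts = np.empty((n, m), dtype=int)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], masked[i])

    sample_ids = [f"{cohort_label}_{i + 1:03d}" for i in range(n)]
    genus_phylum = spec.genus_phylum
    lineages = {
        g: TaxonLineage(
            taxon_id=g,
            kingdom="Bacteria",
            phylum=genus_phylum[g],
            class_=f"{genus_phylum[g]}_cls",
            order=f"{genus_phylum[g]}_ord",
            family=f"{genus_phylum[g]}_fam",
            genus=g,
        )
        for g in genera
    }
    table = AbundanceTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=genera),
        lineages=lineages,
        mode="counts",
    )

    metadata = None
    if cohort_label in spec.with_metadata:
        rel = table.data.div(table.data.sum(axis=1), axis=0)
        metadata = _generate_clinical(spec, cohort_label, rel, rng)

    truth = SyntheticTruth(
        label=cohort_label,
        seed=int(seed),
        genus_template={g: float(v) for g, v in template.items()},
        presence_probs={g: float(p) for g, p in zip(genera, pi)},
        planted_pairs=list(pairs),
        planted_fold_changes=dict(spec.planted_fold_changes.get(cohort_label, {})),
        planted_correlations=list(spec.planted_correlations.get(cohort_label, [])),
    )
    return CohortStudy(label=cohort_label, table=table, metadata=metadata), truth


def generate_paired_study(
    spec: SyntheticSpec, seed: int
) -> tuple[tuple[CohortStudy, SyntheticTruth], tuple[CohortStudy, SyntheticTruth]]:
    """Generate the obese and nonobese cohorts from independent child seeds
    of ``seed``."""
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    obese = generate_cohort(spec, "obese", int(child[0]))
    nonobese = generate_cohort(spec, "nonobese", int(child[1]))
    return obese, nonobese
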