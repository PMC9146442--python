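"""Core data model for sample-by-taxa abundance tables and clinical metadata.

The central object is :class:`AbundanceTable`: a samples x taxa matrix of
read counts (or relative abundances) together with a taxonomy lineage per
taxon.  Operations here cover TSV I/O, collapsing counts to a taxonomic
rank, conversion to relative abundance, rare-taxon filtering, and derived
clinical variables (BMI, FMI, FFMI, HOMA-IR).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "TaxonLineage",
    "AbundanceTable",
    "ClinicalMetadata",
    "CohortStudy",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "collapse_taxa",
    "to_relative",
    "filter_rare",
    "derive_clinical",
]

#: taxonomic rank ladder, highest to lowest
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: marker for a rank with no confident assignment
UNASSIGNED = "unassigned"

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "d": "kingdom",  # SILVA uses d__ for domain
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

# lineage tokens that carry no taxonomic information
_AMBIGUOUS = {
    "", "uncultured", "unassigned", "unclassified", "unknown",
    "uncultured bacterium", "uncultured organism", "metagenome", "na",
}


def _clean_token(token: str) -> str:
    token = token.strip().strip('"')
    if token.lower() in _AMBIGUOUS:
        return UNASSIGNED
    return token


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomy lineage for one taxon: a name (or ``unassigned``) per rank.

    Invariant: once a rank is unassigned, every lower rank is unassigned.
    """

    taxon_id: str
    kingdom: str = UNASSIGNED
    phylum: str = UNASSIGNED
    class_: str = UNASSIGNED
    order: str = UNASSIGNED
    family: str = UNASSIGNED
    genus: str = UNASSIGNED
    species: str = UNASSIGNED

    def __post_init__(self) -> None:
        names = [self.name_at(r) for r in RANKS]
        seen_unassigned = False
        cleaned = []
        for name in names:
            if seen_unassigned or name == UNASSIGNED:
                seen_unassigned = True
                cleaned.append(UNASSIGNED)
            else:
                cleaned.append(name)
        for rank, name in zip(RANKS, cleaned):
            object.__setattr__(self, _rank_attr(rank), name)

    def name_at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, _rank_attr(rank))

    def assigned_at(self, rank: str) -> bool:
        return self.name_at(rank) != UNASSIGNED

    def truncate(self, rank: str) -> "TaxonLineage":
        """Lineage with all ranks below `rank` set to unassigned."""
        idx = RANKS.index(rank)
        kwargs = {
            _rank_attr(r): (self.name_at(r) if i <= idx else UNASSIGNED)
            for i, r in enumerate(RANKS)
        }
        return TaxonLineage(taxon_id=self.name_at(rank), **kwargs)

    def to_string(self) -> str:
        """Greengenes-style lineage string (``k__...;p__...;...``)."""
        parts = []
        for rank in RANKS:
            prefix = "k" if rank == "kingdom" else rank[0]
            name = self.name_at(rank)
            parts.append(f"{prefix}__{'' if name == UNASSIGNED else name}")
        return ";".join(parts)

    @classmethod
    def parse(cls, taxon_id: str, lineage: str) -> "TaxonLineage":
        """Parse a lineage string in either prefixed (``g__Blautia``) or
        plain semicolon-delimited form.  Unparseable tokens map to
        unassigned; a break in the ladder truncates everything below it.
        """
        tokens = [t for t in (tok.strip() for tok in lineage.split(";"))]
        names: dict[str, str] = {}
        prefixed = any(re.match(r"^[a-zA-Z]__", t) for t in tokens)
        if prefixed:
            for tok in tokens:
                m = re.match(r"^([a-zA-Z])__(.*)$", tok)
                if not m:
                    continue
                rank = _PREFIX_TO_RANK.get(m.group(1).lower())
                if rank is not None:
                    names[rank] = _clean_token(m.group(2))
        else:
            for rank, tok in zip(RANKS, tokens):
                names[rank] = _clean_token(tok)
        # gap-fill: an unassigned intermediate rank above a properly named
        # deeper rank becomes an incertae-sedis placeholder so the deeper
        # assignment survives (mirrors how rank-collapse tools behave)
        resolved = [names.get(r, UNASSIGNED) for r in RANKS]
        assigned_idx = [i for i, n in enumerate(resolved) if n != UNASSIGNED]
        if assigned_idx:
            deepest = assigned_idx[-1]
            last = None
            for i in range(deepest):
                if resolved[i] != UNASSIGNED:
                    last = resolved[i]
                elif last is not None:
                    resolved[i] = f"{last}_incertae_sedis"
                else:
                    resolved[i] = "incertae_sedis"
        kwargs = {_rank_attr(r): n for r, n in zip(RANKS, resolved)}
        return cls(taxon_id=taxon_id, **kwargs)


def _rank_attr(rank: str) -> str:
    return "class_" if rank == "class" else rank


@dataclass
class AbundanceTable:
    """Samples x taxa matrix with per-taxon lineages.

    ``data`` is a DataFrame indexed by sample id with one column per taxon
    id; ``mode`` is ``"counts"`` (non-negative integers) or ``"relative"``
    (rows sum to 1).
    """

    data: pd.DataFrame
    lineages: Mapping[str, TaxonLineage]
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        missing = [t for t in self.data.columns if t not in self.lineages]
        if missing:
            raise ValueError(f"taxa without lineage: {missing[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance values")
        if (values < 0).any():
            raise ValueError("negative abundance values")
        if self.mode == "counts":
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts mode requires integer values")
        else:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise ValueError(
                    "relative mode requires rows summing to 1; offending "
                    f"samples: {self.data.index[bad].tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def lineage(self, taxon_id: str) -> TaxonLineage:
        return self.lineages[taxon_id]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalMetadata:
    """Per-sample clinical variables with declared types.

    ``var_types`` maps column name to ``continuous`` / ``binary`` /
    ``ordinal``; columns not listed default to continuous.
    """

    data: pd.DataFrame
    var_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for name, kind in self.var_types.items():
            if kind not in ("continuous", "binary", "ordinal"):
                raise ValueError(f"unknown variable type {kind!r} for {name!r}")
            if name not in self.data.columns:
                continue
            col = self.data[name].dropna()
            if kind == "binary" and not col.isin([0, 1]).all():
                raise ValueError(f"binary variable {name!r} has values outside {{0,1}}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def variable(self, name: str) -> pd.Series:
        return self.data[name]


#: template clinical variable names (anthropometry, body composition, diet,
#: activity, fasting blood chemistry) used throughout the pipeline
TEMPLATE_VARIABLES: dict[str, str] = {
    "age_yr": "continuous",
    "sex": "binary",               # 1 = male
    "weight_kg": "continuous",
    "height_cm": "continuous",
    "bmi_z": "continuous",
    "waist_cm": "continuous",
    "sbp_mmhg": "continuous",
    "acanthosis": "binary",
    "fm_kg": "continuous",
    "ffm_kg": "continuous",
    "fmi_kg_m2": "continuous",
    "ffmi_kg_m2": "continuous",
    "body_fat_pct": "continuous",
    "trunk_fmi_kg_m2": "continuous",
    "vfa_cm2": "continuous",
    "energy_kcal_d": "continuous",
    "fiber_g_per_1000kcal": "continuous",
    "fat_energy_pct": "continuous",
    "screen_weekday_h": "continuous",
    "screen_weekend_h": "continuous",
    "sedentary_h": "continuous",
    "exercise_min_wk": "continuous",
    "tc_mg_dl": "continuous",
    "ldl_c_mg_dl": "continuous",
    "hdl_c_mg_dl": "continuous",
    "tg_mg_dl": "continuous",
    "alt_u_l": "continuous",
    "fpg_mg_dl": "continuous",
    "fi_mu_l": "continuous",
}


@dataclass
class CohortStudy:
    """A labelled cohort: abundance table plus (optional) clinical metadata."""

    label: str
    table: AbundanceTable
    metadata: ClinicalMetadata | None = None

    def __post_init__(self) -> None:
        if self.metadata is not None:
            t = set(self.table.sample_ids)
            m = set(self.metadata.sample_ids)
            if t != m:
                raise ValueError(
                    f"cohort {self.label!r}: table/metadata sample mismatch "
                    f"(only-table={sorted(t - m)[:3]}, only-meta={sorted(m - t)[:3]})"
                )


# ---------------------------------------------------------------------------
# I/O

_LINEAGE_COLUMNS = ("taxonomy", "taxon", "lineage", "consensus lineage")


def _looks_like_lineage(value: object) -> bool:
    return isinstance(value, str) and (";" in value or "__" in value)


def read_feature_table(path) -> AbundanceTable:
    """Read a TSV feature table (QIIME2-export style) into counts mode.

    Accepts taxa in rows (with a lineage column or lineage strings as row
    ids) or taxa in columns; a leading ``#Constructed from biom file``
    header line is tolerated.  Orientation is auto-detected from where the
    lineage strings live, with ties resolved as taxa-in-rows.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.readlines()
    lines = [ln for ln in lines if not ln.startswith("#Constructed")]
    if not lines:
        raise ValueError(f"empty feature table: {path}")
    if lines[0].startswith("#OTU ID"):
        lines[0] = lines[0][1:]
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("feature table needs an id column plus data columns")

    lineage_col = next(
        (c for c in df.columns if c.strip().lower() in _LINEAGE_COLUMNS), None
    )
    first = df.columns[0]
    if lineage_col is not None or df[first].map(_looks_like_lineage).all():
        # taxa in rows
        if lineage_col is None:
            lineage_col = first
            taxon_ids = [f"taxon_{i + 1}" for i in range(len(df))]
        else:
            taxon_ids = df[first].tolist()
        lineage_strings = df[lineage_col].tolist()
        sample_cols = [c for c in df.columns if c not in (first, lineage_col)]
        matrix = df[sample_cols].T
        matrix.columns = taxon_ids
    elif all(_looks_like_lineage(c) for c in df.columns[1:]):
        # taxa in columns, header row carries lineages
        taxon_ids = [f"taxon_{i + 1}" for i in range(df.shape[1] - 1)]
        lineage_strings = list(df.columns[1:])
        matrix = df.set_index(first)
        matrix.columns = taxon_ids
    else:
        raise ValueError(
            "could not locate taxonomy lineages in rows or columns of "
            f"{path}; expected ';'-delimited or 'g__'-prefixed strings"
        )

    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError("duplicate taxon ids in feature table")
    try:
        values = matrix.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric counts in feature table: {exc}") from None
    if (values.to_numpy() < 0).any():
        raise ValueError("negative counts in feature table")
    lineages = {
        tid: TaxonLineage.parse(tid, ls) for tid, ls in zip(taxon_ids, lineage_strings)
    }
    values.index.name = "sample_id"
    return AbundanceTable(data=values, lineages=lineages, mode="counts")


def write_feature_table(table: AbundanceTable, path) -> None:
    """Write a TSV with taxa in rows: taxon_id, taxonomy, then one column
    per sample."""
    out = table.data.T.copy()
    out.insert(0, "taxonomy", [table.lineages[t].to_string() for t in out.index])
    out.index.name = "taxon_id"
    float_format = None if table.mode == "counts" else "%.17g"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_metadata(path, var_types: Mapping[str, str] | None = None) -> ClinicalMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata TSV must have a 'sample_id' column")
    df = df.set_index("sample_id")
    types = dict(var_types or {})
    for name in df.columns:
        types.setdefault(name, TEMPLATE_VARIABLES.get(name, "continuous"))
    return ClinicalMetadata(data=df, var_types=types)


def write_metadata(meta: ClinicalMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transformations


def collapse_taxa(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts over taxa sharing the same name at ``rank``.

    Taxa unassigned at ``rank`` are dropped from the collapsed table (they
    remain usable at any higher rank where they are assigned).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.mode != "counts":
        raise ValueError("collapse_taxa requires counts mode")
    groups: dict[str, list[str]] = {}
    for tid in table.taxon_ids:
        name = table.lineages[tid].name_at(rank)
        if name == UNASSIGNED:
            continue
        groups.setdefault(name, []).append(tid)
    if not groups:
        raise ValueError(f"no taxa assigned at rank {rank!r}")
    data = pd.DataFrame(
        {name: table.data[cols].sum(axis=1) for name, cols in groups.items()},
        index=table.data.index,
    )
    lineages = {
        name: table.lineages[cols[0]].truncate(rank) for name, cols in groups.items()
    }
    return AbundanceTable(data=data, lineages=lineages, mode="counts")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample's row by its total; the result sums to 1 per row."""
    if table.mode == "relative":
        return table
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {zero.index.tolist()}")
    data = table.data.div(totals, axis=0)
    return AbundanceTable(data=data, lineages=dict(table.lineages), mode="relative")


def filter_rare(table: AbundanceTable, min_mean_relative: float = 0.001) -> AbundanceTable:
    """Drop taxa whose mean relative abundance across samples is strictly
    below ``min_mean_relative`` (the default 0.1%); ties at the threshold
    are kept.  Column order is preserved; mode is preserved."""
    if not (0 <= min_mean_relative < 1):
        raise ValueError("min_mean_relative must be in [0, 1)")
    rel = to_relative(table)
    means = rel.data.mean(axis=0)
    keep = [t for t in table.taxon_ids if means[t] >= min_mean_relative]
    data = table.data[keep]
    lineages = {t: table.lineages[t] for t in keep}
    if table.mode == "relative":
        # keep-set decided on the full composition; rows no longer sum to 1,
        # so return counts-free relative values renormalized per sample
        totals = data.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("a sample has zero abundance after filtering")
        data = data.div(totals, axis=0)
    return AbundanceTable(data=data, lineages=lineages, mode=table.mode)


# ---------------------------------------------------------------------------
# Clinical derivations

#: mg/dL -> mmol/L conversion for glucose
MGDL_PER_MMOL_GLUCOSE = 18.0


def derive_clinical(meta: ClinicalMetadata) -> ClinicalMetadata:
    """Add derived columns: BMI, FMI, FFMI (kg/m^2) and HOMA-IR.

    BMI-family indices divide a mass in kg by height squared in metres.
    HOMA-IR = FI [mU/L] x FPG [mmol/L] / 22.5, with FPG supplied in mg/dL
    and converted by /18.0.  Existing columns are left untouched.
    """
    df = meta.data.copy()
    types = dict(meta.var_types)

    if "height_cm" in df.columns:
        h = df["height_cm"].astype(float)
        if (h.dropna() <= 0).any():
            bad = df.index[h <= 0].tolist()
            raise ValueError(f"non-positive height for samples {bad[:5]}")
        h_m2 = (h / 100.0) ** 2
        for mass_col, out_col in (
            ("weight_kg", "bmi_kg_m2"),
            ("fm_kg", "fmi_kg_m2"),
            ("ffm_kg", "ffmi_kg_m2"),
        ):
            if mass_col in df.columns:
                df[out_col] = df[mass_col].astype(float) / h_m2
                types[out_col] = "continuous"

    if "fi_mu_l" in df.columns and "fpg_mg_dl" in df.columns:
        fi = df["fi_mu_l"].astype(float)
        fpg = df["fpg_mg_dl"].astype(float)
        if (fi.dropna() < 0).any() or (fpg.dropna() < 0).any():
            raise ValueError("negative fasting insulin or glucose")
        df["homa_ir"] = fi * (fpg / MGDL_PER_MMOL_GLUCOSE) / 22.5
        types["homa_ir"] = "continuous"

    return ClinicalMetadata(data=df, var_types=types)


def homa_ir(fi_mu_l: float, fpg_mg_dl: float) -> float:
    """HOMA-IR from fasting insulin (mU/L) and fasting glucose (mg/dL)."""
    if fi_mu_l < 0 or fpg_mg_dl < 0:
        raise ValueError("negative fasting insulin or glucose")
    return fi_mu_l * (fpg_mg_dl / MGDL_PER_MMOL_GLUCOSE) / 22.5
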