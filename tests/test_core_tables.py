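"""Data model, lineage parsing, collapsing, filtering, and clinical math."""

import numpy as np
import pandas as pd
import pytest

from microcohort.core_tables import (
    AbundanceTable,
    ClinicalMetadata,
    TaxonLineage,
    UNASSIGNED,
    collapse_taxa,
    derive_clinical,
    filter_rare,
    homa_ir,
    read_feature_table,
    to_relative,
    write_feature_table,
)

from conftest import make_table


class TestLineageParsing:
    def test_greengenes_prefixes(self):
        lin = TaxonLineage.parse(
            "t1", "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
            "f__Lactobacillaceae;g__Lactobacillus;s__"
        )
        assert lin.phylum == "Firmicutes"
        assert lin.genus == "Lactobacillus"
        assert lin.species == UNASSIGNED

    def test_plain_semicolon_silva_style(self):
        lin = TaxonLineage.parse(
            "t1", "Bacteria;Firmicutes;Bacilli;Lactobacillales;"
            "Lactobacillaceae;Lactobacillus"
        )
        assert lin.genus == "Lactobacillus"

    def test_truncated_at_family_leaves_genus_unassigned(self):
        lin = TaxonLineage.parse(
            "t1", "Bacteria;Firmicutes;Clostridia;Oscillospirales;Ruminococcaceae"
        )
        assert lin.family == "Ruminococcaceae"
        assert lin.genus == UNASSIGNED
        assert lin.species == UNASSIGNED

    def test_ambiguous_intermediate_gap_filled(self):
        lin = TaxonLineage.parse(
            "t1", "Bacteria;Firmicutes;uncultured;Oscillospirales;X;Y"
        )
        assert lin.phylum == "Firmicutes"
        # an uninformative middle token becomes an incertae-sedis
        # placeholder so the deeper assignment survives
        assert lin.class_ == "Firmicutes_incertae_sedis"
        assert lin.genus == "Y"

    def test_trailing_ambiguous_tokens_truncate(self):
        lin = TaxonLineage.parse("t1", "Bacteria;Firmicutes;uncultured")
        assert lin.phylum == "Firmicutes"
        assert lin.class_ == UNASSIGNED
        assert lin.genus == UNASSIGNED

    def test_unknown_rank_errors(self):
        lin = TaxonLineage.parse("t1", "Bacteria;Firmicutes")
        with pytest.raises(ValueError):
            lin.name_at("tribe")


class TestIO:
    def test_round_trip_counts_exact(self, tmp_path, random_counts_table):
        path = tmp_path / "table.tsv"
        write_feature_table(random_counts_table, path)
        back = read_feature_table(path)
        assert back.mode == "counts"
        pd.testing.assert_frame_equal(
            back.data.astype(float),
            random_counts_table.data.astype(float),
            check_names=False,
        )
        for t in random_counts_table.taxon_ids:
            assert back.lineages[t].genus == random_counts_table.lineages[t].genus

    def test_round_trip_relative_close(self, tmp_path, random_counts_table):
        rel = to_relative(random_counts_table)
        path = tmp_path / "rel.tsv"
        write_feature_table(rel, path)
        # relative tables are written at full precision; compare numerically
        raw = pd.read_csv(path, sep="\t", index_col=0)
        vals = raw.drop(columns=["taxonomy"]).T.to_numpy(float)
        np.testing.assert_allclose(vals, rel.values(), atol=1e-12)

    def test_toy_tsv_with_biom_header(self, tmp_path):
        text = (
            "#Constructed from biom file\n"
            "#OTU ID\ttaxonomy\ts1\ts2\n"
            "o1\tk__Bacteria;p__Firmicutes;g__Blautia\t3\t0\n"
            "o2\tk__Bacteria;p__Bacteroidetes;g__Prevotella\t1\t5\n"
            "o3\tk__Bacteria;p__Firmicutes\t2\t2\n"
        )
        path = tmp_path / "toy.tsv"
        path.write_text(text)
        table = read_feature_table(path)
        assert table.n_samples == 2 and table.n_taxa == 3
        assert table.data.loc["s2", "o2"] == 5
        assert table.lineages["o1"].genus == "Blautia"
        assert table.lineages["o3"].genus == UNASSIGNED

    def test_negative_counts_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("#OTU ID\ttaxonomy\ts1\no1\tk__B;p__F\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            read_feature_table(path)

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["s1", "s1"], columns=["a", "b"])
        lineages = {t: TaxonLineage.parse(t, "Bacteria;Firmicutes") for t in "ab"}
        with pytest.raises(ValueError, match="duplicate sample"):
            AbundanceTable(data=df, lineages=lineages, mode="counts")


class TestCollapse:
    def test_additivity_same_phylum(self):
        table = make_table([[3, 4]], phyla=["Firmicutes", "Firmicutes"])
        phylum = collapse_taxa(table, "phylum")
        assert phylum.data.loc["s0", "Firmicutes"] == 7

    def test_genus_unassigned_phylum_assigned_kept_at_phylum(self):
        lineages = {
            "o1": TaxonLineage.parse("o1", "Bacteria;Firmicutes;C;O;F;Blautia"),
            "o2": TaxonLineage.parse("o2", "Bacteria;Firmicutes"),
        }
        table = AbundanceTable(
            data=pd.DataFrame([[5, 2]], index=["s0"], columns=["o1", "o2"]),
            lineages=lineages,
            mode="counts",
        )
        assert collapse_taxa(table, "phylum").data.loc["s0", "Firmicutes"] == 7
        genus = collapse_taxa(table, "genus")
        assert list(genus.taxon_ids) == ["Blautia"]
        assert genus.data.loc["s0", "Blautia"] == 5

    def test_collapse_never_increases_sample_totals(self, rng):
        # oracle: direct per-sample summation before and after
        counts = rng.integers(0, 50, size=(8, 60))
        phyla = rng.choice(["Firmicutes", "Bacteroidetes", "Proteobacteria"], 60)
        table = make_table(counts, phyla=list(phyla))
        collapsed = collapse_taxa(table, "phylum")
        before = counts.sum(axis=1)
        after = collapsed.data.sum(axis=1).to_numpy()
        assert (after <= before).all()
        np.testing.assert_array_equal(after, before)  # all assigned here

    def test_unknown_rank_errors(self, random_counts_table):
        with pytest.raises(ValueError):
            collapse_taxa(random_counts_table, "superkingdom")


class TestRelativeAndFilter:
    def test_to_relative_examples(self):
        table = make_table([[2, 2], [1, 3]])
        rel = to_relative(table)
        np.testing.assert_allclose(rel.data.loc["s0"], [0.5, 0.5])
        np.testing.assert_allclose(rel.data.loc["s1"], [0.25, 0.75])

    def test_rows_sum_to_one(self, random_counts_table):
        rel = to_relative(random_counts_table)
        np.testing.assert_allclose(rel.data.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_sample_named_in_error(self):
        table = make_table([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            to_relative(table)

    def test_boundary_mean_abundance_kept(self):
        # taxa with mean relative abundance 0.0005 / 0.001 / ~0.9985
        n = 4
        col0 = np.full(n, 0.0005)
        col1 = np.full(n, 0.0010)
        col2 = 1 - col0 - col1
        table = make_table(np.column_stack([col0, col1, col2]), mode="relative")
        kept = filter_rare(table, 0.001)
        assert kept.taxon_ids == ["g1", "g2"]

    def test_threshold_zero_keeps_everything(self, random_counts_table):
        assert (
            filter_rare(random_counts_table, 0.0).taxon_ids
            == random_counts_table.taxon_ids
        )

    def test_kept_set_matches_bruteforce_means(self, rng):
        counts = rng.integers(0, 30, size=(10, 20))
        counts[:, 0] += 1
        table = make_table(counts)
        thr = 0.02
        kept = filter_rare(table, thr).taxon_ids
        rel = counts / counts.sum(axis=1, keepdims=True)
        expected = [f"g{j}" for j in range(20) if rel[:, j].mean() >= thr]
        assert kept == expected

    def test_filter_idempotent(self, random_counts_table):
        once = filter_rare(random_counts_table, 0.01)
        twice = filter_rare(once, 0.01)
        assert once.taxon_ids == twice.taxon_ids
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_invalid_threshold(self, random_counts_table):
        with pytest.raises(ValueError):
            filter_rare(random_counts_table, 1.0)

    def test_collapse_then_relative_commutes(self, rng):
        counts = rng.integers(0, 40, size=(6, 30))
        counts[:, 0] += 1
        phyla = list(rng.choice(["Firmicutes", "Bacteroidetes"], 30))
        table = make_table(counts, phyla=phyla)
        a = to_relative(collapse_taxa(table, "phylum")).data
        rel = to_relative(table).data
        groups = {}
        for j, p in enumerate(phyla):
            groups.setdefault(p, []).append(f"g{j}")
        b = pd.DataFrame({p: rel[cols].sum(axis=1) for p, cols in groups.items()})
        np.testing.assert_allclose(
            a.to_numpy(), b[a.columns].to_numpy(), atol=1e-12
        )


class TestClinicalDerivations:
    def _meta(self, **cols):
        df = pd.DataFrame(cols, index=["s1"])
        return ClinicalMetadata(data=df)

    def test_homa_ir_worked_example(self):
        # mean fasting insulin 14.5 mU/L, glucose 82.6 mg/dL
        value = homa_ir(14.5, 82.6)
        assert value == pytest.approx(14.5 * (82.6 / 18.0) / 22.5)
        assert round(value, 1) == 3.0

    def test_homa_ir_zero_insulin(self):
        assert homa_ir(0.0, 90.0) == 0.0

    def test_fmi_direct_formula(self):
        meta = self._meta(height_cm=150.0, fm_kg=29.0)
        out = derive_clinical(meta)
        assert out.data.loc["s1", "fmi_kg_m2"] == pytest.approx(29.0 / 1.5**2)

    def test_derive_adds_columns_keeps_existing(self):
        meta = self._meta(
            height_cm=150.0, weight_kg=60.0, fm_kg=25.0, ffm_kg=35.0,
            fi_mu_l=10.0, fpg_mg_dl=90.0, age_yr=11.0,
        )
        out = derive_clinical(meta)
        for col in ("bmi_kg_m2", "fmi_kg_m2", "ffmi_kg_m2", "homa_ir"):
            assert col in out.data.columns
        assert out.data.loc["s1", "age_yr"] == 11.0
        assert out.data.loc["s1", "bmi_kg_m2"] == pytest.approx(60.0 / 2.25)

    def test_nonpositive_height_errors(self):
        with pytest.raises(ValueError, match="height"):
            derive_clinical(self._meta(height_cm=0.0, weight_kg=50.0))

    def test_negative_insulin_errors(self):
        with pytest.raises(ValueError):
            derive_clinical(self._meta(fi_mu_l=-1.0, fpg_mg_dl=80.0))
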