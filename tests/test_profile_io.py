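"""Profile parsing, cohort filters, and age-quartile assignment."""

import numpy as np
import pandas as pd
import pytest

from vulvasig.profile_io import (
    EnzymeTable,
    ProfileParseError,
    SampleMeta,
    TaxonTable,
    assign_age_quartiles,
    filter_enzymes,
    filter_low_abundance_species,
    filter_low_read_samples,
    read_taxon_table,
    write_table,
)


def make_meta(ages=None, read_counts=None, statuses=None):
    n = len(next(x for x in (ages, read_counts, statuses) if x is not None))
    ids = [f"s{i}" for i in range(n)]
    return SampleMeta(
        pd.DataFrame(
            {
                "age": ages if ages is not None else [40] * n,
                "cohort": ["TNO"] * n,
                "status": statuses if statuses is not None else ["healthy"] * n,
                "read_count": read_counts if read_counts is not None else [50_000] * n,
            },
            index=ids,
        )
    )


class TestReadTaxonTable:
    def test_metaphlan_species_rows_only(self, metaphlan_file):
        table = read_taxon_table(metaphlan_file, dialect="metaphlan_merged")
        # kingdom/phylum/genus summaries and the t__ strain row are dropped
        assert len(table.feature_ids) == 5
        assert table.unit == "relabund"

    def test_metaphlan_rescales_percent_to_fraction(self, metaphlan_file):
        table = read_taxon_table(metaphlan_file, dialect="metaphlan_merged")
        assert table.values.loc["S1", "Staphylococcus epidermidis"] == pytest.approx(0.125)
        assert table.genus_of["Staphylococcus epidermidis"] == "Staphylococcus"

    def test_plain_matrix_preserves_counts(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "species\tA\tB\nEscherichia coli\t3\t0\nFinegoldia magna\t1\t5\n"
            "Lactobacillus iners\t2\t2\n"
        )
        table = read_taxon_table(path, dialect="plain_matrix")
        assert table.unit == "count"
        assert table.values.sum(axis=1).tolist() == [6.0, 7.0]

    def test_unparseable_clade_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("clade\tA\nk__Bacteria|s__nounderscore\t1.0\n")
        with pytest.raises(ProfileParseError, match="line 2"):
            read_taxon_table(path, dialect="metaphlan_merged")

    def test_duplicate_species_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "clade\tA\nk__B|s__Finegoldia_magna\t1.0\nk__X|s__Finegoldia_magna\t2.0\n"
        )
        with pytest.raises(ProfileParseError, match="duplicate species"):
            read_taxon_table(path, dialect="metaphlan_merged")

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("clade\tA\nk__B|s__Finegoldia_magna\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            read_taxon_table(path, dialect="metaphlan_merged")

    def test_round_trip(self, tmp_path, small_cohort):
        taxa, _, _ = small_cohort
        path = tmp_path / "rt.tsv"
        taxa.values.T.to_csv(path, sep="\t", index_label="species")
        again = read_taxon_table(path, dialect="plain_matrix")
        assert list(again.feature_ids) == list(taxa.feature_ids)
        assert list(again.sample_ids) == list(taxa.sample_ids)
        np.testing.assert_allclose(
            again.values.to_numpy(), taxa.values.to_numpy(), atol=1e-12
        )

    def test_write_table_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {"x": [0.123456789012, 1e-7], "y": [3.0, 4.5]}, index=["a", "b"]
        )
        path = tmp_path / "w.tsv"
        write_table(frame, path)
        again = pd.read_csv(path, sep="\t", index_col=0)
        np.testing.assert_allclose(again.to_numpy(), frame.to_numpy(), rtol=1e-11)


class TestFilterLowReadSamples:
    def test_threshold_rule(self):
        meta = make_meta(read_counts=[15_000, 25_000])
        kept, report = filter_low_read_samples(meta, 20_000)
        assert kept.sample_ids == ["s1"]
        assert report.index.tolist() == ["s0"]
        assert report["value"].tolist() == [15_000]

    def test_boundary_inclusive(self):
        meta = make_meta(read_counts=[20_000, 20_001])
        kept, _ = filter_low_read_samples(meta, 20_000)
        assert kept.sample_ids == ["s1"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 40_001, size=100)
        meta = make_meta(read_counts=counts)
        kept, report = filter_low_read_samples(meta, 20_000)
        expected = [f"s{i}" for i, c in enumerate(counts) if c > 20_000]
        assert kept.sample_ids == expected
        assert len(report) == 100 - len(expected)

    def test_idempotent(self):
        meta = make_meta(read_counts=[10_000, 30_000, 50_000])
        once, _ = filter_low_read_samples(meta)
        twice, report = filter_low_read_samples(once)
        assert twice.sample_ids == once.sample_ids
        assert report.empty


class TestFilterLowAbundanceSpecies:
    def test_species_below_share_removed(self):
        values = pd.DataFrame(
            {"X": [2.0, 2.0], "Y": [4998.0, 4998.0]}, index=["a", "b"]
        )  # X share = 4/10000 = 0.0004
        table = TaxonTable(values=values, unit="count")
        out = filter_low_abundance_species(table, 0.0005)
        assert out.feature_ids == ["Y"]

    def test_boundary_share_retained(self):
        values = pd.DataFrame({"X": [5.0], "Y": [9995.0]}, index=["a"])
        out = filter_low_abundance_species(TaxonTable(values=values), 0.0005)
        assert out.feature_ids == ["X", "Y"]

    def test_no_renormalization(self):
        values = pd.DataFrame({"X": [1.0], "Y": [9999.0]}, index=["a"])
        out = filter_low_abundance_species(TaxonTable(values=values), 0.0005)
        assert out.values.loc["a"].sum() == 9999.0

    def test_matches_brute_force_shares(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.poisson(3.0, size=(50, 200)).astype(float),
            index=[f"s{i}" for i in range(50)],
            columns=[f"sp{j}" for j in range(200)],
        )
        out = filter_low_abundance_species(TaxonTable(values=values), 0.004)
        grand = values.to_numpy().sum()
        expected = [c for c in values.columns if values[c].sum() / grand >= 0.004]
        assert out.feature_ids == expected

    def test_all_zero_table_errors(self):
        values = pd.DataFrame({"X": [0.0], "Y": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="all-zero"):
            filter_low_abundance_species(TaxonTable(values=values))

    def test_idempotent(self, small_cohort):
        taxa, _, _ = small_cohort
        once = filter_low_abundance_species(taxa, 0.001)
        twice = filter_low_abundance_species(once, 0.001)
        assert twice.feature_ids == once.feature_ids


class TestFilterEnzymes:
    def test_low_prevalence_removed(self):
        values = pd.DataFrame(0.0, index=[f"s{i}" for i in range(30)], columns=["E1", "E2"])
        values.iloc[:2, 0] = 1.0       # 2/30 < 10%
        values.iloc[:10, 1] = 1.0      # 10/30 >= 10%
        out = filter_enzymes(EnzymeTable(values), 0.10)
        assert out.feature_ids == ["E2"]

    def test_duplicate_ec_ids_summed(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["EC 4.2.1.19", "EC 4.2.1.19"]
        )
        out = filter_enzymes(EnzymeTable(values), 0.0)
        assert out.feature_ids == ["EC 4.2.1.19"]
        assert out.values["EC 4.2.1.19"].tolist() == [3.0, 7.0]

    def test_identical_vectors_deduplicated_first_kept(self):
        values = pd.DataFrame(
            {"EC 2": [1.0, 2.0], "EC 1": [1.0, 2.0], "EC 3": [5.0, 6.0]},
            index=["a", "b"],
        )
        out = filter_enzymes(EnzymeTable(values), 0.0)
        # lexicographically first duplicate survives
        assert sorted(out.feature_ids) == ["EC 1", "EC 3"]

    def test_matches_brute_force_prevalence(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.random((40, 100)) * (rng.random((40, 100)) > 0.7),
            index=[f"s{i}" for i in range(40)],
            columns=[f"E{j:03d}" for j in range(100)],
        )
        out = filter_enzymes(EnzymeTable(values), 0.10)
        expected = [c for c in values.columns if (values[c] > 0).sum() / 40 >= 0.10]
        assert out.feature_ids == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.random((20, 30)) * (rng.random((20, 30)) > 0.5),
            index=[f"s{i}" for i in range(20)],
            columns=[f"E{j}" for j in range(30)],
        )
        once = filter_enzymes(EnzymeTable(values))
        twice = filter_enzymes(once)
        assert twice.feature_ids == once.feature_ids


class TestAssignAgeQuartiles:
    def test_even_split_distinct_ages(self):
        meta = make_meta(ages=[21, 25, 31, 40, 52, 60, 65, 80])
        out = assign_age_quartiles(meta)
        q = out.table.sort_values("age")["age_quartile"].tolist()
        assert q == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_tie_moves_to_younger_quartile(self):
        meta = make_meta(ages=[30, 30, 30, 40, 50, 60, 70, 80])
        out = assign_age_quartiles(meta)
        table = out.table
        assert set(table.loc[table["age"] == 30, "age_quartile"]) == {"Q1"}
        # later quartiles rebalance over the remaining five samples
        assert table.loc[table["age"] == 40, "age_quartile"].iloc[0] == "Q2"
        assert table.loc[table["age"] == 50, "age_quartile"].iloc[0] == "Q2"
        assert table.loc[table["age"] == 60, "age_quartile"].iloc[0] == "Q3"
        assert table.loc[table["age"] == 80, "age_quartile"].iloc[0] == "Q4"

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(4)
        ages = rng.integers(22, 83, size=58)
        out = assign_age_quartiles(make_meta(ages=ages))

        # independent oracle: same rule, written differently (recursive
        # even split of whatever is still unassigned, ties pulled younger)
        order = sorted(range(58), key=lambda i: (ages[i], i))
        labels = {}

        def fill(start, quartile):
            if quartile == 4 or start >= 58:
                return
            remaining = 58 - start
            size = int(np.ceil(remaining / (4 - quartile)))
            end = 58 if quartile == 3 else start + size
            while end < 58 and ages[order[end]] == ages[order[end - 1]]:
                end += 1
            for i in order[start:end]:
                labels[i] = quartile
            fill(end, quartile + 1)

        fill(0, 0)
        expected = {f"s{i}": f"Q{labels[i] + 1}" for i in range(58)}
        got = out.table["age_quartile"].to_dict()
        assert got == expected

    def test_quartile_max_ages_monotone(self):
        rng = np.random.default_rng(5)
        ages = rng.integers(22, 83, size=58)
        out = assign_age_quartiles(make_meta(ages=ages))
        maxima = out.table.groupby("age_quartile")["age"].max()
        assert list(maxima.index) == ["Q1", "Q2", "Q3", "Q4"]
        assert maxima.is_monotonic_increasing

    def test_total_partition_never_splits_an_age(self):
        rng = np.random.default_rng(6)
        ages = rng.integers(30, 40, size=40)  # heavy ties
        out = assign_age_quartiles(make_meta(ages=ages))
        assert out.table["age_quartile"].notna().all()
        per_age = out.table.groupby("age")["age_quartile"].nunique()
        assert (per_age == 1).all()

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_age_quartiles(make_meta(ages=[30, 40, 50]))


class TestMetaValidation:
    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError, match="status"):
            make_meta(ages=[30, 40], statuses=["healthy", "sick"])

    def test_duplicate_sample_ids_rejected(self):
        frame = pd.DataFrame(
            {"age": [30, 40], "cohort": ["TNO"] * 2, "status": ["healthy"] * 2,
             "read_count": [1, 1]},
            index=["dup", "dup"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            SampleMeta(frame)
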