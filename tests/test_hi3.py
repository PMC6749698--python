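"""Hi3 quantification: normalization, top-3 rule, filters, fractions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prsascreen import hi3
from prsascreen.synthetic import ProteomeTruth, SimulationConfig, generate_peptide_table

from oracles import hi3_pipeline_oracle


def make_records(intensities, protein="P1", strain="A", rep="rep1", modified=False):
    return pd.DataFrame(
        {
            "protein_id": protein,
            "peptide_seq": [f"PEP{i}K" for i in range(len(intensities))],
            "is_modified": modified,
            "strain_id": strain,
            "replicate_id": rep,
            "intensity": intensities,
        }
    )


class TestFilters:
    def test_unmodified_table_unchanged(self):
        records = make_records([10.0, 20.0])
        assert hi3.filter_modified(records).equals(records)

    def test_all_modified_yields_nothing_quantifiable(self):
        records = make_records([10.0, 20.0, 30.0], modified=True)
        out = hi3.run_pipeline(records)
        assert out.empty

    def test_surviving_count_matches_generator_manifest(self):
        truth = [ProteomeTruth(f"P{i}", 5, 100.0, {"A": 1.0}) for i in range(8)]
        cfg = SimulationConfig(missing_rate=0.0, modified_fraction=0.4, seed=21)
        table, manifest = generate_peptide_table(truth, cfg)
        surviving = hi3.filter_modified(table)
        expected = (~manifest["peptides"]["is_modified"]).sum() * cfg.n_replicates
        assert len(surviving) == expected

    def test_zero_intensity_counts_as_unreported(self):
        records = make_records([10.0, 0.0, 30.0, 40.0])
        normalized = hi3.median_normalize(records)
        assert len(normalized) == 3  # zero row dropped
        assert np.median(normalized["norm_intensity"]) == 1.0


class TestMedianNormalize:
    def test_even_count_median_is_mean_of_middle_two(self):
        records = make_records([10.0, 20.0, 30.0, 40.0])
        normalized = hi3.median_normalize(records)
        assert sorted(normalized["norm_intensity"]) == [0.4, 0.8, 1.2, 1.6]

    def test_single_intensity_normalizes_to_one(self):
        normalized = hi3.median_normalize(make_records([123.4]))
        assert normalized["norm_intensity"].tolist() == [1.0]

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance_within_replicate(self, scale):
        records = make_records([5.0, 7.0, 11.0, 13.0, 17.0])
        scaled = records.assign(intensity=records["intensity"] * scale)
        a = hi3.median_normalize(records)["norm_intensity"].to_numpy()
        b = hi3.median_normalize(scaled)["norm_intensity"].to_numpy()
        assert np.allclose(a, b, rtol=1e-12)


class TestHi3Values:
    def test_top_three_of_four(self):
        normalized = hi3.median_normalize(make_records([10.0, 20.0, 30.0, 40.0]))
        out = hi3.hi3_per_replicate(normalized)
        assert out["hi3"].tolist() == [pytest.approx(0.8 + 1.2 + 1.6)]

    def test_exactly_three_equal_peptides(self):
        normalized = make_records([1.0, 1.0, 1.0]).assign(norm_intensity=1.0)
        out = hi3.hi3_per_replicate(normalized)
        assert out["hi3"].tolist() == [3.0]

    def test_two_peptides_yield_no_value(self):
        normalized = hi3.median_normalize(make_records([10.0, 20.0]))
        assert hi3.hi3_per_replicate(normalized).empty

    def test_ties_at_third_place_sum_by_value(self):
        normalized = make_records([2.0, 2.0, 2.0, 2.0]).assign(norm_intensity=2.0)
        out = hi3.hi3_per_replicate(normalized)
        assert out["hi3"].tolist() == [6.0]


class TestReplicateFilter:
    @pytest.mark.parametrize("n_present,quantifiable", [(3, True), (2, True), (1, False)])
    def test_two_of_three_rule(self, n_present, quantifiable):
        quants = pd.DataFrame(
            {
                "strain_id": "A",
                "replicate_id": [f"rep{i + 1}" for i in range(n_present)],
                "protein_id": "P1",
                "hi3": 1.0,
            }
        )
        out = hi3.replicate_filter(quants, n_replicates=3)
        assert out["quantifiable"].all() == quantifiable

    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 2), (4, 3), (6, 4), (9, 6)])
    def test_generalized_threshold_is_ceil_two_thirds(self, n, expected):
        assert hi3.default_min_present(n) == expected


class TestRelativeAbundance:
    def test_single_protein_takes_full_fraction(self):
        records = make_records([10.0, 20.0, 30.0])
        out = hi3.run_pipeline(records, n_replicates=1, min_present=1)
        assert out["fraction"].tolist() == [1.0]

    def test_equal_proteins_split_evenly(self):
        a = make_records([10.0, 20.0, 30.0], protein="P1")
        b = make_records([10.0, 20.0, 30.0], protein="P2")
        out = hi3.run_pipeline(pd.concat([a, b]), n_replicates=1, min_present=1)
        assert out["fraction"].tolist() == [0.5, 0.5]

    def test_fractions_sum_to_one_per_replicate(self, rng):
        truth = [
            ProteomeTruth(f"P{i}", int(rng.integers(3, 7)), float(rng.uniform(10, 500)), {"A": 1.0})
            for i in range(12)
        ]
        table, _ = generate_peptide_table(truth, SimulationConfig(seed=5))
        out = hi3.run_pipeline(table, n_replicates=3)
        sums = out.groupby(["strain_id", "replicate_id"])["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unquantifiable_target_reports_absent_not_zero(self):
        records = make_records([10.0, 20.0, 30.0])
        quants = hi3.replicate_filter(
            hi3.hi3_per_replicate(hi3.median_normalize(records)), n_replicates=3
        )
        result = hi3.relative_abundance(quants, "P1", "A")
        assert not result.quantifiable
        assert math.isnan(result.mean)

    def test_monotonicity_in_target_intensity(self):
        base = pd.concat(
            [
                make_records([10.0, 20.0, 30.0], protein="P1"),
                make_records([15.0, 25.0, 35.0], protein="P2"),
            ]
        )
        boosted = base.copy()
        mask = boosted["protein_id"] == "P1"
        boosted.loc[mask, "intensity"] *= 3.0
        f0 = hi3.run_pipeline(base, n_replicates=1, min_present=1)
        f1 = hi3.run_pipeline(boosted, n_replicates=1, min_present=1)
        get = lambda df: df.loc[df["protein_id"] == "P1", "fraction"].iloc[0]
        assert get(f1) >= get(f0)

    def test_mode_switch_ratio_of_means(self):
        a = make_records([10.0, 20.0, 30.0], rep="rep1")
        b = make_records([12.0, 22.0, 28.0], rep="rep2")
        quants = hi3.replicate_filter(
            hi3.hi3_per_replicate(hi3.median_normalize(pd.concat([a, b]))),
            n_replicates=2,
        )
        r1 = hi3.relative_abundance(quants, "P1", "A", mode="per_replicate")
        r2 = hi3.relative_abundance(quants, "P1", "A", mode="ratio_of_means")
        assert r1.mean == pytest.approx(1.0) and r2.mean == pytest.approx(1.0)


class TestFoldChange:
    def test_identical_strains_give_unity(self):
        truth = [ProteomeTruth(f"P{i}", 4, 100.0, {"A": 1.0, "B": 1.0}) for i in range(5)]
        table, _ = generate_peptide_table(
            truth, SimulationConfig(intensity_cv=0, missing_rate=0, modified_fraction=0, seed=1)
        )
        out = hi3.run_pipeline(table, n_replicates=3)
        ra = hi3.relative_abundance(out, "P0", "A")
        rb = hi3.relative_abundance(out, "P0", "B")
        ratio, _ = hi3.strain_fold_change(ra, rb)
        assert ratio == pytest.approx(1.0)

    def test_replicate_scale_invariance_of_full_pipeline(self):
        truth = [ProteomeTruth(f"P{i}", 4, 100.0, {"A": 1.0}) for i in range(4)]
        table, _ = generate_peptide_table(truth, SimulationConfig(seed=8))
        scaled = table.copy()
        mask = scaled["replicate_id"] == "rep2"
        scaled.loc[mask, "intensity"] *= 37.5
        f0 = hi3.run_pipeline(table, n_replicates=3).sort_values(
            ["protein_id", "replicate_id"]
        )
        f1 = hi3.run_pipeline(scaled, n_replicates=3).sort_values(
            ["protein_id", "replicate_id"]
        )
        assert np.allclose(f0["hi3"], f1["hi3"], rtol=1e-12)
        assert np.allclose(f0["fraction"], f1["fraction"], rtol=1e-12)


class TestOracleEquivalence:
    def test_pipeline_matches_bruteforce_on_small_tables(self, rng):
        from conftest import random_peptide_rows

        for _ in range(25):
            rows = random_peptide_rows(rng)
            table = pd.DataFrame(rows)
            out = hi3.run_pipeline(table, n_replicates=3)
            _, fractions = hi3_pipeline_oracle(rows, n_replicates=3)
            got = {
                (r.strain_id, r.replicate_id, r.protein_id): r.fraction
                for r in out.itertuples()
                if not pd.isna(r.fraction)
            }
            assert set(got) == set(fractions)
            for key, value in fractions.items():
                assert got[key] == pytest.approx(value, abs=1e-9)


class TestSearchEngineShim:
    def test_wide_table_maps_onto_dialect(self):
        wide = pd.DataFrame(
            {
                "Sequence": ["AAAK", "CCCR"],
                "Proteins": ["P1;P9", "P2"],
                "Modifications": ["Unmodified", "Oxidation (M)"],
                "Intensity s1": [100.0, 0.0],
                "Intensity s2": [110.0, 55.0],
            }
        )
        out = hi3.from_search_engine(
            wide, {"s1": ("A", "rep1"), "s2": ("A", "rep2")}
        )
        assert set(out["protein_id"]) == {"P1", "P2"}
        assert out.loc[out["peptide_seq"] == "CCCR", "is_modified"].all()
        # zero intensity dropped
        assert len(out.loc[(out["peptide_seq"] == "CCCR")]) == 1
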