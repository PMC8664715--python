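"""Pooling, ranking, top-table cuts, and dose-bipartite flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosecmap import (ParameterError, dose_band, flag_bipartite,
                      pool_duplicates, top_tables)


def results_df(rows):
    """rows: (drug, dose, score, p, zstat, combined)"""
    return pd.DataFrame(rows, columns=["drug_id", "dose_um", "score", "p",
                                       "zstat", "combined"])


class TestDoseBand:
    def test_boundary(self):
        assert dose_band(3.3, 5.0) == "low"
        assert dose_band(10.0, 5.0) == "high"
        assert dose_band(5.0, 5.0) == "high"

    def test_bad_boundary(self):
        with pytest.raises(ParameterError):
            dose_band(1.0, 0.0)


class TestPoolDuplicates:
    def test_mean_of_duplicates(self):
        df = results_df([("D", 1.0, 0.1, 0.5, 1.0, 0.2),
                         ("D", 1.0, 0.3, 0.5, 2.0, 0.4)])
        out = pool_duplicates(df, group_by="drug")
        assert out.mean_combined.iloc[0] == pytest.approx(0.3)
        assert out.n_conditions.iloc[0] == 2

    def test_dose_banding_splits_conditions(self):
        df = results_df([("LY", 3.3, 0.2, 0.1, 1.0, 1.0),
                         ("LY", 0.37, 0.2, 0.1, 1.0, 1.0),
                         ("LY", 10.0, -0.2, 0.1, -1.0, -1.0)])
        out = pool_duplicates(df, "drug_dose_band", dose_boundary=5.0)
        bands = dict(zip(out.dose_band, out.n_conditions))
        assert bands == {"low": 2, "high": 1}

    def test_fisher_pooled_p(self):
        df = results_df([("D", 1.0, 0.1, 0.05, 1.0, 0.2),
                         ("D", 1.0, 0.1, 0.05, 1.0, 0.2)])
        out = pool_duplicates(df, group_by="drug")
        stat = -2 * 2 * np.log(0.05)
        assert stat == pytest.approx(11.983, abs=1e-3)
        assert out.pooled_p.iloc[0] == pytest.approx(
            stats.chi2.sf(stat, 4), rel=1e-12)
        assert out.pooled_p.iloc[0] == pytest.approx(0.0175, abs=2e-4)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        df = results_df([(f"D{i % 5}", float(rng.choice([1, 10])),
                          float(rng.normal()), float(rng.uniform(0.01, 1)),
                          float(rng.normal()), float(rng.normal()))
                         for i in range(40)])
        a = pool_duplicates(df)
        b = pool_duplicates(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_group_means_conserve_global_mean(self):
        rng = np.random.default_rng(5)
        df = results_df([(f"D{i % 7}", 1.0, rng.normal(),
                          float(rng.uniform(0.01, 1)), rng.normal(),
                          rng.normal()) for i in range(70)])
        out = pool_duplicates(df, group_by="drug")
        weighted = (out.mean_combined * out.n_conditions).sum() / \
            out.n_conditions.sum()
        assert weighted == pytest.approx(df.combined.mean(), abs=1e-12)

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(6)
        df = results_df([(f"D{i}", 1.0, 0.0, 0.5, 0.0, rng.normal())
                         for i in range(20)])
        out = pool_duplicates(df)
        assert sorted(out["rank"]) == list(range(1, 21))
        assert out.mean_combined.is_monotonic_decreasing

    def test_nonfinite_rejected(self):
        df = results_df([("D", 1.0, np.nan, 0.5, 0.0, 0.0)])
        with pytest.raises(ParameterError):
            pool_duplicates(df)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            pool_duplicates(results_df([]))


class TestTopTables:
    def test_sign_gate_keeps_tables_pure(self):
        rng = np.random.default_rng(7)
        df = results_df([(f"D{i}", 1.0, 0.0, 0.5, 0.0,
                          float(abs(rng.normal()) + 0.1)) for i in range(10)])
        table = pool_duplicates(df)
        pro, anti = top_tables(table, k_pro=25, k_anti=15)
        assert len(pro) == 10 and anti.empty

    def test_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(8)
        df = results_df([(f"D{i:02d}", 1.0, 0.0, float(rng.uniform(0.01, 1)),
                          0.0, float(rng.normal())) for i in range(50)])
        table = pool_duplicates(df)
        pro, anti = top_tables(table, k_pro=5, k_anti=5)
        pos = table[table.mean_combined > 0].sort_values(
            "mean_combined", ascending=False)
        neg = table[table.mean_combined < 0].sort_values("mean_combined")
        assert list(pro.drug_id) == list(pos.drug_id[:5])
        assert list(anti.drug_id) == list(neg.drug_id[:5])
        assert not (set(zip(pro.drug_id, pro.dose_band))
                    & set(zip(anti.drug_id, anti.dose_band)))

    def test_zero_combined_excluded(self):
        df = results_df([("D0", 1.0, 0.0, 1.0, 0.0, 0.0)])
        pro, anti = top_tables(pool_duplicates(df), 5, 5)
        assert pro.empty and anti.empty


class TestFlagBipartite:
    def _tables(self, rows):
        df = results_df(rows)
        table = pool_duplicates(df, "drug_dose_band", 5.0)
        pro, anti = top_tables(table, 25, 15)
        return pro, anti, table

    def test_dose_flip_drug_flagged(self):
        pro, anti, table = self._tables(
            [("FLIP", 1.0, 0.5, 0.01, 3.0, 6.0),
             ("FLIP", 10.0, -0.5, 0.01, -3.0, -6.0),
             ("OTHER", 1.0, 0.2, 0.1, 1.0, 1.0)])
        flags = {f.drug_id: f for f in flag_bipartite(pro, anti, table)}
        assert flags["FLIP"].is_bipartite
        assert flags["FLIP"].orientation == "low_pro_high_anti"
        assert not flags["OTHER"].is_bipartite

    def test_reverse_orientation_flagged(self):
        pro, anti, table = self._tables(
            [("REV", 10.0, 0.5, 0.01, 3.0, 6.0),
             ("REV", 1.0, -0.5, 0.01, -3.0, -6.0)])
        flags = {f.drug_id: f for f in flag_bipartite(pro, anti, table)}
        assert flags["REV"].is_bipartite
        assert flags["REV"].orientation == "high_pro_low_anti"

    def test_monotone_pro_drug_not_flagged(self):
        pro, anti, table = self._tables(
            [("MONO", 1.0, 0.5, 0.01, 3.0, 6.0),
             ("MONO", 10.0, 0.5, 0.01, 3.0, 6.0)])
        flags = flag_bipartite(pro, anti, table)
        assert not any(f.is_bipartite for f in flags)

    def test_empty_anti_table_means_no_flags(self):
        pro, anti, table = self._tables(
            [("A", 1.0, 0.5, 0.01, 3.0, 6.0),
             ("B", 10.0, 0.5, 0.01, 3.0, 6.0)])
        assert anti.empty
        assert not any(f.is_bipartite
                       for f in flag_bipartite(pro, anti, table))

    def test_unbanded_tables_rejected(self):
        df = results_df([("D", 1.0, 0.1, 0.5, 1.0, 0.5)])
        table = pool_duplicates(df, group_by="drug")
        with pytest.raises(ParameterError):
            flag_bipartite(table, table, table)
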