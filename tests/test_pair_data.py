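"""Pair-table IO, residualization, and standardization."""

import numpy as np
import pandas as pd
import pytest

from twinprs import (SimConfig, average_hemispheres, read_pair_table,
                     residualize, simulate_pairs, standardize_prs,
                     write_pair_table)
from twinprs.pair_data import (GroupLabelError, SchemaError, VariableSchema,
                               default_schema)


def small_schema():
    return VariableSchema(roi_names=("hippocampus",), prs_names=("hip_prs",),
                          covariate_names=("age",))


def write_csv(tmp_path, text, name="pairs.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = ("family_id,group,hippocampus_t1,hippocampus_t2,"
          "hip_prs_t1,hip_prs_t2,age_t1,age_t2\n")


class TestReadPairTable:
    def test_group_counts(self, tmp_path):
        path = write_csv(tmp_path, HEADER +
                         "f1,MZ,1,2,0.1,0.1,10,10\n"
                         "f2,dz,3,4,0.2,0.3,9,9\n"
                         "f3,Sib,5,6,0.4,0.5,11,9\n")
        data = read_pair_table(path, small_schema())
        assert data.group_counts() == {"MZ": 1, "DZ": 1, "SIB": 1}

    def test_sentinel_becomes_missing(self, tmp_path):
        path = write_csv(tmp_path, HEADER + "f1,MZ,1,NA,0.1,0.1,10,10\n")
        data = read_pair_table(path, small_schema())
        row = data.table.iloc[0]
        assert np.isnan(row["hippocampus_t2"])
        assert np.isfinite(row["hippocampus_t1"])
        assert np.isfinite(row["hip_prs_t2"])

    def test_bad_group_label_cites_row(self, tmp_path):
        path = write_csv(tmp_path, HEADER + "f1,XZ,1,2,0.1,0.1,10,10\n")
        with pytest.raises(GroupLabelError, match="row 1"):
            read_pair_table(path, small_schema())

    def test_missing_column_named(self, tmp_path):
        path = write_csv(tmp_path,
                         "family_id,group,hippocampus_t1\nf1,MZ,1\n")
        with pytest.raises(SchemaError, match="hippocampus_t2"):
            read_pair_table(path, small_schema())

    def test_duplicate_family_id(self, tmp_path):
        path = write_csv(tmp_path, HEADER +
                         "f1,MZ,1,2,0.1,0.1,10,10\nf1,DZ,3,4,0,0,9,9\n")
        with pytest.raises(SchemaError, match="f1"):
            read_pair_table(path, small_schema())

    def test_roundtrip_exact(self, tmp_path):
        data, _ = simulate_pairs(SimConfig(n_mz=5, n_dz=5, n_sib=5, seed=7,
                                           missing_rate=0.2))
        path = tmp_path / "rt.csv"
        write_pair_table(data, path)
        back = read_pair_table(path, data.schema)
        cols = data.schema.member_columns(data.schema.variables)
        a = data.table[cols].to_numpy()
        b = back.table[cols].to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b))
        # CSV text round trip: values agree to full float precision
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_tsv_delimiter(self, tmp_path):
        path = write_csv(tmp_path, HEADER.replace(",", "\t") +
                         "f1\tMZ\t1\t2\t0.1\t0.1\t10\t10\n", name="pairs.tsv")
        assert len(read_pair_table(path, small_schema())) == 1


class TestResidualize:
    def test_orthogonality_and_idempotence(self):
        data, _ = simulate_pairs(SimConfig(n_mz=100, n_dz=100, n_sib=100, seed=1))
        covs = ["age", "sex", "icv"]
        out = residualize(data, "roi", covs)
        long = out.stacked_individuals(["roi"] + covs).dropna()
        for c in covs:
            assert abs(np.corrcoef(long["roi"], long[c])[0, 1]) < 1e-10
        again = residualize(out, "roi", covs)
        np.testing.assert_allclose(
            out.member_matrix(["roi"]), again.member_matrix(["roi"]), atol=1e-10)

    def test_no_covariates_centers(self):
        data, _ = simulate_pairs(SimConfig(n_mz=50, n_dz=0, n_sib=0, seed=2))
        out = residualize(data, "roi", [])
        vals = out.member_matrix(["roi"]).ravel()
        raw = data.member_matrix(["roi"]).ravel()
        assert abs(vals.mean()) < 1e-10
        np.testing.assert_allclose(vals, raw - raw.mean(), atol=1e-10)

    def test_recovers_generator_noise(self):
        # age slope 2.0 baked in; residual variance should match the model
        # part's total variance at n=2000 individuals
        cfg = SimConfig(n_mz=400, n_dz=300, n_sib=300, seed=3, age_effect=2.0,
                        sex_effect=0.0, icv_effect=0.0, pc_effects=(0.0,) * 10)
        data, truth = simulate_pairs(cfg)
        out = residualize(data, "roi", ["age"])
        long = out.stacked_individuals(["roi", "age"]).dropna()
        assert abs(np.corrcoef(long["roi"], long["age"])[0, 1]) < 1e-10
        mc_se = truth.total_variance * np.sqrt(2 / len(long))
        assert abs(long["roi"].var() - truth.total_variance) < 3 * mc_se

    def test_missing_covariate_gives_missing_residual(self):
        data, _ = simulate_pairs(SimConfig(n_mz=20, n_dz=20, n_sib=20, seed=4))
        data.table.loc[0, "age_t1"] = np.nan
        out = residualize(data, "roi", ["age"])
        assert np.isnan(out.table.loc[0, "roi_t1"])
        assert np.isfinite(out.table.loc[0, "roi_t2"])

    def test_zero_variance_covariate(self):
        data, _ = simulate_pairs(SimConfig(n_mz=20, n_dz=0, n_sib=0, seed=5))
        for m in (1, 2):
            data.table[f"icv_t{m}"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            residualize(data, "roi", ["icv"])

    def test_insufficient_data(self):
        data, _ = simulate_pairs(SimConfig(n_mz=1, n_dz=0, n_sib=0, seed=6))
        data.table["roi_t2"] = np.nan
        with pytest.raises(ValueError, match="insufficient"):
            residualize(data, "roi", ["age", "sex", "icv"])


class TestStandardizePrs:
    def test_moments_and_idempotence(self):
        data, _ = simulate_pairs(SimConfig(n_mz=100, n_dz=100, n_sib=100, seed=7))
        out = standardize_prs(data, "roi_prs")
        vals = out.member_matrix(["roi_prs"]).ravel()
        assert abs(vals.mean()) < 1e-12
        assert abs(vals.std(ddof=1) - 1) < 1e-12
        again = standardize_prs(out, "roi_prs")
        np.testing.assert_allclose(vals, again.member_matrix(["roi_prs"]).ravel(),
                                   atol=1e-12)

    def test_closed_form_three_values(self):
        # three observed values {1, 2, 3} over two pairs -> {-1, 0, 1}
        from twinprs.pair_data import PairDataset
        table = pd.DataFrame({
            "family_id": ["a", "b"], "group": ["DZ", "SIB"],
            "hippocampus_t1": [0.0, 0.0], "hippocampus_t2": [0.0, 0.0],
            "hip_prs_t1": [1.0, 3.0], "hip_prs_t2": [2.0, np.nan],
            "age_t1": [10.0, 10.0], "age_t2": [10.0, 10.0],
        })
        data = PairDataset(table, small_schema())
        out = standardize_prs(data, "hip_prs")
        vals = out.member_matrix(["hip_prs"]).ravel()
        got = sorted(vals[np.isfinite(vals)])
        np.testing.assert_allclose(got, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mz_equality_preserved(self):
        data, _ = simulate_pairs(SimConfig(seed=8))
        out = standardize_prs(data, "roi_prs")
        mz = out.table[out.table.group == "MZ"]
        np.testing.assert_array_equal(mz["roi_prs_t1"], mz["roi_prs_t2"])

    def test_constant_column_errors(self):
        data, _ = simulate_pairs(SimConfig(n_mz=10, n_dz=0, n_sib=0, seed=9))
        for m in (1, 2):
            data.table[f"sud_prs_t{m}"] = 5.0
        with pytest.raises(ValueError, match="zero variance"):
            standardize_prs(data, "sud_prs")


class TestAverageHemispheres:
    @pytest.mark.parametrize("left,right,expected", [
        ([10.0], [12.0], [11.0]),
        ([3.5], [3.5], [3.5]),
        ([np.nan], [12.0], [np.nan]),
    ])
    def test_elementwise_mean(self, left, right, expected):
        got = average_hemispheres(left, right)
        np.testing.assert_array_equal(got, expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            average_hemispheres([1.0, 2.0], [1.0])


def test_default_schema_covers_generator_columns():
    schema = default_schema()
    data, _ = simulate_pairs(SimConfig(n_mz=2, n_dz=2, n_sib=2, seed=0))
    for col in schema.member_columns(schema.variables):
        assert col in data.table.columns
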