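"""Twin dataset I/O, residualization and descriptive statistics."""

import logging

import numpy as np
import pandas as pd
import pytest

import twinpath as tp
from twinpath.data import (PhenotypeParseError, SchemaError,
                           SingularDesignError, TwinDataset)


class TestLoad:
    def test_toy_readback(self, toy_csv):
        ds = tp.load_twin_table(toy_csv)
        assert (ds.n_mz, ds.n_dz, ds.p) == (2, 1, 2)
        assert ds.items == ["item1", "item2"]
        assert ds.frame.loc[0, "item1_t2"] == 2.0

    def test_singleton_pair_retained(self, toy_csv, tmp_path):
        raw = pd.read_csv(toy_csv)
        raw.loc[0, ["item1_t2", "item2_t2"]] = np.nan
        path = tmp_path / "singleton.csv"
        raw.to_csv(path, index=False)
        ds = tp.load_twin_table(path)
        assert ds.n_pairs == 3
        assert np.isnan(ds.frame.loc[0, "item1_t2"])

    def test_unknown_zygosity_dropped_with_log(self, toy_csv, tmp_path, caplog):
        raw = pd.read_csv(toy_csv)
        raw.loc[1, "zygosity"] = "XZ"
        path = tmp_path / "badzyg.csv"
        raw.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING):
            ds = tp.load_twin_table(path)
        assert ds.n_pairs == 2
        assert any("unknown zygosity" in r.message for r in caplog.records)

    def test_missing_mandatory_column(self, toy_csv, tmp_path):
        raw = pd.read_csv(toy_csv).drop(columns=["zygosity"])
        path = tmp_path / "nozyg.csv"
        raw.to_csv(path, index=False)
        with pytest.raises(SchemaError):
            tp.load_twin_table(path)

    def test_non_numeric_phenotype_names_cell(self, toy_csv, tmp_path):
        raw = pd.read_csv(toy_csv)
        raw["item2_t1"] = raw["item2_t1"].astype(object)
        raw.loc[2, "item2_t1"] = "oops"
        path = tmp_path / "badcell.csv"
        raw.to_csv(path, index=False)
        with pytest.raises(PhenotypeParseError, match="item2_t1.*row 2"):
            tp.load_twin_table(path)

    def test_schema_mapping(self, tmp_path):
        pd.DataFrame({
            "zyg": ["1", "2"], "g1a": [1.0, 2.0], "g1b": [2.0, 3.0],
        }).to_csv(tmp_path / "mapped.csv", index=False)
        ds = tp.load_twin_table(tmp_path / "mapped.csv", schema={
            "zygosity": "zyg", "zygosity_map": {"1": "MZ", "2": "DZ"},
            "items": {"g1": ["g1a", "g1b"]}})
        assert (ds.n_mz, ds.n_dz, ds.items) == (1, 1, ["g1"])

    def test_round_trip(self, tmp_path):
        cfg = tp.SimConfig(n_mz=40, n_dz=60, model="univariate_ace",
                           parameters=tp.UnivariateACEParams(0.3, 0.4, 0.8),
                           missing_rate=0.1, seed=2)
        ds = tp.simulate(cfg)
        path = tmp_path / "rt.csv"
        ds.write_csv(path)
        back = tp.load_twin_table(path)
        y0, y1 = ds.phenotypes(), back.phenotypes()
        assert np.array_equal(np.isnan(y0), np.isnan(y1))
        assert np.allclose(y0[~np.isnan(y0)], y1[~np.isnan(y1)])

    def test_opposite_sex_mz_dropped(self):
        frame = pd.DataFrame({
            "zygosity": ["MZ", "MZ"], "x_t1": [1.0, 2.0], "x_t2": [1.0, 2.0],
            "sex_t1": ["f", "f"], "sex_t2": ["m", "f"]})
        ds = TwinDataset(frame, ["x"])
        assert ds.n_pairs == 1


class TestResidualize:
    def _age_dataset(self, rng, n=400, slope=2.0, noise=0.05):
        age1 = rng.uniform(30, 80, n)
        age2 = age1 + rng.normal(0, 1, n)
        frame = pd.DataFrame({
            "zygosity": ["MZ"] * (n // 2) + ["DZ"] * (n - n // 2),
            "x_t1": slope * age1 + rng.normal(0, noise, n),
            "x_t2": slope * age2 + rng.normal(0, noise, n),
            "age_t1": age1, "age_t2": age2,
        })
        return TwinDataset(frame, ["x"])

    def test_residual_orthogonal_to_covariate(self):
        ds = self._age_dataset(np.random.default_rng(0))
        out = tp.residualize(ds, ["age"])
        resid = np.concatenate([out.frame["x_t1"], out.frame["x_t2"]])
        ages = np.concatenate([out.frame["age_t1"], out.frame["age_t2"]])
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_hand_computed_regression(self):
        # 4 observations (2 pairs): y on age; beta by hand via normal equations
        frame = pd.DataFrame({
            "zygosity": ["MZ", "DZ"],
            "y_t1": [1.0, 2.0], "y_t2": [2.0, 5.0],
            "age_t1": [10.0, 20.0], "age_t2": [30.0, 40.0],
        })
        y = np.array([1.0, 2.0, 2.0, 5.0])
        a = np.array([10.0, 20.0, 30.0, 40.0])
        bhat = np.sum((a - a.mean()) * (y - y.mean())) / np.sum((a - a.mean()) ** 2)
        expected = y - (y.mean() + bhat * (a - a.mean()))
        out = tp.residualize(TwinDataset(frame, ["y"]), ["age"])
        got = np.concatenate([out.frame["y_t1"], out.frame["y_t2"]])
        assert np.allclose(got, expected)

    def test_idempotent(self):
        ds = self._age_dataset(np.random.default_rng(1))
        once = tp.residualize(ds, ["age"])
        twice = tp.residualize(once, ["age"])
        assert np.allclose(once.phenotypes(), twice.phenotypes(), atol=1e-10)

    def test_null_covariate_equals_centering(self):
        rng = np.random.default_rng(2)
        n = 5000
        frame = pd.DataFrame({
            "zygosity": ["MZ"] * n,
            "x_t1": rng.normal(5, 1, n), "x_t2": rng.normal(5, 1, n),
            "age_t1": rng.uniform(30, 80, n), "age_t2": rng.uniform(30, 80, n),
        })
        ds = TwinDataset(frame, ["x"])
        out = tp.residualize(ds, ["age"])
        centered = ds.phenotypes() - np.nanmean(ds.phenotypes())
        # residuals agree with mean-centered values up to the (tiny) fitted slope
        assert np.allclose(out.phenotypes(), centered, atol=0.15)

    def test_missing_phenotype_stays_missing(self):
        ds = self._age_dataset(np.random.default_rng(3), n=20)
        ds.frame.loc[0, "x_t2"] = np.nan
        out = tp.residualize(ds, ["age"])
        assert np.isnan(out.frame.loc[0, "x_t2"])

    def test_constant_covariate_raises(self):
        ds = self._age_dataset(np.random.default_rng(4), n=20)
        ds.frame["age_t1"] = 50.0
        ds.frame["age_t2"] = 50.0
        with pytest.raises(SingularDesignError):
            tp.residualize(ds, ["age"])


class TestDescriptives:
    def test_identical_twins_give_r_one(self):
        frame = pd.DataFrame({
            "zygosity": ["MZ"] * 5 + ["DZ"] * 5,
            "x_t1": np.arange(10.0), "x_t2": np.arange(10.0)})
        desc = tp.descriptives(TwinDataset(frame, ["x"]))
        assert desc.table.loc["x", "r_mz"] == pytest.approx(1.0)
        assert desc.table.loc["x", "r_dz"] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # pairs {(1,2),(2,1),(3,4),(4,3)}: textbook formula gives r = 0.6
        frame = pd.DataFrame({
            "zygosity": ["MZ"] * 4 + ["DZ"] * 3,
            "x_t1": [1.0, 2.0, 3.0, 4.0, 1, 2, 3],
            "x_t2": [2.0, 1.0, 4.0, 3.0, 1, 2, 3]})
        desc = tp.descriptives(TwinDataset(frame, ["x"]))
        assert desc.table.loc["x", "r_mz"] == pytest.approx(0.6)
        r = 0.6
        assert desc.table.loc["x", "se_mz"] == pytest.approx(
            (1 - r ** 2) / np.sqrt(4 - 2))

    def test_group_average_is_mean_of_item_correlations(self, small_item_dataset):
        desc = tp.descriptives(small_item_dataset)
        for g in ("mz", "dz"):
            assert desc.avg_r[g.upper()] == pytest.approx(
                desc.table[f"r_{g}"].mean())

    def test_printed_average_convention(self):
        # a six-item MZ correlation column like the published one averages
        # to 0.205, printed as 0.21 at 2 dp
        vals = [0.20, 0.28, 0.29, 0.20, 0.10, 0.16]
        assert np.mean(vals) == pytest.approx(0.205)
        assert abs(np.mean(vals) - 0.21) < 0.006

    def test_too_few_pairs_is_nan_not_error(self):
        frame = pd.DataFrame({
            "zygosity": ["MZ", "MZ", "DZ", "DZ", "DZ"],
            "x_t1": [1.0, 2.0, 1.0, 2.0, 3.0],
            "x_t2": [1.0, 2.0, 1.0, 2.0, 3.0]})
        desc = tp.descriptives(TwinDataset(frame, ["x"]))
        assert np.isnan(desc.table.loc["x", "r_mz"])
        assert desc.table.loc["x", "r_dz"] == pytest.approx(1.0)

    def test_recovers_generating_correlation(self):
        # simulated truth: r_MZ = 0.75, r_DZ = 0.50
        params = tp.UnivariateACEParams(a=np.sqrt(0.5), c=np.sqrt(0.25),
                                        e=np.sqrt(0.25))
        ds = tp.simulate(tp.SimConfig(n_mz=5000, n_dz=5000,
                                      model="univariate_ace",
                                      parameters=params, seed=9))
        desc = tp.descriptives(ds)
        se_mz = (1 - 0.75 ** 2) / np.sqrt(5000)
        se_dz = (1 - 0.5 ** 2) / np.sqrt(5000)
        assert abs(desc.table.loc["scale", "r_mz"] - 0.75) < 3 * se_mz
        assert abs(desc.table.loc["scale", "r_dz"] - 0.50) < 3 * se_dz
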