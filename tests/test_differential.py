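"""Differential engines: normalization, dispersion recovery, NB Wald vs a
direct-likelihood oracle, moderated t limits and calibration, methylation
summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from rejuvenome.differential import (average_techreps, bh_adjust,
                                     estimate_dispersions, filter_cpgs,
                                     filter_low_expression,
                                     halflife_normalize,
                                     moderated_linear_test, nb_wald_test,
                                     region_methylation, size_factors)
from rejuvenome.differential import DispersionModel
from rejuvenome.regions import RegionSet

from conftest import two_group_sheet


def nb_loglik(y, mu, alpha):
    if alpha <= 0:
        from scipy.stats import poisson
        return poisson.logpmf(y, mu).sum()
    r = 1.0 / alpha
    p = r / (r + mu)
    return (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(p) + y * np.log1p(-p)).sum()


def grid_mle_log2fc(y1, y2, sf1, sf2, alpha):
    """Direct NB likelihood maximization per group (fine 1-D optimization
    over the log-mean); the independent oracle for the IRLS engine."""
    def fit_group(y, sf):
        def nll(logmu):
            return -nb_loglik(y, np.exp(logmu) * sf, alpha)
        res = optimize.minimize_scalar(nll, bounds=(-10, 20), method="bounded",
                                       options={"xatol": 1e-12})
        return res.x
    return (fit_group(y2, sf2) - fit_group(y1, sf1)) / np.log(2.0)


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        m = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = size_factors(m)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14], "c": [5, 9, 14]})
        assert np.allclose(size_factors(m), 1.0)

    def test_scale_equivariance(self, rng):
        m = pd.DataFrame(rng.poisson(50, size=(100, 4)),
                         columns=list("abcd")) + 1
        sf = size_factors(m)
        m2 = m.copy()
        m2["c"] = m["c"] * 3
        sf2 = size_factors(m2)
        assert sf2["c"] / sf["c"] == pytest.approx(3.0 * sf2["a"] / sf["a"])

    def test_error_when_no_all_nonzero_feature(self):
        m = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="filter"):
            size_factors(m)


class TestExpressionFilter:
    def test_rule_matches_brute_force(self, rng):
        sheet = two_group_sheet(3)
        counts = pd.DataFrame(rng.poisson(8, size=(200, 6)),
                              columns=sheet["sample"])
        counts.iloc[0] = 0  # all-zero feature must be dropped
        counts.iloc[1] = 1000  # strong feature must be kept
        out, rep = filter_low_expression(counts, sheet)
        lib = counts.sum(axis=0).to_numpy(float)
        cut = 10.0 / (np.median(lib) / 1e6)
        cpm = counts.to_numpy(float) / lib * 1e6
        want = (cpm >= cut).sum(axis=1) >= 3
        assert list(out.index) == list(counts.index[want])
        assert not want[0] and want[1]
        assert rep["kept"] + rep["dropped"] == 200


class TestDispersions:
    def _counts(self, rng, alpha, n=2000, reps=6):
        sheet = two_group_sheet(reps)
        mu = 2.0 ** rng.uniform(5, 10, size=n)
        if alpha == 0:
            arr = rng.poisson(mu[:, None], size=(n, 2 * reps))
        else:
            r = 1 / alpha
            arr = rng.negative_binomial(r, r / (r + mu[:, None]),
                                        size=(n, 2 * reps))
        return pd.DataFrame(arr, columns=sheet["sample"]), sheet

    def test_poisson_data_small_alpha(self, rng):
        counts, sheet = self._counts(rng, 0.0)
        model = estimate_dispersions(counts, size_factors(counts), sheet)
        assert np.median(model.final) <= 0.05

    def test_nb_alpha_recovered(self, rng):
        counts, sheet = self._counts(rng, 0.2)
        model = estimate_dispersions(counts, size_factors(counts), sheet)
        assert 0.1 <= np.median(model.final) <= 0.3

    def test_constant_feature_raw_zero(self, rng):
        sheet = two_group_sheet(3)
        arr = rng.poisson(40, size=(5, 6))
        arr[0] = 40  # constant feature
        counts = pd.DataFrame(arr, columns=sheet["sample"])
        sf = pd.Series(1.0, index=counts.columns)
        model = estimate_dispersions(counts, sf, sheet)
        assert model.raw[0] == 0.0
        assert model.final[0] == pytest.approx(
            max(1e-8, 0.5 * model.trend(model.base_mean[:1])[0]))


class TestNbWald:
    def test_matches_grid_mle_oracle(self, rng):
        """IRLS log2FC within 1e-3 of direct NB likelihood maximization."""
        sheet = two_group_sheet(4)
        worst = 0.0
        for _ in range(50):
            alpha = float(rng.uniform(0.01, 0.3))
            mu = float(2.0 ** rng.uniform(4, 9))
            lfc = float(rng.normal(0, 1))
            r = 1 / alpha
            y1 = rng.negative_binomial(r, r / (r + mu), size=4)
            y2 = rng.negative_binomial(r, r / (r + mu * 2 ** lfc), size=4)
            counts = pd.DataFrame([np.concatenate([y1, y2])],
                                  columns=sheet["sample"]) + 1
            sf = pd.Series(1.0, index=counts.columns)
            disp = DispersionModel(np.array([alpha]), (alpha, 0.0),
                                   np.array([alpha]), np.array([mu]))
            res = nb_wald_test(counts, sheet, "aging_ctrl", disp, sf)
            oracle = grid_mle_log2fc(counts.iloc[0, :4], counts.iloc[0, 4:],
                                     1.0, 1.0, alpha)
            worst = max(worst, abs(res["log2fc"].iloc[0] - oracle))
        assert worst < 1e-3

    def test_all_equal_counts_zero_lfc(self):
        sheet = two_group_sheet(3)
        counts = pd.DataFrame([[37] * 6], columns=sheet["sample"])
        sf = pd.Series(1.0, index=counts.columns)
        disp = DispersionModel(np.array([0.1]), (0.1, 0.0),
                               np.array([0.1]), np.array([37.0]))
        res = nb_wald_test(counts, sheet, "aging_ctrl", disp, sf)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_fourfold_recovered(self, rng):
        # mostly-null matrix so median-of-ratios normalization stays anchored
        sheet = two_group_sheet(6)
        alpha, mu = 0.01, 500.0
        r = 1 / alpha
        n_de, n_null = 200, 800
        null = rng.negative_binomial(r, r / (r + mu), size=(n_null, 12))
        y1 = rng.negative_binomial(r, r / (r + mu), size=(n_de, 6))
        y2 = rng.negative_binomial(r, r / (r + 4 * mu), size=(n_de, 6))
        counts = pd.DataFrame(np.vstack([np.hstack([y1, y2]), null]),
                              columns=sheet["sample"])
        res = nb_wald_test(counts, sheet, "aging_ctrl")
        assert abs(res["log2fc"].iloc[:n_de].median() - 2.0) < 0.2

    def test_contrast_symmetry_negates_lfc(self, rng):
        sheet = two_group_sheet(3)
        counts = pd.DataFrame(rng.poisson(100, size=(50, 6)) + 1,
                              columns=sheet["sample"])
        res = nb_wald_test(counts, sheet, "aging_ctrl")
        flipped = sheet.copy()
        flipped["age"] = flipped["age"].map({"young": "old", "old": "young"})
        res2 = nb_wald_test(counts, flipped, "aging_ctrl")
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-6)
        assert np.allclose(res["p"], res2["p"], atol=1e-9)

    def test_bh_padj_geq_p(self, rng):
        sheet = two_group_sheet(3)
        counts = pd.DataFrame(rng.poisson(60, size=(300, 6)) + 1,
                              columns=sheet["sample"])
        res = nb_wald_test(counts, sheet, "aging_ctrl")
        ok = res["p"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "p"] - 1e-12).all()
        assert (res.loc[ok, "padj"] <= 1.0).all()


class TestTechReps:
    def test_identical_reps_unchanged_and_pair_averaged(self):
        sheet = pd.DataFrame({
            "sample": ["a1", "a2", "b1", "b2"],
            "age": ["young"] * 4, "env": ["ctrl"] * 4,
            "replicate": [1, 1, 2, 2],
            "techrep_group": ["A", "A", "B", "B"]})
        m = pd.DataFrame({"a1": [5.0, 1.0], "a2": [5.0, 3.0],
                          "b1": [2.0, 1.0], "b2": [2.0, 3.0]})
        out, collapsed = average_techreps(m, sheet)
        assert list(out.columns) == ["A", "B"]
        assert out["A"].tolist() == [5.0, 2.0]
        assert out["B"].tolist() == [2.0, 2.0]
        assert len(collapsed) == 2

    def test_missing_sheet_entry_rejected(self):
        sheet = pd.DataFrame({"sample": ["a1"], "age": ["young"],
                              "env": ["ctrl"], "replicate": [1],
                              "techrep_group": ["A"]})
        m = pd.DataFrame({"a1": [1.0], "zz": [2.0]})
        with pytest.raises(ValueError, match="missing"):
            average_techreps(m, sheet)


class TestModeratedT:
    def _mat(self, rng, n=2000, reps=3):
        sheet = two_group_sheet(reps)
        return pd.DataFrame(rng.normal(0, 1, size=(n, 2 * reps)),
                            columns=sheet["sample"]), sheet

    def test_d0_infinite_limit_pools_all_variances(self, rng):
        m, sheet = self._mat(rng)
        res = moderated_linear_test(m, sheet, "aging_ctrl", d0_override=np.inf)
        # all moderated variances equal => a single common se
        assert res["se"].nunique() == 1

    def test_d0_zero_limit_is_ordinary_t(self, rng):
        m, sheet = self._mat(rng, n=50)
        res = moderated_linear_test(m, sheet, "aging_ctrl", d0_override=0.0)
        from scipy import stats
        y = m.to_numpy()
        t, p = stats.ttest_ind(y[:, 3:], y[:, :3], axis=1, equal_var=True)
        assert np.allclose(res["stat"], t, atol=1e-9)
        assert np.allclose(res["p"], p, atol=1e-9)

    def test_null_calibration(self, rng):
        m, sheet = self._mat(rng, n=2000)
        res = moderated_linear_test(m, sheet, "aging_ctrl")
        rate = float((res["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_zero_residual_df_rejected(self):
        sheet = two_group_sheet(1, age_levels=("young", "old"))
        m = pd.DataFrame(np.ones((3, 2)), columns=sheet["sample"])
        with pytest.raises(ValueError):
            moderated_linear_test(m, sheet, "aging_ctrl")


class TestHalflife:
    def test_division_and_identity(self):
        m = pd.DataFrame({"s": [10.0, 8.0]}, index=["p1", "p2"])
        hl = pd.Series([2.0, 1.0], index=["p1", "p2"])
        out, dropped = halflife_normalize(m, hl)
        assert out.loc["p1", "s"] == 5.0 and out.loc["p2", "s"] == 8.0
        assert dropped == []

    def test_missing_halflife_row_dropped(self):
        m = pd.DataFrame({"s": [10.0, 8.0]}, index=["p1", "p2"])
        hl = pd.Series([2.0, -1.0], index=["p1", "p2"])
        out, dropped = halflife_normalize(m, hl)
        assert list(out.index) == ["p1"] and dropped == ["p2"]


class TestCpGFilters:
    def test_boundary_at_ten_counts(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3],
                           "meth": [4, 5, 6], "total": [9, 10, 11],
                           "sample": "s1"})
        out = filter_cpgs(df)
        assert set(out["pos"]) == {2, 3}
        assert np.allclose(out["beta"], out["meth"] / out["total"])

    def test_equal_totals_only_low_rule_acts(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": range(100),
                           "meth": 5, "total": 20, "sample": "s1"})
        assert len(filter_cpgs(df)) == 100

    def test_matches_brute_force_rule(self, rng):
        rows = []
        for sid in ["s1", "s2"]:
            totals = rng.poisson(30, size=500)
            rows.append(pd.DataFrame({
                "chrom": "chr1", "pos": np.arange(500), "meth": 0,
                "total": totals, "sample": sid}))
        df = pd.concat(rows, ignore_index=True)
        out = filter_cpgs(df)
        for sid, sub in df.groupby("sample"):
            hi = sub["total"].quantile(0.999, interpolation="higher")
            want = sub[(sub["total"] >= 10) & (sub["total"] <= hi)]
            got = out[out["sample"] == sid]
            assert len(got) == len(want)
            assert set(zip(got["pos"], got["total"])) \
                == set(zip(want["pos"], want["total"]))


class TestRegionMethylation:
    def test_mean_beta_and_empty_flagging(self):
        cpgs = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 500, 520],
            "meth": [2, 4, 5, 5], "total": [10, 10, 10, 10],
            "sample": ["s1", "s1", "s1", "s1"]})
        cpgs["beta"] = cpgs["meth"] / cpgs["total"]
        regions = RegionSet.from_tuples(
            [("chr1", 0, 100, "rA"), ("chr1", 490, 530, "rB"),
             ("chr1", 900, 950, "rC")])
        out, empty = region_methylation(cpgs, regions)
        assert out.loc["rA", "s1"] == pytest.approx(0.3)
        assert out.loc["rB", "s1"] == pytest.approx(0.5)
        assert empty == ["rC"]

    def test_matches_per_cpg_scan(self, rng):
        cpgs = pd.DataFrame({
            "chrom": "chr1", "pos": rng.choice(10_000, size=400, replace=False),
            "meth": rng.integers(0, 10, size=400),
            "total": 10, "sample": rng.choice(["s1", "s2"], size=400)})
        cpgs["beta"] = cpgs["meth"] / cpgs["total"]
        regions = RegionSet.from_tuples(
            [("chr1", int(s), int(s) + 500, f"r{i}")
             for i, s in enumerate(range(0, 9_500, 1_000))])
        out, _ = region_methylation(cpgs, regions)
        for rid, s in zip(out.index, range(0, 9_500, 1_000)):
            for sid in ["s1", "s2"]:
                inside = cpgs[(cpgs["pos"] >= s) & (cpgs["pos"] < s + 500)
                              & (cpgs["sample"] == sid)]
                if inside.empty:
                    assert np.isnan(out.loc[rid, sid])
                else:
                    assert out.loc[rid, sid] == pytest.approx(inside["beta"].mean())


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_nan_passthrough_and_range_check(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_statsmodels_stepup(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            want = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), want, atol=1e-12)
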