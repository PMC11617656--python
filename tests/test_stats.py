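"""Linear models, Tukey-HSD, Bray-Curtis, PERMANOVA and PCoA."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from terpenebudget.simulate import GeneratorParams, generate_cohort
from terpenebudget.stats import (
    DegenerateDesignError,
    SingularDesignError,
    bray_curtis,
    fit_lm,
    pcoa_projection,
    permanova,
    tukey_hsd,
)


class TestFitLm:
    def test_exact_line_recovered(self):
        data = pd.DataFrame({"x": np.arange(10.0)})
        data["y"] = 2.0 * data["x"]
        res = fit_lm(data, "y ~ x")
        assert res.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.coefficients["Intercept"] == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            {
                "x1": rng.normal(size=30),
                "x2": rng.normal(size=30),
                "y": rng.normal(size=30),
            }
        )
        res = fit_lm(data, "y ~ x1 + x2")
        X = np.column_stack([np.ones(30), data["x1"], data["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"].to_numpy())
        assert res.coefficients["Intercept"] == pytest.approx(beta[0],
                                                              abs=1e-10)
        assert res.coefficients["x1"] == pytest.approx(beta[1], abs=1e-10)
        assert res.coefficients["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_anova_df_sum_to_n_minus_1(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 10),
                "x": rng.normal(size=30),
                "y": rng.normal(size=30),
            }
        )
        res = fit_lm(data, "y ~ g + x")
        assert res.anova_type2["df"].sum() == pytest.approx(30 - 1)
        assert np.isfinite(res.shapiro_p)

    def test_rank_deficient_design_raises(self):
        data = pd.DataFrame({"x": np.arange(6.0)})
        data["x2"] = 2 * data["x"]  # aliased
        data["y"] = data["x"] + 1
        with pytest.raises(SingularDesignError, match="x2"):
            fit_lm(data, "y ~ x + x2")

    def test_interaction_detected_on_large_synthetic_cohort(self):
        """The generator embeds an induction slope only in inoculated trees;
        at n=500 the psi x inoculation interaction is unambiguous."""
        cohort = generate_cohort(GeneratorParams(seed=2).scaled_to(500),
                                 with_profiles=False)
        rows = [
            {
                "psi_pd": t.psi_pd,
                "inoculated": t.inoculated,
                "delta": t.mst_post - t.mst_pre,
            }
            for t in cohort
            if t.has_post
        ]
        res = fit_lm(pd.DataFrame(rows), "delta ~ psi_pd * inoculated")
        inter = [i for i in res.anova_type2.index if ":" in i]
        assert len(inter) == 1
        assert res.anova_type2.loc[inter[0], "PR(>F)"] < 0.05


class TestTukey:
    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        data = pd.DataFrame(
            {"g": np.repeat(["a", "b"], 20), "y": np.concatenate([base, base])}
        )
        res = fit_lm(data, "y ~ g")
        tbl = tukey_hsd(res, "g")
        assert abs(float(tbl["meandiff"].iloc[0])) < 1e-12
        assert float(tbl["p-adj"].iloc[0]) > 0.95

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=90)
        y[60:] += 10.0  # shift third group by 10 residual-sd
        data = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 30), "y": y})
        tbl = tukey_hsd(fit_lm(data, "y ~ g"), "g")
        shifted = tbl[(tbl["group1"] != "c") != (tbl["group2"] != "c")]
        not_shifted = tbl[(tbl["group1"] == "a") & (tbl["group2"] == "b")]
        assert (shifted["p-adj"] < 0.05).all()
        assert (not_shifted["p-adj"] > 0.05).all()

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 15), "y": rng.normal(size=45)}
        )
        res = fit_lm(data, "y ~ g")
        tbl = tukey_hsd(res, "g")
        mse = res.residual_sd ** 2
        for _, row in tbl.iterrows():
            diff = float(row["meandiff"])
            t = abs(diff) / np.sqrt(mse * 2 / 15)
            p_unadj = 2 * scipy.stats.t.sf(t, df=45 - 3)
            assert float(row["p-adj"]) >= p_unadj - 1e-12

    def test_absent_factor_raises(self):
        data = pd.DataFrame({"g": ["a", "b"] * 5, "y": np.arange(10.0)})
        res = fit_lm(data, "y ~ g")
        with pytest.raises(KeyError):
            tukey_hsd(res, "h")


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]),
                         relative=False)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        dm = bray_curtis(np.array([[1.0, 0.0], [0.0, 2.0]]), relative=False)
        assert dm.data[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        dm = bray_curtis(np.array([[2.0, 1.0], [1.0, 3.0]]), relative=False)
        assert dm.data[0, 1] == pytest.approx(3.0 / 7.0, abs=1e-12)

    def test_relative_normalisation(self):
        # proportional rows coincide after closure
        dm = bray_curtis(np.array([[2.0, 2.0], [5.0, 5.0]]), relative=True)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_row_undefined_when_relative(self):
        with pytest.raises(ValueError, match="zero-total"):
            bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]), relative=True)

    def test_matrix_properties(self, default_cohort):
        dm = bray_curtis(default_cohort.terpenes_post, relative=True)
        D = dm.data
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()


def _two_cluster_distance(n_per_group=10):
    X = np.zeros((2 * n_per_group, 3))
    X[:n_per_group, 0] = 1.0
    X[n_per_group:, 1] = 1.0
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    return bray_curtis(X, relative=False, ids=ids), ids


class TestPermanova:
    def test_perfect_separation_minimal_p(self):
        dm, ids = _two_cluster_distance(10)
        design = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=ids)
        res = permanova(dm, design, terms=["g"], n_perm=199, seed=3)
        assert res.p_value("g") == pytest.approx(1.0 / 200.0)

    def test_seed_reproducible(self):
        dm, ids = _two_cluster_distance(5)
        rng = np.random.default_rng(8)
        noisy = dm.data + 0.0  # exact copy; noise comes via the design
        design = pd.DataFrame({"g": rng.permutation(["a", "b"] * 5)},
                              index=ids)
        r1 = permanova(dm, design, terms=["g"], n_perm=199, seed=42)
        r2 = permanova(dm, design, terms=["g"], n_perm=199, seed=42)
        assert r1.p_value("g") == r2.p_value("g")

    def test_pseudo_f_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        X = rng.gamma(2.0, size=(16, 6))
        ids = [f"s{i}" for i in range(16)]
        design = pd.DataFrame(
            {"g": rng.permutation(["a", "b"] * 8)}, index=ids
        )
        dm = bray_curtis(X, relative=True, ids=ids)
        res = permanova(dm, design, terms=["g"], n_perm=99, seed=0)
        order = rng.permutation(16)
        dm2 = DistanceMatrix(dm.data[np.ix_(order, order)],
                             ids=[ids[i] for i in order])
        res2 = permanova(dm2, design.iloc[order], terms=["g"], n_perm=99,
                         seed=0)
        assert res.pseudo_f("g") == pytest.approx(res2.pseudo_f("g"),
                                                  rel=1e-10)

    def test_one_way_f_matches_scikit_bio(self):
        """Independent oracle: the one-way pseudo-F must equal scikit-bio's."""
        rng = np.random.default_rng(10)
        X = rng.gamma(2.0, size=(18, 8))
        ids = [f"s{i}" for i in range(18)]
        grouping = rng.permutation(["a", "b", "c"] * 6)
        dm = bray_curtis(X, relative=True, ids=ids)
        design = pd.DataFrame({"g": grouping}, index=ids)
        mine = permanova(dm, design, terms=["g"], n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(grouping), permutations=99)
        assert mine.pseudo_f("g") == pytest.approx(ref["test statistic"],
                                                   rel=1e-10)

    def test_two_factor_partition_matches_vegan_adonis2(self, tmp_path):
        """Cross-check the sequential multi-factor partition against vegan."""
        rng = np.random.default_rng(12)
        X = rng.gamma(2.0, size=(24, 10))
        drought = np.repeat(["wet", "dry"], 12)
        inoc = np.tile(np.repeat(["no", "yes"], 6), 2)
        X[(drought == "wet") & (inoc == "yes")] += 1.0
        ids = [f"s{i}" for i in range(24)]
        dm = bray_curtis(X, relative=True, ids=ids)
        design = pd.DataFrame({"drought": drought, "inoc": inoc}, index=ids)
        mine = permanova(dm, design, terms=["drought", "inoc", "drought:inoc"],
                         n_perm=99, seed=0)

        pd.DataFrame(X).to_csv(tmp_path / "x.csv", index=False)
        design.to_csv(tmp_path / "meta.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            x <- read.csv("{tmp_path}/x.csv")
            meta <- read.csv("{tmp_path}/meta.csv",
                             colClasses=c("character","character"))
            x <- sweep(as.matrix(x), 1, rowSums(x), "/")
            d <- vegdist(x, method="bray")
            res <- adonis2(d ~ drought * inoc, data=meta, permutations=99,
                           by="terms")
            write.csv(as.data.frame(res), "{tmp_path}/out.csv")
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], check=True,
            capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        for mine_term, vegan_term in [
            ("drought", "drought"), ("inoc", "inoc"),
            ("drought:inoc", "drought:inoc"),
        ]:
            assert mine.pseudo_f(mine_term) == pytest.approx(
                float(ref.loc[vegan_term, "F"]), rel=1e-6
            )
            assert float(mine.table.loc[mine_term, "sum_sq"]) == pytest.approx(
                float(ref.loc[vegan_term, "SumOfSqs"]), rel=1e-6
            )

    def test_degenerate_design_rejected(self):
        dm, ids = _two_cluster_distance(5)
        design = pd.DataFrame({"g": ["a"] * 10}, index=ids)
        with pytest.raises(DegenerateDesignError):
            permanova(dm, design, terms=["g"], n_perm=99, seed=0)

    def test_too_few_permutations_rejected(self):
        dm, ids = _two_cluster_distance(5)
        design = pd.DataFrame({"g": ["a", "b"] * 5}, index=ids)
        with pytest.raises(ValueError):
            permanova(dm, design, terms=["g"], n_perm=10, seed=0)


class TestPcoa:
    def test_equidistant_samples_form_equilateral_triangle(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                     dtype=float), ids=list("abc"))
        coords, eig = pcoa_projection(dm, k=2)
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert d01 == pytest.approx(d02, abs=1e-8)
        assert d01 == pytest.approx(d12, abs=1e-8)
        assert d01 == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_samples_coincide(self):
        D = np.array(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float
        )
        coords, _ = pcoa_projection(DistanceMatrix(D, ids=list("abc")), k=2)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 4))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dm = DistanceMatrix(D, ids=[str(i) for i in range(10)])
        coords, eig = pcoa_projection(dm, k=4)
        D2 = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_truncation_warns(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], dtype=float),
                            ids=list("ab"))
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = pcoa_projection(dm, k=5)
        assert coords.shape[0] == 2
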