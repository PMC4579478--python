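"""Community statistics against closed forms and independent oracles
(scipy distances, scikit-bio ordination/permutation tests, statsmodels GLM
and multiple-testing, R vegan adonis2)."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

from nichecore import community_stats as cs
from nichecore.io_tables import OtuTable, SampleMetadata

from conftest import random_table, two_group_metadata


class TestAlphaDiversity:
    def test_richness_counts_nonzero_otus(self):
        table = OtuTable.from_arrays([[3, 0, 1, 0]], ["S1"], list("abcd"))
        assert cs.richness(table)["S1"] == 2

    def test_richness_matches_loop(self, rng):
        table = random_table(rng, n_samples=12, n_otus=40, max_count=2)
        rich = cs.richness(table)
        for sample in table.sample_ids:
            assert rich[sample] == sum(
                1 for v in table.counts.loc[sample] if v > 0
            )

    def test_shannon_uniform_closed_form(self):
        table = OtuTable.from_arrays([[5, 5, 5, 5]], ["S1"], list("abcd"))
        assert cs.shannon(table)["S1"] == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_single_otu_is_zero(self):
        table = OtuTable.from_arrays([[9, 0]], ["S1"], ["a", "b"])
        assert cs.shannon(table)["S1"] == 0.0

    def test_shannon_zero_library_rejected(self):
        table = OtuTable.from_arrays([[1], [0]], ["S1", "S2"], ["a"])
        with pytest.raises(Exception, match="zero library"):
            cs.shannon(table)

    def test_shannon_bounded_by_log_richness(self, rng):
        table = random_table(rng, n_samples=20, n_otus=30)
        h = cs.shannon(table)
        rich = cs.richness(table)
        assert (h <= np.log(rich) + 1e-12).all()


class TestBrayCurtis:
    def test_hand_computed_values(self):
        table = OtuTable.from_arrays(
            [[2, 0], [0, 2], [1, 1], [2, 2]], ["a", "b", "c", "d"], ["x", "y"]
        )
        dm = cs.bray_curtis(table).to_frame()
        assert dm.loc["a", "b"] == pytest.approx(1.0)  # disjoint supports
        assert dm.loc["c", "d"] == pytest.approx(1 / 3)
        assert dm.loc["a", "a"] == 0.0

    def test_identical_samples_distance_zero(self):
        table = OtuTable.from_arrays([[3, 1], [3, 1]], ["a", "b"], ["x", "y"])
        assert cs.bray_curtis(table).to_frame().loc["a", "b"] == 0.0

    def test_matches_scipy_oracle(self, rng):
        table = random_table(rng, n_samples=15, n_otus=60)
        ours = cs.bray_curtis(table).values
        oracle = squareform(pdist(table.counts.to_numpy().astype(float), "braycurtis"))
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_range_and_symmetry(self, rng):
        table = random_table(rng, n_samples=10, n_otus=25)
        d = cs.bray_curtis(table).values
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T)

    def test_all_zero_pair_rejected(self):
        table = OtuTable.from_arrays([[0, 1], [0, 0], [0, 0]], list("abc"), ["x", "y"])
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis(table)


class TestPcoa:
    def test_two_samples_closed_form(self):
        d = 0.6
        dm = cs.DistanceMatrix(("a", "b"), np.array([[0, d], [d, 0.0]]))
        res = cs.pcoa(dm)
        assert res.eigenvalues[0] == pytest.approx(d**2 / 2, abs=1e-12)
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(coords) == pytest.approx([-d / 2, d / 2], abs=1e-12)

    def test_euclidean_embeddable_distances_reconstructed(self, rng):
        points = rng.normal(size=(7, 3))
        d = squareform(pdist(points))
        res = cs.pcoa(cs.DistanceMatrix(tuple("abcdefg"), d))
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_zero_matrix_all_coordinates_zero(self):
        res = cs.pcoa(cs.DistanceMatrix(("a", "b", "c"), np.zeros((3, 3))))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_matches_skbio_eigenvalues(self, rng):
        import skbio

        table = random_table(rng, n_samples=10, n_otus=30)
        dm = cs.bray_curtis(table)
        ours = cs.pcoa(dm)
        oracle = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=list(dm.ids))
        )
        k = len(ours.eigenvalues)
        np.testing.assert_allclose(
            ours.eigenvalues, oracle.eigvals.to_numpy()[:k], atol=1e-8
        )
        # coordinates agree up to per-axis sign
        theirs = oracle.samples.to_numpy()[:, :3]
        for axis in range(3):
            a = ours.coordinates.to_numpy()[:, axis]
            b = theirs[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cs.DistanceMatrix(("a", "b"), np.array([[0, 1], [0.5, 0]]))


def separated_toy_distance():
    """4 samples, two groups, within-distance 0.1, between-distance 0.9."""
    d = np.full((4, 4), 0.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
    return cs.DistanceMatrix(("a", "b", "c", "d"), d)


class TestPermanova:
    def test_perfect_separation_has_maximal_f(self):
        dm = separated_toy_distance()
        meta = two_group_metadata(dm.ids, lambda s: "tissue" if s in "ab" else "holobiont")
        res = cs.permanova(dm, meta, ["Niche"], n_perm=999, seed=0)
        # Of the 4!=24 label permutations only the original partition and its
        # complement (8 permutations) reach the observed F, so p -> 1/3.
        assert res.p_value("Niche") == pytest.approx(1 / 3, abs=0.06)
        assert res.table.loc["Niche", "pseudo_F"] > 1

    def test_r_squared_partition_sums_to_one(self, rng):
        table = random_table(rng, n_samples=12, n_otus=30)
        dm = cs.bray_curtis(table)
        meta = two_group_metadata(
            dm.ids, lambda s: "tissue" if int(s[1:]) % 2 else "holobiont",
            depth=[float(5 + i) for i in range(12)],
        )
        res = cs.permanova(dm, meta, ["Niche", "Depth"], n_perm=99, seed=1)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_skbio_one_factor_f(self, rng):
        import skbio

        table = random_table(rng, n_samples=14, n_otus=40)
        dm = cs.bray_curtis(table)
        meta = two_group_metadata(
            dm.ids, lambda s: "tissue" if int(s[1:]) < 7 else "holobiont"
        )
        ours = cs.permanova(dm, meta, ["Niche"], n_perm=99, seed=0)
        oracle = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=list(dm.ids)),
            grouping=[meta.niche[s] for s in dm.ids],
            permutations=99,
        )
        assert ours.table.loc["Niche", "pseudo_F"] == pytest.approx(
            oracle["test statistic"], abs=1e-10
        )

    def test_matches_vegan_adonis2_sequential(self, tmp_path, rng):
        """Sequential (by-terms) SS of Niche + Depth against R vegan."""
        table = random_table(rng, n_samples=12, n_otus=30)
        dm = cs.bray_curtis(table)
        niche = ["tissue" if int(s[1:]) % 2 else "holobiont" for s in dm.ids]
        depth = [float(v) for v in rng.integers(5, 45, size=12)]
        meta = two_group_metadata(dm.ids, dict(zip(dm.ids, niche)).__getitem__, depth=depth)
        ours = cs.permanova(dm, meta, ["Niche", "Depth"], n_perm=99, seed=0)

        dm_path = tmp_path / "d.tsv"
        pd.DataFrame(dm.values).to_csv(dm_path, sep="\t", index=False, header=False)
        meta_path = tmp_path / "m.tsv"
        pd.DataFrame({"Niche": niche, "Depth": depth}).to_csv(meta_path, sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            d <- as.dist(as.matrix(read.table(args[1], sep="\t")))
            m <- read.table(args[2], sep="\t", header=TRUE)
            res <- adonis2(d ~ Niche + Depth, data=m, permutations=99, by="terms")
            cat(res$SumOfSqs[1], res$SumOfSqs[2], res$F[1], res$F[2], sep="\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(dm_path), str(meta_path)],
            capture_output=True, text=True, check=True,
        )
        ss_niche, ss_depth, f_niche, f_depth = map(float, out.stdout.split())
        assert ours.table.loc["Niche", "sum_sq"] == pytest.approx(ss_niche, rel=1e-6)
        assert ours.table.loc["Depth", "sum_sq"] == pytest.approx(ss_depth, rel=1e-6)
        assert ours.table.loc["Niche", "pseudo_F"] == pytest.approx(f_niche, rel=1e-6)
        assert ours.table.loc["Depth", "pseudo_F"] == pytest.approx(f_depth, rel=1e-6)

    def test_single_level_factor_rejected(self, rng):
        table = random_table(rng, n_samples=6, n_otus=10)
        dm = cs.bray_curtis(table)
        meta = two_group_metadata(dm.ids, lambda s: "tissue")
        with pytest.raises(ValueError, match="Niche"):
            cs.permanova(dm, meta, ["Niche"], n_perm=99, seed=0)

    def test_reproducible_given_seed(self, rng):
        table = random_table(rng, n_samples=10, n_otus=20)
        dm = cs.bray_curtis(table)
        meta = two_group_metadata(dm.ids, lambda s: "tissue" if int(s[1]) < 5 else "holobiont")
        a = cs.permanova(dm, meta, ["Niche"], n_perm=199, seed=42)
        b = cs.permanova(dm, meta, ["Niche"], n_perm=199, seed=42)
        assert a.p_value("Niche") == b.p_value("Niche")


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        res = cs.anosim(
            separated_toy_distance(), ["g1", "g1", "g2", "g2"], n_perm=99, seed=0
        )
        assert res.r == pytest.approx(1.0)

    def test_equal_distances_r_is_zero(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = cs.DistanceMatrix(tuple("abcdef"), d)
        res = cs.anosim(dm, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_skbio_r_statistic(self, rng):
        import skbio

        for _ in range(5):
            table = random_table(rng, n_samples=8, n_otus=25)
            dm = cs.bray_curtis(table)
            grouping = ["g1"] * 4 + ["g2"] * 4
            ours = cs.anosim(dm, grouping, n_perm=99, seed=0)
            oracle = skbio.stats.distance.anosim(
                skbio.DistanceMatrix(dm.values, ids=list(dm.ids)),
                grouping=grouping,
                permutations=99,
            )
            assert ours.r == pytest.approx(oracle["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self, rng):
        table = random_table(rng, n_samples=5, n_otus=10)
        dm = cs.bray_curtis(table)
        with pytest.raises(ValueError, match=">= 2 samples"):
            cs.anosim(dm, ["g1", "g1", "g1", "g1", "g2"], n_perm=99, seed=0)


class TestDiversityModel:
    def test_constant_response_all_f_zero(self):
        meta = two_group_metadata(
            [f"S{i}" for i in range(8)],
            lambda s: "tissue" if int(s[1]) < 4 else "holobiont",
            depth=[5.0, 10, 15, 20, 5, 10, 15, 20],
        )
        y = pd.Series(2.5, index=meta.sample_ids)
        model = cs.diversity_model(y, meta)
        assert (model.loc[["Niche", "Depth"], "F"] == 0).all()
        assert (model.loc[["Niche", "Depth"], "p_value"] == 1).all()

    def test_two_group_closed_form(self, rng):
        # Known means 1 and 2 with small noise: matches textbook one-way ANOVA
        n = 10
        noise = rng.normal(0, 0.1, size=2 * n)
        y_values = np.concatenate([1 + noise[:n], 2 + noise[n:]])
        ids = [f"S{i}" for i in range(2 * n)]
        meta = two_group_metadata(ids, lambda s: "tissue" if int(s[1:]) < n else "holobiont")
        y = pd.Series(y_values, index=ids)
        model = cs.diversity_model(y, meta, terms=("Niche",))
        g1, g2 = y_values[:n], y_values[n:]
        ss_between = n * ((g1.mean() - y_values.mean()) ** 2 + (g2.mean() - y_values.mean()) ** 2)
        ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f_expected = ss_between / (ss_within / (2 * n - 2))
        assert model.loc["Niche", "F"] == pytest.approx(f_expected, rel=1e-10)

    def test_matches_statsmodels_sequential_anova(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        n = 18
        ids = [f"S{i}" for i in range(n)]
        niche = ["tissue", "holobiont", "endosymbiotic"] * 6
        depth = [float(v) for v in rng.integers(5, 50, size=n)]
        meta = two_group_metadata(ids, dict(zip(ids, niche)).__getitem__, depth=depth)
        y = pd.Series(rng.normal(size=n), index=ids)
        ours = cs.diversity_model(y, meta, terms=("Niche", "Depth"))
        frame = pd.DataFrame({"y": y, "Niche": niche, "Depth": depth})
        fit = smf.ols("y ~ C(Niche) + Depth", data=frame).fit()
        oracle = sm.stats.anova_lm(fit, typ=1)
        assert ours.loc["Niche", "F"] == pytest.approx(oracle.loc["C(Niche)", "F"], rel=1e-8)
        assert ours.loc["Depth", "F"] == pytest.approx(oracle.loc["Depth", "F"], rel=1e-8)
        assert ours.loc["Niche", "p_value"] == pytest.approx(
            oracle.loc["C(Niche)", "PR(>F)"], rel=1e-8
        )

    def test_aliased_term_rejected(self):
        meta = two_group_metadata(
            ["S0", "S1", "S2", "S3"],
            lambda s: "tissue" if int(s[1]) < 2 else "holobiont",
            depth=[5.0, 5.0, 9.0, 9.0],  # depth aliased with niche
        )
        y = pd.Series([1.0, 2, 3, 4], index=meta.sample_ids)
        with pytest.raises(ValueError, match="aliased"):
            cs.diversity_model(y, meta, terms=("Niche", "Depth"))

    def test_recovers_planted_niche_effect(self, small_community):
        table, _, metadata, _ = small_community
        samples = metadata.samples_where(species="A_granulosa")
        h = cs.shannon(table.subset_samples(samples))
        model = cs.diversity_model(h, metadata.subset(samples), terms=("Niche",))
        # the symbionts dominate the endosymbiotic niche, depressing evenness
        assert model.loc["Niche", "p_value"] < 0.01


class TestDiffAbundance:
    def make_two_group_table(self, counts_a, counts_b, otu="x"):
        ids = [f"A{i}" for i in range(len(counts_a))] + [
            f"B{i}" for i in range(len(counts_b))
        ]
        values = np.array(counts_a + counts_b)[:, None]
        filler = np.full_like(values, 50)
        table = OtuTable.from_arrays(
            np.hstack([values, filler]), ids, [otu, "filler"]
        )
        meta = two_group_metadata(ids, lambda s: "tissue" if s[0] == "A" else "holobiont")
        return table, meta

    def test_equal_groups_rate_ratio_one(self):
        table, meta = self.make_two_group_table([10, 10], [10, 10])
        res = cs.diff_abundance(table, meta)
        row = res.table.loc["x"]
        assert row["rate_ratio[Niche[tissue]]"] == pytest.approx(1.0, abs=1e-8)
        assert row["F"] == pytest.approx(0.0, abs=1e-8)
        assert row["p_value"] == pytest.approx(1.0)

    def test_saturated_fit_reproduces_group_means(self, rng):
        counts_a = [int(v) for v in rng.poisson(30, size=6)]
        counts_b = [int(v) for v in rng.poisson(80, size=6)]
        table, meta = self.make_two_group_table(counts_a, counts_b)
        res = cs.diff_abundance(table, meta)
        row = res.table.loc["x"]
        # the IRLS fixed point solves the score equation sum(y - mu) = 0 per
        # group, so each fitted group rate is the group's ratio of sums
        sizes = table.library_sizes.to_numpy()
        rate_a = np.sum(counts_a) / sizes[:6].sum()
        rate_b = np.sum(counts_b) / sizes[6:].sum()
        assert row["rate_ratio[Niche[tissue]]"] == pytest.approx(rate_a / rate_b, rel=1e-8)

    def test_matches_statsmodels_quasipoisson(self, rng):
        import statsmodels.api as sm

        counts = [int(v) for v in rng.negative_binomial(5, 0.3, size=12)]
        table, meta = self.make_two_group_table(counts[:6], counts[6:])
        res = cs.diff_abundance(table, meta)
        row = res.table.loc["x"]

        y = np.array(counts, dtype=float)
        X = np.column_stack(
            [np.ones(12), [1.0 if s[0] == "A" else 0.0 for s in table.sample_ids]]
        )
        offset = np.log(table.library_sizes.to_numpy().astype(float))
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        assert row["rate_ratio[Niche[tissue]]"] == pytest.approx(
            float(np.exp(fit.params[1])), rel=1e-7
        )
        phi = float(fit.pearson_chi2 / fit.df_resid)
        assert row["dispersion"] == pytest.approx(phi, rel=1e-6)
        null = sm.GLM(y, X[:, :1], family=sm.families.Poisson(), offset=offset).fit()
        f_expected = (null.deviance - fit.deviance) / phi
        assert row["F"] == pytest.approx(f_expected, rel=1e-6)

    def test_fixed_dispersion_one_reproduces_poisson_deviance_test(self, rng):
        from scipy import stats as sps

        counts = [int(v) for v in rng.poisson(20, size=10)]
        table, meta = self.make_two_group_table(counts[:5], counts[5:])
        res = cs.diff_abundance(table, meta, dispersion=1.0)
        row = res.table.loc["x"]
        # with phi=1 the F statistic is the deviance difference (df_num=1)
        import statsmodels.api as sm

        y = np.array(counts, dtype=float)
        X = np.column_stack([np.ones(10), [1.0] * 5 + [0.0] * 5])
        offset = np.log(table.library_sizes.to_numpy().astype(float))
        full = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        null = sm.GLM(y, X[:, :1], family=sm.families.Poisson(), offset=offset).fit()
        assert row["F"] == pytest.approx(null.deviance - full.deviance, rel=1e-6, abs=1e-8)

    def test_all_zero_otu_flagged_and_excluded(self):
        ids = ["A0", "A1", "B0", "B1"]
        table = OtuTable.from_arrays(
            [[0, 5], [0, 7], [0, 4], [0, 9]], ids, ["dead", "alive"]
        )
        meta = two_group_metadata(ids, lambda s: "tissue" if s[0] == "A" else "holobiont")
        res = cs.diff_abundance(table, meta)
        assert res.table.loc["dead", "status"] == "all_zero"
        assert np.isnan(res.table.loc["dead", "q_value"])
        assert res.table.loc["alive", "status"] == "ok"


class TestBhAdjust:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            cs.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate_inputs(self):
        assert cs.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(cs.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_matches_statsmodels_and_dominates_p(self, p_values):
        from statsmodels.stats.multitest import multipletests

        q = cs.bh_adjust(p_values)
        _, q_oracle, *_ = multipletests(p_values, method="fdr_bh")
        np.testing.assert_allclose(q, q_oracle, atol=1e-12)
        assert (q >= np.asarray(p_values) - 1e-15).all()
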