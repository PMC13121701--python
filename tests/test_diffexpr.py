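"""Moderated-t contrasts: textbook oracles, shrinkage limits, BH, volcano logic."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from medivar import (
    SimConfig,
    generate,
    ContrastSpec,
    ModerationPrior,
    PairwiseContrast,
    fit_contrast,
    fit_all_contrasts,
    adjust_bh,
    classify_volcano,
    collect_de_sets,
    pairwise_summary,
    top_fc_subset,
    top_genes_table,
)
from medivar.diffexpr import DesignError, DegenerateFitError, estimate_prior


def _toy(seed=0, n_genes=40):
    rng = np.random.default_rng(seed)
    log2 = pd.DataFrame(
        rng.normal(8, 1, size=(n_genes, 6)),
        index=[f"g{i:02d}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(6)],
    )
    samples = pd.DataFrame(
        {"medium": ["A"] * 3 + ["B"] * 3, "donor": ["d1", "d2", "d3"] * 2},
        index=log2.columns,
    )
    return log2, samples


SPEC_AB = ContrastSpec("medium", "A", "B")


class TestFitContrast:
    def test_identical_groups_null(self):
        log2, samples = _toy()
        log2.iloc[:, 3:] = log2.iloc[:, :3].to_numpy()  # group B = group A sample-for-sample
        res = fit_contrast(log2, samples, SPEC_AB, prior=ModerationPrior(4.0, 0.05))
        assert np.allclose(res.table["log2fc"], 0.0)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["pvalue"], 1.0)

    def test_plain_t_matches_pooled_oracle(self):
        log2, samples = _toy(seed=1)
        res = fit_contrast(log2, samples, SPEC_AB, prior=ModerationPrior(0.0, 1.0))
        from scipy import stats

        for g in log2.index:
            a = log2.loc[g, samples.index[samples["medium"] == "A"]]
            b = log2.loc[g, samples.index[samples["medium"] == "B"]]
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert res.table.loc[g, "t"] == pytest.approx(t_ref, abs=1e-10)
            assert res.table.loc[g, "pvalue"] == pytest.approx(p_ref, abs=1e-10)

    def test_infinite_prior_fully_pools(self):
        log2, samples = _toy(seed=2)
        res = fit_contrast(log2, samples, SPEC_AB, prior=ModerationPrior(math.inf, 0.3))
        assert np.allclose(res.table["s2_moderated"], 0.3)

    def test_moderation_shrinks_toward_prior_monotonically(self):
        log2, samples = _toy(seed=3, n_genes=200)
        prior = ModerationPrior(4.0, 0.5)
        mod = fit_contrast(log2, samples, SPEC_AB, prior=prior)
        plain = fit_contrast(log2, samples, SPEC_AB, prior=ModerationPrior(0.0, 1.0))
        s2 = mod.table["s2"]
        below = (s2 < prior.s0_sq) & (plain.table["t"] != 0)
        above = s2 > prior.s0_sq
        assert (mod.table.loc[below, "t"].abs() < plain.table.loc[below, "t"].abs()).all()
        assert (mod.table.loc[above, "t"].abs() > plain.table.loc[above, "t"].abs()).all()

    def test_antisymmetry_under_level_swap(self):
        log2, samples = _toy(seed=4)
        fwd = fit_contrast(log2, samples, SPEC_AB)
        rev = fit_contrast(log2, samples, ContrastSpec("medium", "B", "A"))
        np.testing.assert_allclose(rev.table["log2fc"], -fwd.table["log2fc"])
        np.testing.assert_allclose(rev.table["pvalue"], fwd.table["pvalue"])
        assert (rev.table["volcano_class"] == fwd.table["volcano_class"]).all()

    def test_underreplicated_level_rejected(self):
        log2, samples = _toy()
        samples.loc[samples.index[0], "medium"] = "C"
        with pytest.raises(DesignError, match="replicate"):
            PairwiseContrast(log2, samples, ContrastSpec("medium", "C", "B"))

    def test_all_zero_variance_degenerate_for_estimation(self):
        log2, samples = _toy()
        log2.iloc[:, :] = 1.0
        with pytest.raises(DegenerateFitError):
            fit_contrast(log2, samples, SPEC_AB, prior="estimate")

    def test_matches_limma_reference(self, tmp_path):
        """The estimated prior and moderated statistics agree with the R
        reference implementation of empirical-Bayes variance shrinkage."""
        log2, samples = _toy(seed=6, n_genes=150)
        res = fit_contrast(log2, samples, SPEC_AB, prior="estimate")
        mat_path = tmp_path / "m.tsv"
        log2.to_csv(mat_path, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("%s", row.names = 1))
            design <- cbind(Intercept = 1, AvsB = c(1, 1, 1, 0, 0, 0))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(
              gene = rownames(m),
              t = fit$t[, "AvsB"],
              p = fit$p.value[, "AvsB"],
              d0 = fit$df.prior,
              s0 = fit$s2.prior
            )
            write.table(out, "%s", sep = "\t", row.names = FALSE, quote = FALSE)
            """
            % (mat_path, tmp_path / "out.tsv")
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        assert res.prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(res.table["t"], ref["t"].reindex(res.table.index), rtol=1e-6)
        np.testing.assert_allclose(res.table["pvalue"], ref["p"].reindex(res.table.index), rtol=1e-6)


class TestEstimatePrior:
    def test_recovers_prior_from_simulated_variances(self):
        # s_g^2 ~ s0^2 * F(dg, d0) scaled: moment matching should land near truth
        rng = np.random.default_rng(10)
        d0, s0, dg, n = 6.0, 0.2, 4, 50_000
        s2 = s0 * rng.chisquare(dg, n) / dg * d0 / rng.chisquare(d0, n)
        prior = estimate_prior(s2, dg)
        assert prior.d0 == pytest.approx(d0, rel=0.1)
        assert prior.s0_sq == pytest.approx(s0, rel=0.05)

    def test_homoscedastic_variances_give_infinite_df(self):
        prior = estimate_prior(np.full(100, 0.25), dg=4)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25, rel=1e-6)


class TestAdjustBH:
    def test_worked_step_up_example(self):
        out = adjust_bh(np.array([0.01, 0.02, 0.04, 0.5]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_ties_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.full(7, 0.02)), 0.02)

    def test_adjusted_at_least_raw_and_bounded(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))


class TestClassifyVolcano:
    @pytest.mark.parametrize(
        "log2fc,adj_p,expected",
        [
            (1.5, 0.01, "red"),
            (-1.5, 0.01, "red"),
            (0.5, 0.01, "blue"),
            (1.0, 0.05, "green"),  # boundary p = alpha is non-significant
            (1.0, 0.2, "green"),
            (0.2, 0.8, "grey"),
        ],
    )
    def test_classes(self, log2fc, adj_p, expected):
        assert classify_volcano(np.array([log2fc]), np.array([adj_p]))[0] == expected


class TestDeSetOperations:
    def _fitted(self, seed=20, **sim_kwargs):
        from medivar import exclude_sex_genes

        matrix, samples, genes, truth = generate(SimConfig(seed=seed, n_genes=300, **sim_kwargs))
        # sex-linked genes are removed before DE, as in the pipeline; a
        # male-vs-female contrast flags them by construction otherwise
        log2 = np.log2(exclude_sex_genes(matrix, genes))
        media = fit_all_contrasts(log2, samples, "medium")
        donors = fit_all_contrasts(log2, samples, "donor")
        return media, donors

    def test_null_data_gives_empty_sets(self):
        media, donors = self._fitted(seed=21, sigma_medium=0.0, sigma_donor=0.0)
        m, l, c = collect_de_sets(media, donors)
        assert m == set() and l == set() and c == set()

    def test_union_bound_and_order_invariance(self):
        media, donors = self._fitted(seed=22)
        m, l, c = collect_de_sets(media, donors)
        assert len(c) <= len(m) + len(l)
        reordered = dict(reversed(list(media.items())))
        m2, l2, c2 = collect_de_sets(reordered, donors)
        assert (m2, l2, c2) == (m, l, c)

    def test_pairwise_summary_formulas(self):
        class Fake:
            def __init__(self, n):
                self._n = n

            def red_genes(self):
                return list(range(self._n))

        assert pairwise_summary({"a": Fake(2), "b": Fake(4)}) == (3.0, pytest.approx(math.sqrt(2)))
        mean, sd = pairwise_summary({"a": Fake(100), "b": Fake(200), "c": Fake(600)})
        assert mean == pytest.approx(300.0)
        assert sd == pytest.approx(264.57513110645906)
        same = pairwise_summary({"a": Fake(5), "b": Fake(5), "c": Fake(5)})
        assert same == (5.0, 0.0)
        with pytest.raises(ValueError):
            pairwise_summary({"a": Fake(1)})


class TestTopSubsets:
    def _single_contrast(self, n_red=100, seed=30):
        rng = np.random.default_rng(seed)
        n = n_red + 50
        table = pd.DataFrame(
            {
                "log2fc": np.concatenate([rng.uniform(1, 5, n_red), rng.uniform(0, 0.5, 50)]),
                "adj_pvalue": np.concatenate([rng.uniform(0, 0.04, n_red), rng.uniform(0.1, 1, 50)]),
            },
            index=[f"g{i:03d}" for i in range(n)],
        )
        table["volcano_class"] = classify_volcano(table["log2fc"], table["adj_pvalue"])

        class Res:
            pass

        r = Res()
        r.table = table
        return r

    def test_top_fraction_of_single_contrast(self):
        r = self._single_contrast(n_red=100)
        subset = top_fc_subset({"c": r}, fraction=0.05)
        assert len(subset) == 5
        red = r.table[r.table["volcano_class"] == "red"]
        expected = set(red["log2fc"].abs().nlargest(5).index)
        assert subset == expected

    def test_union_deduplicates_shared_top_genes(self):
        r = self._single_contrast()
        subset = top_fc_subset({"c1": r, "c2": r}, fraction=0.05)
        assert len(subset) == 5

    def test_per_contrast_then_union_counting(self):
        rs = {f"c{i}": self._single_contrast(seed=40 + i) for i in range(6)}
        subset = top_fc_subset(rs, fraction=0.05)
        # 6 disjoint-ish contrasts x ceil(0.05*100) = 5 each
        per = [set(top_fc_subset({k: v}, 0.05)) for k, v in rs.items()]
        assert subset == set().union(*per)

    def test_top_genes_table_truncation_and_tiebreak(self):
        r = self._single_contrast(n_red=2)
        t = top_genes_table({"c": r}, k=3)
        assert len(t) == 2
        # equal |log2fc|: order by adjusted p then gene id
        tbl = pd.DataFrame(
            {
                "log2fc": [2.0, -2.0, 2.0],
                "adj_pvalue": [0.01, 0.001, 0.001],
            },
            index=["gb", "gc", "ga"],
        )
        tbl["volcano_class"] = classify_volcano(tbl["log2fc"], tbl["adj_pvalue"])

        class Res:
            pass

        r2 = Res()
        r2.table = tbl
        t2 = top_genes_table({"c": r2}, k=3)
        assert t2["gene"].tolist() == ["ga", "gc", "gb"]
        assert t2["fold_change"].tolist() == pytest.approx([4.0, 4.0, 4.0])
        assert t2.loc[1, "direction"] == "down"
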