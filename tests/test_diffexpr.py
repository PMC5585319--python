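"""Moderated t, BH FDR, group summaries and candidate selection."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from lncsig import (DEResult, ModeratedTTest, bh_fdr, differential_abundance,
                    group_summary, moderated_t, select_candidates)
from lncsig.reference import (N_BENIGN, N_MALIGNANT, SIGNATURE_PROBES,
                              panel_summary)
from tests.helpers import null_matrix


def _matrix_with_group_means(benign_means, malignant_means, jitter=0.0,
                             seed=0):
    """Matrix whose group means are exactly the given values (n = 21/30)."""
    rng = np.random.default_rng(seed)
    probes = list(benign_means.index)
    rows = []
    for mean_vec, n in ((benign_means, N_BENIGN), (malignant_means, N_MALIGNANT)):
        block = np.tile(mean_vec.to_numpy(float), (n, 1))
        if jitter:
            noise = rng.normal(0, jitter, size=block.shape)
            block = block + noise - noise.mean(axis=0)   # means stay exact
        rows.append(block)
    X = pd.DataFrame(np.vstack(rows), columns=probes)
    y = np.array([False] * N_BENIGN + [True] * N_MALIGNANT)
    return X, y


class TestGroupSummary:
    def test_reference_panel_arithmetic(self):
        """Size-weighted overall means and mean-ratio fold changes recomputed
        from the printed group means agree with the printed columns (the
        printed inputs are rounded to one decimal, bounding the achievable
        agreement)."""
        ref = panel_summary()
        X, y = _matrix_with_group_means(ref["benign_mean"],
                                        ref["malignant_mean"], jitter=0.3)
        out = group_summary(X, y)
        assert np.allclose(out["benign_mean"], ref["benign_mean"], atol=1e-9)
        assert np.allclose(out["malignant_mean"], ref["malignant_mean"],
                           atol=1e-9)
        sig = list(SIGNATURE_PROBES)
        assert (np.abs(out.loc[sig, "overall_mean"]
                       - ref.loc[sig, "overall_mean"]) <= 0.08).all()
        assert (np.abs(out.loc[sig, "fold_change"]
                       - ref.loc[sig, "fold_change"]) <= 0.06).all()
        # worked examples at exact one-decimal rounding
        assert round(out.loc["PANDA", "fold_change"], 1) == 1.3
        assert round(out.loc["GLIS3-AS1", "overall_mean"], 1) == 11.7

    def test_equal_group_means_give_unit_fold(self):
        means = pd.Series([8.0, 12.0], index=["A", "B"])
        X, y = _matrix_with_group_means(means, means)
        out = group_summary(X, y)
        assert np.allclose(out["fold_change"], 1.0)
        assert np.allclose(out["overall_mean"], means)

    def test_overall_mean_is_size_weighted(self):
        b = pd.Series([10.6], index=["G"])
        m = pd.Series([12.4], index=["G"])
        X, y = _matrix_with_group_means(b, m)
        out = group_summary(X, y)
        expected = (N_BENIGN * 10.6 + N_MALIGNANT * 12.4) / 51
        assert out.loc["G", "overall_mean"] == pytest.approx(expected)

    def test_empty_group_is_error(self):
        X = pd.DataFrame({"A": [1.0, 2.0]})
        with pytest.raises(ValueError):
            group_summary(X, np.array([True, True]))


class TestModeratedT:
    def test_prior_df_zero_equals_pooled_t(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        y = np.array([False, False, False, True, True, True])
        res = moderated_t(X, y, prior_df=0)
        assert res.loc["A", "moderated_t"] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))
        assert res.loc["A", "moderated_t"] == pytest.approx(res.loc["A", "t"])

    def test_prior_df_infinite_pools_all_variances(self):
        X, y = null_matrix(6, 6, 30, seed=2)
        res = moderated_t(X, y, prior_df=np.inf)
        s0 = res.attrs["s0_sq"]
        # all posterior variances collapse to the prior: t is diff / const
        se = np.sqrt(s0 * (1 / 6 + 1 / 6))
        assert np.allclose(res["moderated_t"], res["diff"] / se)

    def test_equal_group_means_give_zero_t_unit_p(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array([False] * 3 + [True] * 3)
        res = moderated_t(X, y)
        assert res.loc["A", "moderated_t"] == pytest.approx(0.0)
        assert res.loc["A", "p"] == pytest.approx(1.0)

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check of the empirical-Bayes fit and moderated
        statistics against the Bioconductor reference implementation."""
        rng = np.random.default_rng(1)
        n1, n2, p = 9, 12, 40
        X = pd.DataFrame(
            rng.normal(8, 1, size=(n1 + n2, p)) * rng.uniform(0.5, 2, size=p),
            columns=[f"P{i}" for i in range(p)],
        )
        y = np.array([0] * n1 + [1] * n2)
        mat_path = tmp_path / "mat.csv"
        out_path = tmp_path / "limma.csv"
        X.T.to_csv(mat_path)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.csv('{mat_path}', row.names=1))\n"
            f"y <- c({','.join(map(str, y))})\n"
            "fit <- eBayes(lmFit(x, cbind(1, y)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  d0=fit$df.prior, s0=fit$s2.prior)\n"
            f"write.csv(out, '{out_path}')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_path, index_col=0)
        res = moderated_t(X, y)
        assert res.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.attrs["s0_sq"] == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        assert np.allclose(res["moderated_t"], ref["t"], rtol=1e-9, atol=1e-12)
        assert np.allclose(res["p"], ref["p"], rtol=1e-9, atol=1e-12)

    def test_all_zero_variance_is_error(self):
        X = pd.DataFrame({"A": [1.0, 1.0, 1.0, 1.0]})
        y = np.array([False, False, True, True])
        with pytest.raises(ValueError):
            moderated_t(X, y)

    def test_tiny_groups_rejected(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            moderated_t(X, np.array([False, True, True]))


class TestBHFdr:
    def test_stepup_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_fixed_point(self):
        q = bh_fdr([0.3] * 7)
        assert np.allclose(q, 0.3)

    def test_reference_fdr_column_reproduced(self):
        """BH over the printed p column reproduces the printed FDR column to
        about one print unit (the published FDRs were computed from
        unrounded p-values; three-decimal printed inputs propagate to just
        over 0.01 in the step-up)."""
        ref = panel_summary()
        q = bh_fdr(ref["p"].to_numpy())
        assert np.abs(q - ref["fdr"].to_numpy()).max() <= 0.012

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_dominates_p(self, ps):
        q = bh_fdr(ps)
        _, q_ref, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert ((0 <= q) & (q <= 1)).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q = bh_fdr(ps)
        q_perm = bh_fdr([ps[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)


class TestSelection:
    def _reference_de(self):
        ref = panel_summary()
        table = ref.rename(columns={"fdr": "q_printed"}).copy()
        table["q"] = bh_fdr(table["p"].to_numpy())
        return DEResult(table=table, d0=np.nan, s0_sq=np.nan)

    def test_reference_panel_selects_the_eight_signature_probes(self):
        de = self._reference_de()
        selected = select_candidates(de, alpha=0.05)
        assert set(selected) == set(SIGNATURE_PROBES)
        assert len(selected) == 8
        assert selected[0] == "GLIS3-AS1"      # sorted by p ascending

    def test_alpha_extremes(self):
        de = self._reference_de()
        assert select_candidates(de, alpha=0.0) == []
        assert len(select_candidates(de, alpha=1.0)) == 28

    def test_null_fdr_calibration(self):
        """Average fraction of probes at q < 0.05 under the null stays at or
        below the nominal level."""
        fracs = []
        for seed in range(5):
            X, y = null_matrix(30, 21, 400, seed=seed)
            de = differential_abundance(X, y)
            fracs.append((de.table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_estimator_transform_selects_columns(self):
        X, y = null_matrix(10, 10, 20, seed=0)
        X["PLANTED"] = np.where(y, 12.0, 8.0) + \
            np.random.default_rng(1).normal(0, 0.5, 20)
        est = ModeratedTTest(alpha=0.01).fit(X, y)
        assert "PLANTED" in est.selected_probes_
        assert list(est.transform(X).columns) == est.selected_probes_
        assert est.q_values_.min() >= est.p_values_.min()
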