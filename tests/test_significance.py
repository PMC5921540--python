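import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ampcna as a
from ampcna.containers import AmpcnaError
from ampcna.significance import MAD_CONSTANT, _bonferroni_factor, _correct_one


def _cnm(arr, amps=None, samples=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    amps = amps or [f"g{i}_1" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return a.CopyNumberMatrix(pd.DataFrame(arr, index=amps, columns=samples))


# ---------------------------------------------------------------- null models


class TestNullModels:
    def test_hand_computed_mad(self):
        nulls = a.fit_null_models(_cnm([1.8, 1.9, 2.0, 2.1, 2.2]))
        assert nulls.sigma.iloc[0] == pytest.approx(1.4826 * 0.1, abs=1e-12)
        assert not nulls.degenerate.iloc[0]

    def test_constant_row_is_degenerate(self):
        nulls = a.fit_null_models(_cnm([2.0, 2.0, 2.0]))
        assert nulls.sigma.iloc[0] == 0.0
        assert nulls.degenerate_amplicons == ["g0_1"]

    def test_majority_constant_row_is_degenerate_despite_outlier(self):
        # median of |deviations| is 0: robustness cuts both ways
        nulls = a.fit_null_models(_cnm([2.0, 2.0, 2.0, 10.0]))
        assert nulls.degenerate.iloc[0]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_normal_consistent_mad(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(2.0, 0.3, (4, 25))
        nulls = a.fit_null_models(_cnm(vals))
        expected = stats.median_abs_deviation(vals, axis=1, scale="normal")
        np.testing.assert_allclose(nulls.sigma.to_numpy(), expected, rtol=2e-4)


# ------------------------------------------------------------ outlier p-values


def _norm_sf_oracle(z: float) -> float:
    """Upper-tail standard normal probability via the error function."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


class TestAmpliconPvalues:
    def test_center_gives_half_half(self):
        cn = _cnm([1.8, 1.9, 2.0, 2.1, 2.2])
        table = a.amplicon_pvalues(cn, a.fit_null_models(cn))
        assert table.p_gain.iloc[0, 2] == pytest.approx(0.5, abs=1e-15)
        assert table.p_loss.iloc[0, 2] == pytest.approx(0.5, abs=1e-15)

    def test_tail_matches_independent_cdf(self):
        # sigma fixed by construction: MAD of the row is 0.2 / 1.4826... no,
        # construct directly: z = (2.392 - 2) / 0.2 = 1.96
        nulls = a.NullModelSet(sigma=pd.Series([0.2], index=["g0_1"]))
        cn = _cnm([[2.392]])
        table = a.amplicon_pvalues(cn, nulls)
        z = 1.96
        assert table.p_gain.iloc[0, 0] == pytest.approx(_norm_sf_oracle(z), abs=1e-10)
        assert table.p_gain.iloc[0, 0] == pytest.approx(0.0250, abs=5e-5)

    @given(st.floats(0.0, 8.0), st.floats(0.05, 2.0))
    def test_gain_plus_loss_is_one(self, dev, sigma):
        nulls = a.NullModelSet(sigma=pd.Series([sigma], index=["g0_1"]))
        table = a.amplicon_pvalues(_cnm([[2.0 + dev]]), nulls)
        total = table.p_gain.iloc[0, 0] + table.p_loss.iloc[0, 0]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_amplicon_is_uncallable(self):
        cn = _cnm([[2.0, 2.0, 9.0]])
        table = a.amplicon_pvalues(cn, a.fit_null_models(cn))
        assert (table.p_gain.to_numpy() == 1.0).all()
        assert (table.p_loss.to_numpy() == 1.0).all()

    def test_amplicon_mismatch_rejected(self):
        cn = _cnm([[2.0, 2.1, 1.9]])
        nulls = a.NullModelSet(sigma=pd.Series([0.1], index=["other"]))
        with pytest.raises(AmpcnaError, match="different amplicon set"):
            a.amplicon_pvalues(cn, nulls)


# ------------------------------------------------------------- Fisher's method


def _fisher_df4_oracle(p1: float, p2: float) -> float:
    """Closed-form chi-square survival at 4 df: e^{-x/2} (1 + x/2)."""
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def _amp_table(p_gain, amps, samples=("s1",)):
    pg = pd.DataFrame(p_gain, index=amps, columns=list(samples))
    return a.SignificanceTable(axis="amplicon", p_gain=pg, p_loss=1.0 - pg)


class TestFisherCombination:
    def test_single_amplicon_is_identity(self):
        gmap = a.parse_gene_map(["A_1"])
        table = _amp_table([[0.03]], ["A_1"])
        gene = a.combine_fisher(table, gmap)
        assert gene.p_gain.iloc[0, 0] == pytest.approx(0.03, abs=1e-12)

    @pytest.mark.parametrize(
        "p1, p2",
        [(0.5, 0.5), (0.01, 0.04), (0.9, 0.2), (1e-8, 0.7)],
    )
    def test_two_amplicons_match_closed_form(self, p1, p2):
        gmap = a.parse_gene_map(["A_1", "A_2"])
        gene = a.combine_fisher(_amp_table([[p1], [p2]], ["A_1", "A_2"]), gmap)
        assert gene.p_gain.iloc[0, 0] == pytest.approx(
            _fisher_df4_oracle(p1, p2), rel=1e-10
        )

    def test_order_invariant_within_gene(self):
        gmap = a.parse_gene_map(["A_1", "A_2"])
        g1 = a.combine_fisher(_amp_table([[0.01], [0.4]], ["A_1", "A_2"]), gmap)
        g2 = a.combine_fisher(_amp_table([[0.4], [0.01]], ["A_1", "A_2"]), gmap)
        assert g1.p_gain.iloc[0, 0] == g2.p_gain.iloc[0, 0]

    def test_zero_pvalue_is_clamped_and_counted(self):
        gmap = a.parse_gene_map(["A_1", "A_2"])
        gene = a.combine_fisher(_amp_table([[0.0], [0.5]], ["A_1", "A_2"]), gmap)
        assert np.isfinite(gene.p_gain.iloc[0, 0])
        assert gene.p_gain.iloc[0, 0] < 1e-100
        assert gene.zero_p_clamped >= 1

    def test_degenerate_amplicons_are_excluded(self):
        gmap = a.parse_gene_map(["A_1", "A_2"])
        table = _amp_table([[0.03], [1.0]], ["A_1", "A_2"])
        table.degenerate_units = ["A_2"]
        gene = a.combine_fisher(table, gmap)
        # behaves like the single-amplicon gene
        assert gene.p_gain.iloc[0, 0] == pytest.approx(0.03, abs=1e-12)

    def test_gene_with_only_degenerate_amplicons_is_uncallable(self):
        gmap = a.parse_gene_map(["A_1"])
        table = _amp_table([[1.0]], ["A_1"])
        table.degenerate_units = ["A_1"]
        gene = a.combine_fisher(table, gmap)
        assert gene.p_gain.iloc[0, 0] == 1.0
        assert gene.degenerate_units == ["A"]  # the gene itself is uncallable


# --------------------------------------------------- multiple-testing control


def _bh_bruteforce(p):
    """Step-up definition, evaluated literally: adj_i = min over j with
    p_(j) >= p_(i) of m * p_(j) / j, capped at 1."""
    p = list(p)
    m = len(p)
    srt = sorted(p)
    out = []
    for pi in p:
        candidates = [
            m * pj / (j + 1) for j, pj in enumerate(srt) if pj >= pi - 1e-300
        ]
        out.append(min(1.0, min(candidates)))
    return np.array(out)


class TestCorrections:
    def test_scope_none_is_identity(self):
        rng = np.random.default_rng(0)
        p = pd.DataFrame(rng.uniform(size=(3, 4)))
        for method in ("bonferroni", "bh"):
            out = _correct_one(p, "none", method)
            np.testing.assert_allclose(out.to_numpy(), p.to_numpy(), atol=1e-15)

    def test_bonferroni_scope_both_cohort_factor(self):
        # 48 genes x 184 samples -> factor 8832
        assert _bonferroni_factor("both", 184, 48) == 8832
        p = pd.DataFrame(np.full((48, 184), 1e-6))
        out = _correct_one(p, "both", "bonferroni")
        np.testing.assert_allclose(out.to_numpy(), 8.832e-3)

    def test_bh_pooled_worked_example(self):
        p = pd.DataFrame([[0.01, 0.02], [0.03, 0.04]])
        out = _correct_one(p, "both", "bh")
        np.testing.assert_allclose(out.to_numpy(), 0.04)

    @pytest.mark.parametrize("scope", ["none", "samples", "genes", "both"])
    @pytest.mark.parametrize("method", ["bonferroni", "bh"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_small_matrices(self, scope, method, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(1, 6, size=2)
        p = pd.DataFrame(np.round(rng.uniform(size=shape), 3))
        out = _correct_one(p, scope, method).to_numpy()
        arr = p.to_numpy()
        n_units, n_samples = arr.shape
        if method == "bonferroni":
            expected = np.minimum(arr * _bonferroni_factor(scope, n_samples, n_units), 1.0)
        elif scope == "none":
            expected = arr
        elif scope == "both":
            expected = _bh_bruteforce(arr.ravel()).reshape(arr.shape)
        elif scope == "samples":
            expected = np.vstack([_bh_bruteforce(row) for row in arr])
        else:
            expected = np.column_stack([_bh_bruteforce(col) for col in arr.T])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_corrected_at_least_raw_and_bh_at_most_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = pd.DataFrame(rng.uniform(size=(4, 6)))
        for scope in ("samples", "genes", "both"):
            bonf = _correct_one(p, scope, "bonferroni").to_numpy()
            bh = _correct_one(p, scope, "bh").to_numpy()
            assert (bonf >= p.to_numpy() - 1e-15).all()
            assert (bh >= p.to_numpy() - 1e-15).all()
            assert (bh <= bonf + 1e-15).all()

    def test_unknown_scope_or_method_rejected(self):
        table = _amp_table([[0.5]], ["A_1"])
        with pytest.raises(AmpcnaError, match="scope"):
            a.correct_pvalues(table, "cohort", "bh")
        with pytest.raises(AmpcnaError, match="method"):
            a.correct_pvalues(table, "both", "holm")


# ------------------------------------------------------------------- calling


def _pipeline(cov):
    model = a.CopyNumberModel(cov)
    return model


class TestCalling:
    def _tables(self, p_gain_gene, cn_gene, p_gain_amp, gmap, samples=("s1",)):
        genes = gmap.genes
        pg = pd.DataFrame(p_gain_gene, index=genes, columns=list(samples))
        gene_table = a.SignificanceTable(
            axis="gene",
            p_gain=pg,
            p_loss=1 - pg,
            p_gain_corrected=pg,
            p_loss_corrected=1 - pg,
            correction_scope="none",
            correction_method="bonferroni",
        )
        amps = gmap.amplicons
        pa = pd.DataFrame(p_gain_amp, index=amps, columns=list(samples))
        amp_table = a.SignificanceTable(
            axis="amplicon",
            p_gain=pa,
            p_loss=1 - pa,
            p_gain_corrected=pa,
            p_loss_corrected=1 - pa,
            correction_scope="none",
            correction_method="bonferroni",
        )
        gene_cn = a.GeneCopyNumberMatrix(
            pd.DataFrame(cn_gene, index=genes, columns=list(samples))
        )
        return gene_table, gene_cn, amp_table

    def test_nothing_passes_when_all_p_are_one(self):
        gmap = a.parse_gene_map(["A_1", "A_2"])
        gt, gcn, at = self._tables([[1.0]], [[4.0]], [[1.0], [1.0]], gmap)
        # p == 1 in both directions requires building tables by hand
        gt.p_loss_corrected.iloc[:, :] = 1.0
        at.p_loss_corrected.iloc[:, :] = 1.0
        calls = a.call_cnas(gt, gcn, at, gmap)
        assert calls.n_gains == 0 and calls.n_losses == 0

    def test_gain_requires_cn_above_two(self):
        gmap = a.parse_gene_map(["A_1"])
        gt, gcn, at = self._tables([[1e-9]], [[1.7]], [[1e-9]], gmap)
        calls = a.call_cnas(gt, gcn, at, gmap)
        assert calls.n_gains == 0  # significant but CN below 2: not a gain

    def test_support_count_and_fraction_rules(self):
        gmap = a.parse_gene_map(["A_1", "A_2", "A_3"])
        # only one amplicon individually significant
        gt, gcn, at = self._tables([[1e-9]], [[5.0]], [[1e-9], [0.4], [0.6]], gmap)
        assert a.call_cnas(gt, gcn, at, gmap, support=("none",)).n_gains == 1
        assert a.call_cnas(gt, gcn, at, gmap, support=("count", 2)).n_gains == 0
        # 50% of 3 amplicons means at least 2 (ceiling)
        assert a.call_cnas(gt, gcn, at, gmap, support=("fraction", 0.5)).n_gains == 0
        at.p_gain_corrected.iloc[1, 0] = 1e-4
        assert a.call_cnas(gt, gcn, at, gmap, support=("fraction", 0.5)).n_gains == 1

    def test_alpha_out_of_range_rejected(self):
        gmap = a.parse_gene_map(["A_1"])
        gt, gcn, at = self._tables([[0.5]], [[2.0]], [[0.5]], gmap)
        with pytest.raises(AmpcnaError, match="alpha"):
            a.call_cnas(gt, gcn, at, gmap, alpha=1.5)

    def test_amplicon_wise_single_gain(self):
        cn = _cnm([[3.0, 2.0, 2.1, 1.9, 2.05]])
        nulls = a.NullModelSet(sigma=pd.Series([0.1], index=cn.amplicon_ids))
        table = a.amplicon_pvalues(cn, nulls)
        calls = a.run_amplicon_wise(table, cn, scope="none", method="bonferroni")
        assert calls.mode == "amplicon_wise"
        assert calls.n_gains == 1
        assert calls.status.iloc[0, 0] == "gain"

    def test_amplicon_wise_no_calls_at_p_half(self):
        cn = _cnm([[2.0, 2.0, 2.0, 2.0]])
        nulls = a.NullModelSet(sigma=pd.Series([0.1], index=cn.amplicon_ids))
        calls = a.run_amplicon_wise(
            a.amplicon_pvalues(cn, nulls), cn, scope="none", method="bonferroni"
        )
        assert calls.n_gains == 0 and calls.n_losses == 0


# -------------------------------------------------- cohort-level set relations


@pytest.fixture(scope="module")
def cohort_model(spiked_cohort):
    cov, _ = spiked_cohort
    return a.CopyNumberModel(cov)


class TestCallSetRelations:
    def test_fdr_calls_are_superset_of_fwer_calls(self, cohort_model):
        fwer = cohort_model.fit(method="bonferroni").calls
        fdr = cohort_model.fit(method="bh").calls
        called_fwer = fwer.status != "none"
        assert fdr.n_gains >= fwer.n_gains and fdr.n_losses >= fwer.n_losses
        assert (fdr.status.to_numpy()[called_fwer.to_numpy()] != "none").all()

    def test_supported_calls_are_subset_of_unfiltered(self, cohort_model):
        plain = cohort_model.fit(support=("none",)).calls
        strict = cohort_model.fit(support=("count", 2)).calls
        assert strict.n_gains <= plain.n_gains and strict.n_losses <= plain.n_losses
        called_strict = (strict.status != "none").to_numpy()
        assert (plain.status.to_numpy()[called_strict] != "none").all()

    def test_amplicon_calls_cover_gene_call_support(self, cohort_model):
        res = cohort_model.fit()
        amp_calls = a.run_amplicon_wise(
            res.amplicon_table, res.cn, alpha=res.alpha
        )
        n_amp_calls = amp_calls.n_gains + amp_calls.n_losses
        support_of_called = res.calls.support_count.to_numpy()[
            (res.calls.status != "none").to_numpy()
        ]
        # genes partition amplicons, so the supporting amplicon calls behind
        # distinct gene-level calls are distinct amplicon-level calls
        assert n_amp_calls >= support_of_called.sum()
        assert support_of_called.sum() > 0
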