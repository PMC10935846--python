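"""Expression scaling, eigenarray signatures, integration and PS/NS split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tradeoff import signature as sg
from tradeoff import synthetic as syn
from tradeoff.errors import ContractError, EmptyResultError

from conftest import frame, jaccard


def _em(values, dialect="relative"):
    return sg.ExpressionMatrix(frame(values, rows="g", cols="s"), dialect=dialect)


class TestScaling:
    def test_scale_samples_centres_columns(self):
        out = sg.scale_samples(_em([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.values.iloc[:, 0], [-1, 0, 1])

    def test_scale_samples_idempotent(self, rng):
        out = sg.scale_samples(_em(rng.normal(size=(5, 4))))
        out2 = sg.scale_samples(out)
        pd.testing.assert_frame_equal(out.values, out2.values)

    def test_constant_column_becomes_zero(self):
        out = sg.scale_samples(_em([[7.0], [7.0]]))
        np.testing.assert_allclose(out.values.iloc[:, 0], [0, 0])

    def test_center_genes_centres_rows(self):
        out = sg.center_genes(_em([[2.0, 4.0, 6.0]], dialect="absolute"))
        np.testing.assert_allclose(out.values.iloc[0], [-2, 0, 2])

    def test_center_genes_rejects_relative_dialect(self):
        with pytest.raises(ContractError):
            sg.center_genes(_em([[1.0, 2.0]], dialect="relative"))

    def test_center_then_scale_stepwise_hand_case(self):
        # ((1,3),(5,7)): row-centred -> ((-1,1),(-1,1)); column-centred -> 0
        out = sg.scale_samples(sg.center_genes(
            _em([[1.0, 3.0], [5.0, 7.0]], dialect="absolute")))
        np.testing.assert_allclose(out.values.to_numpy(), np.zeros((2, 2)))


class TestFirstEigenarray:
    def test_rank_one_matrix_recovers_loading(self, rng):
        g = rng.normal(size=20)
        g -= g.mean()  # so columns are already sample-centred
        t = rng.normal(size=8)
        sig = sg.first_eigenarray(_em(np.outer(g, t)))
        rho = np.corrcoef(sig.score, g)[0, 1]
        assert abs(rho) > 1 - 1e-10

    def test_sign_orientation_largest_score_positive(self, rng):
        g = rng.normal(size=20)
        g -= g.mean()
        sig = sg.first_eigenarray(_em(np.outer(g, rng.normal(size=8))))
        assert sig.score.loc[sig.score.abs().idxmax()] > 0

    def test_duplicated_genes_get_equal_scores(self, rng):
        m = rng.normal(size=(6, 5))
        m[3] = m[0]
        m -= m.mean(axis=0)
        sig = sg.first_eigenarray(_em(m))
        assert sig.score.iloc[0] == pytest.approx(sig.score.iloc[3], abs=1e-12)

    def test_degenerate_top_pair_rejected(self):
        m = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        with pytest.raises(ContractError, match="degenerate"):
            sg.first_eigenarray(_em(m))

    def test_unscaled_matrix_rejected(self):
        with pytest.raises(ContractError, match="sample-scaled"):
            sg.first_eigenarray(_em([[5.0, 1.0], [9.0, 3.0]]))

    def test_scale_invariance(self, rng):
        m = rng.normal(size=(30, 10))
        m -= m.mean(axis=0)
        s1 = sg.first_eigenarray(_em(m)).score
        s2 = sg.first_eigenarray(_em(3.7 * m)).score
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestRobustSignature:
    def test_zero_noise_keeps_all_nonzero_genes_consistent(self, rng):
        e = syn.gen_expression(60, 20, signature_sd=2.0, noise_sd=0.3, seed=31)
        scaled = sg.scale_samples(e.matrix)
        sig = sg.robust_signature(scaled, n_iterations=5, noise_sd=0.0, seed=32)
        assert sig.consistent[sig.score != 0].all()

    def test_planted_signature_recovery(self):
        e = syn.gen_expression(500, 100, signature_sd=3.0, noise_sd=0.5, seed=33)
        sig = sg.robust_signature(sg.scale_samples(e.matrix),
                                  n_iterations=50, noise_sd=1.0, seed=34)
        rho = stats.spearmanr(sig.score, e.true_signature).statistic
        assert abs(rho) > 0.95
        strong = e.true_signature.abs() > e.true_signature.abs().median()
        assert sig.consistent[strong].mean() >= 0.8

    def test_pure_noise_yields_few_consistent_genes(self):
        e = syn.gen_expression(300, 40, signature_sd=0.0, noise_sd=1.0, seed=35)
        sig = sg.robust_signature(sg.scale_samples(e.matrix),
                                  n_iterations=100, noise_sd=1.0, seed=36)
        assert sig.consistent.mean() < 0.2

    def test_same_seed_bit_identical(self):
        e = syn.gen_expression(50, 15, seed=37)
        scaled = sg.scale_samples(e.matrix)
        a = sg.robust_signature(scaled, n_iterations=10, seed=38)
        b = sg.robust_signature(scaled, n_iterations=10, seed=38)
        pd.testing.assert_series_equal(a.score, b.score)
        pd.testing.assert_series_equal(a.consistent, b.consistent)

    def test_uninformative_when_no_signature(self):
        e = syn.gen_expression(500, 60, signature_sd=0.0, noise_sd=1.0, seed=39)
        sig = sg.robust_signature(sg.scale_samples(e.matrix),
                                  n_iterations=5, noise_sd=1.0, seed=40)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # truth vector is constant (all zero)
            rho = stats.spearmanr(sig.score, e.true_signature).statistic
        assert np.isnan(rho) or abs(rho) < 0.3

    def test_recovery_degrades_with_noise(self):
        # |rho| vs truth is non-increasing (majority over 3 seeds) as the
        # noise-to-signature ratio grows
        ratios = [0.1, 0.5, 1.0, 2.0, 4.0]
        wins = 0
        for seed in range(3):
            rhos = []
            for r in ratios:
                e = syn.gen_expression(200, 50, signature_sd=1.0, noise_sd=r,
                                       seed=100 + seed)
                s = sg.first_eigenarray(sg.scale_samples(e.matrix))
                rhos.append(abs(stats.spearmanr(s.score, e.true_signature).statistic))
            wins += all(rhos[i] >= rhos[i + 1] - 0.05 for i in range(len(rhos) - 1))
        assert wins >= 2


class TestIntegration:
    def test_same_matrix_twice_doubles_samples(self, rng):
        m = frame(rng.normal(size=(10, 4)), rows="g", cols="s")
        out = sg.integrate_datasets([sg.ExpressionMatrix(m), sg.ExpressionMatrix(m)])
        assert out.values.shape == (10, 8)
        left = out.values.iloc[:, :4].to_numpy()
        right = out.values.iloc[:, 4:].to_numpy()
        np.testing.assert_allclose(left, right)

    def test_disjoint_genes_rejected(self, rng):
        a = sg.ExpressionMatrix(frame(rng.normal(size=(3, 2)), rows="a", cols="s"))
        b = sg.ExpressionMatrix(frame(rng.normal(size=(3, 2)), rows="b", cols="s"))
        with pytest.raises(EmptyResultError):
            sg.integrate_datasets([a, b])

    def test_batch_offsets_removed_signature_recovered(self):
        e = syn.gen_expression(300, 80, signature_sd=3.0, noise_sd=0.5,
                               n_batches=2, batch_sd=3.0, seed=41)
        batches = e.batch_label
        parts = [sg.ExpressionMatrix(e.matrix.loc[:, batches.index[batches == b]])
                 for b in sorted(batches.unique())]
        merged = sg.integrate_datasets(parts)
        sig = sg.robust_signature(sg.scale_samples(merged), n_iterations=20,
                                  seed=42)
        rho = stats.spearmanr(sig.score, e.true_signature).statistic
        assert abs(rho) > 0.9


class TestIntegrateSignatures:
    def _sig(self, scores: dict) -> sg.RecurrentSignature:
        s = pd.Series(scores, dtype=float)
        return sg.RecurrentSignature(score=s, consistent=pd.Series(True, index=s.index))

    def test_self_integration_is_identity(self):
        a = self._sig({"g1": 0.5, "g2": -0.3, "g3": 0.1})
        out = sg.integrate_signatures(a, a)
        pd.testing.assert_series_equal(out.score, a.score.sort_index(),
                                       check_names=False)

    def test_opposite_sign_gene_excluded(self):
        a = self._sig({f"g{i}": v for i, v in enumerate([0.5, -0.3, 0.1, 0.2, -0.1])})
        b_scores = a.score.copy()
        b_scores["g2"] = -b_scores["g2"]
        out = sg.integrate_signatures(a, self._sig(b_scores.to_dict()))
        assert "g2" not in out.score.index
        assert out.source_tag == "integrated"

    def test_symmetric_in_arguments(self, rng):
        base = rng.normal(size=30)
        a = self._sig({f"g{i}": base[i] + rng.normal(0, 0.1) for i in range(30)})
        b = self._sig({f"g{i}": base[i] + rng.normal(0, 0.1) for i in range(30)})
        ab = sg.integrate_signatures(a, b)
        ba = sg.integrate_signatures(b, a)
        pd.testing.assert_series_equal(ab.score, ba.score)

    def test_anticorrelated_signature_is_flipped(self, rng):
        base = rng.normal(size=30)
        a = self._sig({f"g{i}": base[i] for i in range(30)})
        b = self._sig({f"g{i}": -base[i] for i in range(30)})
        out = sg.integrate_signatures(a, b)
        assert len(out.score) == 30  # all genes concordant after flip

    def test_integration_does_not_hurt_truth_recovery(self):
        e = syn.gen_expression(300, 60, signature_sd=2.0, noise_sd=1.5, seed=43)
        scaled = sg.scale_samples(e.matrix)
        s1 = sg.robust_signature(scaled, n_iterations=10, noise_sd=1.0, seed=44)
        e2 = syn.gen_expression(300, 60, signature_sd=2.0, noise_sd=1.5, seed=43)
        noisy = e2.matrix + np.random.default_rng(45).normal(
            0, 1.0, size=e2.matrix.shape)
        s2 = sg.robust_signature(sg.scale_samples(noisy), n_iterations=10,
                                 noise_sd=1.0, seed=46)
        merged = sg.integrate_signatures(s1, s2)
        truth = e.true_signature
        r_merged = abs(stats.spearmanr(merged.score,
                                       truth.loc[merged.score.index]).statistic)
        r1 = abs(stats.spearmanr(s1.score.loc[merged.score.index],
                                 truth.loc[merged.score.index]).statistic)
        r2 = abs(stats.spearmanr(s2.score.loc[merged.score.index],
                                 truth.loc[merged.score.index]).statistic)
        assert r_merged >= min(r1, r2) - 1e-9


class TestSplitPsNs:
    def test_simple_split(self):
        s = pd.Series({"g1": 1.0, "g2": -1.0, "g3": 2.0})
        sig = sg.RecurrentSignature(score=s, consistent=pd.Series(True, index=s.index))
        ps, ns = sg.split_ps_ns(sig)
        assert ps.members == {"g1", "g3"} and ns.members == {"g2"}

    def test_one_sided_signature_rejected(self):
        s = pd.Series({"g1": 1.0, "g2": 2.0})
        sig = sg.RecurrentSignature(score=s, consistent=pd.Series(True, index=s.index))
        with pytest.raises(EmptyResultError):
            sg.split_ps_ns(sig)

    def test_planted_arms_recovered(self):
        e = syn.gen_expression(400, 80, signature_sd=3.0, noise_sd=0.5, seed=47)
        sig = sg.robust_signature(sg.scale_samples(e.matrix), n_iterations=30,
                                  seed=48)
        if stats.spearmanr(sig.score, e.true_signature).statistic < 0:
            sig = sg.RecurrentSignature(score=-sig.score, consistent=sig.consistent)
        ps, ns = sg.split_ps_ns(sig)
        true_ps = set(e.true_signature.index[e.true_signature > 0])
        true_ns = set(e.true_signature.index[e.true_signature < 0])
        assert jaccard(ps.members, true_ps) > 0.8
        assert jaccard(ns.members, true_ns) > 0.8


class TestCompareAndCharacterize:
    def _sig(self, values, index=None) -> sg.RecurrentSignature:
        s = pd.Series(values, index=index)
        return sg.RecurrentSignature(score=s, consistent=pd.Series(True, index=s.index))

    def test_self_and_negated_comparison(self, rng):
        s = self._sig(rng.normal(size=20), [f"g{i}" for i in range(20)])
        neg = self._sig(-s.score.to_numpy(), s.score.index)
        assert sg.compare_signatures(s, s)[0] == pytest.approx(1.0)
        assert sg.compare_signatures(s, neg)[0] == pytest.approx(-1.0)

    def test_independent_signatures_uncorrelated(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = self._sig(r.normal(size=1000), [f"g{i}" for i in range(1000)])
            b = self._sig(r.normal(size=1000), [f"g{i}" for i in range(1000)])
            if abs(sg.compare_signatures(a, b)[0]) < 0.1:
                hits += 1
        assert hits >= 90

    def test_insufficient_overlap_rejected(self, rng):
        a = self._sig(rng.normal(size=5), [f"a{i}" for i in range(5)])
        with pytest.raises(ContractError):
            sg.compare_signatures(a, a)

    def test_gene_set_distributions_separate_arms(self):
        e = syn.gen_expression(400, 80, signature_sd=3.0, noise_sd=0.5, seed=49)
        sig = sg.robust_signature(sg.scale_samples(e.matrix), n_iterations=10,
                                  seed=50)
        ps_proxy = sg.GeneSet("growth_like",
                              frozenset(e.true_signature.nlargest(50).index))
        ns_proxy = sg.GeneSet("stress_like",
                              frozenset(e.true_signature.nsmallest(50).index))
        dists, tests = sg.gene_set_score_distribution(sig, [ps_proxy, ns_proxy])
        assert set(dists) == {"growth_like", "stress_like"}
        assert tests.loc[0, "p"] < 1e-4

    def test_disjoint_set_skipped_with_warning(self):
        sig = self._sig([1.0, -1.0, 0.5], ["g1", "g2", "g3"])
        stray = sg.GeneSet("absent", frozenset({"x1", "x2"}))
        inside = sg.GeneSet("here", frozenset({"g1", "g2"}))
        with pytest.warns(UserWarning, match="absent"):
            dists, _ = sg.gene_set_score_distribution(sig, [stray, inside])
        assert set(dists) == {"here"}

    def test_measurement_correlation_identity_and_permutation(self, rng):
        sig = self._sig(rng.normal(size=1000), [f"g{i}" for i in range(1000)])
        rho, _ = sg.correlate_signature_with_measurement(sig, sig.score)
        assert rho == pytest.approx(1.0)
        rhos = []
        for _ in range(100):
            perm = pd.Series(rng.permutation(sig.score.to_numpy()),
                             index=sig.score.index)
            rhos.append(abs(sg.correlate_signature_with_measurement(sig, perm)[0]))
        assert np.mean(rhos) < 0.1

    def test_measurement_ties_use_midranks(self):
        sig = self._sig([1.0, 2.0, 3.0, 4.0, 5.0],
                        ["g1", "g2", "g3", "g4", "g5"])
        meas = pd.Series([1.0, 1.0, 2.0, 2.0, 3.0], index=sig.score.index)
        rho, _ = sg.correlate_signature_with_measurement(sig, meas, min_shared=5)
        # oracle: pearson on midranks
        r_sig = stats.rankdata(sig.score)
        r_meas = stats.rankdata(meas)
        assert rho == pytest.approx(np.corrcoef(r_sig, r_meas)[0, 1], abs=1e-12)


class TestGroupLog2fc:
    def test_identical_groups_zero(self, rng):
        vals = np.abs(rng.normal(size=(4, 6))) + 1
        vals[:, 3:] = vals[:, :3]
        m = frame(vals, rows="g", cols="s")
        labels = pd.Series(["w"] * 3 + ["d"] * 3, index=m.columns)
        gs = sg.GeneSet("all", frozenset(m.index))
        out = sg.group_log2fc(m, labels, gs)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_twofold_difference(self):
        m = frame([[2.0, 2.0, 1.0, 1.0], [4.0, 4.0, 2.0, 2.0]], rows="g", cols="s")
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=m.columns)
        gs = sg.GeneSet("all", frozenset(m.index))
        out = sg.group_log2fc(m, labels, gs)
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_hand_case_and_prelogged(self):
        m = frame([[8.0, 2.0], [3.0, 3.0], [1.0, 4.0]], rows="g", cols="s")
        labels = pd.Series(["a", "b"], index=m.columns)
        gs = sg.GeneSet("all", frozenset(m.index))
        out = sg.group_log2fc(m, labels, gs).sort_index()
        np.testing.assert_allclose(out.to_numpy(),
                                   [np.log2(4), 0.0, np.log2(0.25)])
        pre = sg.group_log2fc(m, labels, gs, pre_logged=True).sort_index()
        np.testing.assert_allclose(pre.to_numpy(), [6.0, 0.0, -3.0])

    def test_nonpositive_mean_rejected(self):
        m = frame([[0.0, 1.0]], rows="g", cols="s")
        labels = pd.Series(["a", "b"], index=m.columns)
        gs = sg.GeneSet("all", frozenset(m.index))
        with pytest.raises(ContractError):
            sg.group_log2fc(m, labels, gs)
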