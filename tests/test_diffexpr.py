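"""Moderated differential expression: group stats, variance shrinkage,
BH adjustment, candidate gating — each checked against an independent route.
"""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from pleuramir import (GroupDesign, SyntheticConfig, bh_adjust,
                       compute_group_stats, filter_probes, filter_samples,
                       fit_moderation, generate, moderated_test, run_diffexpr,
                       select_candidates, select_references, delta_normalize)
from pleuramir.diffexpr import DiffexprError, ModerationFit

from conftest import make_ct


def two_group_dct(control, cancer, n_probes=1, rng=None):
    """Build a dCt matrix + design from per-group expression values
    (remember: dCt = -expression)."""
    e = np.atleast_2d(np.concatenate([control, cancer], axis=-1))
    cols = [f"c{i}" for i in range(np.shape(control)[-1])] + \
           [f"t{i}" for i in range(np.shape(cancer)[-1])]
    dct = make_ct(-e, samples=cols)
    design = GroupDesign(control=tuple(cols[: np.shape(control)[-1]]),
                         cancer=tuple(cols[np.shape(control)[-1]:]))
    return dct, design


class TestGroupStats:
    def test_hand_computed_pooled_stats(self):
        dct, design = two_group_dct([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = compute_group_stats(dct, design)
        assert out["logFC"].iloc[0] == pytest.approx(3.0)
        assert out["s_sq"].iloc[0] == pytest.approx(1.0)
        assert out["d"].iloc[0] == 4

    def test_identical_groups_are_flat(self):
        dct, design = two_group_dct([2.0, 2.0], [2.0, 2.0])
        out = compute_group_stats(dct, design)
        assert out["logFC"].iloc[0] == 0 and out["s_sq"].iloc[0] == 0

    def test_negating_dct_flips_logfc(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(8, 10))
        dct = make_ct(-e)
        design = GroupDesign(control=tuple(dct.columns[:5]),
                             cancer=tuple(dct.columns[5:]))
        a = compute_group_stats(dct, design)["logFC"]
        b = compute_group_stats(-dct, design)["logFC"]
        np.testing.assert_allclose(a.values, -b.values)

    def test_relabeling_groups_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(1)
        dct = make_ct(rng.normal(size=(30, 12)))
        fwd = GroupDesign(control=tuple(dct.columns[:6]),
                          cancer=tuple(dct.columns[6:]))
        rev = GroupDesign(control=fwd.cancer, cancer=fwd.control)
        t1, _ = run_diffexpr(dct, fwd)
        t2, _ = run_diffexpr(dct, rev)
        t1 = t1.set_index("probe_id")
        t2 = t2.set_index("probe_id").loc[t1.index]
        np.testing.assert_allclose(t1["logFC"], -t2["logFC"], atol=1e-12)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_small_groups_rejected(self):
        dct, _ = two_group_dct([1.0, 2.0], [3.0])
        with pytest.raises(DiffexprError, match=">= 2 samples"):
            compute_group_stats(dct, GroupDesign(control=("c0", "c1"),
                                                 cancer=("t0",)))


class TestModeration:
    def test_prior_recovery_from_scaled_inv_chisq(self):
        """Variances simulated from the hierarchical model (d0=4, s0^2=1,
        d=32) are recovered by the moment-matching fit."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 4.0, 1.0, 32
        true_var = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s_sq = true_var * rng.chisquare(d, size=5000) / d
        fit = fit_moderation(s_sq, d)
        assert fit.d0 == pytest.approx(d0_true, rel=0.15)
        assert fit.s0_sq == pytest.approx(s0_true, rel=0.05)

    def test_shrinkage_bound(self):
        rng = np.random.default_rng(2)
        s_sq = rng.chisquare(5, size=300) / 5
        fit = fit_moderation(s_sq, d=10)
        lo = np.minimum(s_sq, fit.s0_sq)
        hi = np.maximum(s_sq, fit.s0_sq)
        assert np.all(fit.s_tilde_sq >= lo - 1e-12)
        assert np.all(fit.s_tilde_sq <= hi + 1e-12)

    def test_identical_variances_shrink_to_common(self):
        s_sq = np.full(50, 0.7)
        fit = fit_moderation(s_sq, d=8)
        assert np.isinf(fit.d0)
        np.testing.assert_allclose(fit.s_tilde_sq, fit.s0_sq)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(DiffexprError, match="degenerate"):
            fit_moderation(np.zeros(10), d=4)

    def test_vanishing_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        control = rng.normal(size=(40, 6))
        cancer = rng.normal(0.5, 1.0, size=(40, 5))
        dct, design = two_group_dct(control, cancer)
        out = compute_group_stats(dct, design)
        d = out["d"].iloc[0]
        s_sq = out["s_sq"].to_numpy()
        fit = ModerationFit(d0=1e-8, s0_sq=1.0, d=d, s_sq=s_sq,
                            s_tilde_sq=(1e-8 * 1.0 + d * s_sq) / (1e-8 + d))
        t_mod, p_mod = moderated_test(out["logFC"].to_numpy(), fit, 6, 5)
        t_ref, p_ref = sps.ttest_ind(cancer.T, control.T, axis=0)
        np.testing.assert_allclose(t_mod, t_ref, rtol=1e-6)
        np.testing.assert_allclose(p_mod, p_ref, rtol=1e-4)


class TestModeratedTest:
    def test_zero_logfc_gives_p_one(self):
        fit = ModerationFit(d0=4.0, s0_sq=1.0, d=10.0, s_sq=np.array([1.0]),
                            s_tilde_sq=np.array([1.0]))
        t, p = moderated_test(np.array([0.0]), fit, 5, 7)
        assert t[0] == 0 and p[0] == pytest.approx(1.0)

    def test_p_matches_t_cdf_brute_force(self):
        fit = ModerationFit(d0=3.5, s0_sq=0.8, d=12.0, s_sq=np.array([1.3]),
                            s_tilde_sq=np.array([(3.5 * 0.8 + 12 * 1.3) / 15.5]))
        logfc = np.array([1.7])
        t, p = moderated_test(logfc, fit, 9, 8)
        expect_t = 1.7 / np.sqrt(fit.s_tilde_sq[0] * (1 / 9 + 1 / 8))
        df = 3.5 + 12.0
        expect_p = 2 * (1 - sps.t.cdf(abs(expect_t), df))
        assert t[0] == pytest.approx(expect_t)
        assert p[0] == pytest.approx(expect_p, rel=1e-12)

    def test_null_type_i_error_is_nominal(self):
        """Null cohorts (no group effect): fraction of raw p < 0.05 is ~5%,
        averaged over seeds."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            control = rng.normal(25, 1, size=(500, 20))
            cancer = rng.normal(25, 1, size=(500, 14))
            dct, design = two_group_dct(control, cancer)
            table, _ = run_diffexpr(dct, design)
            fracs.append((table["p"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_constant_vector(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=754)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        # O(m^2) direct minimization: adj_(i) = min_{j >= i} m p_(j) / j
        adj_sorted = np.array([
            min(m * p[order[j]] / (j + 1) for j in range(i, m))
            for i in range(m)])
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200) ** 2
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=40))
    def test_monotone_and_dominates_p(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(DiffexprError):
            bh_adjust(np.array([0.5, 1.2]))


class TestCandidateSelection:
    def make_table(self, adj_p, logfc):
        return pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(adj_p))],
                             "logFC": logfc, "adj_p": adj_p})

    def test_both_gates_are_strict(self):
        table = self.make_table([0.04, 0.05, 0.04], [2.9, 5.0, 3.0])
        out = select_candidates(table)
        assert out.empty  # fold gate, p gate, and |logFC| = 3 all fail

    def test_passing_probe_selected_and_sorted(self):
        table = self.make_table([0.04, 0.001], [3.5, -4.0])
        out = select_candidates(table)
        assert out["probe_id"].tolist() == ["p1", "p0"]

    def test_spike_recovery_with_correct_signs(self):
        """All 14 spiked probes (5 up, 9 down, effect 6) pass the gate with
        the right direction; nothing else does."""
        cfg = SyntheticConfig(n_probes=300, n_up=5, n_down=9, effect_size=6.0,
                              noise_sd=0.8, seed=3)
        ct, sheet, truth = generate(cfg)
        ct, _ = filter_probes(ct)
        ct, _ = filter_samples(ct, groups=sheet.set_index("sample_id")["group"])
        refs = select_references(ct)
        dct = delta_normalize(ct, refs)
        design = GroupDesign.from_sample_sheet(sheet, sample_ids=dct.columns)
        table, _ = run_diffexpr(dct, design)
        cand = table[table["candidate"]].set_index("probe_id")
        assert set(cand.index) == truth.spiked_up | truth.spiked_down
        assert set(cand.index[cand["logFC"] > 0]) == truth.spiked_up
        assert set(cand.index[cand["logFC"] < 0]) == truth.spiked_down

    def test_power_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 2.0, 4.0, 6.0):
            recovered = 0
            for seed in range(3):
                cfg = SyntheticConfig(n_probes=150, n_up=4, n_down=4,
                                      effect_size=effect, seed=seed)
                ct, sheet, truth = generate(cfg)
                ct, _ = filter_probes(ct)
                refs = select_references(ct)
                table, _ = run_diffexpr(delta_normalize(ct, refs),
                                        GroupDesign.from_sample_sheet(sheet))
                cand = set(table.loc[table["candidate"], "probe_id"])
                recovered += len(cand & (truth.spiked_up | truth.spiked_down))
            rates.append(recovered)
        assert all(a <= b for a, b in zip(rates, rates[1:]))


LIMMA_SCRIPT = textwrap.dedent("""
    suppressMessages(library(limma))
    args <- commandArgs(trailingOnly = TRUE)
    e <- as.matrix(read.csv(args[1], row.names = 1, check.names = FALSE))
    group <- factor(read.csv(args[2])$group, levels = c("control", "cancer"))
    design <- model.matrix(~ group)
    fit <- eBayes(lmFit(e, design))
    out <- data.frame(probe = rownames(e),
                      logFC = fit$coefficients[, 2],
                      t = fit$t[, 2],
                      p = fit$p.value[, 2])
    out$d0 <- fit$df.prior
    out$s0 <- fit$s2.prior
    write.csv(out, args[3], row.names = FALSE)
""")


class TestLimmaCrossCheck:
    def test_matches_limma_moderated_t(self, tmp_path):
        """The moderated pipeline agrees with the reference R implementation
        on a heterogeneous-variance fixture."""
        rng = np.random.default_rng(12)
        n1, n2 = 8, 7
        scales = rng.uniform(0.3, 2.5, size=40)
        control = rng.normal(0, 1, size=(40, n1)) * scales[:, None]
        cancer = (rng.normal(0, 1, size=(40, n2)) * scales[:, None]
                  + rng.normal(0, 2, size=(40, 1)))
        dct, design = two_group_dct(control, cancer)
        e = -dct  # expression proxy fed to both implementations
        e_path, g_path, out_path = (tmp_path / n for n in
                                    ("e.csv", "g.csv", "out.csv"))
        e.to_csv(e_path)
        pd.DataFrame({"sample_id": dct.columns,
                      "group": ["control"] * n1 + ["cancer"] * n2}
                     ).to_csv(g_path, index=False)
        script = tmp_path / "limma_check.R"
        script.write_text(LIMMA_SCRIPT)
        subprocess.run(["Rscript", str(script), str(e_path), str(g_path),
                        str(out_path)], check=True, timeout=300,
                       capture_output=True)
        ref = pd.read_csv(out_path).set_index("probe")

        table, fit = run_diffexpr(dct, design)
        table = table.set_index("probe_id").loc[ref.index]
        np.testing.assert_allclose(table["logFC"], ref["logFC"], rtol=1e-8)
        assert fit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert fit.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(table["t_mod"], ref["t"], rtol=1e-5)
        np.testing.assert_allclose(table["p"], ref["p"], rtol=1e-4)
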