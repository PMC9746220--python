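"""MR engine: harmonization, Wald/IVW, BH, Steiger, end-to-end workflow."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protmr import mr, pqtl
from protmr import simulate as sim
from conftest import make_sumstats


def exp_row(vid="rs1", pos=100, ea="A", nea="G", eaf=0.3, beta=0.5, se=0.05):
    return (vid, "1", pos, ea, nea, eaf, beta, se)


class TestHarmonize:
    def test_allele_swap_flips_beta_and_eaf(self):
        exposure = make_sumstats([exp_row(ea="A", nea="G", beta=0.5)])
        outcome = make_sumstats([exp_row(ea="G", nea="A", eaf=0.7, beta=0.3)])
        pair = mr.harmonize(exposure, outcome).iloc[0]
        assert pair["action"] == "flip"
        assert pair["beta_out"] == pytest.approx(-0.3)
        assert pair["eaf_out"] == pytest.approx(0.3)

    def test_strand_complement_preserves_sign(self):
        exposure = make_sumstats([exp_row(ea="A", nea="G", beta=0.5)])
        outcome = make_sumstats([exp_row(ea="T", nea="C", beta=0.3)])
        pair = mr.harmonize(exposure, outcome).iloc[0]
        assert pair["action"] == "strand_flip"
        assert pair["beta_out"] == pytest.approx(0.3)

    def test_strand_complement_with_swap_flips(self):
        exposure = make_sumstats([exp_row(ea="A", nea="G", beta=0.5)])
        outcome = make_sumstats([exp_row(ea="C", nea="T", eaf=0.7, beta=0.3)])
        pair = mr.harmonize(exposure, outcome).iloc[0]
        assert pair["action"] == "strand_flip+flip"
        assert pair["beta_out"] == pytest.approx(-0.3)

    def test_ambiguous_palindrome_dropped(self):
        exposure = make_sumstats([exp_row(ea="A", nea="T", eaf=0.50)])
        outcome = make_sumstats([exp_row(ea="A", nea="T", eaf=0.50)])
        pair = mr.harmonize(exposure, outcome).iloc[0]
        assert pair["action"] == "drop(palindromic_ambiguous)"

    def test_informative_palindrome_aligned_by_frequency(self):
        exposure = make_sumstats([exp_row(ea="A", nea="T", eaf=0.2)])
        same = make_sumstats([exp_row(ea="A", nea="T", eaf=0.22, beta=0.3)])
        flipped = make_sumstats([exp_row(ea="A", nea="T", eaf=0.8, beta=0.3)])
        assert mr.harmonize(exposure, same).iloc[0]["beta_out"] == pytest.approx(0.3)
        assert mr.harmonize(exposure, flipped).iloc[0]["beta_out"] == pytest.approx(-0.3)

    def test_incompatible_alleles_dropped(self):
        exposure = make_sumstats([exp_row(ea="A", nea="G")])
        outcome = make_sumstats([exp_row(ea="A", nea="C")])
        assert mr.harmonize(exposure, outcome).iloc[0]["action"] == (
            "drop(incompatible_alleles)"
        )

    def test_missing_variant_dropped_not_error(self):
        exposure = make_sumstats([exp_row(pos=100)])
        outcome = make_sumstats([exp_row(vid="rs2", pos=999)])
        pair = mr.harmonize(exposure, outcome).iloc[0]
        assert pair["action"] == "drop(missing_from_outcome)"

    def test_involution_second_pass_is_identity(self):
        exposure = make_sumstats(
            [exp_row("rs1", 100, "A", "G", 0.3, 0.5), exp_row("rs2", 200, "T", "C", 0.2, 0.4)]
        )
        outcome = make_sumstats(
            [exp_row("rs1", 100, "G", "A", 0.7, 0.3), exp_row("rs2", 200, "A", "G", 0.2, 0.1)]
        )
        first = mr.harmonize(exposure, outcome)
        # feed the harmonized outcome back in: alleles now match the exposure
        out2 = make_sumstats(
            [
                (r["variant_id"], "1", 100 if r["variant_id"] == "rs1" else 200,
                 r["ea"], r["nea"], r["eaf_out"], r["beta_out"], r["se_out"])
                for _, r in first.iterrows()
            ]
        )
        second = mr.harmonize(exposure, out2)
        assert (second["action"] == "none").all()
        assert np.allclose(second["beta_out"], first["beta_out"])
        assert np.allclose(second["eaf_out"], first["eaf_out"])


class TestEstimators:
    def test_wald_ratio_formula(self):
        b, se, p = mr.wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.04)

    def test_wald_null_outcome(self):
        b, se, p = mr.wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert b == 0.0
        assert p == pytest.approx(1.0)

    def test_wald_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_ivw_symmetric_average(self):
        b, se, p = mr.ivw([0.5, 0.5], [0.01, 0.01], [0.1, 0.2], [0.05, 0.05])
        assert b == pytest.approx(0.3)  # ratios 0.2 and 0.4, equal weights

    def test_ivw_single_pair_rejected_and_routed(self):
        with pytest.raises(ValueError):
            mr.ivw([0.5], [0.01], [0.1], [0.05])
        pairs = pd.DataFrame(
            {
                "beta_exp": [0.5],
                "se_exp": [0.05],
                "beta_out": [0.1],
                "se_out": [0.02],
                "action": ["none"],
            }
        )
        method, b, se, p = mr.mr_estimate(pairs)
        assert method == "wald"
        assert (b, se) == (pytest.approx(0.2), pytest.approx(0.04))

    def test_ivw_matches_zero_intercept_wls_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 8))
            be = rng.uniform(0.2, 0.8, m) * rng.choice([-1, 1], m)
            se_e = rng.uniform(0.01, 0.1, m)
            bo = rng.standard_normal(m) * 0.1
            so = rng.uniform(0.01, 0.1, m)
            b, se, p = mr.ivw(be, se_e, bo, so)
            # oracle: weighted regression through the origin of bo on be
            w = be**2 / so**2
            b_o = np.sum(w * bo / be) / np.sum(w)
            se_o = np.sum(w) ** -0.5
            assert b == pytest.approx(b_o, abs=1e-10)
            assert se == pytest.approx(se_o, abs=1e-10)


class TestFdr:
    def test_single_test_unchanged(self):
        rec = pd.DataFrame({"p_mr": [0.03]})
        assert mr.fdr_adjust(rec)["fdr_q"].iloc[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        rec = pd.DataFrame({"p_mr": [0.001, 0.01, 0.02, 0.8]})
        q = mr.fdr_adjust(rec)["fdr_q"].to_numpy()
        assert q == pytest.approx([0.004, 0.02, 4 * 0.02 / 3, 0.8])

    def test_all_unit_pvalues(self):
        rec = pd.DataFrame({"p_mr": [1.0, 1.0, 1.0]})
        assert (mr.fdr_adjust(rec)["fdr_q"] == 1.0).all()

    def test_q_monotone_in_p(self, rng):
        rec = pd.DataFrame({"p_mr": rng.uniform(0, 1, 50)})
        out = mr.fdr_adjust(rec).sort_values("p_mr")
        assert out["fdr_q"].is_monotonic_increasing

    def test_scope_grouping_is_independent(self, rng):
        rec = pd.DataFrame(
            {
                "p_mr": np.r_[rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)],
                "tissue": ["csf"] * 10 + ["plasma"] * 10,
            }
        )
        out = mr.fdr_adjust(rec, scope=["tissue"])
        for t in ("csf", "plasma"):
            sub = rec[rec["tissue"] == t]
            solo = mr.fdr_adjust(sub)["fdr_q"].to_numpy()
            assert np.allclose(out.loc[out["tissue"] == t, "fdr_q"], solo)


class TestSteiger:
    def make_pairs(self, t_exp, t_out, n=1000.0):
        # build betas with unit se so t = beta
        return pd.DataFrame(
            {
                "beta_exp": [t_exp],
                "se_exp": [1.0],
                "beta_out": [t_out],
                "se_out": [1.0],
                "n_exp": [n],
                "n_out": [n],
                "action": ["none"],
            }
        )

    def test_strong_exposure_correct_direction(self):
        # r2_exp ~ 0.04, r2_out ~ 0.0004 at n=1000
        t_exp = np.sqrt(0.04 * 998 / 0.96)
        t_out = np.sqrt(0.0004 * 998 / 0.9996)
        correct, p = mr.steiger_filter(self.make_pairs(t_exp, t_out))
        assert correct
        # Fisher-z oracle
        z = (np.arctanh(np.sqrt(0.04)) - np.arctanh(np.sqrt(0.0004))) / np.sqrt(2 / 997)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-6)
        assert p < 1e-3

    def test_equal_r2_is_not_correct(self):
        correct, p = mr.steiger_filter(self.make_pairs(3.0, 3.0))
        assert not correct
        assert p == pytest.approx(1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="exceed 3"):
            mr.steiger_filter(self.make_pairs(3.0, 1.0, n=3))


class TestWorkflow:
    def test_causal_pair_reported_significant(self, causal_study):
        panel, manifest, proteins, gwas = causal_study
        cfg = mr.MRConfig(
            panel=panel,
            proteins=proteins,
            outcomes=gwas,
            genes=manifest.genes,
            thresholds=pqtl.ThresholdSpec(n_pcs=4, study_wide_alpha=5e-8 / 4),
            workflow="both",
        )
        rec = mr.run_workflow(cfg)
        hit = rec[(rec["protein_id"] == "P001") & (rec["workflow"] == "a")].iloc[0]
        assert hit["significant"]
        assert abs(hit["beta_mr"] - 0.3) < 3 * hit["se_mr"]
        assert (rec["provenance"] == "cis_only").all()
        nulls = rec[rec["protein_id"] != "P001"]
        assert not nulls["significant"].any()

    def test_ld_confounded_pair_blocked_by_coloc(self):
        # protein driven by variant 0; outcome driven directly by variant 4
        # of the same high-LD block: MR can fire but PP.H4 must not
        panel = sim.simulate_genotypes(3000, [(9, 0.9, (0.28, 0.32))], seed=31)
        manifest = sim.design_truth(panel, 1, ["Y1"], b_cis=0.6, seed=32)
        direct_var = panel.variant_ids[8]
        manifest.direct_effects = {direct_var: {"Y1": 0.25}}
        proteins = sim.simulate_proteins(panel, manifest, seed=33)
        gwas = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=34)
        cfg = mr.MRConfig(
            panel=panel,
            proteins=proteins,
            outcomes=gwas,
            genes=manifest.genes,
            thresholds=pqtl.ThresholdSpec(n_pcs=1, study_wide_alpha=5e-8),
            workflow="a",
        )
        rec = mr.run_workflow(cfg)
        if len(rec):  # instrument survived
            assert rec.iloc[0]["pp_h4"] <= 0.8 or not rec.iloc[0]["significant"]
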