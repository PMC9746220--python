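"""Canonical simulation studies that measure the pipeline's operating
characteristics on synthetic data with known ground truth.

Each study fixes a study design (sample sizes, effect sizes, noise levels)
and returns the measured quantities; they are what the validation suite and
the reproduction script run. Designs: instrument effect b_cis = 0.5 on a
log-abundance scale, causal effect theta = 0.3 (0.4 where noted), unit
residual noise, n = 2000 individuals — a strong single cis instrument of
the kind the MR workflows rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc as coloc_mod
from . import meta as meta_mod
from . import mr as mr_mod
from . import pqtl as pqtl_mod
from . import qc as qc_mod
from . import simulate as sim


def _spawn(seed: int, k: int) -> list[int]:
    """Independent child seeds below 2^31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def parameter_recovery(
    n_runs: int = 200,
    n_samples: int = 2000,
    b_cis: float = 0.5,
    theta: float = 0.3,
    seed: int = 0,
) -> dict:
    """Wald-ratio recovery of a known causal effect across replicates.

    Each replicate simulates one protein with a single cis instrument and a
    quantitative outcome, maps the pQTL, harmonizes against the outcome
    GWAS, and estimates theta by the Wald ratio. Reports the mean estimate
    and the 95% CI coverage.
    """
    estimates, covered = [], 0
    for s in _spawn(seed, n_runs):
        panel = sim.simulate_genotypes(n_samples, [(3, 0.0, (0.2, 0.4))], seed=s)
        manifest = sim.design_truth(
            panel, 1, {"Y1": {"P001": theta}}, b_cis=b_cis, seed=s + 1
        )
        proteins = sim.simulate_proteins(panel, manifest, noise_sd=1.0, seed=s + 2)
        gwas = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=s + 3)
        assocs = pqtl_mod.fit_pqtl(proteins, panel)
        cis = manifest.cis_assignment["P001"][0]
        exposure = assocs[assocs["variant_id"] == cis]
        pairs = mr_mod.harmonize(exposure, gwas["Y1"])
        _, b, se, _ = mr_mod.mr_estimate(pairs)
        estimates.append(b)
        if abs(b - theta) <= 1.96 * se:
            covered += 1
    estimates = np.asarray(estimates)
    return {
        "n_runs": n_runs,
        "theta": theta,
        "mean_estimate": float(estimates.mean()),
        "bias": float(estimates.mean() - theta),
        "coverage_percent": 100.0 * covered / n_runs,
    }


def null_calibration(
    n_proteins: int = 100,
    n_outcomes: int = 5,
    n_samples: int = 2000,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive control of the MR pipeline under the global null.

    theta = 0 for every protein-outcome pair (proteins keep strong cis
    pQTLs, outcomes are pure noise); the full workflow-b path runs without
    colocalization and the fraction of pairs called at FDR < alpha is
    reported, along with a Kolmogorov-Smirnov test of p-value uniformity.
    """
    s = _spawn(seed, 4)
    panel = sim.simulate_genotypes(
        n_samples, [(3, 0.3, (0.1, 0.4))] * n_proteins, seed=s[0]
    )
    outcomes = [f"Y{i + 1}" for i in range(n_outcomes)]
    manifest = sim.design_truth(panel, n_proteins, outcomes, b_cis=0.5, seed=s[1])
    proteins = sim.simulate_proteins(panel, manifest, noise_sd=1.0, seed=s[2])
    gwas = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=s[3])
    cfg = mr_mod.MRConfig(
        panel=panel,
        proteins=proteins,
        outcomes=gwas,
        genes=manifest.genes,
        thresholds=pqtl_mod.ThresholdSpec(n_pcs=1, study_wide_alpha=5e-8),
        workflow="b",
        run_coloc=False,
        fdr_alpha=fdr_alpha,
    )
    records = mr_mod.run_workflow(cfg)
    n_tests = len(records)
    called = int((records["fdr_q"] < fdr_alpha).sum())
    ks_p = float(stats.kstest(records["p_mr"], "uniform").pvalue)
    return {
        "n_tests": n_tests,
        "n_called": called,
        "fraction_called": called / n_tests if n_tests else float("nan"),
        "ks_uniformity_p": ks_p,
    }


def coloc_discrimination(
    n_regions: int = 100,
    n_samples: int = 2000,
    n_variants: int = 50,
    seed: int = 0,
) -> dict:
    """Colocalization discrimination between shared and distinct causals.

    Shared scenario: the outcome is causally downstream of the protein, so
    both traits' association signals sit on the same cis variant; expect
    PP.H4 > 0.8. Distinct scenario: the outcome is driven directly by a
    different variant of the same region (LD confounding, no causal
    protein effect); expect H3 to dominate.
    """
    h4_hits = h3_hits = 0
    for s in _spawn(seed, n_regions):
        panel = sim.simulate_genotypes(
            n_samples, [(n_variants, 0.5, (0.2, 0.4))], seed=s
        )
        center = panel.variant_ids[n_variants // 2]
        # shared causal variant: outcome = theta * protein + noise
        manifest = sim.design_truth(
            panel, 1, {"Y1": {"P001": 0.4}}, b_cis=0.5, seed=s + 1
        )
        manifest.cis_assignment["P001"] = (center, 0.5)
        proteins = sim.simulate_proteins(panel, manifest, seed=s + 2)
        exp_stats = sim.marginal_gwas(
            proteins.values["P001"].to_numpy(), panel
        )
        out_stats = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=s + 3)["Y1"]
        res = coloc_mod.coloc_abf(exp_stats, out_stats)
        if res.pp_h4 > 0.8:
            h4_hits += 1
        # distinct causal variants: outcome driven by a far variant
        far = panel.variant_ids[-1]
        manifest2 = sim.design_truth(panel, 1, ["Y1"], b_cis=0.5, seed=s + 4)
        manifest2.cis_assignment["P001"] = (panel.variant_ids[0], 0.5)
        manifest2.direct_effects = {far: {"Y1": 0.25}}
        proteins2 = sim.simulate_proteins(panel, manifest2, seed=s + 5)
        exp2 = sim.marginal_gwas(proteins2.values["P001"].to_numpy(), panel)
        out2 = sim.simulate_outcome_gwas(panel, proteins2, manifest2, 1.0, seed=s + 6)["Y1"]
        res2 = coloc_mod.coloc_abf(exp2, out2)
        if max(res2.pp, key=res2.pp.get) == "pp_h3":
            h3_hits += 1
    return {
        "n_regions": n_regions,
        "shared_pph4_rate": h4_hits / n_regions,
        "distinct_h3_rate": h3_hits / n_regions,
    }


def steiger_reverse_filtering(
    n_runs: int = 200,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    """Steiger filtering of reverse-causal protein-phenotype pairs.

    The phenotype is genetically driven (b = 0.5) and the protein is
    downstream of the phenotype (protein = 0.3 * phenotype + noise), so
    the instruments explain more outcome than exposure variance and the
    pair must be filtered.
    """
    filtered = 0
    for s in _spawn(seed, n_runs):
        panel = sim.simulate_genotypes(n_samples, [(3, 0.0, (0.2, 0.4))], seed=s)
        rng = np.random.default_rng(s + 1)
        g = panel.dosage(panel.variant_ids[0]).astype(float)
        y = 0.5 * g + rng.normal(0, 1, n_samples)
        protein = 0.3 * y + rng.normal(0, 1, n_samples)
        exp_stats = sim.marginal_gwas(protein, panel)
        out_stats = sim.marginal_gwas(y, panel)
        pairs = mr_mod.harmonize(exp_stats.iloc[[0]], out_stats)
        correct, _ = mr_mod.steiger_filter(pairs)
        if not correct:
            filtered += 1
    return {"n_runs": n_runs, "filtered_rate": filtered / n_runs}


def qc_fixture_recovery(n_samples: int = 240, n_analytes: int = 20, seed: int = 0) -> dict:
    """Defect recovery of the QC filters on ledgered raw fixtures.

    One fixture carries all four analyte defect kinds; a second is
    defect-free. Reports the recall of ledgered defects and the number of
    false removals across both fixtures.
    """
    s = _spawn(seed, 6)
    panel = sim.simulate_genotypes(n_samples, [(n_analytes, 0.0, (0.1, 0.4))], seed=s[0])
    manifest = sim.design_truth(panel, n_analytes, ["Y1"], seed=s[1])
    clean = sim.simulate_proteins(panel, manifest, seed=s[2])
    defects = [
        sim.Defect("lod", analyte="P001", fraction=0.2),
        sim.Defect("cv", analyte="P005", magnitude=0.30),
        sim.Defect("scale_factor", analyte="P009"),
        sim.Defect("iqr", analyte="P013", fraction=0.2),
    ]
    raw, ledger = sim.make_raw_proteomics(clean, defects, seed=s[3])
    _, report = qc_mod.run_qc(raw)
    removed = set(report.removed_analytes)
    ledgered = set(ledger["analytes"])
    recall = len(removed & ledgered) / len(ledgered)
    false_with = len(removed - ledgered)
    raw_clean, _ = sim.make_raw_proteomics(clean, seed=s[4])
    _, report2 = qc_mod.run_qc(raw_clean)
    return {
        "defect_recall": recall,
        "false_removals": false_with + len(report2.removed_analytes),
    }


def oracle_equivalence(seed: int = 0) -> dict:
    """Agreement of the core estimators with independent brute-force oracles.

    OLS vs normal equations, IVW vs zero-intercept WLS, BH vs the step-up
    enumeration, heterogeneity Q vs the direct chi-square formula, and
    coloc posteriors vs a log-sum-exp enumeration. Returns the maximum
    absolute (or relative, for OLS) deviation per estimator.
    """
    rng = np.random.default_rng(seed)
    out = {}

    # OLS vs lstsq normal equations on random designs
    worst = 0.0
    for _ in range(25):
        n = int(rng.integers(30, 80))
        g = rng.integers(0, 3, size=(n, 1)).astype(float)
        while g.std() == 0:
            g = rng.integers(0, 3, size=(n, 1)).astype(float)
        y = rng.standard_normal(n) + 0.3 * g[:, 0]
        meta = pd.DataFrame(
            {"chrom": "1", "pos": [1], "ea": "A", "nea": "G", "maf": g.mean() / 2, "block": 0},
            index=["rs0"],
        )
        panel = sim.GenotypePanel(dosages=g.astype(int), variant_meta=meta)
        rec = pqtl_mod.fit_pqtl(
            pd.DataFrame({"P1": y}, index=panel.sample_ids), panel, maf_min=0.0
        ).iloc[0]
        x = np.column_stack([np.ones(n), g])
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        se = np.sqrt(
            np.linalg.inv(x.T @ x)[1, 1] * (resid @ resid) / (n - 2)
        )
        worst = max(
            worst,
            abs(rec["beta"] - coef[1]) / abs(coef[1]),
            abs(rec["se"] - se) / se,
        )
    out["ols_max_rel_err"] = worst

    # IVW vs zero-intercept WLS
    worst = 0.0
    for _ in range(25):
        m = int(rng.integers(2, 8))
        be = rng.uniform(0.2, 0.8, m) * rng.choice([-1, 1], m)
        bo = 0.1 * rng.standard_normal(m)
        so = rng.uniform(0.01, 0.1, m)
        b, se, _ = mr_mod.ivw(be, np.full(m, 0.02), bo, so)
        w = be**2 / so**2
        worst = max(worst, abs(b - np.sum(w * bo / be) / w.sum()), abs(se - w.sum() ** -0.5))
    out["ivw_max_abs_err"] = worst

    # BH vs step-up enumeration
    worst = 0.0
    for _ in range(10):
        m = int(rng.integers(1, 30))
        p = rng.uniform(0, 1, m)
        q = mr_mod.fdr_adjust(pd.DataFrame({"p_mr": p}))["fdr_q"].to_numpy()
        order = np.argsort(p)
        q_o = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q_o[i] = prev
        worst = max(worst, np.abs(q - q_o).max())
    out["bh_max_abs_err"] = worst

    # heterogeneity Q vs direct chi-square formula
    worst = 0.0
    for _ in range(25):
        m = int(rng.integers(2, 6))
        b = rng.standard_normal(m)
        s = rng.uniform(0.1, 1.0, m)
        q, p = meta_mod.heterogeneity(betas=b, ses=s)
        w = 1 / s**2
        q_o = float(np.sum(w * (b - np.sum(w * b) / w.sum()) ** 2))
        worst = max(worst, abs(q - q_o), abs(p - stats.chi2.sf(q_o, m - 1)))
    out["het_q_max_abs_err"] = worst

    # coloc posteriors vs enumeration
    from scipy.special import logsumexp

    worst = 0.0
    for _ in range(10):
        m = 200
        frames = []
        for z in (rng.normal(0, 2, m), rng.normal(0, 2, m)):
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": [f"rs{j}" for j in range(m)],
                        "chrom": "1",
                        "pos": np.arange(m),
                        "ea": "A",
                        "nea": "G",
                        "eaf": 0.3,
                        "beta": z * 0.03,
                        "se": 0.03,
                        "pval": 0.5,
                        "n": 10_000,
                    }
                )
            )
        res = coloc_mod.coloc_abf(frames[0], frames[1])
        l1 = np.asarray(coloc_mod.wakefield_log_abf(frames[0]["beta"], frames[0]["se"], 0.15))
        l2 = np.asarray(coloc_mod.wakefield_log_abf(frames[1]["beta"], frames[1]["se"], 0.15))
        p1, p2, p12 = res.priors
        cross = logsumexp([l1[j] + l2[k] for j in range(m) for k in range(m) if j != k])
        masses = np.array(
            [
                0.0,
                np.log(p1) + logsumexp(l1),
                np.log(p2) + logsumexp(l2),
                np.log(p1 * p2) + cross,
                np.log(p12) + logsumexp(l1 + l2),
            ]
        )
        expected = np.exp(masses - logsumexp(masses))
        got = np.array([res.pp[h] for h in coloc_mod.HYPOTHESES])
        worst = max(worst, np.abs(got - expected).max())
    out["coloc_max_abs_err"] = worst
    return out
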