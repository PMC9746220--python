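"""Synthetic-data generator: LD structure, ground-truth wiring, determinism."""

import numpy as np
import pandas as pd
import pytest

from protmr import simulate as sim


class TestGenotypes:
    def test_independent_block_has_no_ld(self):
        panel = sim.simulate_genotypes(1000, [(8, 0.0, (0.1, 0.4))], seed=1)
        r2 = panel.ld_r2(panel.variant_ids).to_numpy()
        off = r2[np.triu_indices(8, 1)]
        assert np.all(np.sqrt(off) < 0.1)

    def test_high_rho_gives_strong_adjacent_ld(self):
        panel = sim.simulate_genotypes(2000, [(5, 0.9, (0.25, 0.35))], seed=2)
        r2 = panel.ld_r2(panel.variant_ids).to_numpy()
        adjacent = [r2[i, i + 1] for i in range(4)]
        assert min(adjacent) > 0.5

    def test_adjacent_r2_tracks_rho_squared_for_matched_mafs(self):
        # with near-equal MAFs the Frechet bound is far away and the
        # calibrated copula should deliver dosage r ~ rho
        panel = sim.simulate_genotypes(4000, [(5, 0.9, (0.30, 0.32))], seed=2)
        r2 = panel.ld_r2(panel.variant_ids).to_numpy()
        adjacent = [r2[i, i + 1] for i in range(4)]
        assert abs(np.mean(adjacent) - 0.81) < 0.08

    def test_cross_block_independence(self):
        panel = sim.simulate_genotypes(
            500, [(5, 0.8, (0.1, 0.4)), (5, 0.8, (0.1, 0.4))], seed=3
        )
        r = np.corrcoef(panel.dosages, rowvar=False)
        cross = np.abs(r[:5, 5:])
        assert cross.max() < 0.15

    def test_realized_maf_tracks_target(self):
        panel = sim.simulate_genotypes(1000, [(20, 0.3, (0.05, 0.5))], seed=4)
        realized = panel.dosages.mean(axis=0) / 2
        assert np.all(np.abs(realized - panel.variant_meta["maf"]) < 0.05)

    def test_same_seed_reproduces_dosages(self):
        blocks = [(5, 0.5, (0.1, 0.4))]
        a = sim.simulate_genotypes(200, blocks, seed=9)
        b = sim.simulate_genotypes(200, blocks, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variant_meta.equals(b.variant_meta)

    def test_positions_strictly_increasing_per_chromosome(self):
        panel = sim.simulate_genotypes(
            50, [(4, 0.0, (0.1, 0.4))] * 30, seed=5
        )  # 30 blocks wrap onto 22 chromosomes
        for _, grp in panel.variant_meta.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].nunique() == len(grp)

    @pytest.mark.parametrize(
        "n_samples,blocks,err",
        [
            (1, [(5, 0.5, (0.1, 0.4))], "n_samples"),
            (100, [(0, 0.5, (0.1, 0.4))], "non-positive"),
            (100, [(5, 0.5, (0.0, 0.4))], "MAF"),
            (100, [(5, 0.5, (0.1, 0.6))], "MAF"),
            (100, [(5, 1.0, (0.1, 0.4))], "rho"),
        ],
    )
    def test_invalid_inputs_rejected(self, n_samples, blocks, err):
        with pytest.raises(ValueError, match=err):
            sim.simulate_genotypes(n_samples, blocks, seed=0)


class TestTruthAndProteins:
    def test_cis_variant_within_window_of_tss(self, small_panel):
        manifest = sim.design_truth(small_panel, 4, ["Y1"], seed=1)
        for pid, (vid, _) in manifest.cis_assignment.items():
            gene = manifest.genes.loc[pid]
            vmeta = small_panel.variant_meta.loc[vid]
            assert str(gene["chrom"]) == str(vmeta["chrom"])
            assert abs(vmeta["pos"] - gene["tss"]) <= 1_000_000

    def test_theta_recorded_for_all_pairs(self, small_panel):
        manifest = sim.design_truth(
            small_panel, 3, {"Y1": {"P001": 0.4}, "Y2": {}}, seed=1
        )
        for p in manifest.proteins:
            for o in ("Y1", "Y2"):
                assert o in manifest.theta[p]
        assert manifest.theta["P002"]["Y1"] == 0.0

    def test_hub_wired_into_at_least_five_proteins(self, small_panel):
        hub_var = small_panel.variant_ids[2]
        manifest = sim.design_truth(
            small_panel, 8, ["Y1"], hub=(hub_var, 5, 0.4), seed=1
        )
        targets = [
            p
            for p, tl in manifest.trans_assignment.items()
            if any(v == hub_var for v, _ in tl)
        ]
        assert len(targets) >= 5
        assert manifest.pleiotropic_hubs == [hub_var]

    def test_pure_noise_protein_has_unit_variance(self, small_panel):
        manifest = sim.design_truth(small_panel, 2, ["Y1"], b_cis=0.0, seed=1)
        prot = sim.simulate_proteins(small_panel, manifest, noise_sd=1.0, seed=2)
        assert np.allclose(prot.values.var(ddof=1), 1.0, atol=0.25)

    def test_noiseless_cis_protein_takes_three_dosage_values(self, small_panel):
        manifest = sim.design_truth(small_panel, 1, ["Y1"], b_cis=1.0, seed=1)
        prot = sim.simulate_proteins(small_panel, manifest, noise_sd=0.0, seed=2)
        assert set(np.unique(prot.values["P001"])) <= {0.0, 1.0, 2.0}

    def test_ols_on_dosage_recovers_cis_effect(self):
        panel = sim.simulate_genotypes(2000, [(5, 0.0, (0.2, 0.4))], seed=6)
        manifest = sim.design_truth(panel, 1, ["Y1"], b_cis=0.5, seed=1)
        prot = sim.simulate_proteins(panel, manifest, noise_sd=1.0, seed=2)
        g = panel.dosage(manifest.cis_assignment["P001"][0]).astype(float)
        y = prot.values["P001"].to_numpy()
        slope = np.polyfit(g, y, 1)[0]
        se = 1.0 / (g.std() * np.sqrt(len(g)))  # noise_sd / (sd(g) sqrt(n))
        assert abs(slope - 0.5) < 3 * se

    def test_unknown_manifest_variant_raises(self, small_panel):
        manifest = sim.design_truth(small_panel, 1, ["Y1"], seed=1)
        manifest.cis_assignment["P001"] = ("rs999999", 0.5)
        with pytest.raises(KeyError):
            sim.simulate_proteins(small_panel, manifest, seed=2)


class TestOutcomeGwas:
    def test_null_gwas_is_calibrated(self):
        panel = sim.simulate_genotypes(800, [(50, 0.0, (0.1, 0.4))], seed=7)
        manifest = sim.design_truth(panel, 1, ["Y1"], b_cis=0.0, seed=1)
        prot = sim.simulate_proteins(panel, manifest, seed=2)
        gwas = sim.simulate_outcome_gwas(panel, prot, manifest, 1.0, seed=3)["Y1"]
        frac = (gwas["pval"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.06

    def test_marginal_beta_at_cis_variant_is_theta_times_bcis(self):
        # path-tracing oracle: beta_marginal = theta * b_cis in expectation
        est = []
        for s in range(40):
            panel = sim.simulate_genotypes(2000, [(3, 0.0, (0.25, 0.35))], seed=100 + s)
            manifest = sim.design_truth(
                panel, 1, {"Y1": {"P001": 0.4}}, b_cis=0.5, seed=1
            )
            prot = sim.simulate_proteins(panel, manifest, seed=200 + s)
            gwas = sim.simulate_outcome_gwas(panel, prot, manifest, 1.0, seed=300 + s)
            cis = manifest.cis_assignment["P001"][0]
            est.append(gwas["Y1"].set_index("variant_id").loc[cis, "beta"])
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.2) < 3 * mc_se

    def test_same_seed_gives_identical_sumstats(self, causal_study):
        panel, manifest, proteins, _ = causal_study
        a = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=5)["Y1"]
        b = sim.simulate_outcome_gwas(panel, proteins, manifest, 1.0, seed=5)["Y1"]
        assert a.equals(b)


class TestRawProteomics:
    def make_clean(self, n=240, k=20, seed=31):
        panel = sim.simulate_genotypes(n, [(k, 0.0, (0.1, 0.4))], seed=seed)
        manifest = sim.design_truth(panel, k, ["Y1"], seed=seed + 1)
        return sim.simulate_proteins(panel, manifest, seed=seed + 2)

    def test_ledger_records_each_defect_kind(self):
        clean = self.make_clean()
        defects = [
            sim.Defect("lod", analyte="P001", fraction=0.2),
            sim.Defect("cv", analyte="P002", magnitude=0.30),
            sim.Defect("scale_factor", analyte="P003"),
            sim.Defect("iqr", analyte="P004", fraction=0.2),
        ]
        _, ledger = sim.make_raw_proteomics(clean, defects, seed=1)
        assert ledger["analytes"] == {
            "P001": "lod",
            "P002": "cv",
            "P003": "scale_factor",
            "P004": "iqr",
        }

    def test_contradictory_defects_rejected(self):
        clean = self.make_clean()
        with pytest.raises(ValueError, match="contradictory"):
            sim.make_raw_proteomics(
                clean,
                [sim.Defect("lod", analyte="P001"), sim.Defect("cv", analyte="P001")],
                seed=1,
            )

    def test_unknown_analyte_rejected(self):
        clean = self.make_clean()
        with pytest.raises(ValueError, match="unknown analyte"):
            sim.make_raw_proteomics(clean, [sim.Defect("lod", analyte="nope")], seed=1)

    def test_plate_metadata_has_calibrators_and_buffers(self):
        clean = self.make_clean()
        raw, _ = sim.make_raw_proteomics(clean, seed=1, n_plates=3)
        roles = raw.sample_meta.groupby(["plate", "role"]).size()
        for plate in (f"plate-{i}" for i in (1, 2, 3)):
            assert roles[(plate, "calibrator")] == 8
            assert roles[(plate, "buffer")] == 4

    def test_determinism(self):
        clean = self.make_clean()
        a, _ = sim.make_raw_proteomics(clean, [sim.Defect("lod", analyte="P001")], seed=7)
        b, _ = sim.make_raw_proteomics(clean, [sim.Defect("lod", analyte="P001")], seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)
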