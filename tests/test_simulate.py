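"""Generator contracts: reproducibility, analytic limits, and convergence
of simulated frequencies to their configured probabilities."""

import numpy as np
import pandas as pd
import pytest

from lymphpanel.cnv import fit_normal_panel
from lymphpanel.io import variants_to_frame
from lymphpanel.simulate import (
    PANEL_GENES,
    SimulationConfig,
    build_default_panel,
    is_driver_hotspot,
    simulate_coverage,
    simulate_normals,
    simulate_paired,
    simulate_survival,
    simulate_variants,
)
from lymphpanel.survival import SurvivalDataset, cox_univariable


def loss_truth(samples, loss, purity):
    return pd.DataFrame({"sample_id": samples, "loss": loss, "purity": purity})


class TestDeterminism:
    def test_coverage_bit_reproducible(self, panel):
        cfg = SimulationConfig(seed=5)
        truth = loss_truth([f"T{i}" for i in range(5)], "monoallelic", 0.7)
        a, _ = simulate_coverage(cfg, panel, truth)
        b, _ = simulate_coverage(SimulationConfig(seed=5), panel, truth)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_variants_bit_reproducible(self, panel):
        a, ta = simulate_variants(SimulationConfig(seed=5), panel)
        b, tb = simulate_variants(SimulationConfig(seed=5), panel)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_sample_order_irrelevant(self, panel):
        cfg = SimulationConfig(seed=5)
        t1 = loss_truth(["A", "B"], "none", 1.0)
        t2 = loss_truth(["B", "A"], "none", 1.0)
        c1, _ = simulate_coverage(cfg, panel, t1)
        c2, _ = simulate_coverage(cfg, panel, t2)
        pd.testing.assert_series_equal(c1.df["A"], c2.df["A"])


class TestCoverage:
    def test_purity_validated(self, panel, sim_config):
        with pytest.raises(ValueError, match="purity"):
            simulate_coverage(sim_config, panel, loss_truth(["T"], "none", 1.2))
        with pytest.raises(ValueError, match="purity"):
            simulate_coverage(sim_config, panel, loss_truth(["T"], "biallelic", 0.0))

    def test_unknown_loss_label_rejected(self, panel, sim_config):
        with pytest.raises(ValueError, match="loss"):
            simulate_coverage(sim_config, panel, loss_truth(["T"], "hemizygous", 0.5))

    def test_biallelic_purity_one_is_zero_dosage(self, panel, sim_config):
        cov, _ = simulate_coverage(
            sim_config, panel, loss_truth(["T"], "biallelic", 1.0))
        cdkn2a = [a.amplicon_id for a in panel.gene_amplicons("CDKN2A")]
        assert (cov.df.loc[cdkn2a, "T"] == 0).all()
        assert (cov.df.drop(index=cdkn2a)["T"] > 0).all()

    def test_no_loss_normalized_coverage_near_one(self, panel):
        """Loss-free samples: factor-normalized coverage on CDKN2A ~ 1."""
        cfg = SimulationConfig(seed=9)
        normals = simulate_normals(cfg, panel)
        model = fit_normal_panel(normals, panel, "CDKN2A")
        truth = loss_truth([f"T{i}" for i in range(200)], "none", 1.0)
        cov, _ = simulate_coverage(cfg, panel, truth)
        cdkn2a = model.amplicon_ids
        med = cov.df.median(axis=0)
        ratios = (cov.df.loc[cdkn2a] / med).div(model.factor, axis=0)
        # geometric mean matches the factor's log2 construction (the
        # arithmetic mean carries a small Jensen bias)
        gm = np.exp(np.log(ratios.to_numpy()).mean())
        assert abs(gm - 1.0) < 0.01

    def test_monoallelic_dosage_recovered(self, panel):
        """Monte-Carlo oracle for the dosage model: monoallelic loss at
        purity 0.6 leaves 1 - 0.6/2 = 0.7 of the diploid signal."""
        cfg = SimulationConfig(seed=9)
        normals = simulate_normals(cfg, panel)
        model = fit_normal_panel(normals, panel, "CDKN2A")
        truth = loss_truth([f"M{i}" for i in range(500)], "monoallelic", 0.6)
        cov, _ = simulate_coverage(cfg, panel, truth)
        med = cov.df.median(axis=0)
        ratios = (cov.df.loc[model.amplicon_ids] / med).div(model.factor, axis=0)
        gm = np.exp(np.log(ratios.to_numpy()).mean())
        assert abs(gm - 0.7) < 0.01


class TestVariants:
    def test_hotspot_probability_one(self, panel):
        cfg = SimulationConfig(seed=3, n_patients=40, hotspot_probs=(1.0, 0.0))
        recs, truth = simulate_variants(cfg, panel)
        per_patient = truth[truth.is_hotspot].groupby("sample_id").gene.agg(set)
        assert len(per_patient) == 40
        assert all(s == {"MYD88"} for s in per_patient)

    def test_artefact_off_switch(self, panel):
        cfg = SimulationConfig(seed=3, ffpe_transition_rate=0.0)
        _, truth = simulate_variants(cfg, panel)
        assert not truth.is_artefact.any()

    def test_artefacts_are_low_vaf_transitions(self, panel):
        cfg = SimulationConfig(seed=3, n_patients=30, ffpe_transition_rate=6.0)
        recs, truth = simulate_variants(cfg, panel)
        df = variants_to_frame(recs).merge(
            truth[["sample_id", "chrom", "pos", "is_artefact"]],
            on=["sample_id", "chrom", "pos"])
        art = df[df.is_artefact]
        assert len(art) > 50
        assert ((art.ref == "C") & (art.alt == "T") | (art.ref == "G") & (art.alt == "A")).all()
        assert (art.vaf < 0.10).all()
        assert (art.variant_class <= 3).all()

    def test_myd88_frequency_converges(self, panel):
        """Binomial oracle: at n = 5700 the observed MYD88-mutated patient
        fraction lands within +/-2% of the configured 79% marginal."""
        cfg = SimulationConfig(seed=17, n_patients=5700, ffpe_transition_rate=0.0,
                               background_variant_rate=0.0)
        _, truth = simulate_variants(cfg, panel)
        frac = truth[truth.gene == "MYD88"].sample_id.nunique() / 5700
        assert abs(frac - 0.79) < 0.02

    def test_unknown_gene_rejected(self, panel):
        probs = {"NOT_A_GENE": 0.5}
        cfg = SimulationConfig(seed=3, gene_mutation_probs=probs)
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            simulate_variants(cfg, panel)


class TestPaired:
    def _primary(self, seed=21, n=50):
        cfg = SimulationConfig(seed=seed, n_patients=n, ffpe_transition_rate=0.0)
        recs, truth = simulate_variants(cfg)
        return cfg, recs

    def test_identity_when_retention_one(self):
        cfg, recs = self._primary()
        cfg.retention_prob = 1.0
        cfg.shm_gain_rate = 0.0
        relapse, _ = simulate_paired(cfg, recs)
        primary_keys = {(v.sample_id, v.gene, v.pos, v.ref, v.alt) for v in recs}
        relapse_keys = {(v.sample_id[:-2], v.gene, v.pos, v.ref, v.alt) for v in relapse}
        assert primary_keys == relapse_keys

    def test_drivers_survive_total_nondriver_wipeout(self):
        cfg, recs = self._primary()
        cfg.retention_prob = 0.0
        cfg.shm_gain_rate = 0.0
        relapse, _ = simulate_paired(cfg, recs)
        assert relapse  # hotspots exist in a 50-patient cohort
        assert all(is_driver_hotspot(v) for v in relapse)

    def test_retention_fraction_binomial(self):
        """Binomial oracle: with retention 0.6 and gains off, the retained
        fraction of non-driver variants is 0.6 within 3 SDs."""
        cfg, recs = self._primary(seed=22, n=1000)
        cfg.retention_prob = 0.6
        cfg.shm_gain_rate = 0.0
        relapse, _ = simulate_paired(cfg, recs)
        n_nondriver = sum(1 for v in recs if not is_driver_hotspot(v))
        kept = sum(1 for v in relapse if not is_driver_hotspot(v))
        se = np.sqrt(0.6 * 0.4 / n_nondriver)
        assert abs(kept / n_nondriver - 0.6) < 3 * se

    def test_loss_flags_persist(self):
        cfg, recs = self._primary()
        cfg.cdkn2a_gain_prob = 0.0
        loss = {v: (i % 2 == 0) for i, v in enumerate(sorted({r.sample_id for r in recs}))}
        _, relapse_loss = simulate_paired(cfg, recs, primary_loss=loss)
        assert {k[:-2]: v for k, v in relapse_loss.items()} == loss


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = SimulationConfig(seed=31, censor_rate=0.0)
        cov = pd.DataFrame({"flag": [0, 1] * 25}, index=[f"P{i}" for i in range(50)])
        recs = simulate_survival(cfg, cov)
        assert all(r.os_event for r in recs)

    def test_unknown_hazard_key_rejected(self):
        cfg = SimulationConfig(seed=31, hazard_log_hr={"missing": 1.0})
        cov = pd.DataFrame({"flag": [0, 1]}, index=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            simulate_survival(cfg, cov)

    def test_hazard_ratio_recovered(self):
        """Parameter-recovery oracle: a log-HR of log(3) injected on a flag
        is recovered by univariable Cox within ~10% at n = 2000."""
        beta = np.log(3.0)
        cfg = SimulationConfig(seed=31, hazard_log_hr={"flag": beta}, censor_rate=0.005)
        idx = [f"P{i}" for i in range(2000)]
        cov = pd.DataFrame({"flag": np.tile([0.0, 1.0], 1000)}, index=idx)
        recs = simulate_survival(cfg, cov)
        df = pd.DataFrame(
            {"time_months": [r.follow_up_months for r in recs],
             "event": [r.os_event for r in recs],
             "flag": cov["flag"].to_numpy()},
            index=idx)
        ds = SurvivalDataset("OS", df)
        bhat, _, p, ok = cox_univariable(ds, "flag")
        assert ok and p < 1e-10
        assert abs(bhat - beta) / beta < 0.10
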