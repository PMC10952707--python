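import dataclasses

import numpy as np
import pandas as pd
import pytest

from agespec import synthetic
from agespec.synthetic import (
    AtacSpec,
    ConfigurationError,
    CytokineSpec,
    SimulationConfig,
    planted_cytokine_pairs,
    simulate_atac_peaks,
    simulate_cohorts,
    simulate_cytokines,
)
from conftest import small_config


class TestConfigValidation:
    def test_class_fractions_over_one_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            SimulationConfig(frac_shared=0.7, frac_infant_specific=0.4).validate()

    def test_small_block_size_rejected(self):
        with pytest.raises(ConfigurationError, match="dmr_block_size"):
            SimulationConfig(dmr_block_size=3).validate()


class TestSimulateCohorts:
    def test_same_seed_bit_identical(self):
        cfg = small_config(n_probes=1000, n_dmr_blocks=4, seed=5)
        out1 = simulate_cohorts(cfg)
        out2 = simulate_cohorts(cfg)
        assert out1[0].data.equals(out2[0].data)
        assert out1[1].equals(out2[1])
        assert out1[2].equals(out2[2])
        assert out1[3].equals(out2[3])

    def test_different_seeds_differ(self):
        no_corr = tuple(CytokineSpec(n) for n in ("IL2", "IL6"))
        a = simulate_cohorts(small_config(n_probes=500, n_dmr_blocks=2,
                                          cytokine_spec=no_corr, seed=1))
        b = simulate_cohorts(small_config(n_probes=500, n_dmr_blocks=2,
                                          cytokine_spec=no_corr, seed=2))
        assert not a[0].data.equals(b[0].data)
        assert list(a[3].columns) == list(b[3].columns)

    def test_zero_effect_all_null(self):
        cfg = small_config(n_probes=600, n_dmr_blocks=2, effect_delta_beta=0.0, seed=7)
        beta, sheet, manifest, truth = simulate_cohorts(cfg)
        assert (truth["true_class"] == "null").all()
        # per-probe condition difference centered on zero in expectation
        from agespec.differential import delta_beta

        db = delta_beta(beta, sheet)
        assert abs(float(np.mean(db))) < 0.01

    def test_class_counts_match_fractions_exactly(self, sim_config, sim_data):
        _, _, _, truth = sim_data
        counts = truth["true_class"].value_counts()
        expected = sim_config.class_counts()
        for cls, n in expected.items():
            assert counts.get(cls, 0) == n

    def test_hypo_fractions_exact(self, sim_config, sim_data):
        _, _, _, truth = sim_data
        for cls, frac in sim_config.hypo_fraction_by_class.items():
            sub = truth[truth["true_class"] == cls]
            col = ("true_delta_beta_adolescent" if cls == "adolescent_specific"
                   else "true_delta_beta_infant")
            n_hypo = int((sub[col] < 0).sum())
            assert n_hypo == round(frac * len(sub))

    def test_beta_strictly_inside_unit_interval(self, sim_data):
        values = sim_data[0].values
        assert values.min() > 0 and values.max() < 1

    def test_manifest_positions_increasing_within_chromosome(self, sim_data):
        manifest = sim_data[2]
        for _, sub in manifest.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_dmr_blocks_within_span_and_shared_sign(self, sim_config, sim_data):
        _, _, manifest, truth = sim_data
        man = manifest.set_index("probe_id")
        for _, block in truth[truth["dmr_block_id"].notna()].groupby("dmr_block_id"):
            assert len(block) == sim_config.dmr_block_size
            pos = man.loc[block["probe_id"], "pos"]
            chrom = man.loc[block["probe_id"], "chrom"]
            assert chrom.nunique() == 1
            assert pos.max() - pos.min() <= sim_config.dmr_block_span_bp
            assert block["true_delta_beta_infant"].nunique() == 1

    def test_paired_design(self, sim_data):
        sheet = sim_data[1]
        assert (sheet.groupby("donor_id")["condition"].nunique() == 2).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_shared_delta_beta_calibrated(self, seed):
        """Empirical mean delta-beta over planted shared probes hits the target.

        20,000 probes, full donor counts, logit noise 0.3: the mean recovered
        effect must land within 0.10 +/- 0.01 despite the nonlinear
        back-transform.
        """
        cfg = SimulationConfig(n_probes=20_000, noise_sd_logit=0.3, seed=seed)
        beta, sheet, manifest, truth = simulate_cohorts(cfg)
        from agespec.differential import delta_beta

        inf = sheet[sheet["cohort"] == "infant"]
        db = delta_beta(beta.subset_samples(inf["sample_id"]), inf)
        shared = (truth["true_class"] == "shared").to_numpy()
        sign = np.sign(truth["true_delta_beta_infant"].to_numpy()[shared])
        recovered = float(np.mean(db[shared] * sign))
        assert recovered == pytest.approx(0.10, abs=0.01)


class TestSimulateAtacPeaks:
    def test_zero_peaks_requested(self, sim_data):
        beta, sheet, manifest, truth = sim_data
        cfg = small_config(atac_spec=AtacSpec(n_peaks=0))
        peaks = simulate_atac_peaks(truth, manifest, cfg)
        assert len(peaks) == 0
        from agespec.integrate import overlap_probes_peaks

        assert len(overlap_probes_peaks(manifest, truth["probe_id"], peaks)) == 0

    def test_strong_concordance_dominates_expected_cells(self):
        """9:1 odds on ~2,000 planted probes: (hypo, gain) and (hyper, loss)
        dominate their rows, close to the binomial expectation 0.9."""
        cfg = small_config(
            n_probes=8000, frac_shared=0.25, n_dmr_blocks=0, seed=3,
            atac_spec=AtacSpec(n_peaks=4000, cover_prob=1.0, concordance_odds=9.0),
        )
        beta, sheet, manifest, truth = simulate_cohorts(cfg)
        peaks = simulate_atac_peaks(truth, manifest, cfg)
        from agespec.integrate import overlap_probes_peaks

        responsive = truth[truth["true_class"] != "null"]
        assign = overlap_probes_peaks(manifest, responsive["probe_id"], peaks)
        merged = assign.merge(responsive, on="probe_id")
        gain = peaks.loc[merged["peak_index"], "direction"].to_numpy() == "gain"
        hypo = (merged["true_delta_beta_infant"] < 0).to_numpy()
        p_gain_hypo = gain[hypo].mean()
        p_loss_hyper = (~gain[~hypo]).mean()
        assert p_gain_hypo == pytest.approx(0.9, abs=0.03)
        assert p_loss_hyper == pytest.approx(0.9, abs=0.03)

    def test_peaks_are_half_open_and_cover_their_probe(self, sim_config, sim_data):
        beta, sheet, manifest, truth = sim_data
        peaks = simulate_atac_peaks(truth, manifest, sim_config)
        assert (peaks["start"] < peaks["end"]).all()


class TestSimulateCytokines:
    def test_null_fold_change_not_significant(self):
        """With fold change 1 everywhere the cohort comparison is null."""
        from agespec.integrate import compare_cohort_fc, cytokine_log2fc

        n_sig = 0
        n_total = 0
        for seed in range(6):
            spec = tuple(
                CytokineSpec(name, baseline=50.0, fc_infant=1.0, fc_adolescent=1.0)
                for name in ("IL2", "IL6", "IL10", "IFNG", "TNF")
            )
            cfg = small_config(n_probes=400, n_dmr_blocks=0, cytokine_spec=spec, seed=seed)
            beta, sheet, manifest, truth = simulate_cohorts(cfg)
            cyto = simulate_cytokines(sheet, beta, truth, cfg)
            tests = compare_cohort_fc(cytokine_log2fc(cyto, sheet))
            n_sig += int((tests["p"] < 0.05).sum())
            n_total += len(tests)
        assert n_sig / n_total <= 0.10

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_correlation_recovered(self, seed):
        """rho = 0.9 at n = 15 activated samples gives sample r > 0.6."""
        from scipy.stats import pearsonr

        cfg = small_config(n_probes=2000, n_dmr_blocks=4, seed=seed)
        beta, sheet, manifest, truth = simulate_cohorts(cfg)
        cyto = simulate_cytokines(sheet, beta, truth, cfg)
        pairs = planted_cytokine_pairs(truth)
        assert len(pairs) == 4
        for _, row in pairs.iterrows():
            sub = sheet[sheet["cohort"] == row["cohort"]]
            donors = sorted(sub["donor_id"].unique())
            samples = [f"{d}_activated" for d in donors]
            x = beta.data.loc[row["probe_id"], samples].to_numpy()
            conc = cyto[(cyto["cytokine"] == row["cytokine"])
                        & (cyto["condition"] == "activated")].set_index("sample_id")
            y = conc.loc[samples, "concentration"].to_numpy()
            assert pearsonr(x, y)[0] > 0.6

    def test_concentrations_positive(self, sim_config, sim_data):
        beta, sheet, manifest, truth = sim_data
        cyto = simulate_cytokines(sheet, beta, truth, sim_config)
        assert (cyto["concentration"] > 0).all()

    def test_noncanonical_cytokine_warned_but_generated(self, caplog):
        cfg = small_config(
            n_probes=300, n_dmr_blocks=0,
            cytokine_spec=(CytokineSpec("IL42", baseline=10.0),), seed=0,
        )
        beta, sheet, manifest, truth = simulate_cohorts(cfg)
        with caplog.at_level("WARNING", logger="agespec"):
            cyto = simulate_cytokines(sheet, beta, truth, cfg)
        assert "IL42" in caplog.text
        assert set(cyto["cytokine"]) == {"IL42"}
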