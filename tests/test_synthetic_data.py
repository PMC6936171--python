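"""Synthetic-study generator: determinism, structure, and round trips."""

import numpy as np
import pandas as pd
import pytest

from dielsplice.fragment_quant import quantify_peak_table
from dielsplice.synthetic_data import (
    SimConfig,
    simulate_abundances,
    simulate_peak_tables,
    simulate_study,
    simulate_temperature,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        s1 = simulate_study(SimConfig(seed=5))
        s2 = simulate_study(SimConfig(seed=5))
        pd.testing.assert_frame_equal(s1.abundances, s2.abundances)
        pd.testing.assert_frame_equal(s1.metadata, s2.metadata)
        for season in s1.temperature:
            assert np.array_equal(s1.temperature[season].temp_c,
                                  s2.temperature[season].temp_c)

    def test_distinct_seeds_distinct_noise(self):
        s1 = simulate_study(SimConfig(seed=5))
        s2 = simulate_study(SimConfig(seed=6))
        assert not np.allclose(s1.abundances["norm_abundance"],
                               s2.abundances["norm_abundance"])


class TestStructure:
    def test_course_dimensions(self, default_study):
        meta = default_study.metadata
        # winter: L1 only; summer: three organs; 14 points x 3 replicates each
        assert len(meta) == (1 + 3) * 14 * 3
        counts = meta.groupby(["season_id", "organ"]).size()
        assert (counts == 42).all()
        assert set(meta["replicate"]) == {1, 2, 3}

    def test_zero_noise_replicates_equal_truth(self):
        cfg = SimConfig(seed=3, noise_sd=0.0)
        study = simulate_abundances(cfg)
        merged = study.abundances.merge(
            study.truth_abundances, on=["sample_id", "gene_id", "isoform_id"]
        )
        assert np.allclose(merged["norm_abundance"], merged["true_abundance"])

    def test_truth_params_record_every_isoform(self, default_study):
        cfg = default_study.config
        expected = (len(cfg.genes) + len(cfg.events)) * len(cfg.seasons)
        assert len(default_study.truth_params) == expected
        assert {"true_peak_zt", "temp_slope", "rel_level"} <= set(
            default_study.truth_params.columns
        )

    def test_as_truth_peaks_before_fs(self, default_study):
        """The configured study places every AS peak earlier (mod 24) than
        its gene's FS peak, as observed in leaf courses."""
        tp = default_study.truth_params.set_index(["season_id", "gene_id", "isoform_id"])
        for (season, gene, iso), row in tp.iterrows():
            if iso == "FS":
                continue
            fs_peak = tp.loc[(season, gene, "FS"), "true_peak_zt"]
            assert row["true_peak_zt"] < fs_peak


class TestTemperature:
    def test_constant_when_no_amplitude_no_noise(self):
        from dielsplice.synthetic_data import TempSim

        cfg = SimConfig(seed=0, temperature=TempSim(
            mean_c={"winter": 18.0, "summer": 26.0},
            diel_amplitude_c=0.0, ar1_sd=0.0))
        temps = simulate_temperature(cfg)
        assert np.allclose(temps["winter"].temp_c, 18.0)
        assert np.allclose(temps["summer"].temp_c, 26.0)

    def test_winter_cooler_than_summer(self, default_study):
        t = default_study.temperature
        assert t["winter"].temp_c.mean() < t["summer"].temp_c.mean()

    def test_covers_all_sampling_instants(self, default_study):
        for season, grp in default_study.metadata.groupby("season_id"):
            temps = default_study.temperature[season]
            vals = temps.at(grp["clock_time"].to_numpy())
            assert np.all(np.isfinite(vals))

    def test_ar1_marginal_sd_matches_configuration(self):
        from dielsplice.synthetic_data import TempSim

        ts = TempSim(mean_c={"winter": 18.0, "summer": 26.0},
                     diel_amplitude_c=0.0, ar1_sd=0.8,
                     interval_h=0.01, duration_h=100.0)  # 10,001 points
        cfg = SimConfig(seed=9, temperature=ts)
        temps = simulate_temperature(cfg)
        sd = temps["winter"].temp_c.std()
        assert abs(sd - 0.8) / 0.8 < 0.10


class TestPeakTables:
    def test_round_trip_recovers_abundance_ratios(self):
        """No gain noise: quantified normalized abundances equal the noisy
        simulated abundances up to the per-sample reference factor, so
        AS/FS ratios match exactly."""
        cfg = SimConfig(seed=7, gain_sd=0.0)
        study = simulate_abundances(cfg)
        peaks = simulate_peak_tables(study)
        defs, refs, ladder = cfg.panel()
        quant = quantify_peak_table(peaks, defs, refs, ladder_sizes=ladder)
        merged = quant.merge(study.abundances, on=["sample_id", "gene_id", "isoform_id"],
                             suffixes=("_q", "_sim"))
        piv = merged.pivot_table(index="sample_id", columns="isoform_id",
                                 values=["norm_abundance_q", "norm_abundance_sim"])
        r_q = piv[("norm_abundance_q", "I1R")] / piv[("norm_abundance_q", "FS")]
        r_s = piv[("norm_abundance_sim", "I1R")] / piv[("norm_abundance_sim", "FS")]
        ok = r_s.notna()
        assert np.allclose(r_q[ok], r_s[ok], rtol=1e-2)

    def test_gain_invariance_after_normalization(self):
        """Lognormal per-sample gain cancels in reference normalization: the
        quantified/simulated quotient is constant within each sample."""
        cfg = SimConfig(seed=7, gain_sd=0.5)
        study = simulate_abundances(cfg)
        peaks = simulate_peak_tables(study)
        defs, refs, ladder = cfg.panel()
        quant = quantify_peak_table(peaks, defs, refs, ladder_sizes=ladder)
        merged = quant.merge(study.abundances, on=["sample_id", "gene_id", "isoform_id"],
                             suffixes=("_q", "_sim"))
        merged = merged[merged["norm_abundance_sim"] > 0]
        merged["q"] = merged["norm_abundance_q"] / merged["norm_abundance_sim"]
        spread = merged.groupby("sample_id")["q"].agg(lambda s: s.max() / s.min())
        assert (spread < 1.02).all()

    def test_ladder_present_per_sample(self, default_study):
        peaks = simulate_peak_tables(default_study)
        ladder_counts = peaks[peaks["dye"] == "ladder"].groupby("sample_id").size()
        assert (ladder_counts == len(default_study.config.ladder_sizes)).all()

    def test_empty_panel_rejected(self):
        cfg = SimConfig(seed=0, genes=[], events=[], reference_genes=[])
        study = simulate_abundances(cfg)
        with pytest.raises(ValueError):
            simulate_peak_tables(study)
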