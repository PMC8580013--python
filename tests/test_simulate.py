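import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from microstab import simulate
from microstab.simulate import (
    SimConfig,
    dryness_probability,
    evolve_subject,
    generate_cohort,
    generate_symptoms,
    sample_community,
)


class TestSampleCommunity:
    def test_counts_sum_to_depth(self, rng):
        cfg = SimConfig()
        vec = sample_community("CT-A", 5000, cfg, rng)
        assert vec.sum() == 5000
        assert (vec >= 0).all()

    def test_high_concentration_matches_profile_mean(self, rng):
        # with a near-infinite Dirichlet concentration the draw is a plain
        # multinomial around the template, so Lactobacillus ~ profile * depth
        cfg = SimConfig(ct_concentration=1e9)
        profile = cfg.ct_profiles["CT-A"]
        idx = list(profile).index("Lactobacillus")
        draws = np.array([sample_community("CT-A", 10_000, cfg, rng)[idx]
                          for _ in range(50)])
        expected = profile["Lactobacillus"] * 10_000
        assert abs(draws.mean() - expected) < 3 * np.sqrt(10_000 * 0.05)

    def test_streptococcus_dominates_ct_c(self, rng):
        cfg = SimConfig()
        profile = cfg.ct_profiles["CT-C"]
        assert profile["Streptococcus"] > 0.40

    def test_zero_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_community("CT-A", 0, SimConfig(), rng)

    def test_unknown_ct_rejected(self, rng):
        with pytest.raises(KeyError):
            sample_community("CT-Z", 100, SimConfig(), rng)


class TestEvolveSubject:
    def test_zero_switch_probability_constant(self, rng):
        cfg = SimConfig(transition={"healthy": 0.0, "cancer": 0.6})
        seq = evolve_subject("healthy", "CT-B", 4, cfg, rng)
        assert seq == ["CT-B"] * 4

    def test_certain_switch_always_changes(self, rng):
        cfg = SimConfig(transition={"cancer": 1.0, "healthy": 0.2})
        seq = evolve_subject("cancer", "CT-A", 6, cfg, rng)
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_switch_counts_follow_binomial_expectation(self):
        # 3 transitions at p=0.6 vs p=0.2 -> expected 1.8 vs 0.6 switches
        cfg = SimConfig()
        rng = np.random.default_rng(11)
        def mean_switches(cohort):
            tot = 0
            for _ in range(500):
                seq = evolve_subject(cohort, "CT-A", 4, cfg, rng)
                tot += sum(a != b for a, b in zip(seq, seq[1:]))
            return tot / 500
        mc, mh = mean_switches("cancer"), mean_switches("healthy")
        assert mc > mh
        assert abs(mc - 1.8) < 0.15
        assert abs(mh - 0.6) < 0.15

    def test_unknown_cohort_rejected(self, rng):
        with pytest.raises(KeyError):
            evolve_subject("reference", "CT-A", 4, SimConfig(), rng)


class TestSymptoms:
    def test_dryness_probability_decreases_with_lactobacillus(self):
        cfg = SimConfig()
        assert dryness_probability(0.99, cfg) < dryness_probability(0.0, cfg)

    def test_high_lacto_dryness_below_low_lacto(self, rng):
        cfg = SimConfig()
        comp_hi = {g: 0.0 for g in simulate.GENUS_PANEL}
        comp_hi["Lactobacillus"] = 1.0
        comp_lo = {g: 1.0 / len(simulate.GENUS_PANEL) for g in simulate.GENUS_PANEL}
        n = 400
        dry_hi = sum(generate_symptoms(comp_hi, "healthy", cfg, rng)["pro_dryness"] > 0
                     for _ in range(n)) / n
        dry_lo = sum(generate_symptoms(comp_lo, "healthy", cfg, rng)["pro_dryness"] > 0
                     for _ in range(n)) / n
        assert dry_hi < dry_lo

    def test_ph_rises_when_lactobacillus_lost(self, rng):
        cfg = SimConfig()
        comp_hi = {g: 0.0 for g in simulate.GENUS_PANEL}
        comp_hi["Lactobacillus"] = 1.0
        comp_lo = dict(comp_hi)
        comp_lo["Lactobacillus"] = 0.0
        comp_lo["Prevotella"] = 1.0
        n = 300
        hi = np.mean([generate_symptoms(comp_hi, "healthy", cfg, rng)["pH"] >= 5
                      for _ in range(n)])
        lo = np.mean([generate_symptoms(comp_lo, "healthy", cfg, rng)["pH"] >= 5
                      for _ in range(n)])
        assert lo > hi

    def test_zero_slope_prevalence_ignores_composition(self, rng):
        cfg = SimConfig(dryness_slope=0.0, dryness_intercept=0.0)
        assert dryness_probability(0.0, cfg) == dryness_probability(1.0, cfg) == 0.5

    def test_bad_composition_rejected(self, rng):
        comp = {g: 0.0 for g in simulate.GENUS_PANEL}
        with pytest.raises(ValueError, match="sums to"):
            generate_symptoms(comp, "healthy", SimConfig(), rng)


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        a = generate_cohort(SimConfig(seed=7))
        b = generate_cohort(SimConfig(seed=7))
        assert a.counts == b.counts
        assert a.blanks == b.blanks
        assert a.tree == b.tree
        pd.testing.assert_frame_equal(a.metadata.data, b.metadata.data)
        pd.testing.assert_frame_equal(a.symptoms, b.symptoms)
        assert a.truth == b.truth

    def test_study_shape(self, default_study):
        # 25 cancer + 27 healthy subjects x 4 timepoints
        assert len(default_study.counts.samples) == 208
        assert len(default_study.truth) == 52
        assert set(default_study.metadata.data["cohort"]) == {"cancer", "healthy"}

    def test_every_sample_has_metadata(self, default_study):
        assert set(default_study.counts.samples) == set(default_study.metadata.samples)

    def test_blank_totals_capped(self, default_study):
        cfg = SimConfig()
        assert (default_study.blanks.totals() <= cfg.blank_depth_max).all()

    def test_depth_median_near_target(self, default_study):
        med = default_study.counts.totals().median()
        assert abs(med - 35200) / 35200 < 0.10

    def test_planted_dryness_link(self):
        study = generate_cohort(SimConfig(seed=5, n_cancer=250, n_healthy=250))
        rel = study.counts.relative_abundance()
        lacto = rel.loc["Lactobacillus"]
        dryness = study.symptoms.loc[lacto.index, "pro_dryness"]
        rho, p = spearmanr(lacto, dryness)
        assert rho < 0
        assert p < 0.01

    def test_cancer_less_stable_than_healthy(self):
        from microstab.stability import stability_table
        study = generate_cohort(SimConfig(seed=9, n_cancer=200, n_healthy=200))
        rel = study.counts.relative_abundance()
        stab = stability_table(rel, study.counts.sample_index)
        coh = pd.Series({s: v["cohort"] for s, v in study.truth.items()})
        coh = coh.reindex(stab.index)
        mean_cancer = stab.loc[coh == "cancer", "overall_stability"].mean()
        mean_healthy = stab.loc[coh == "healthy", "overall_stability"].mean()
        assert mean_cancer > mean_healthy

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimConfig(n_timepoints=1))
        with pytest.raises(ValueError):
            generate_cohort(SimConfig(transition={"cancer": 1.5, "healthy": 0.2}))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=3, n_cancer=5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_write_outputs(self, default_study, tmp_path):
        default_study.write(tmp_path / "study")
        for name in ["counts.tsv", "blanks.tsv", "tree.nwk", "metadata.csv",
                     "symptoms.csv", "truth.json"]:
            assert (tmp_path / "study" / name).exists()
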