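"""Synthetic-cohort generator: determinism, noise-free round trips,
pattern semantics, jitter calibration."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from nglyco.chem import ion_mz, parse_adduct_label, parse_composition, ppm_error
from nglyco.errors import ConfigurationError
from nglyco.pipeline import quantify_cohort, run_synthetic_pipeline, species_mz_map
from nglyco.quantify import GROUPS, group_summaries
from nglyco.simulate import (
    SpeciesDesign,
    SynthConfig,
    generate_cohort,
    study_profile_config,
)

SMALL_GLYCOME = (
    SpeciesDesign("(Hex)5(HexNAc)2", "[M+Na]+", baseline=80.0, pattern="ubiquitous"),
    SpeciesDesign("(Hex)3(HexNAc)4(Fuc)1", "[M+Na]+", baseline=30.0, pattern="control-only"),
    SpeciesDesign("(Hex)4(HexNAc)3", "[M-H]-", baseline=20.0, pattern="treatment-induced"),
    SpeciesDesign("(Hex)2(HexNAc)6", "[M-H]-", baseline=40.0, pattern="treatment-suppressed"),
)


def _noise_free(seed=0, **kw):
    return SynthConfig(seed=seed, species=SMALL_GLYCOME, sigma_log=0.0, mass_jitter_ppm=0.0, **kw)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = study_profile_config(seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.behavior.equals(b.behavior)
        assert a.manifest.equals(b.manifest)
        for sample in a.peaklists:
            assert a.peaklists[sample] == b.peaklists[sample]

    def test_different_seed_different_noise(self):
        a = generate_cohort(study_profile_config(seed=1))
        b = generate_cohort(study_profile_config(seed=2))
        assert not a.behavior.equals(b.behavior)


class TestNoiseFreeRoundTrip:
    def test_pipeline_recovers_configured_intensities(self):
        """With zero noise the quantified matrix equals the designed
        baselines and detectability exactly."""
        cfg = _noise_free()
        cohort = generate_cohort(cfg)
        keys = species_mz_map(cohort.ground_truth.species["key"])
        matrix, _, excluded = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=keys)
        assert excluded == []
        for d in cfg.species:
            for group in GROUPS:
                values = matrix.replicates(d.key, group)
                expected = d.group_mean(group)
                assert values == pytest.approx([expected] * len(values), abs=1e-9)

    def test_detectability_matches_ground_truth(self):
        cohort = generate_cohort(_noise_free())
        keys = species_mz_map(cohort.ground_truth.species["key"])
        matrix, _, _ = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=keys)
        summ = group_summaries(matrix)
        for _, row in cohort.ground_truth.species.iterrows():
            for group in GROUPS:
                assert summ.loc[row["key"], f"{group}_detectable"] == row[f"det_{group}"]

    def test_species_discovery_by_assignment(self):
        """Without ground-truth keys, composition assignment recovers the
        same species keys from the emitted peaks."""
        cohort = generate_cohort(_noise_free())
        matrix, _, _ = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=None)
        assert set(matrix.species) == set(cohort.ground_truth.species["key"])


class TestPatterns:
    def test_pattern_presence_semantics(self):
        cohort = generate_cohort(_noise_free())
        keys = species_mz_map(cohort.ground_truth.species["key"])
        matrix, _, _ = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=keys)
        induced = SMALL_GLYCOME[2].key
        assert not matrix.replicates(induced, "control").any()
        assert not matrix.replicates(induced, "model").any()
        assert matrix.replicates(induced, "treated").all()
        suppressed = SMALL_GLYCOME[3].key
        assert matrix.replicates(suppressed, "model").all()
        assert not matrix.replicates(suppressed, "treated").any()

    def test_planted_species_must_exist(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(species=SMALL_GLYCOME, planted=("(Hex)9(HexNAc)9 [M+Na]+", "di_short", 0.9))

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            SpeciesDesign("(Hex)3", "[M+Na]+", baseline=1.0, pattern="sometimes")


class TestJitterCalibration:
    def test_empirical_ppm_sd_matches_configuration(self):
        """Over >= 1000 emitted peaks the sample SD of ppm errors is within
        15% of the configured jitter."""
        cfg = SynthConfig(
            seed=8,
            species=SMALL_GLYCOME,
            group_sizes=(150, 150, 150),
            sigma_log=0.0,
            mass_jitter_ppm=2.0,
        )
        cohort = generate_cohort(cfg)
        theo = {d.key: ion_mz(parse_composition(d.composition), parse_adduct_label(d.adduct)) for d in cfg.species}
        errors = []
        for sample, peaks in cohort.peaklists.items():
            for p in peaks:
                for mz in theo.values():
                    if abs(p.mz - mz) < 0.5:
                        errors.append(ppm_error(p.mz, mz))
        assert len(errors) >= 1000
        sd = np.std(errors, ddof=1)
        assert abs(sd - 2.0) / 2.0 < 0.15


class TestStudyShapedConfig:
    def test_census_matches_study_profile(self):
        counts = {}
        for seed in (0, 123):
            _, _, _, _, counts = run_synthetic_pipeline(study_profile_config(seed=seed), significance="markers")
            assert counts["control_only"] == 9
            assert counts["model_only"] == 5
            assert counts["treatment_induced"] == 15
            assert counts["treatment_suppressed"] == 5
            assert counts["modulated_by_treatment"] == 21

    def test_noise_free_variant_recovers_baselines(self):
        cfg = replace(study_profile_config(seed=5), sigma_log=0.0, mass_jitter_ppm=0.0)
        cfg = replace(cfg, species=tuple(replace(d, sigma_log=0.0) for d in cfg.species))
        cohort = generate_cohort(cfg)
        keys = species_mz_map(cohort.ground_truth.species["key"])
        matrix, _, _ = quantify_cohort(cohort.peaklists, cohort.manifest, species_keys=keys)
        summ = group_summaries(matrix)
        for d in cfg.species:
            for group in GROUPS:
                assert summ.loc[d.key, f"{group}_mean"] == pytest.approx(d.group_mean(group), abs=1e-9)

    def test_recomputed_tests_flag_the_responsive_species(self):
        cfg = study_profile_config(seed=31)
        _, _, _, calls, _ = run_synthetic_pipeline(cfg, significance="recomputed")
        call = next(c for c in calls if c.species == cfg.planted[0])
        assert "significantly_changed_by_treatment" in call
        assert "significantly_different_model_vs_control" in call
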