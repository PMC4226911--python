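import numpy as np
import pandas as pd
import pytest

from mirscreen.quantify import normalize_screen
from mirscreen.simulate import (
    ConfigError,
    PlantSpec,
    PlantingError,
    ReporterComponents,
    SimulationConfig,
    build_reporter_transcript,
    mirna_names,
    simulate_guides,
    simulate_isomir_catalog,
    simulate_screen,
    simulate_transcript,
)
from mirscreen.seed_affinity import seed_sites
from mirscreen.transcripts import MiRNASpec
from tests.conftest import noise_free_config

GUIDE = "ACGUACGUACGUACGUACGUAC"


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("n_mirnas", 0), ("n_transfections", 0), ("dropout_prob", 1.0),
         ("dropout_prob", -0.1), ("membrane_sd", -1.0), ("sirna_fold", 0.0)],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**{field: value}).validate()

    def test_planted_effect_must_be_positive(self):
        config = SimulationConfig(planted_effects={"miR-sim-001": -2.0})
        with pytest.raises(ConfigError, match="planted_effects"):
            config.validate()

    def test_planted_effect_unknown_treatment_rejected(self):
        config = SimulationConfig(n_mirnas=3, planted_effects={"nope": 2.0})
        with pytest.raises(ConfigError, match="unknown treatments"):
            simulate_screen(config)

    def test_default_expected_usable_measures(self):
        """5 transfections x 2 blots x (1 - 0.17) dropout = 8.3 on average."""
        c = SimulationConfig()
        expected = c.n_transfections * c.n_blots_per_transfection * (1 - c.dropout_prob)
        assert expected == pytest.approx(8.3)


class TestSimulateScreen:
    def test_identical_seed_identical_output(self):
        config = SimulationConfig(n_mirnas=10, rng_seed=42)
        a, _ = simulate_screen(config)
        b, _ = simulate_screen(config)
        pd.testing.assert_frame_equal(a, b)
        c, _ = simulate_screen(SimulationConfig(n_mirnas=10, rng_seed=43))
        assert not a["intensity"].equals(c["intensity"])

    def test_noise_free_null_every_corrected_amount_is_one(self):
        table, _ = simulate_screen(noise_free_config())
        corrected = normalize_screen(table)
        non_sirna = corrected.loc[corrected["treatment"] != "siRNA", "corrected"]
        assert np.allclose(non_sirna, 1.0, atol=1e-12)

    def test_channels_complete_per_lane(self):
        table, _ = simulate_screen(SimulationConfig(n_mirnas=5, rng_seed=1))
        per_lane = table.groupby(["membrane_id", "lane_id"])["channel"].nunique()
        assert (per_lane == 3).all()

    def test_truth_covers_emitted_membranes_and_lanes(self):
        table, truth = simulate_screen(SimulationConfig(n_mirnas=5, rng_seed=2))
        assert set(table["membrane_id"]) <= set(truth.membrane_effect)
        lanes = set(map(tuple, table[["membrane_id", "lane_id"]].drop_duplicates().values))
        assert lanes == set(truth.lane_efficiency)

    def test_dropout_rate_close_to_nominal(self):
        config = SimulationConfig(n_mirnas=40, dropout_prob=0.17, rng_seed=3)
        table, truth = simulate_screen(config)
        total = len(table) // 3 + len(truth.dropped_lanes)
        observed = len(truth.dropped_lanes) / total
        assert observed == pytest.approx(0.17, abs=0.02)

    def test_mean_usable_measures_near_eight_point_three(self):
        config = SimulationConfig(rng_seed=5)  # full-size default screen
        table, _ = simulate_screen(config)
        corrected = normalize_screen(table)
        # controls sit on every membrane group, so only the per-miRNA counts
        # track the usable-measure average
        mirna_measures = (
            corrected.loc[corrected["treatment"].str.startswith("miR-sim")]
            .groupby("treatment").size()
        )
        assert mirna_measures.mean() == pytest.approx(8.3, abs=0.5)

    def test_controls_present_on_every_membrane(self):
        table, _ = simulate_screen(SimulationConfig(n_mirnas=30, rng_seed=6,
                                                    dropout_prob=0.0))
        per_membrane = table.groupby("membrane_id")["treatment"].agg(set)
        assert all({"NC1", "NC2", "siRNA"} <= s for s in per_membrane)


class TestSimulateGuides:
    def test_deterministic_and_well_formed(self):
        names = mirna_names(5)
        a = simulate_guides(names, rng_seed=1)
        b = simulate_guides(names, rng_seed=1)
        assert a == b
        assert all(len(g) == 22 and set(g) <= set("ACGU") for g in a.values())


class TestSimulateTranscript:
    def test_single_6mer_in_orf_only(self):
        transcript, truth = simulate_transcript(
            {"five_prime_utr": 100, "orf": 300, "three_prime_utr": 150},
            [PlantSpec("X", "orf", "6mer")], {"X": GUIDE}, rng_seed=11,
        )
        profile = seed_sites(MiRNASpec("X", GUIDE), transcript)
        assert profile.count("orf", "6mer") == 1
        assert profile.total() == 1
        assert truth[0].region_name == "orf"

    def test_planted_truth_matches_hierarchical_scan(self):
        plants = [PlantSpec("X", "orf", "8mer"), PlantSpec("X", "orf", "6mer"),
                  PlantSpec("X", "three_prime_utr", "7mer-A1")]
        transcript, truth = simulate_transcript(
            {"orf": 400, "three_prime_utr": 200}, plants, {"X": GUIDE}, rng_seed=12,
        )
        profile = seed_sites(MiRNASpec("X", GUIDE), transcript)
        for spec in plants:
            planted = sum(
                1 for t in truth
                if (t.region_name, t.site_class) == (spec.region_name, spec.site_class)
            )
            assert profile.count(spec.region_name, spec.site_class) == planted

    def test_explicit_position_honoured(self):
        transcript, truth = simulate_transcript(
            {"orf": 100}, [PlantSpec("X", "orf", "6mer", position=40)],
            {"X": GUIDE}, rng_seed=13,
        )
        assert truth[0].position == 40
        from mirscreen.seed_affinity import site_strings
        assert transcript.sequence[40:46] == site_strings(GUIDE)["6mer"]

    def test_infeasible_packing_errors(self):
        with pytest.raises(PlantingError):
            simulate_transcript(
                {"orf": 10}, [PlantSpec("X", "orf", "8mer"), PlantSpec("X", "orf", "8mer")],
                {"X": GUIDE}, rng_seed=14,
            )

    def test_unnamed_mirnas_left_unconstrained(self):
        transcript, truth = simulate_transcript(
            {"orf": 500}, [], {}, rng_seed=15
        )
        assert len(transcript) == 500
        assert truth == []


class TestReporterLayout:
    def test_published_component_arithmetic(self):
        """Default components give a 1,405-bp insert in a 1,436-nt
        transcript, 93.1% of which is the native target mRNA."""
        skeleton, report = build_reporter_transcript()
        assert report["insert_bp"] == 1405
        assert report["transcript_bp"] == 1436
        assert report["ovine_percent"] == pytest.approx(93.1, abs=0.05)
        assert report["ovine_percent"] > 93.0
        assert len(skeleton) == 1436
        region_spans = {(r.name, r.start, r.end) for r in skeleton.regions}
        assert ("five_prime_utr", 0, 210) in region_spans
        assert ("orf", 210, 1164) in region_spans
        assert ("three_prime_utr", 1170, 1406) in region_spans
        assert report["extra_upstream_bp"] == 36
        assert report["extra_internal_bp"] == 33
        assert report["extra_downstream_bp"] == 30

    def test_no_extras_means_fully_native(self):
        components = ReporterComponents(
            vector_5p=0, upstream_non_ovine=0, ha_tag=0, linker=0, vector_3p=0
        )
        _, report = build_reporter_transcript(components)
        assert report["ovine_percent"] == pytest.approx(100.0)

    def test_half_vector_half_native_is_fifty_percent(self):
        components = ReporterComponents(
            vector_5p=10, upstream_non_ovine=0, five_prime_utr=0, orf_ovine=10,
            ha_tag=0, linker=0, three_prime_utr=0, vector_3p=0,
        )
        _, report = build_reporter_transcript(components)
        assert report["ovine_percent"] == pytest.approx(50.0)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ReporterComponents(ha_tag=-1)


class TestIsomirCatalog:
    def test_deterministic(self):
        a, ea = simulate_isomir_catalog(rng_seed=7)
        b, eb = simulate_isomir_catalog(rng_seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert ea == eb

    def test_truth_relationships_hold_in_counts(self):
        catalog, expected = simulate_isomir_catalog(n_precursors=6, rng_seed=8)
        libs = [c for c in catalog.columns if c.startswith("lib_")]
        by_name = catalog.set_index("name")
        for p in range(1, 7):
            ref, alt = f"pre-mir-{p:03d}-3p", f"pre-mir-{p:03d}-3p.alt"
            ref_total = by_name.loc[ref, libs].sum()
            alt_total = by_name.loc[alt, libs].sum()
            alt_max = by_name.loc[alt, libs].max()
            in_expected = alt in expected
            assert in_expected == (
                alt_total > ref_total / 3 or alt_max > 200
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_isomir_catalog(n_precursors=0)
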