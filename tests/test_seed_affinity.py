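import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirscreen.seed_affinity import (
    SITE_CLASSES,
    SeedAmbiguityError,
    affinity_effect_correlation,
    attach_external_scores,
    seed_matches,
    seed_score,
    seed_sites,
    site_strings,
)
from mirscreen.simulate import PlantSpec, simulate_transcript
from mirscreen.transcripts import MiRNASpec, Region, TargetTranscript
from tests.conftest import random_guide, random_target
from tests.oracles import oracle_matches, oracle_site_strings

GUIDE = "ACGUACGUACGUACGUACGUAC"

rna = st.text(alphabet="ACGU", min_size=16, max_size=25)


class TestSiteStrings:
    @given(guide=rna)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_site_strings_match_biopython_oracle(self, guide):
        assert site_strings(guide) == oracle_site_strings(guide)

    def test_ambiguous_seed_rejected(self):
        spec = MiRNASpec("amb", "ACGRACGUACGUACGUACGUAC", mixed_positions=frozenset({4}))
        with pytest.raises(SeedAmbiguityError):
            site_strings(spec)

    def test_ambiguity_outside_seed_tolerated(self):
        spec = MiRNASpec("amb", "ACGUACGUACGUACGUACGURC", mixed_positions=frozenset({21}))
        assert set(site_strings(spec)) == set(SITE_CLASSES)


class TestSeedSites:
    def test_poly_a_target_with_non_a_seed_has_no_sites(self):
        target = TargetTranscript("t", "A" * 100)
        profile = seed_sites(GUIDE, target)
        assert profile.total() == 0

    def test_planted_8mer_hierarchical_vs_overlapping(self):
        transcript, _ = simulate_transcript(
            {"orf": 200}, [PlantSpec("X", "orf", "8mer")], {"X": GUIDE}, rng_seed=3
        )
        hier = seed_sites(MiRNASpec("X", GUIDE), transcript, "hierarchical")
        over = seed_sites(MiRNASpec("X", GUIDE), transcript, "overlapping")
        assert {c: hier.count("orf", c) for c in SITE_CLASSES} == {
            "8mer": 1, "7mer-m8": 0, "7mer-A1": 0, "6mer": 0, "6mer-offset": 0
        }
        assert all(over.count("orf", c) == 1 for c in SITE_CLASSES)

    def test_dna_and_rna_alphabets_scan_identically(self):
        rng = np.random.default_rng(8)
        seq = random_target(rng, 300)
        a = seed_matches(GUIDE, seq)
        b = seed_matches(GUIDE, seq.replace("U", "T"))
        assert a == b

    def test_region_additivity_with_uncovered_gap(self):
        rng = np.random.default_rng(9)
        seq = random_target(rng, 400)
        covered = TargetTranscript(
            "t", seq, (Region("orf", 0, 200), Region("three_prime_utr", 250, 400))
        )
        profile = seed_sites(GUIDE, covered, "overlapping")
        for cls in SITE_CLASSES:
            region_sum = profile.count("orf", cls) + profile.count("three_prime_utr", cls)
            assert profile.count("full_length", cls) >= region_sum

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            guide = random_guide(rng)
            seq = random_target(rng, int(rng.integers(50, 400)))
            for mode in ("hierarchical", "overlapping"):
                assert sorted(seed_matches(guide, seq, mode)) == sorted(
                    oracle_matches(guide, seq, mode)
                ), (guide, seq, mode)

    def test_hierarchy_conservation(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            guide, seq = random_guide(rng), random_target(rng, 300)
            target = TargetTranscript("t", seq)
            hier = seed_sites(guide, target, "hierarchical")
            over = seed_sites(guide, target, "overlapping")
            for cls in SITE_CLASSES:
                assert over.count("full_length", cls) >= hier.count("full_length", cls)

    def test_repeat_rich_sites_counted_at_every_offset(self):
        # guide seed complement is UUUUUU -> poly-U run of length 8 holds 3 6mers
        guide = "AAAAAAAACGUACGUACGUACG"
        sites = site_strings(guide)
        assert sites["6mer"] == "UUUUUU"
        seq = "G" * 20 + "U" * 8 + "G" * 20
        counts = [c for c, _ in seed_matches(guide, seq, "overlapping")]
        assert counts.count("6mer") == 3

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            seed_sites(GUIDE, TargetTranscript("t", "ACGU"))


class TestSeedScore:
    def test_empty_profile_scores_zero(self):
        profile = seed_sites(GUIDE, TargetTranscript("t", "A" * 50))
        assert seed_score(profile) == 0.0

    def test_unit_weights_sum_counts(self):
        transcript, _ = simulate_transcript(
            {"orf": 300},
            [PlantSpec("X", "orf", "8mer"), PlantSpec("X", "orf", "6mer"),
             PlantSpec("X", "orf", "6mer")],
            {"X": GUIDE}, rng_seed=17,
        )
        profile = seed_sites(MiRNASpec("X", GUIDE), transcript)
        assert seed_score(profile) == 3.0

    def test_weighted_hand_example(self):
        """Counts (1,0,0,2,1) with weights (4,3,2,1,0.5) -> 4 + 2 + 0.5 = 6.5."""
        profile_counts = {"full_length": {
            "8mer": 1, "7mer-m8": 0, "7mer-A1": 0, "6mer": 2, "6mer-offset": 1}}
        from mirscreen.seed_affinity import SeedMatchProfile
        profile = SeedMatchProfile("x", "hierarchical", profile_counts)
        weights = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "6mer-offset": 0.5}
        assert seed_score(profile, weights) == pytest.approx(6.5)

    def test_negative_weight_rejected(self):
        profile = seed_sites(GUIDE, TargetTranscript("t", "A" * 50))
        with pytest.raises(ValueError, match="negative weight"):
            seed_score(profile, {"6mer": -1.0})


def effects_frame(pairs: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"treatment": list(pairs), "mean_corrected": list(pairs.values())}
    )


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        effects = effects_frame({"a": 3.0, "b": 2.0, "c": 1.0, "NC1": 9.0})
        res = affinity_effect_correlation({"a": 1.0, "b": 2.0, "c": 3.0}, effects)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.n == 3

    def test_hand_computed_pearson(self):
        """Pairs (1,2), (2,4), (3,5) -> r = 3/sqrt(2 * 14/3) ~ 0.982."""
        effects = effects_frame({"a": 2.0, "b": 4.0, "c": 5.0})
        res = affinity_effect_correlation({"a": 1.0, "b": 2.0, "c": 3.0}, effects)
        assert res.pearson_r == pytest.approx(0.9819805, abs=1e-6)

    def test_controls_excluded_from_pairs(self):
        effects = effects_frame({"a": 1.0, "b": 2.0, "c": 3.0, "siRNA": 0.3, "NC1": 1.0})
        scores = {"a": 1.0, "b": 2.0, "c": 2.5, "siRNA": 99.0, "NC1": 99.0}
        assert affinity_effect_correlation(scores, effects).n == 3

    def test_constant_scores_flagged_undefined(self, caplog):
        effects = effects_frame({"a": 1.0, "b": 2.0, "c": 3.0})
        with caplog.at_level("WARNING"):
            res = affinity_effect_correlation({"a": 1.0, "b": 1.0, "c": 1.0}, effects)
        assert not res.defined
        assert "undefined" in caplog.text

    def test_too_few_pairs_rejected(self):
        effects = effects_frame({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            affinity_effect_correlation({"a": 1.0, "b": 2.0}, effects)

    def test_null_simulation_r_centered_on_zero(self):
        rng = np.random.default_rng(31)
        rs = []
        for _ in range(100):
            effects = effects_frame({f"m{i}": rng.lognormal(0, 0.1) for i in range(20)})
            scores = {f"m{i}": float(rng.integers(0, 6)) for i in range(20)}
            rs.append(affinity_effect_correlation(scores, effects).pearson_r)
        assert abs(np.mean(rs)) < 0.06
        assert np.std(rs) == pytest.approx(1 / np.sqrt(20 - 1), rel=0.35)


class TestExternalScores:
    def test_identical_scores_give_identical_correlation(self):
        effects = effects_frame({"a": 2.0, "b": 4.0, "c": 5.0})
        internal = {"a": 1.0, "b": 2.0, "c": 3.0}
        joined = attach_external_scores(pd.DataFrame(
            {"mirna": list(internal), "score": list(internal.values())}
        ), effects)
        a = affinity_effect_correlation(internal, effects)
        b = affinity_effect_correlation(joined, effects)
        assert a.pearson_r == pytest.approx(b.pearson_r)

    def test_unknown_name_warned_and_skipped(self, caplog):
        effects = effects_frame({"a": 1.0, "b": 2.0})
        with caplog.at_level("WARNING"):
            joined = attach_external_scores({"a": 1.0, "b": 2.0, "zz": 3.0}, effects)
        assert set(joined) == {"a", "b"}
        assert "zz" in caplog.text

    def test_empty_overlap_errors(self):
        effects = effects_frame({"a": 1.0})
        with pytest.raises(ValueError, match="no overlap"):
            attach_external_scores({"zz": 1.0}, effects)
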