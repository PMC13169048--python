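"""Rule-engine behaviour: ICD-10 grading, item exclusion, sensitivity mode."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dialdep.cisr import (
    ADDITIONAL_ITEMS,
    CORE_ITEMS,
    SOMATIC_CRITERIA,
    Category,
    ClassificationError,
    ImputationMode,
    PAPER_DEFAULT_RULES,
    RuleConfigError,
    RuleTable,
    SENSITIVITY_RULES,
    SymptomProfile,
    apply_sensitivity,
    classify,
    classify_cohort,
)

ITEMS = CORE_ITEMS + ADDITIONAL_ITEMS
SOMATIC = sorted(SOMATIC_CRITERIA)


def make_profile(endorsed, duration=4.0, n_somatic=0, **extra):
    return SymptomProfile(
        duration_weeks=duration,
        somatic_flags=frozenset(SOMATIC[:n_somatic]),
        **{i: True for i in endorsed},
        **extra,
    )


class TestClassify:
    def test_empty_profile_is_none(self):
        dx = classify(SymptomProfile(), PAPER_DEFAULT_RULES)
        assert dx.category is Category.none
        assert dx.total_count == 0
        assert not dx.somatic_syndrome

    def test_two_core_two_additional_is_mild(self):
        p = make_profile(
            ["depressed_mood", "loss_of_interest", "concentration", "sleep_disturbance"]
        )
        dx = classify(p, PAPER_DEFAULT_RULES)
        assert dx.category is Category.mild
        assert (dx.core_count, dx.additional_count) == (2, 2)

    def test_same_profile_shifts_band_under_imputation(self):
        # the three imputed items lift a 4-symptom mild episode to 7 symptoms
        p = make_profile(
            ["depressed_mood", "loss_of_interest", "concentration", "sleep_disturbance"]
        )
        dx = classify(p, SENSITIVITY_RULES)
        assert dx.category is Category.moderate_severe
        assert dx.total_count == 7

    @pytest.mark.parametrize(
        "duration,expected",
        [(0, Category.none), (1.9, Category.none), (2, Category.mild), (52, Category.mild)],
    )
    def test_duration_gate(self, duration, expected):
        p = make_profile(
            ["depressed_mood", "fatigue", "guilt", "concentration"], duration=duration
        )
        assert classify(p, PAPER_DEFAULT_RULES).category is expected

    def test_one_core_never_an_episode(self):
        p = make_profile(
            ["depressed_mood", "guilt", "concentration", "sleep_disturbance", "self_esteem_low"]
        )
        assert classify(p, PAPER_DEFAULT_RULES).category is Category.none

    def test_severe_subflag_needs_all_core_and_eight_symptoms(self):
        full = make_profile(list(ITEMS))  # 3 core + 6 additional = 9
        dx = classify(full, PAPER_DEFAULT_RULES)
        assert dx.category is Category.moderate_severe
        assert dx.severe_subflag
        two_core = make_profile([i for i in ITEMS if i != "fatigue"])  # total 8, core 2
        dx2 = classify(two_core, PAPER_DEFAULT_RULES)
        assert dx2.category is Category.moderate_severe
        assert not dx2.severe_subflag

    def test_somatic_syndrome_thresholds(self):
        episode = ["depressed_mood", "loss_of_interest", "guilt", "concentration"]
        assert not classify(make_profile(episode, n_somatic=2), PAPER_DEFAULT_RULES).somatic_syndrome
        assert classify(make_profile(episode, n_somatic=3), PAPER_DEFAULT_RULES).somatic_syndrome
        # somatic flags are irrelevant (reported false) without an episode
        assert not classify(make_profile([], n_somatic=5), PAPER_DEFAULT_RULES).somatic_syndrome

    def test_negative_duration_rejected(self):
        with pytest.raises(ClassificationError):
            SymptomProfile(duration_weeks=-1)

    def test_unknown_excluded_item_rejected(self):
        with pytest.raises(RuleConfigError):
            RuleTable(excluded_items=frozenset({"not_an_item"}))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(RuleConfigError):
            RuleTable(mild_total_range=(4, 6), moderate_total_range=(6, 7))


class TestExhaustiveOracle:
    def test_engine_matches_brute_force_transcription(self):
        """Every endorsement pattern x duration x somatic count agrees with
        an independent ICD-10 transcription, in both administration modes."""
        from oracles import reference_icd10

        for bits in itertools.product([False, True], repeat=9):
            endorsed = frozenset(i for i, b in zip(ITEMS, bits) if b)
            for duration in (0, 1, 2, 4):
                for n_som in range(6):
                    p = make_profile(endorsed, duration=duration, n_somatic=n_som)
                    for rules, impute in (
                        (PAPER_DEFAULT_RULES, False),
                        (SENSITIVITY_RULES, True),
                    ):
                        dx = classify(p, rules)
                        cat, som = reference_icd10(endorsed, duration, n_som, impute)
                        assert dx.category.name == cat, (endorsed, duration, rules)
                        assert dx.somatic_syndrome == som


class TestSensitivityMode:
    def test_imputes_all_excluded_items(self):
        p = SymptomProfile(depressed_mood=True)
        out = apply_sensitivity(p, SENSITIVITY_RULES)
        assert out.appetite_change and out.weight_change and out.impairment
        assert out.depressed_mood and not out.fatigue
        assert out.duration_weeks == p.duration_weeks

    def test_idempotent(self):
        p = SymptomProfile(appetite_change=True, weight_change=True, impairment=True)
        assert apply_sensitivity(p, SENSITIVITY_RULES) == p

    def test_requires_impute_mode(self):
        with pytest.raises(RuleConfigError):
            apply_sensitivity(SymptomProfile(), PAPER_DEFAULT_RULES)


# ---------------------------------------------------------------------------
# Property tests

profile_strategy = st.builds(
    make_profile,
    endorsed=st.sets(st.sampled_from(ITEMS)),
    duration=st.floats(min_value=0, max_value=60, allow_nan=False),
    n_somatic=st.integers(min_value=0, max_value=5),
)


@settings(max_examples=200, deadline=None)
@given(profile=profile_strategy, extra=st.sampled_from(ITEMS))
def test_adding_a_symptom_never_lowers_the_category(profile, extra):
    augmented = make_profile(
        {i for i in ITEMS if getattr(profile, i)} | {extra},
        duration=profile.duration_weeks,
        n_somatic=len(profile.somatic_flags),
    )
    assert (
        classify(augmented, PAPER_DEFAULT_RULES).category
        >= classify(profile, PAPER_DEFAULT_RULES).category
    )


@settings(max_examples=200, deadline=None)
@given(
    profile=profile_strategy,
    appetite=st.sampled_from([None, False, True]),
    weight=st.sampled_from([None, False, True]),
    impair=st.sampled_from([None, False, True]),
)
def test_excluded_item_values_never_influence_default_output(
    profile, appetite, weight, impair
):
    from dataclasses import replace

    modified = replace(
        profile, appetite_change=appetite, weight_change=weight, impairment=impair
    )
    assert classify(modified, PAPER_DEFAULT_RULES) == classify(profile, PAPER_DEFAULT_RULES)


@settings(max_examples=100, deadline=None)
@given(profiles=st.lists(profile_strategy, min_size=1, max_size=20))
def test_sensitivity_never_lowers_any_participant(profiles):
    base = classify_cohort(profiles, PAPER_DEFAULT_RULES)
    sens = classify_cohort(profiles, SENSITIVITY_RULES)
    for b, s in zip(base, sens):
        assert s.category >= b.category


def test_cohort_errors_carry_participant_index():
    profiles = [SymptomProfile(), SymptomProfile()]
    with pytest.raises(ClassificationError):
        classify_cohort([], PAPER_DEFAULT_RULES)
    out = classify_cohort(profiles, PAPER_DEFAULT_RULES)
    assert [d.category for d in out] == [Category.none, Category.none]


def test_rule_table_yaml_round_trip(tmp_path):
    import yaml

    path = tmp_path / "rules.yaml"
    path.write_text(yaml.safe_dump(SENSITIVITY_RULES.to_dict()))
    loaded = RuleTable.from_yaml(path)
    assert loaded == SENSITIVITY_RULES
    assert loaded.imputation_mode is ImputationMode.impute_present


def test_shipped_presets_load():
    from importlib import resources

    base = resources.files("dialdep") / "rules"
    assert RuleTable.from_yaml(str(base / "paper_default.yaml")) == PAPER_DEFAULT_RULES
    assert RuleTable.from_yaml(str(base / "sensitivity.yaml")) == SENSITIVITY_RULES
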