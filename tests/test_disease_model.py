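"""State space, transition matrices and per-cycle rewards."""

import numpy as np
import pytest

from pdrcea.disease_model import (
    ANTIVEGF,
    DEAD,
    DME,
    INITIAL_STATE,
    NPDR,
    PDR,
    PRP,
    SECOND,
    SVL,
    STRATEGIES,
    State,
    age_adjusted_utility,
    build_state_space,
    cycle_rewards,
    pdr_treatment_probs,
    transition_matrix,
    utility_vector,
)
from pdrcea.life_table import gompertz_life_table
from pdrcea.params import sample_parameter_set


def _frozen_disease(params):
    """Parameters under which nothing progresses and nobody is treated."""
    return params.with_values(
        p_loss_followup=1.0, p_pdr_to_svl=0.0, p_pdr_to_dme=0.0,
        p_npdr_to_dme=0.0, p_recur_after_prp=0.0, p_dme_success=0.0,
        p_endoph_per_injection=0.0,
    )


class TestStateSpace:
    def test_single_line_strategies_never_reach_second_line(self):
        for name in ("prp-only", "antivegf-only"):
            assert all(s.line != SECOND for s in build_state_space(name))

    def test_antivegf_only_never_administers_prp(self):
        space = build_state_space("antivegf-only")
        assert all(not s.ever_prp for s in space)
        assert all(s.last_tx != PRP for s in space)

    def test_six_svl_tenure_variants_per_pvfd_flag(self):
        # tunnel states: exactly one SVL state per tenure year and reachable
        # pVFD flag value
        for name, space in ((n, build_state_space(n)) for n in STRATEGIES):
            flags = {s.ever_prp for s in space if s.clinical == SVL}
            svl = [(s.svl_tenure, s.ever_prp) for s in space if s.clinical == SVL]
            assert len(svl) == len(set(svl)) == 6 * len(flags), name
            assert {t for t, _ in svl} == {1, 2, 3, 4, 5, 6}

    def test_attribute_consistency(self):
        for name in STRATEGIES:
            for s in build_state_space(name):
                assert (s.dme_origin is not None) == (s.clinical == DME)
                assert (s.svl_tenure is not None) == (s.clinical == SVL)

    def test_deterministic_ordering_with_dead_last(self):
        a = build_state_space("prp-first")
        b = build_state_space("prp-first")
        assert a == b
        assert a[-1].clinical == DEAD


class TestTreatmentProbs:
    def test_prp_uses_published_values(self, base_params):
        assert pdr_treatment_probs(PRP, base_params) == (0.2008, 0.0169)

    def test_antivegf_scales_by_relative_risks(self, base_params):
        s, r = pdr_treatment_probs(ANTIVEGF, base_params)
        assert s == pytest.approx(0.3514)
        assert r == pytest.approx(0.019435)

    def test_unit_relative_risks_equalise_therapies(self, base_params):
        ps = base_params.with_values(rr_antivegf_effect=1.0, rr_antivegf_recur=1.0)
        assert pdr_treatment_probs(ANTIVEGF, ps) == pdr_treatment_probs(PRP, ps)


class TestTransitionMatrix:
    def test_rows_sum_to_one_all_strategies_all_ages(self, base_params, life_table):
        for name in STRATEGIES:
            space = build_state_space(name)
            for age in (50, 65, 80, 99):
                m = transition_matrix(name, age, base_params, life_table, space)
                assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(m >= 0)

    def test_dead_row_is_absorbing(self, base_params, life_table):
        space = build_state_space("prp-only")
        m = transition_matrix("prp-only", 60, base_params, life_table, space)
        i = space.index(State(DEAD))
        expected = np.zeros(len(space))
        expected[i] = 1.0
        assert np.array_equal(m[i], expected)

    def test_hand_computed_pdr_cure_mass(self, base_params, life_table):
        """From the entry PDR state under PRP-only, the mass reaching NPDR
        equals survivors x treated fraction x PRP success."""
        space = build_state_space("prp-only")
        m = transition_matrix("prp-only", 50, base_params, life_table, space)
        i = space.index(INITIAL_STATE)
        j = space.index(State(NPDR, "first", PRP, True))
        q = min(1.0, life_table.q(50) * 1.49)
        assert m[i, j] == pytest.approx((1 - q) * 0.8 * 0.2008, rel=1e-12)

    def test_frozen_disease_is_identity_up_to_tenure_clock(
        self, base_params, zero_mortality_table
    ):
        """With all transition probabilities zero and no mortality, every row
        is an identity row except the SVL tenure clock, which still
        advances."""
        ps = _frozen_disease(base_params)
        for name in STRATEGIES:
            space = build_state_space(name)
            m = transition_matrix(name, 70, ps, zero_mortality_table, space)
            for i, s in enumerate(space):
                if s.clinical == SVL and s.svl_tenure < 6:
                    j = space.index(
                        State(SVL, ever_prp=s.ever_prp, svl_tenure=s.svl_tenure + 1)
                    )
                else:
                    j = i
                assert m[i, j] == pytest.approx(1.0)

    def test_row_stochastic_over_random_parameter_draws(
        self, base_params, life_table
    ):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = sample_parameter_set(base_params, rng)
            for name in STRATEGIES:
                m = transition_matrix(name, 62, ps, life_table)
                assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_inconsistent_overrides_raise(self, base_params, life_table):
        bad = base_params.with_values(p_pdr_to_svl=0.9, p_pdr_to_dme=0.9)
        with pytest.raises(ValueError):
            transition_matrix("prp-only", 60, bad, life_table)


class TestUtility:
    def test_published_endpoints_and_interpolation(self, base_params):
        assert age_adjusted_utility(NPDR, 50, base_params) == pytest.approx(0.904)
        assert age_adjusted_utility(NPDR, 100, base_params) == pytest.approx(0.849)
        assert age_adjusted_utility(NPDR, 75, base_params) == pytest.approx(0.8765)

    def test_anchor_censored_at_one(self, base_params):
        ps = base_params.with_values(u_dme=1.0)
        assert age_adjusted_utility(DME, 50, ps) == 1.0

    def test_dead_utility_is_zero(self, base_params):
        assert age_adjusted_utility(DEAD, 70, base_params) == 0.0

    def test_pvfd_disutility_applies_to_prp_exposed(self, base_params):
        space = build_state_space("prp-only")
        u = utility_vector(space, 50, base_params)
        i = space.index(State(NPDR, "first", PRP, True))
        assert u[i] == pytest.approx(0.904 - 0.01)


class TestCycleRewards:
    def test_npdr_healthcare_cost_matches_published(self, base_params):
        space = build_state_space("prp-only")
        rew = cycle_rewards("prp-only", 50, base_params, space)
        i = space.index(State(NPDR, "first", PRP, True))
        assert rew.cost("healthcare")[i] == pytest.approx(160 + 12)
        assert rew.cost("payer")[i] == pytest.approx(160)
        assert rew.cost("societal")[i] == pytest.approx(160 + 12 + 4 + 82)

    def test_svl_care_cost_capped_at_age_90(self, base_params):
        space = build_state_space("prp-only")
        i = space.index(State(SVL, ever_prp=False, svl_tenure=3))
        young = cycle_rewards("prp-only", 89, base_params, space)
        old = cycle_rewards("prp-only", 91, base_params, space)
        assert young.components["care"][i] == 11826.0
        assert old.components["care"][i] == 0.0
        # continuation scales only the injection components
        assert young.components["covered"][i] == pytest.approx(
            338 + 2 * 0.65 * (447 + 0.0006 * 2143)
        )

    def test_pdr_prp_bills_one_episode_for_treated_fraction(self, base_params):
        space = build_state_space("prp-only")
        rew = cycle_rewards("prp-only", 50, base_params, space)
        i = space.index(INITIAL_STATE)
        assert rew.cost("payer")[i] == pytest.approx(348 + 0.8 * 188)

    def test_pdr_antivegf_loading_dose_not_payer_covered(self, base_params):
        """Three injections per treated PDR year; the injection bill is
        non-covered for this indication, so only the state cost and the
        (covered) expected endophthalmitis care reach the payer."""
        space = build_state_space("antivegf-only")
        rew = cycle_rewards("antivegf-only", 50, base_params, space)
        i = space.index(INITIAL_STATE)
        n_inj = 0.8 * 3
        assert rew.cost("payer")[i] == pytest.approx(348 + n_inj * 0.0006 * 2143)
        assert rew.cost("healthcare")[i] == pytest.approx(
            348 + 44 + n_inj * (447 + 63) + n_inj * 0.0006 * (2143 + 1208)
        )

    def test_dme_injections_keep_covered_split(self, base_params):
        space = build_state_space("antivegf-only")
        rew = cycle_rewards("antivegf-only", 50, base_params, space)
        i = space.index(State(DME, "first", ANTIVEGF, False, dme_origin=NPDR))
        assert rew.cost("payer")[i] == pytest.approx(
            1732 + 3 * 447 + 3 * 0.0006 * 2143
        )

    def test_all_components_non_negative(self, base_params):
        for name in STRATEGIES:
            rew = cycle_rewards(name, 70, base_params)
            for arr in rew.components.values():
                assert np.all(arr >= 0)
            assert np.all((rew.utility >= 0) & (rew.utility <= 1))


def test_svl_occupancy_monotone_in_progression_risk(base_params, life_table):
    """Raising the PDR->SVL hazard never decreases lifetime SVL occupancy
    (checked through the cohort engine on random parameter sets)."""
    from pdrcea.cohort import run_cohort

    rng = np.random.default_rng(17)
    for _ in range(10):
        ps = sample_parameter_set(base_params, rng)
        hi = ps.with_values(p_pdr_to_svl=min(1.0, ps.p_pdr_to_svl * 1.2))
        space = build_state_space("prp-only")
        svl_cols = [s.label for s in space if s.clinical == SVL]
        lo_occ = run_cohort("prp-only", ps, life_table)[0][svl_cols].to_numpy().sum()
        hi_occ = run_cohort("prp-only", hi, life_table)[0][svl_cols].to_numpy().sum()
        assert hi_occ >= lo_occ - 1e-12
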