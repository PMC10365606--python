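"""The built-in home-care causal loop model and its intervention scenarios.

This module constructs, in code, the published core of a qualitative
systems model of home care for older adults: the demand–control work
stress engine, the home care staff cluster around workload, coping and
burnout, the home care user cluster around needs met and adverse events,
the provider organization (leadership, cost pressure, deskilling,
technology), the user's social support network, and a handful of
societal-level drivers.  It is a faithful, reviewed subset of the full
published model (122 elements / 223 connections) restricted to the
elements and connections named in the study's main narrative.

Sign provenance is tracked per connection through ``evidence_refs``:

``reported``
    The direction of the effect is stated in the source narrative
    ("increased", "led to a reduction", "positive effect", ...).
``derived``
    The connection (or only its sign) is not stated explicitly; the value
    used here is the minimal assignment that reproduces every stated
    feedback-loop polarity and every stated simulation outcome.  Each
    such edge carries an inline comment saying which stated behaviour
    requires it.

The five scenarios returned by :func:`fixture_scenarios` encode the
published what-if activations (person-centred care, workload, technology
adoption, distress) and the staff-training/supervision verification case,
together with their expected signed outcomes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model import CLDModel, ElementNode, SignedConnection, assert_valid
from .simulate import Scenario

_REPORTED = ("reported",)
_DERIVED = ("derived",)

# (id, label, category)
_STRESS_ELEMENTS = [
    ("job_demand", "Job demand"),
    ("control", "Control"),
    ("overload", "Work overload"),
    ("underload", "Work underload"),
    ("distress", "Distress"),
    ("ability_to_cope", "Ability to cope"),
]

# The demand-control engine.  Demand and control drive work overload and
# underload in exactly opposite directions (the linear stand-in for the
# U-shaped demand-control interaction), both of which feed distress, and
# distress erodes the ability to cope, which sustains control.
_STRESS_EDGES = [
    ("job_demand", "overload", +1, _REPORTED),
    ("control", "overload", -1, _REPORTED),
    ("control", "underload", +1, _REPORTED),
    ("job_demand", "underload", -1, _REPORTED),
    ("overload", "distress", +1, _REPORTED),
    ("underload", "distress", +1, _REPORTED),
    ("ability_to_cope", "control", +1, _REPORTED),
    # Feedback of the stress response onto coping; direction derived
    # (distress must erode coping for the overload loop to reinforce).
    ("distress", "ability_to_cope", -1, _DERIVED),
]


def build_stress_core() -> CLDModel:
    """The six-element demand-control stress engine as a standalone model."""
    elements = [ElementNode(i, lbl, "stress") for i, lbl in _STRESS_ELEMENTS]
    connections = [SignedConnection(s, t, p, refs)
                   for s, t, p, refs in _STRESS_EDGES]
    return assert_valid(CLDModel(elements, connections, name="stress_core"))


_STAFF = "home_care_staff"
_USER = "home_care_user"
_ORG = "organization"
_SOCIAL = "social_support"
_SOCIETAL = "societal"

_FIXTURE_ELEMENTS: list[tuple[str, str, str]] = [
    *[(i, lbl, "stress") for i, lbl in _STRESS_ELEMENTS],
    # home care staff
    ("learning_demands", "Learning demands", _STAFF),
    ("decision_demands", "Decision demands", _STAFF),
    ("quantitative_demands", "Quantitative demands", _STAFF),
    ("complexity_of_work_tasks", "Complexity of work tasks", _STAFF),
    ("workload", "Workload", _STAFF),
    ("work_pace", "Work pace", _STAFF),
    ("mastery_of_work", "Mastery of work and professional competence", _STAFF),
    ("job_involvement", "Job involvement", _STAFF),
    ("job_satisfaction", "Job satisfaction", _STAFF),
    ("recovery", "Recovery", _STAFF),
    ("social_support_staff", "Home care staff social support", _STAFF),
    ("personal_life_demands", "Personal life demands", _STAFF),
    ("shift_work", "Shift work", _STAFF),
    ("overtime_unscheduled_work", "Overtime and unscheduled work", _STAFF),
    ("work_life_balance", "Work-life balance", _STAFF),
    ("health_safety_risk", "Home care staff health and safety risk", _STAFF),
    ("stress_of_conscience", "Stress of conscience", _STAFF),
    ("physio_mental_health_response",
     "Physiological and mental health response", _STAFF),
    ("burnout", "Burnout", _STAFF),
    ("provision_of_care_and_services", "Provision of care and services", _STAFF),
    ("continuity", "Continuity", _STAFF),
    ("suitability", "Suitability", _STAFF),
    ("availability", "Availability", _STAFF),
    ("personal_relation", "Personal relation", _STAFF),
    ("confirming_communication",
     "Confirming home care staff-user relationship and family communication",
     _STAFF),
    ("language_proficiency", "Language proficiency", _STAFF),
    ("training_and_specialization", "Training and specialization", _STAFF),
    ("quality_of_care", "Quality of care", _STAFF),
    ("job_turnover", "Job turnover", _STAFF),
    # home care user
    ("user_influence", "Home care user influence", _USER),
    ("trust_in_home_care_staff", "Trust in home care staff", _USER),
    ("ability_to_communicate", "Ability to communicate", _USER),
    ("adl_needs", "Activities of daily living needs", _USER),
    ("social_needs", "Social needs", _USER),
    ("emotional_needs", "Emotional needs", _USER),
    ("informational_needs", "Informational needs", _USER),
    ("treatment_needs", "Treatment needs", _USER),
    ("self_sufficiency_needs", "Self-sufficiency needs", _USER),
    ("needs_met", "Needs met", _USER),
    ("satisfaction_with_care", "Satisfaction with care", _USER),
    ("self_perceived_health", "Self-perceived health", _USER),
    ("quality_of_life_user", "Home care user quality of life", _USER),
    ("adverse_events_progression",
     "Adverse events or progression of disease", _USER),
    ("need_for_care", "Need for care", _USER),
    ("likelihood_institutional_care", "Likelihood of institutional care", _USER),
    ("time_spent_in_care", "Time spent in care", _USER),
    ("functional_ability_autonomy", "Functional ability and autonomy", _USER),
    # organization
    ("role_conflict", "Role conflict", _ORG),
    ("recognition", "Recognition", _ORG),
    ("quality_of_supervision", "Quality of supervision", _ORG),
    ("empowering_leadership", "Empowering leadership", _ORG),
    ("human_resource_primacy", "Human resource primacy", _ORG),
    ("commitment_to_organization", "Commitment to the organization", _ORG),
    ("emphasis_cost_effectiveness", "Emphasis on cost-effectiveness", _ORG),
    ("inadequate_income", "Inadequate income", _ORG),
    ("deskilling", "Deskilling", _ORG),
    ("working_with_sophisticated_technology",
     "Working with sophisticated technology", _ORG),
    ("equipment_problems", "Equipment problems", _ORG),
    ("support_from_superior", "Support from superior", _ORG),
    ("person_centered_care", "Person-centered care", _ORG),
    ("adoption_of_technology",
     "Home care staff-user adoption of technology", _ORG),
    # social support network of the home care user
    ("social_support_network",
     "Social support network of the home care user", _SOCIAL),
    ("qol_informal_caregiver",
     "Quality of life of the informal caregiver", _SOCIAL),
    ("delivery_informal_care", "Delivery of informal care", _SOCIAL),
    ("informal_caregiver_stress", "Informal caregiver stress", _SOCIAL),
    # societal level
    ("county_unemployment", "County unemployment", _SOCIETAL),
    ("care_capacity", "Care capacity", _SOCIETAL),
    ("capital_income", "Capital income", _SOCIETAL),
    ("stigmatization_toward_profession",
     "Stigmatization toward the profession", _SOCIETAL),
    ("health_care_spending", "Health care spending", _SOCIETAL),
]

_FIXTURE_EDGES: list[tuple[str, str, int, tuple[str, ...]]] = [
    *_STRESS_EDGES,
    # --- demand cluster: what feeds job demand ---
    ("learning_demands", "job_demand", +1, _REPORTED),
    ("decision_demands", "job_demand", +1, _REPORTED),
    ("quantitative_demands", "job_demand", +1, _REPORTED),
    # Wiring of the named demand drivers onto the three demand types is
    # not spelled out; assignments chosen to reproduce the workload
    # activation outcomes (demand elements rise, provision falls).
    ("complexity_of_work_tasks", "learning_demands", +1, _DERIVED),
    ("complexity_of_work_tasks", "decision_demands", +1, _DERIVED),
    ("workload", "quantitative_demands", +1, _DERIVED),
    ("work_pace", "quantitative_demands", +1, _DERIVED),
    ("workload", "work_pace", +1, _DERIVED),
    ("workload", "decision_demands", +1, _DERIVED),
    ("workload", "role_conflict", +1, _DERIVED),
    ("workload", "provision_of_care_and_services", -1, _DERIVED),
    # --- coping cluster: what sustains or erodes the ability to cope ---
    ("mastery_of_work", "ability_to_cope", +1, _DERIVED),
    ("job_involvement", "ability_to_cope", +1, _DERIVED),
    ("job_satisfaction", "ability_to_cope", +1, _DERIVED),
    ("recovery", "ability_to_cope", +1, _REPORTED),
    ("social_support_staff", "recovery", +1, _REPORTED),
    ("personal_life_demands", "recovery", -1, _DERIVED),
    ("shift_work", "recovery", -1, _DERIVED),
    ("overtime_unscheduled_work", "recovery", -1, _DERIVED),
    ("work_life_balance", "recovery", +1, _DERIVED),
    ("health_safety_risk", "ability_to_cope", -1, _DERIVED),
    ("stress_of_conscience", "ability_to_cope", -1, _DERIVED),
    # --- health cluster: stress response, burnout and their downstream ---
    ("distress", "physio_mental_health_response", +1, _REPORTED),
    ("physio_mental_health_response", "burnout", +1, _REPORTED),
    # Required by the distress activation outcomes: health risk rises,
    # involvement and quality of care fall.
    ("distress", "health_safety_risk", +1, _DERIVED),
    ("burnout", "job_involvement", -1, _DERIVED),
    ("burnout", "quality_of_care", -1, _DERIVED),
    # --- organization cluster ---
    ("role_conflict", "job_satisfaction", -1, _DERIVED),
    ("recognition", "job_satisfaction", +1, _REPORTED),
    ("recognition", "job_involvement", +1, _REPORTED),
    ("quality_of_supervision", "empowering_leadership", +1, _REPORTED),
    ("quality_of_supervision", "human_resource_primacy", +1, _REPORTED),
    ("quality_of_supervision", "commitment_to_organization", +1, _REPORTED),
    ("empowering_leadership", "recognition", +1, _REPORTED),
    ("human_resource_primacy", "recognition", +1, _REPORTED),
    ("commitment_to_organization", "recognition", +1, _REPORTED),
    ("emphasis_cost_effectiveness", "inadequate_income", +1, _REPORTED),
    ("emphasis_cost_effectiveness", "deskilling", +1, _REPORTED),
    ("deskilling", "job_satisfaction", -1, _REPORTED),
    ("deskilling", "training_and_specialization", -1, _REPORTED),
    ("deskilling", "mastery_of_work", -1, _REPORTED),
    ("deskilling", "trust_in_home_care_staff", -1, _DERIVED),
    ("deskilling", "complexity_of_work_tasks", -1, _DERIVED),
    ("deskilling", "distress", +1, _DERIVED),
    ("working_with_sophisticated_technology",
     "complexity_of_work_tasks", +1, _REPORTED),
    ("working_with_sophisticated_technology", "workload", +1, _REPORTED),
    ("equipment_problems", "complexity_of_work_tasks", +1, _REPORTED),
    ("equipment_problems", "workload", +1, _REPORTED),
    ("support_from_superior", "job_satisfaction", +1, _REPORTED),
    # --- provision of care and its balancing feedback with needs met ---
    ("continuity", "provision_of_care_and_services", +1, _REPORTED),
    ("suitability", "provision_of_care_and_services", +1, _REPORTED),
    ("availability", "provision_of_care_and_services", +1, _REPORTED),
    ("personal_relation", "provision_of_care_and_services", +1, _REPORTED),
    ("user_influence", "provision_of_care_and_services", +1, _REPORTED),
    ("mastery_of_work", "provision_of_care_and_services", +1, _REPORTED),
    # Closes the first balancing loop (provision raises needs met, which
    # relaxes demand for provision).
    ("provision_of_care_and_services", "needs_met", +1, _DERIVED),
    ("needs_met", "provision_of_care_and_services", -1, _REPORTED),
    ("needs_met", "stress_of_conscience", -1, _REPORTED),
    # Closes the second balancing loop through stress of conscience: unmet
    # needs weigh on staff conscience, which pushes provision back up.
    ("stress_of_conscience", "provision_of_care_and_services", +1, _DERIVED),
    ("provision_of_care_and_services", "quality_of_care", +1, _DERIVED),
    # --- communication cluster ---
    ("ability_to_communicate", "confirming_communication", +1, _REPORTED),
    ("mastery_of_work", "confirming_communication", +1, _REPORTED),
    ("language_proficiency", "confirming_communication", +1, _REPORTED),
    ("confirming_communication", "user_influence", +1, _REPORTED),
    ("confirming_communication", "trust_in_home_care_staff", +1, _REPORTED),
    ("confirming_communication", "functional_ability_autonomy", +1, _REPORTED),
    ("training_and_specialization", "confirming_communication", +1, _REPORTED),
    ("training_and_specialization", "mastery_of_work", +1, _DERIVED),
    # --- home care user cluster ---
    # Need elements lower "needs met" at a given level of provision; signs
    # are not stated in the narrative.
    ("adl_needs", "needs_met", -1, _DERIVED),
    ("social_needs", "needs_met", -1, _DERIVED),
    ("emotional_needs", "needs_met", -1, _DERIVED),
    ("informational_needs", "needs_met", -1, _DERIVED),
    ("treatment_needs", "needs_met", -1, _DERIVED),
    ("self_sufficiency_needs", "needs_met", -1, _DERIVED),
    ("needs_met", "satisfaction_with_care", +1, _REPORTED),
    ("needs_met", "self_perceived_health", +1, _REPORTED),
    ("needs_met", "quality_of_life_user", +1, _REPORTED),
    ("needs_met", "adverse_events_progression", -1, _REPORTED),
    ("adverse_events_progression", "need_for_care", +1, _REPORTED),
    # Closes the stated reinforcing loop: growing need for care makes
    # needs harder to meet.
    ("need_for_care", "needs_met", -1, _DERIVED),
    ("adverse_events_progression", "likelihood_institutional_care", +1,
     _REPORTED),
    ("time_spent_in_care", "likelihood_institutional_care", +1, _REPORTED),
    ("likelihood_institutional_care", "health_care_spending", +1, _REPORTED),
    ("functional_ability_autonomy", "need_for_care", -1, _DERIVED),
    # --- reablement / technology cluster ---
    ("person_centered_care", "provision_of_care_and_services", +1, _REPORTED),
    ("person_centered_care", "trust_in_home_care_staff", +1, _REPORTED),
    ("person_centered_care", "health_safety_risk", -1, _REPORTED),
    # Reablement by definition enhances functioning and independence.
    ("person_centered_care", "functional_ability_autonomy", +1, _DERIVED),
    ("adoption_of_technology", "complexity_of_work_tasks", +1, _REPORTED),
    ("adoption_of_technology", "person_centered_care", +1, _REPORTED),
    ("adoption_of_technology", "equipment_problems", +1, _DERIVED),
    # --- social support cluster ---
    ("social_support_network", "delivery_informal_care", +1, _REPORTED),
    ("qol_informal_caregiver", "delivery_informal_care", +1, _REPORTED),
    ("delivery_informal_care", "needs_met", +1, _REPORTED),
    ("needs_met", "informal_caregiver_stress", -1, _REPORTED),
    ("needs_met", "qol_informal_caregiver", +1, _REPORTED),
    # --- societal cluster: labour-market drivers of turnover ---
    ("care_capacity", "job_turnover", +1, _DERIVED),
    ("capital_income", "job_turnover", +1, _DERIVED),
    ("stigmatization_toward_profession", "job_turnover", +1, _DERIVED),
    ("county_unemployment", "job_turnover", -1, _DERIVED),
]


def build_homecare_fixture() -> CLDModel:
    """The full built-in home-care CLD (stress core plus all named clusters)."""
    elements = [ElementNode(i, lbl, cat) for i, lbl, cat in _FIXTURE_ELEMENTS]
    connections = [SignedConnection(s, t, p, refs)
                   for s, t, p, refs in _FIXTURE_EDGES]
    return assert_valid(CLDModel(
        elements, connections, name="homecare_fixture",
        metadata={"scope": "named-elements subset of the full home-care model"},
    ))


def fixture_scenarios() -> list[Scenario]:
    """The five curated intervention scenarios with expected signed outcomes."""
    return [
        Scenario(
            name="person_centered_care_activation",
            activations={"person_centered_care": +1},
            expected_outcomes={
                "trust_in_home_care_staff": +1,
                "provision_of_care_and_services": +1,
                "needs_met": +1,
                "health_safety_risk": -1,
                "functional_ability_autonomy": +1,
                "quality_of_life_user": +1,
            },
            notes=("Reablement: activates delivery and quality of care, "
                   "improves user quality of life, reduces staff health and "
                   "safety risks."),
        ),
        Scenario(
            name="workload_activation",
            activations={"workload": +1},
            expected_outcomes={
                "quantitative_demands": +1,
                "decision_demands": +1,
                "work_pace": +1,
                "role_conflict": +1,
                "provision_of_care_and_services": -1,
                "needs_met": -1,
                "job_satisfaction": -1,
                "distress": 0,
            },
            notes=("Demand elements rise and provision falls; distress stays "
                   "unmodulated because the equal-weight scheme cancels the "
                   "overload and underload channels."),
        ),
        Scenario(
            name="adoption_of_technology_activation",
            activations={"adoption_of_technology": +1},
            expected_outcomes={
                "complexity_of_work_tasks": +1,
                "person_centered_care": +1,
                "equipment_problems": +1,
            },
            notes=("Technology adoption supports person-centred care but "
                   "raises task complexity and equipment problems."),
        ),
        Scenario(
            name="distress_activation",
            activations={"distress": +1},
            expected_outcomes={
                "physio_mental_health_response": +1,
                "burnout": +1,
                "health_safety_risk": +1,
                "job_involvement": -1,
                "quality_of_care": -1,
            },
            notes=("Distress degrades staff health (risk and burnout rise), "
                   "job involvement and quality of care."),
        ),
        Scenario(
            name="training_and_supervision",
            activations={
                "training_and_specialization": +1,
                "support_from_superior": +1,
            },
            expected_outcomes={
                "confirming_communication": +1,
                "functional_ability_autonomy": +1,
                "job_satisfaction": +1,
            },
            notes=("Staff training improves the confirming staff-user "
                   "relationship and, through it, user functional ability; "
                   "supervisor support improves job satisfaction."),
        ),
    ]


def fixture_data_dir() -> Path:
    """Directory of the shipped elements.csv/connections.csv pair."""
    return Path(resources.files("carecld") / "data" / "fixture")


def scenario_data_dir() -> Path:
    """Directory of the shipped scenario YAML files."""
    return Path(resources.files("carecld") / "data" / "scenarios")
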