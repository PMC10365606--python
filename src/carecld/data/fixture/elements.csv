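id,label,category,description,evidence_refs
job_demand,Job demand,stress,,
control,Control,stress,,
overload,Work overload,stress,,
underload,Work underload,stress,,
distress,Distress,stress,,
ability_to_cope,Ability to cope,stress,,
learning_demands,Learning demands,home_care_staff,,
decision_demands,Decision demands,home_care_staff,,
quantitative_demands,Quantitative demands,home_care_staff,,
complexity_of_work_tasks,Complexity of work tasks,home_care_staff,,
workload,Workload,home_care_staff,,
work_pace,Work pace,home_care_staff,,
mastery_of_work,Mastery of work and professional competence,home_care_staff,,
job_involvement,Job involvement,home_care_staff,,
job_satisfaction,Job satisfaction,home_care_staff,,
recovery,Recovery,home_care_staff,,
social_support_staff,Home care staff social support,home_care_staff,,
personal_life_demands,Personal life demands,home_care_staff,,
shift_work,Shift work,home_care_staff,,
overtime_unscheduled_work,Overtime and unscheduled work,home_care_staff,,
work_life_balance,Work-life balance,home_care_staff,,
health_safety_risk,Home care staff health and safety risk,home_care_staff,,
stress_of_conscience,Stress of conscience,home_care_staff,,
physio_mental_health_response,Physiological and mental health response,home_care_staff,,
burnout,Burnout,home_care_staff,,
provision_of_care_and_services,Provision of care and services,home_care_staff,,
continuity,Continuity,home_care_staff,,
suitability,Suitability,home_care_staff,,
availability,Availability,home_care_staff,,
personal_relation,Personal relation,home_care_staff,,
confirming_communication,Confirming home care staff-user relationship and family communication,home_care_staff,,
language_proficiency,Language proficiency,home_care_staff,,
training_and_specialization,Training and specialization,home_care_staff,,
quality_of_care,Quality of care,home_care_staff,,
job_turnover,Job turnover,home_care_staff,,
user_influence,Home care user influence,home_care_user,,
trust_in_home_care_staff,Trust in home care staff,home_care_user,,
ability_to_communicate,Ability to communicate,home_care_user,,
adl_needs,Activities of daily living needs,home_care_user,,
social_needs,Social needs,home_care_user,,
emotional_needs,Emotional needs,home_care_user,,
informational_needs,Informational needs,home_care_user,,
treatment_needs,Treatment needs,home_care_user,,
self_sufficiency_needs,Self-sufficiency needs,home_care_user,,
needs_met,Needs met,home_care_user,,
satisfaction_with_care,Satisfaction with care,home_care_user,,
self_perceived_health,Self-perceived health,home_care_user,,
quality_of_life_user,Home care user quality of life,home_care_user,,
adverse_events_progression,Adverse events or progression of disease,home_care_user,,
need_for_care,Need for care,home_care_user,,
likelihood_institutional_care,Likelihood of institutional care,home_care_user,,
time_spent_in_care,Time spent in care,home_care_user,,
functional_ability_autonomy,Functional ability and autonomy,home_care_user,,
role_conflict,Role conflict,organization,,
recognition,Recognition,organization,,
quality_of_supervision,Quality of supervision,organization,,
empowering_leadership,Empowering leadership,organization,,
human_resource_primacy,Human resource primacy,organization,,
commitment_to_organization,Commitment to the organization,organization,,
emphasis_cost_effectiveness,Emphasis on cost-effectiveness,organization,,
inadequate_income,Inadequate income,organization,,
deskilling,Deskilling,organization,,
working_with_sophisticated_technology,Working with sophisticated technology,organization,,
equipment_problems,Equipment problems,organization,,
support_from_superior,Support from superior,organization,,
person_centered_care,Person-centered care,organization,,
adoption_of_technology,Home care staff-user adoption of technology,organization,,
social_support_network,Social support network of the home care user,social_support,,
qol_informal_caregiver,Quality of life of the informal caregiver,social_support,,
delivery_informal_care,Delivery of informal care,social_support,,
informal_caregiver_stress,Informal caregiver stress,social_support,,
county_unemployment,County unemployment,societal,,
care_capacity,Care capacity,societal,,
capital_income,Capital income,societal,,
stigmatization_toward_profession,Stigmatization toward the profession,societal,,
health_care_spending,Health care spending,societal,,
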