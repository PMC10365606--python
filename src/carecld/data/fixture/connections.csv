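source,target,polarity,evidence_refs
job_demand,overload,+1,reported
control,overload,-1,reported
control,underload,+1,reported
job_demand,underload,-1,reported
overload,distress,+1,reported
underload,distress,+1,reported
ability_to_cope,control,+1,reported
distress,ability_to_cope,-1,derived
learning_demands,job_demand,+1,reported
decision_demands,job_demand,+1,reported
quantitative_demands,job_demand,+1,reported
complexity_of_work_tasks,learning_demands,+1,derived
complexity_of_work_tasks,decision_demands,+1,derived
workload,quantitative_demands,+1,derived
work_pace,quantitative_demands,+1,derived
workload,work_pace,+1,derived
workload,decision_demands,+1,derived
workload,role_conflict,+1,derived
workload,provision_of_care_and_services,-1,derived
mastery_of_work,ability_to_cope,+1,derived
job_involvement,ability_to_cope,+1,derived
job_satisfaction,ability_to_cope,+1,derived
recovery,ability_to_cope,+1,reported
social_support_staff,recovery,+1,reported
personal_life_demands,recovery,-1,derived
shift_work,recovery,-1,derived
overtime_unscheduled_work,recovery,-1,derived
work_life_balance,recovery,+1,derived
health_safety_risk,ability_to_cope,-1,derived
stress_of_conscience,ability_to_cope,-1,derived
distress,physio_mental_health_response,+1,reported
physio_mental_health_response,burnout,+1,reported
distress,health_safety_risk,+1,derived
burnout,job_involvement,-1,derived
burnout,quality_of_care,-1,derived
role_conflict,job_satisfaction,-1,derived
recognition,job_satisfaction,+1,reported
recognition,job_involvement,+1,reported
quality_of_supervision,empowering_leadership,+1,reported
quality_of_supervision,human_resource_primacy,+1,reported
quality_of_supervision,commitment_to_organization,+1,reported
empowering_leadership,recognition,+1,reported
human_resource_primacy,recognition,+1,reported
commitment_to_organization,recognition,+1,reported
emphasis_cost_effectiveness,inadequate_income,+1,reported
emphasis_cost_effectiveness,deskilling,+1,reported
deskilling,job_satisfaction,-1,reported
deskilling,training_and_specialization,-1,reported
deskilling,mastery_of_work,-1,reported
deskilling,trust_in_home_care_staff,-1,derived
deskilling,complexity_of_work_tasks,-1,derived
deskilling,distress,+1,derived
working_with_sophisticated_technology,complexity_of_work_tasks,+1,reported
working_with_sophisticated_technology,workload,+1,reported
equipment_problems,complexity_of_work_tasks,+1,reported
equipment_problems,workload,+1,reported
support_from_superior,job_satisfaction,+1,reported
continuity,provision_of_care_and_services,+1,reported
suitability,provision_of_care_and_services,+1,reported
availability,provision_of_care_and_services,+1,reported
personal_relation,provision_of_care_and_services,+1,reported
user_influence,provision_of_care_and_services,+1,reported
mastery_of_work,provision_of_care_and_services,+1,reported
provision_of_care_and_services,needs_met,+1,derived
needs_met,provision_of_care_and_services,-1,reported
needs_met,stress_of_conscience,-1,reported
stress_of_conscience,provision_of_care_and_services,+1,derived
provision_of_care_and_services,quality_of_care,+1,derived
ability_to_communicate,confirming_communication,+1,reported
mastery_of_work,confirming_communication,+1,reported
language_proficiency,confirming_communication,+1,reported
confirming_communication,user_influence,+1,reported
confirming_communication,trust_in_home_care_staff,+1,reported
confirming_communication,functional_ability_autonomy,+1,reported
training_and_specialization,confirming_communication,+1,reported
training_and_specialization,mastery_of_work,+1,derived
adl_needs,needs_met,-1,derived
social_needs,needs_met,-1,derived
emotional_needs,needs_met,-1,derived
informational_needs,needs_met,-1,derived
treatment_needs,needs_met,-1,derived
self_sufficiency_needs,needs_met,-1,derived
needs_met,satisfaction_with_care,+1,reported
needs_met,self_perceived_health,+1,reported
needs_met,quality_of_life_user,+1,reported
needs_met,adverse_events_progression,-1,reported
adverse_events_progression,need_for_care,+1,reported
need_for_care,needs_met,-1,derived
adverse_events_progression,likelihood_institutional_care,+1,reported
time_spent_in_care,likelihood_institutional_care,+1,reported
likelihood_institutional_care,health_care_spending,+1,reported
functional_ability_autonomy,need_for_care,-1,derived
person_centered_care,provision_of_care_and_services,+1,reported
person_centered_care,trust_in_home_care_staff,+1,reported
person_centered_care,health_safety_risk,-1,reported
person_centered_care,functional_ability_autonomy,+1,derived
adoption_of_technology,complexity_of_work_tasks,+1,reported
adoption_of_technology,person_centered_care,+1,reported
adoption_of_technology,equipment_problems,+1,derived
social_support_network,delivery_informal_care,+1,reported
qol_informal_caregiver,delivery_informal_care,+1,reported
delivery_informal_care,needs_met,+1,reported
needs_met,informal_caregiver_stress,-1,reported
needs_met,qol_informal_caregiver,+1,reported
care_capacity,job_turnover,+1,derived
capital_income,job_turnover,+1,derived
stigmatization_toward_profession,job_turnover,+1,derived
county_unemployment,job_turnover,-1,derived
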