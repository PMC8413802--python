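item,domain,label,base_rate_pct,pss_rho,sig,household_level
1,work,laid_off_or_closed_business,16.0,-0.003,,0
2,work,reduced_hours_or_furloughed,30.8,-0.008,,0
3,work,had_to_lay_off_employees,7.2,0.002,,0
4,work,worked_despite_contact_risk,34.8,0.125,**,0
5,work,time_disinfecting_home_work_contact,32.4,0.103,**,0
6,work,increased_workload,38.7,0.192,**,0
7,work,job_hard_due_to_caregiving,18.4,0.171,**,0
8,work,hard_transition_to_wfh,34.5,0.179,**,0
9,work,direct_care_to_infected,8.7,0.063,,0
10,work,supportive_care_to_infected,14.1,0.097,*,0
11,work,care_to_people_who_died,4.8,0.107,**,0
12,home,child_unable_to_attend_school,33.0,0.038,,0
13,work,adult_unable_to_attend_school,13.3,0.063,,0
14,home,childcare_unavailable,11.5,0.110,**,0
15,home,difficulty_caring_for_children,12.3,0.184,**,0
16,home,more_conflict_or_harsher_discipline_child,13.2,0.159,**,0
17,home,had_to_teach_child,20.7,0.096,*,0
18,home,family_moved_into_home,7.5,0.032,,0
19,home,more_time_caring_for_family_member,19.2,0.129,**,0
20,home,had_to_move_or_relocate,4.6,0.082,*,0
21,home,became_homeless,0.3,0.046,,0
22,home,verbal_conflict_with_partner,20.1,0.185,**,0
23,home,physical_conflict_with_partner,1.2,0.068,,0
24,home,verbal_conflict_with_other_adult,13.0,0.218,**,0
25,home,physical_conflict_with_other_adult,0.6,0.102,**,0
26,home,physical_conflict_among_children,3.1,0.107,**,0
27,social,separated_from_family_or_friends,90.2,0.021,,0
28,social,no_means_to_contact_family,10.7,-0.030,,0
29,social,unable_to_visit_care_facility,22.5,-0.021,,0
30,social,celebrations_canceled,90.8,0.070,,0
31,social,travel_canceled,79.4,0.011,,0
32,social,religious_activities_canceled,51.4,0.018,,0
33,social,unable_to_be_with_critical_family_member,12.4,0.099,**,0
34,social,unable_to_attend_funeral,24.2,0.043,,0
35,social,unable_to_join_clubs_sports_volunteering,73.9,-0.015,,0
36,social,unable_to_do_hobbies,85.1,0.080,*,0
37,home,unable_to_get_enough_food,9.5,0.172,**,0
38,home,unable_to_access_clean_water,0.5,-0.008,,0
39,home,unable_to_pay_bills,7.2,0.147,**,0
40,home,transportation_difficulty,16.1,0.100,*,0
41,home,unable_to_get_medications,6.1,0.045,,0
42,health,child_behavioral_problems_increase,16.1,0.160,**,1
43,health,child_sleep_difficulties_increase,12.9,0.121,**,1
44,health,mental_health_problems_increase,69.8,0.388,**,0
45,health,sleep_problems_increase,66.3,0.268,**,0
46,health,alcohol_substance_use_increase,32.7,0.094,*,0
47,health,unable_to_access_mental_health_care,12.1,0.149,**,0
48,health,unsatisfied_with_mental_health_care_changes,13.7,0.170,**,0
49,health,more_screen_time,87.3,0.077,*,0
50,health,other_health_problems_increase,21.3,0.116,**,0
51,health,less_physical_activity,69.8,0.104,**,0
52,health,overeating_unhealthy_food,66.7,0.113,**,0
53,health,more_sedentary_time,87.6,0.070,,0
54,health,medical_procedure_canceled,17.3,-0.034,,0
55,health,unable_to_access_serious_medical_care,3.7,0.066,,0
56,health,less_medical_care_than_usual,66.7,0.095,*,0
57,health,elderly_family_member_lacked_help,9.0,0.084,*,0
58,social,isolated_due_to_possible_exposure,30.5,0.074,,0
59,social,isolated_due_to_symptoms,10.4,0.098,*,0
60,social,isolated_due_to_health_conditions,33.9,-0.040,,0
61,social,limited_physical_closeness,44.6,0.081,*,0
62,social,lived_away_due_to_high_risk_job,3.5,0.061,,0
63,social,family_member_quarantined,14.9,0.073,,0
64,social,family_member_unable_to_return,6.4,0.027,,0
65,social,entire_household_quarantined,13.3,0.092,*,1
66,health,current_symptoms_untested,2.8,0.046,,0
67,health,tested_currently_positive,0.6,0.037,,0
68,health,had_symptoms_never_tested,18.1,0.096,*,0
69,health,tested_positive_recovered,1.4,0.025,,0
70,health,medical_treatment_for_severe_symptoms,2.6,0.082,*,0
71,health,hospital_stay,0.5,0.029,,0
72,health,death_in_home_from_disease,0.2,0.052,,0
73,health,death_of_close_friend_or_family,4.9,0.063,,0
74,positive,more_quality_time_family_friends,67.2,0.091,*,0
75,positive,more_quality_time_partner,51.1,-0.039,,0
76,positive,more_quality_time_children,36.2,0.017,,0
77,positive,improved_relationships,35.7,0.069,,0
78,positive,new_supportive_connections,22.4,0.105,**,0
79,positive,increased_exercise,27.0,0.001,,0
80,positive,more_time_outdoors,45.2,0.025,,0
81,positive,more_enjoyable_activities,57.4,-0.087,,0
82,positive,new_hobbies,28.8,0.008,,0
83,positive,more_appreciative,81.3,0.051,,0
84,positive,more_attention_to_health,54.3,0.023,,0
85,positive,more_attention_to_injury_prevention,41.4,0.095,*,0
86,positive,ate_healthier,33.3,0.000,,0
87,positive,less_alcohol_substance_use,12.7,0.057,,0
88,positive,less_screen_time,5.5,-0.009,,0
89,positive,volunteered,19.3,-0.009,,0
90,positive,donated_time_or_goods,34.0,0.045,,0
91,positive,greater_meaning_in_work,33.7,0.068,,0
92,positive,more_productive_in_work,26.1,-0.017,,0
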