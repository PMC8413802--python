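outcome,group,p1,p2,p3,p4,p5
age_ge60,sociodemographic,0.025,0.081,0.312,0.178,0.420
age_le29,sociodemographic,0.070,0.299,0.160,0.218,0.074
male,sociodemographic,0.098,0.101,0.198,0.106,0.212
racial_ethnic_minority,sociodemographic,0.084,0.218,0.056,0.119,0.104
living_with_partner,sociodemographic,0.882,0.659,0.646,0.778,0.729
young_child_in_home,sociodemographic,0.923,0.114,0.089,0.217,0.067
child_adolescent_in_home,sociodemographic,0.313,0.027,0.106,0.272,0.058
young_adult_child_in_home,sociodemographic,0.131,0.164,0.162,0.298,0.136
person_gt60_in_home,sociodemographic,0.090,0.345,0.380,0.249,0.491
employed,sociodemographic,0.793,0.658,0.650,0.922,0.662
laid_off_unemployed,sociodemographic,0.191,0.326,0.154,0.096,0.113
public_or_no_insurance,sociodemographic,0.862,0.861,0.794,0.967,0.692
retired,sociodemographic,0.018,0.024,0.194,0.000,0.221
student,sociodemographic,0.104,0.231,0.095,0.095,0.023
pcptsd_ge3,psychosocial,0.325,0.498,0.277,0.087,0.051
phq9_ge15,psychosocial,0.369,0.645,0.438,0.208,0.009
gad7_ge15,psychosocial,0.451,0.513,0.382,0.183,0.000
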