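artery_id,tnw_segment,route,group,weight,tnw_node
4,head,core,head_brain,0.35,brain
4,head,muscle,head_muscle,0.01,muscle
4,head,fat,head_fat,0.01,fat
4,head,skin,head_skin,0.01,skin
21,head,core,head_brain,0.35,brain
21,head,muscle,head_muscle,0.01,muscle
21,head,fat,head_fat,0.01,fat
21,head,skin,head_skin,0.01,skin
7,head,core,head_brain,0.15,brain
7,head,muscle,head_muscle,0.01,muscle
7,head,fat,head_fat,0.01,fat
7,head,skin,head_skin,0.01,skin
25,head,core,head_brain,0.15,brain
25,head,muscle,head_muscle,0.01,muscle
25,head,fat,head_fat,0.01,fat
25,head,skin,head_skin,0.01,skin
5,head,core,head_skull,0.50,skull
5,head,muscle,head_muscle,0.48,muscle
5,head,fat,head_fat,0.48,fat
5,head,skin,head_skin,0.48,skin
22,head,core,head_skull,0.50,skull
22,head,muscle,head_muscle,0.48,muscle
22,head,fat,head_fat,0.48,fat
22,head,skin,head_skin,0.48,skin
9,neck,core,neck_core,0.50,core
9,neck,muscle,neck_muscle,0.50,muscle
9,neck,fat,neck_fat,0.50,fat
9,neck,skin,neck_skin,0.50,skin
27,neck,core,neck_core,0.50,core
27,neck,muscle,neck_muscle,0.50,muscle
27,neck,fat,neck_fat,0.50,fat
27,neck,skin,neck_skin,0.50,skin
11,upper_arm_r,core,arm_r_core,0.60,core
11,upper_arm_r,muscle,arm_r_muscle,0.645,muscle
11,upper_arm_r,fat,arm_r_fat,0.70,fat
11,upper_arm_r,skin,arm_r_skin,0.60,skin
16,lower_arm_r,core,arm_r_core,0.40,core
16,lower_arm_r,muscle,arm_r_muscle,0.355,muscle
16,lower_arm_r,fat,arm_r_fat,0.30,fat
16,lower_arm_r,skin,arm_r_skin,0.40,skin
13,hand_r,core,hand_r_core,0.50,core
13,hand_r,muscle,hand_r_muscle,0.50,muscle
13,hand_r,fat,hand_r_fat,0.50,fat
13,hand_r,skin,hand_r_skin,0.50,skin
17,hand_r,core,hand_r_core,0.50,core
17,hand_r,muscle,hand_r_muscle,0.50,muscle
17,hand_r,fat,hand_r_fat,0.50,fat
17,hand_r,skin,hand_r_skin,0.50,skin
29,upper_arm_l,core,arm_l_core,0.60,core
29,upper_arm_l,muscle,arm_l_muscle,0.645,muscle
29,upper_arm_l,fat,arm_l_fat,0.70,fat
29,upper_arm_l,skin,arm_l_skin,0.60,skin
34,lower_arm_l,core,arm_l_core,0.40,core
34,lower_arm_l,muscle,arm_l_muscle,0.355,muscle
34,lower_arm_l,fat,arm_l_fat,0.30,fat
34,lower_arm_l,skin,arm_l_skin,0.40,skin
31,hand_l,core,hand_l_core,0.50,core
31,hand_l,muscle,hand_l_muscle,0.50,muscle
31,hand_l,fat,hand_l_fat,0.50,fat
31,hand_l,skin,hand_l_skin,0.50,skin
35,hand_l,core,hand_l_core,0.50,core
35,hand_l,muscle,hand_l_muscle,0.50,muscle
35,hand_l,fat,hand_l_fat,0.50,fat
35,hand_l,skin,hand_l_skin,0.50,skin
38,chest,core,trunk_core,0.005,core
38,chest,muscle,trunk_muscle,0.295,muscle
38,chest,fat,trunk_fat,0.35,fat
38,chest,skin,trunk_skin,0.35,skin
40,chest,core,trunk_core,0.005,core
40,chest,muscle,trunk_muscle,0.295,muscle
40,chest,fat,trunk_fat,0.35,fat
40,chest,skin,trunk_skin,0.35,skin
43,abdomen,core,trunk_core,0.12,core
43,abdomen,muscle,trunk_muscle,0.01,muscle
43,abdomen,fat,trunk_fat,0.01,fat
43,abdomen,skin,trunk_skin,0.01,skin
45,abdomen,core,trunk_core,0.04,core
45,abdomen,muscle,trunk_muscle,0.01,muscle
45,abdomen,fat,trunk_fat,0.01,fat
45,abdomen,skin,trunk_skin,0.01,skin
46,abdomen,core,trunk_core,0.08,core
46,abdomen,muscle,trunk_muscle,0.01,muscle
46,abdomen,fat,trunk_fat,0.01,fat
46,abdomen,skin,trunk_skin,0.01,skin
48,abdomen,core,trunk_core,0.17,core
48,abdomen,muscle,trunk_muscle,0.01,muscle
48,abdomen,fat,trunk_fat,0.01,fat
48,abdomen,skin,trunk_skin,0.01,skin
54,abdomen,core,trunk_core,0.04,core
54,abdomen,muscle,trunk_muscle,0.01,muscle
54,abdomen,fat,trunk_fat,0.01,fat
54,abdomen,skin,trunk_skin,0.01,skin
50,abdomen,core,trunk_core,0.25,core
50,abdomen,muscle,trunk_muscle,0.005,muscle
50,abdomen,fat,trunk_fat,0.005,fat
50,abdomen,skin,trunk_skin,0.005,skin
52,abdomen,core,trunk_core,0.25,core
52,abdomen,muscle,trunk_muscle,0.005,muscle
52,abdomen,fat,trunk_fat,0.005,fat
52,abdomen,skin,trunk_skin,0.005,skin
57,abdomen,core,trunk_core,0.02,core
57,abdomen,muscle,trunk_muscle,0.175,muscle
57,abdomen,fat,trunk_fat,0.12,fat
57,abdomen,skin,trunk_skin,0.12,skin
72,abdomen,core,trunk_core,0.02,core
72,abdomen,muscle,trunk_muscle,0.175,muscle
72,abdomen,fat,trunk_fat,0.12,fat
72,abdomen,skin,trunk_skin,0.12,skin
59,thigh_r,core,leg_r_core,0.50,core
59,thigh_r,muscle,leg_r_muscle,0.55,muscle
59,thigh_r,fat,leg_r_fat,0.50,fat
59,thigh_r,skin,leg_r_skin,0.35,skin
61,thigh_r,core,leg_r_core,0.20,core
61,thigh_r,muscle,leg_r_muscle,0.14,muscle
61,thigh_r,fat,leg_r_fat,0.20,fat
61,thigh_r,skin,leg_r_skin,0.15,skin
63,leg_r,core,leg_r_core,0.10,core
63,leg_r,muscle,leg_r_muscle,0.06,muscle
63,leg_r,fat,leg_r_fat,0.05,fat
63,leg_r,skin,leg_r_skin,0.07,skin
65,leg_r,core,leg_r_core,0.10,core
65,leg_r,muscle,leg_r_muscle,0.135,muscle
65,leg_r,fat,leg_r_fat,0.15,fat
65,leg_r,skin,leg_r_skin,0.23,skin
68,leg_r,core,leg_r_core,0.10,core
68,leg_r,muscle,leg_r_muscle,0.115,muscle
68,leg_r,fat,leg_r_fat,0.10,fat
68,leg_r,skin,leg_r_skin,0.20,skin
74,thigh_l,core,leg_l_core,0.50,core
74,thigh_l,muscle,leg_l_muscle,0.55,muscle
74,thigh_l,fat,leg_l_fat,0.50,fat
74,thigh_l,skin,leg_l_skin,0.35,skin
76,thigh_l,core,leg_l_core,0.20,core
76,thigh_l,muscle,leg_l_muscle,0.14,muscle
76,thigh_l,fat,leg_l_fat,0.20,fat
76,thigh_l,skin,leg_l_skin,0.15,skin
78,leg_l,core,leg_l_core,0.10,core
78,leg_l,muscle,leg_l_muscle,0.06,muscle
78,leg_l,fat,leg_l_fat,0.05,fat
78,leg_l,skin,leg_l_skin,0.07,skin
80,leg_l,core,leg_l_core,0.10,core
80,leg_l,muscle,leg_l_muscle,0.135,muscle
80,leg_l,fat,leg_l_fat,0.15,fat
80,leg_l,skin,leg_l_skin,0.23,skin
83,leg_l,core,leg_l_core,0.10,core
83,leg_l,muscle,leg_l_muscle,0.115,muscle
83,leg_l,fat,leg_l_fat,0.10,fat
83,leg_l,skin,leg_l_skin,0.20,skin
69,foot_r,core,foot_r_core,1.0,core
69,foot_r,muscle,foot_r_muscle,1.0,muscle
69,foot_r,fat,foot_r_fat,1.0,fat
69,foot_r,skin,foot_r_skin,1.0,skin
84,foot_l,core,foot_l_core,1.0,core
84,foot_l,muscle,foot_l_muscle,1.0,muscle
84,foot_l,fat,foot_l_fat,1.0,fat
84,foot_l,skin,foot_l_skin,1.0,skin
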