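group,segment_label,compartment,target_ml_min,per_side,source
head_brain,head,brain,904.0,0,goto
head_skull,head,skull,371.0,0,goto
head_muscle,head,muscle,23.2,0,goto
head_fat,head,fat,46.5,0,goto
head_skin,head,skin,20.3,0,goto
neck_core,neck,core,4.5,0,goto
neck_muscle,neck,muscle,10.6,0,goto
neck_fat,neck,fat,4.5,0,goto
neck_skin,neck,skin,1.7,0,goto
trunk_core,chest_abdomen,core,2070.0,0,goto
trunk_muscle,chest_abdomen,muscle,366.0,0,goto
trunk_fat,chest_abdomen,fat,75.1,0,goto
trunk_skin,chest_abdomen,skin,21.4,0,goto
arm_r_core,arm,core,1.9,1,goto
arm_r_muscle,arm,muscle,104.0,1,goto
arm_r_fat,arm,fat,13.8,1,goto
arm_r_skin,arm,skin,6.0,1,goto
arm_l_core,arm,core,1.9,1,goto
arm_l_muscle,arm,muscle,104.0,1,goto
arm_l_fat,arm,fat,13.8,1,goto
arm_l_skin,arm,skin,6.0,1,goto
hand_r_core,hand,core,0.4,1,goto
hand_r_muscle,hand,muscle,16.2,1,goto
hand_r_fat,hand,fat,13.0,1,goto
hand_r_skin,hand,skin,8.6,1,goto
hand_l_core,hand,core,0.4,1,goto
hand_l_muscle,hand,muscle,16.2,1,goto
hand_l_fat,hand,fat,13.0,1,goto
hand_l_skin,hand,skin,8.6,1,goto
leg_r_core,thigh_leg,core,4.2,1,goto
leg_r_muscle,thigh_leg,muscle,254.0,1,goto
leg_r_fat,thigh_leg,fat,41.7,1,goto
leg_r_skin,thigh_leg,skin,10.6,1,goto
leg_l_core,thigh_leg,core,4.2,1,goto
leg_l_muscle,thigh_leg,muscle,254.0,1,goto
leg_l_fat,thigh_leg,fat,41.7,1,goto
leg_l_skin,thigh_leg,skin,10.6,1,goto
foot_r_core,foot,core,1.5,1,goto
foot_r_muscle,foot,muscle,12.7,1,goto
foot_r_fat,foot,fat,10.4,1,goto
foot_r_skin,foot,skin,4.7,1,goto
foot_l_core,foot,core,1.5,1,goto
foot_l_muscle,foot,muscle,12.7,1,goto
foot_l_fat,foot,fat,10.4,1,goto
foot_l_skin,foot,skin,4.7,1,goto
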