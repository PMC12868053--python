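segment,node,kind,heat_capacity_J_K,basal_met_W,segment_length_m,radius_m,vessel_area_m2,bilateral
head,brain,compartment,5523.3,17.470,0.0,0.070,,0
head,skull,compartment,4208.6,1.109,0.0,0.089,,0
head,muscle,compartment,2627.6,0.486,0.0,0.097,,0
head,fat,compartment,1342.3,0.127,0.0,0.103,,0
head,skin,compartment,958.9,0.148,0.0,0.105,,0
head,artery,artery,,0.0,0.0,,,0
head,vein,vein,,0.0,0.0,,,0
neck,core,compartment,406.4,0.095,0.065,0.025,,0
neck,muscle,compartment,1200.0,0.222,0.065,0.047,,0
neck,fat,compartment,282.3,0.027,0.065,0.054,,0
neck,skin,compartment,173.4,0.027,0.065,0.056,,0
neck,artery,artery,,0.0,0.065,0.004,0.016,0
neck,vein,vein,,0.0,0.065,0.0048,0.019,0
chest,right_heart,compartment,801.4,4.596,0.354,,,0
chest,left_heart,compartment,801.4,4.596,0.354,,,0
chest,lung,compartment,7383.1,1.156,0.354,0.058,,0
chest,core,compartment,8924.9,2.040,0.354,0.079,,0
chest,muscle,compartment,14050.1,2.601,0.354,0.099,,0
chest,fat,compartment,3266.9,0.309,0.354,0.106,,0
chest,skin,compartment,1815.2,0.280,0.354,0.108,,0
abdomen,core,compartment,26520.1,28.286,0.530,0.075,,0
abdomen,muscle,compartment,27446.6,5.082,0.530,0.101,,0
abdomen,fat,compartment,7009.4,0.663,0.530,0.111,,0
abdomen,skin,compartment,2829.2,0.436,0.530,0.113,,0
abdomen,artery,artery,,0.0,0.530,0.007,0.046,0
abdomen,vein,vein,,0.0,0.530,0.008,0.055,0
upper_arm,core,compartment,587.0,0.214,0.288,0.016,,1
upper_arm,muscle,compartment,3892.2,0.721,0.288,0.038,,1
upper_arm,fat,compartment,1006.3,0.095,0.288,0.045,,1
upper_arm,skin,compartment,640.8,0.099,0.288,0.047,,1
upper_arm,artery,artery,,0.0,0.288,0.003,0.010,1
upper_arm,vein,vein,,0.0,0.288,0.0036,0.024,1
upper_arm,superficial_vein,superficial_vein,,0.0,0.288,,,1
lower_arm,core,compartment,305.0,0.111,0.176,0.015,,1
lower_arm,muscle,compartment,1929.3,0.357,0.176,0.034,,1
lower_arm,fat,compartment,371.0,0.035,0.176,0.039,,1
lower_arm,skin,compartment,343.7,0.053,0.176,0.041,,1
lower_arm,artery,artery,,0.0,0.176,0.002,0.006,1
lower_arm,vein,vein,,0.0,0.176,0.0024,0.014,1
lower_arm,superficial_vein,superficial_vein,,0.0,0.176,,,1
hand,core,compartment,193.2,0.070,0.257,0.010,,1
hand,muscle,compartment,449.1,0.083,0.257,0.016,,1
hand,fat,compartment,270.4,0.026,0.257,0.020,,1
hand,skin,compartment,293.4,0.045,0.257,0.022,,1
hand,artery,artery,,0.0,0.257,0.00045,0.003,1
hand,vein,vein,,0.0,0.257,0.00054,0.004,1
hand,superficial_vein,superficial_vein,,0.0,0.257,,,1
thigh,core,compartment,1000.4,0.365,0.254,0.023,,1
thigh,muscle,compartment,11748.2,2.175,0.254,0.068,,1
thigh,fat,compartment,2879.3,0.272,0.254,0.080,,1
thigh,skin,compartment,987.1,0.152,0.254,0.082,,1
thigh,artery,artery,,0.0,0.254,0.003,0.011,1
thigh,vein,vein,,0.0,0.254,0.0036,0.013,1
thigh,superficial_vein,superficial_vein,,0.0,0.254,,,1
leg,core,compartment,1035.6,0.378,0.286,0.022,,1
leg,muscle,compartment,5176.2,0.958,0.286,0.045,,1
leg,fat,compartment,1244.4,0.118,0.286,0.053,,1
leg,skin,compartment,740.7,0.114,0.286,0.055,,1
leg,artery,artery,,0.0,0.286,0.002,0.012,1
leg,vein,vein,,0.0,0.286,0.0024,0.028,1
leg,superficial_vein,superficial_vein,,0.0,0.286,,,1
foot,core,compartment,703.3,0.257,0.288,0.018,,1
foot,muscle,compartment,843.4,0.156,0.288,0.023,,1
foot,fat,compartment,660.1,0.062,0.288,0.030,,1
foot,skin,compartment,484.4,0.075,0.288,0.032,,1
foot,artery,artery,,0.0,0.288,0.00044,0.007,1
foot,vein,vein,,0.0,0.288,0.00053,0.008,1
foot,superficial_vein,superficial_vein,,0.0,0.288,,,1
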