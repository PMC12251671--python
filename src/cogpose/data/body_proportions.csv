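quantity,fraction_of_stature
ankle_height,0.039
knee_height,0.285
hip_height,0.530
shoulder_height,0.818
nose_height,0.870
eye_height,0.900
ear_height,0.880
shoulder_halfwidth,0.1295
hip_halfwidth,0.0955
upper_arm_length,0.186
forearm_length,0.146
hand_length,0.108
foot_length,0.152
heel_offset,0.040
face_halfwidth,0.065
face_height,0.110
eye_halfspacing,0.030
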