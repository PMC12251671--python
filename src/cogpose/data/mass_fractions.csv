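segment,gender,percent
neck,M,8.62
neck,F,8.20
upper_torso,M,16.82
upper_torso,F,16.35
lower_torso,M,27.23
lower_torso,F,27.48
thigh,M,14.19
thigh,F,14.10
calf,M,3.67
calf,F,4.43
upper_arm,M,2.43
upper_arm,F,2.66
forearm,M,1.25
forearm,F,1.14
hand,M,0.64
hand,F,0.42
foot,M,1.48
foot,F,1.24
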