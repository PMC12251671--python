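segment,gender,les,lex
neck,M,46.9,53.1
neck,F,47.3,52.7
upper_torso,M,53.6,46.4
upper_torso,F,49.3,50.7
lower_torso,M,40.3,59.7
lower_torso,F,44.6,55.4
thigh,M,45.3,54.7
thigh,F,44.2,55.8
calf,M,39.3,60.7
calf,F,42.5,57.5
upper_arm,M,47.8,52.2
upper_arm,F,46.7,53.3
forearm,M,42.4,57.6
forearm,F,45.3,54.7
hand,M,36.6,63.4
hand,F,34.9,65.1
foot,M,48.6,51.4
foot,F,45.1,54.9
overall_centroid,M,43.8,56.2
overall_centroid,F,44.5,55.5
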