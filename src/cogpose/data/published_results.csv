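table,method,metric,value
h3wb,simple_baseline,whole_body,125.4
h3wb,simple_baseline,body,125.7
h3wb,simple_baseline,face,24.6
h3wb,simple_baseline,hands,42.5
h3wb,large_simple_baseline,whole_body,112.3
h3wb,large_simple_baseline,body,112.6
h3wb,large_simple_baseline,face,14.6
h3wb,large_simple_baseline,hands,31.7
h3wb,jointformer,whole_body,88.3
h3wb,jointformer,body,84.9
h3wb,jointformer,face,17.8
h3wb,jointformer,hands,43.7
h3wb,3d_lfm,whole_body,64.13
h3wb,3d_lfm,body,60.83
h3wb,3d_lfm,face,10.44
h3wb,3d_lfm,hands,28.22
h3wb,semgan,whole_body,47.87
h3wb,semgan,body,45.39
h3wb,semgan,face,15.95
h3wb,semgan,hands,27.77
h3wb,ours,whole_body,44.49
h3wb,ours,body,40.41
h3wb,ours,face,6.09
h3wb,ours,hands,22.07
constraint_ablation,mass_only,whole_body,67.50
constraint_ablation,mass_only,body,59.24
constraint_ablation,mass_only,face,10.10
constraint_ablation,mass_only,hands,29.41
constraint_ablation,cog_only,whole_body,58.34
constraint_ablation,cog_only,body,50.76
constraint_ablation,cog_only,face,8.32
constraint_ablation,cog_only,hands,25.73
constraint_ablation,mass_and_cog,whole_body,44.49
constraint_ablation,mass_and_cog,body,40.41
constraint_ablation,mass_and_cog,face,6.09
constraint_ablation,mass_and_cog,hands,22.07
loss_ablation,position,whole_body,59.71
loss_ablation,position,body,47.69
loss_ablation,position,face,15.35
loss_ablation,position,hands,31.93
loss_ablation,position_cog,whole_body,51.75
loss_ablation,position_cog,body,44.21
loss_ablation,position_cog,face,13.29
loss_ablation,position_cog,hands,25.61
loss_ablation,position_bone,whole_body,49.29
loss_ablation,position_bone,body,45.57
loss_ablation,position_bone,face,9.90
loss_ablation,position_bone,hands,26.61
loss_ablation,total,whole_body,44.49
loss_ablation,total,body,40.41
loss_ablation,total,face,6.09
loss_ablation,total,hands,22.07
h36m_actions,jointformer,walk,39.4
h36m_actions,jointformer,eat,46.6
h36m_actions,ours,walk,27.9
h36m_actions,ours,eat,33.6
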