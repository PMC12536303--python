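subject_id,group,site,density_pct,diameter_mean_um,diameter_sd_um,vuet_um
1,control,labia_majora,,,,317
1,control,interlabial_sulci,,,,192
1,control,labia_minora,32.97,55.88,18.1,110
2,control,labia_majora,,,,206
2,control,interlabial_sulci,,,,182
2,control,labia_minora,36.156,53.9,7.39,144
3,control,labia_majora,,,,196
3,control,interlabial_sulci,,,,155
3,control,labia_minora,29.21,51.7,9.5,131
4,VLS,labia_majora,,,,221
4,VLS,interlabial_sulci,,,,
4,VLS,labia_minora,39.82,41.38,13.78,181
5,VLS,labia_majora,,,,
5,VLS,interlabial_sulci,,,,
5,VLS,labia_minora,37.09,58.27,14.23,122
6,VLS,labia_majora,,,,177
6,VLS,interlabial_sulci,,,,147
6,VLS,labia_minora,40.56,50.8,16.39,118
7,VLS,labia_majora,,,,162
7,VLS,interlabial_sulci,,,,147
7,VLS,labia_minora,45.8,31.44,8.2,121
8,VLS,labia_majora,,,,121
8,VLS,interlabial_sulci,,,,63
8,VLS,labia_minora,40.32,40.92,10.3,89
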