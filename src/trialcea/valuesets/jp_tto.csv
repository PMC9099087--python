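term,level,decrement
constant,any,0.152
mobility,2,0.075
mobility,3,0.418
self_care,2,0.054
self_care,3,0.102
usual_activities,2,0.044
usual_activities,3,0.133
pain_discomfort,2,0.080
pain_discomfort,3,0.194
anxiety_depression,2,0.063
anxiety_depression,3,0.112
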