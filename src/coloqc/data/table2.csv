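colonoscopy,segment,bbps_rater1,bbps_rater2,pixel_score,mucosa_pct,residue_pct,artifact_pct,lumen_pct
T1,1,1,2,1,34,21,24,21
T1,2,1,1,1,34,13,21,33
T1,3,1,2,2,61,2,20,17
T2,1,1,2,2,58,14,20,8
T2,2,2,1,2,65,11,18,5
T2,3,2,2,3,78,4,13,4
T3,1,1,1,1,34,14,21,31
T3,2,2,2,2,44,4,19,33
T3,3,3,3,3,62,0,14,23
T4,1,2,2,2,50,15,20,15
T4,2,2,3,3,70,5,15,10
T4,3,2,2,3,70,9,13,8
T5,1,1,2,1,38,19,24,19
T5,2,1,2,1,33,29,19,19
T5,3,1,1,2,47,11,21,21
T6,1,2,2,3,72,2,18,8
T6,2,2,2,2,57,17,16,11
T6,3,2,1,3,68,9,11,11
T7,1,2,2,1,41,24,22,14
T7,2,2,1,2,54,12,21,14
T7,3,2,1,3,74,6,14,5
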