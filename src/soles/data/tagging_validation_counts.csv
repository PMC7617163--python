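category,method,specificity,sensitivity,precision,tp,fp,tn,fn
model,fulltext_gt0,0.005,1,0.404,143,208,1,0
model,fulltext_gt1,0.45,0.909,0.526,130,115,94,13
model,fulltext_gt2,0.746,0.692,0.652,99,53,156,44
model,tiabkw,0.933,0.727,0.883,104,14,195,39
model,model_sentence,0.861,0.762,0.793,109,29,180,34
sex,fulltext_gt0,0.053,1,0.865,115,18,1,0
sex,fulltext_gt1,0.579,0.678,0.907,78,8,11,37
sex,fulltext_gt2,0.789,0.417,0.923,48,4,15,67
sex,tiabkw,0.895,0.522,0.968,60,2,17,55
sex,model_sentence,0.632,0.991,0.942,114,7,12,1
species,fulltext_gt0,,1,0.521,99,91,0,0
species,fulltext_gt1,0.143,1,0.559,99,78,13,0
species,fulltext_gt2,0.407,0.626,0.534,62,54,37,37
species,tiabkw,0.967,0.98,0.97,97,3,88,2
species,model_sentence,0.802,0.98,0.843,97,18,73,2
outcome,fulltext_gt0,,1,0.671,161,79,0,0
outcome,fulltext_gt1,0.646,0.932,0.843,150,28,51,11
outcome,fulltext_gt2,0.848,0.497,0.87,80,12,67,81
outcome,tiabkw,0.987,0.422,0.986,68,1,78,93
intervention,tiabkw,,,0.417,85,117,,
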