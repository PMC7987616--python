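stage,reason,count
stage1,age at entry above maximum,1
stage1,no overlap with practice window,2
stage1,practice window empty,2
stage2,exclusion (Amputation) ever recorded,1
stage2,exposure order violated,1
stage2,outcome (Stroke) before index,1
stage2,prevalent at entry: Type2Diabetes,2
stage4,control not selected,15
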