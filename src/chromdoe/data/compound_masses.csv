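name,mz_deprotonated
"quercetin 3,7,4'-O-triglucoside",787.1421
"quercetin 7,4'-O-diglucoside",625.1396
"quercetin 3,4'-O-diglucoside",625.1398
"isorhamnetin 3,4'-O-diglucoside",639.1559
"quercetin 3-O-glucoside",463.0886
"quercetin 4'-O-glucoside",463.0873
"isorhamnetin 4'-O-glucoside",477.1040
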