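peak,compound,tR_min,k,alpha
1,"quercetin 3,7,4'-O-triglucoside",0.945,1.36,
2,"quercetin 7,4'-O-diglucoside",1.478,2.69,1.98
3,"quercetin 3,4'-O-diglucoside",1.688,3.22,1.19
4,"isorhamnetin 3,4'-O-diglucoside",1.835,3.59,1.11
5,"quercetin 3-O-glucoside",2.119,4.30,1.20
6,"quercetin 4'-O-glucoside",2.478,5.19,1.21
7,"isorhamnetin 4'-O-glucoside",2.693,5.73,1.10
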