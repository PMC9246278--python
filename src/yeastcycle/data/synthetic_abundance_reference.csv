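species,measured
Cln3,200
Cln2,700
Clb5,500
Clb3,80
Clb2,500
Sic1,200
Whi5,2400
SBF,400
MBF,250
Cdc14,800
Net1,1800
Swe1,450
Far1,30
Mcm1,500
APC,750
Swi5,500
Mih1,500
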