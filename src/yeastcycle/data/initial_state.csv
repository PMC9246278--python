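name,value
Cln3,160
Cln2,763.106
Clb5,28.9618
Clb3,0.211186
Clb2,0.416193
Clb2_p,0.712847
Sic1,206.548
Sic1_p,135.331
Sic1_Hp,0
Clb5_Sic1,18.9582
Clb5_Sic1_Hp,0
Clb3_Sic1,0.0555742
Clb2_Sic1,0.339125
Whi5,49.6705
Whi5_p,1874.62
SBF,229.265
SBF_Whi5,70.7093
SBF_p,0.0254644
MBF,66.7584
MBF_a,233.242
Mcm1_a,0.670674
APC_a,278.286
Cdc14,463.532
Cdc14_p,536.468
Net1,1381.11
Net1_p,218.888
Swi5_a,335.032
Swe1,221.479
Swe1_p,25.419
Far1,21.5743
Far1_p,0
Cln2_Far1_p,0
Cln3_Far1_p,0
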