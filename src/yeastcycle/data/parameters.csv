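name,value
ks_cln3,8
ks_cln2,0.6
ks_clb5,0.24
ks_clb3,0.0108
ks_clb2,2.5
ks_sic1,2
ks_sic1_swi5,0.2
ks_swe1,15
ks_far1,8
ks_far1_fus3,250
kh_cln2,30
kh_clb5,30
kh_swe1,20
kd_cln3,0.05
kd_cln2,0.15
kd_clb5,0.05
kd_clb5_apc,0.004
kd_clb3,0.03
kd_clb3_apc,0.004
kd_clb2,0.03
kd_clb2_apc,0.004
kd_sic1,0.02
kd_sic1p,0.5
kd_swe1,0.03
kd_swe1p,0.1
kd_far1,0.02
kd_far1p,0.01
kd_far1_cln2,0.0005
kp_sic1c_cln2,0.0005
kp_sic1c_clb5,0.0005
kp_sic1c_hog1,0.1
kp_whi5_cln3,1.1
kp_whi5_cln2,0.15
Km_whi5,300
kp_sbfwhi5_cln3,1.1
kp_sbfwhi5_cln2,0.15
Km_sbfwhi5,100
kdp_whi5_basal,15
kdp_whi5_cdc14,0.3
Km_whi5p,300
ka_sbf_whi5,0.01
kp_sbf_clb2,0.05
Km_sbf,100
kdp_sbf_basal,1
kdp_sbf_cdc14,0.1
Km_sbfp,100
ka_mbf_cln2,0.35
Km_mbf,300
ki_mbf,45
Km_mbfa,300
ka_mcm1_basal,0.001
ka_mcm1_clb3,0.8
ka_mcm1_clb2,0.3
Km_mcm1,600
ki_mcm1,90
Km_mcm1a,150
Mcm1_tot,400
ka_apc_basal,0.0005
ka_apc_mcm1,0.05
ka_apc_cdc14,0.08
Km_apc,250
ki_apc,32
Km_apca,150
APC_tot,600
kp_sic1_cln2,0.2
kp_sic1_clb5,0.2
Km_sic1,200
kdp_sic1_cdc14,0.05
Km_sic1p,200
kp_sic1_hog1,200
Km_sic1h,200
kdp_sic1_hp,0.005
kas_clb5_sic1,0.005
kdi_clb5_sic1,0.05
kas_clb5_sic1h,0.01
kdi_clb5_sic1h,0.05
kas_clb3_sic1,0.002
kdi_clb3_sic1,0.05
kas_clb2_sic1,0.006
kdi_clb2_sic1,0.05
kp_clb2_swe1,1.1
Km_clb2,100
kdp_clb2_mih1,0.18
Mih1,400
Km_clb2p,300
kp_swe1_clb2,0.4
Km_swe1,100
kdp_swe1,5
Km_swe1p,300
kp_net1_clb2,0.3
Km_net1,300
kdp_net1,90
Km_net1p,300
ka_cdc14_net1,0.1
ka_cdc14_apc,0.05
ka_cdc14_self,0.06
Km_cdc14,300
ki_cdc14,105
Km_cdc14p,300
ka_swi5_cdc14,0.4
Km_swi5,300
ki_swi5,30
Km_swi5a,150
Swi5_tot,400
kp_far1_fus3,300
Km_far1,200
kdp_far1,0.1
kas_cln2_far1,0.01
kdi_cln2_far1,0.01
kas_cln3_far1,0.01
kdi_cln3_far1,0.01
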