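# Synthetic reconstruction of the D1R-spine model parameter tables
# (topology from the published block/trafficking diagrams; free rate
# constants hand-calibrated to the documented qualitative behaviors).
# Units: concentrations uM, time s, kf uM^-1 s^-1, kb/kcat s^-1.
label,param_id,a,b,ab,kd,tau,kf,kb,provenance
DA_binds_D1R,b_da_d1r,DA,D1R,DA_D1R,0.5,10.0,,,literature
DAD1R_binds_Golf,b_d1r_golf,DA_D1R,Golf,DA_D1R_Golf,0.3,1.0,,,tuned
Golf_activates_AC5,b_ac5_golf,AC5,DA_D1R_Golf,AC5_Golf,2.0,1.0,,,tuned
Ca_inhibits_AC5,b_ca_ac5,Ca,AC5,AC5_Ca,4.0,0.2,,,literature
Ca_inhibits_AC5Golf,b_ca_ac5g,Ca,AC5_Golf,AC5_Golf_Ca,0.1,10.0,,,tuned
PKA_binds_cAMP_1,b_pka_c1,PKA,cAMP,PKA_cAMP,0.8,0.2,,,literature
PKA_binds_cAMP_2,b_pka_c2,PKA_cAMP,cAMP,PKA_cAMP2,0.8,0.2,,,literature
PKAc_release,b_pkac_rel,PKAr_cAMP2,PKAc,PKA_cAMP2,,,3.0,1.0,tuned
CaM_binds_PDE,b_cam_pde,CaM_Ca4,PDE,PDE_CaM,2.0,1.0,,,tuned
CaM_binds_2Ca,b_cam_ca2,CaM,Ca,CaM_Ca2,,,10.0,100.0,literature
CaMCa2_binds_2Ca,b_cam_ca4,CaM_Ca2,Ca,CaM_Ca4,,,50.0,50.0,literature
CaM_activates_CaMKII,b_kii_cam,CaM_Ca4,CaMKII,CaMKII_CaM,4.0,0.5,,,literature
CaM_activates_PP2B,b_pp2b_cam,PP2B,CaM_Ca4,PP2B_CaM,,,3.0,0.3,literature
Ca_activates_PP2A,b_pp2a_ca,PP2A,Ca,PP2A_Ca,1.7,10.0,,,literature
T75_inhibits_PKA_D32_75,b_t75_pka,D32_75,PKAc,D32_75_PKAc,0.2,2.0,,,literature
T75_inhibits_PKA_D32_75_137,b_t75_pka,D32_75_137,PKAc,D32_75_137_PKAc,0.2,2.0,,,literature
T34_inhibits_PP1_D32_34,b_t34_pp1,D32_34,PP1,D32_34_PP1,0.1,10.0,,,literature
T34_inhibits_PP1_D32_34_137,b_t34_pp1,D32_34_137,PP1,D32_34_137_PP1,0.1,10.0,,,literature
I1p_inhibits_PP1,b_i1_pp1,I1p,PP1,I1p_PP1,0.1,10.0,,,literature
A845_binds_anchor,b_845_anc,AMPAR_845,Anchor,AMPAR_845_A,0.3,500.0,,,tuned
A831_binds_anchor,b_831_anc,AMPAR_845_831,Anchor,AMPAR_845_831_A,0.1,500.0,,,tuned
A0_anchor_release,b_a0_anc,AMPAR,Anchor,AMPAR_A,50.0,2.0,,,tuned
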