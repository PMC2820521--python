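# Synthetic reconstruction of the D1R-spine model parameter tables
# (topology from the published block/trafficking diagrams; free rate
# constants hand-calibrated to the documented qualitative behaviors).
# Units: concentrations uM, time s, kf uM^-1 s^-1, kb/kcat s^-1.
label,param_id,enzyme,substrate,complex_es,product,km,kcat,kf,kb,provenance
AC5_makes_cAMP,e_ac5_cat,AC5_Golf,ATP,AC5_Golf__ATP,cAMP,,2.0,0.01,8.0,literature
PDE_degrades_cAMP,e_pde,PDE,cAMP,PDE__cAMP,AMP,4.0,1.5,,,literature
PKAc_phos_PDE,e_pka_pde,PKAc,PDE,PKAc__PDE,PDEp,,2.0,2.0,8.0,tuned
PDEp_degrades_cAMP,e_pdep,PDEp,cAMP,PDEp__cAMP,AMP,,4.0,5.0,16.0,tuned
PP2C_dephos_PDEp,e_ppm_pdep,PP2C,PDEp,PP2C__PDEp,PDE,,0.5,0.5,2.0,tuned
PDECaM_degrades_cAMP,e_pdecam,PDE_CaM,cAMP,PDE_CaM__cAMP,AMP,,1.0,1.25,4.0,tuned
CaMKII_autophos,e_kii_auto,CaMKII_CaM,CaMKII_CaM,CaMKII_CaM__CaMKII_CaM,CaMKIIp_CaM,,2.0,2.0,8.0,literature
PP1_dephos_CaMKII,e_pp1_kii,PP1,CaMKIIp_CaM,PP1__CaMKIIp_CaM,CaMKII_CaM,,6.0,30.0,24.0,literature
CK1_autophos,e_ck1_auto,CK1,CK1,CK1__CK1,CK1p,,12.0,200.0,48.0,tuned
PP2B_activates_CK1,e_pp2b_ck1,PP2B_CaM,CK1p,PP2B_CaM__CK1p,CK1,,10.0,50.0,40.0,tuned
CK1_activates_Cdk5,e_ck1_cdk5,CK1,Cdk5,CK1__Cdk5,Cdk5a,,2.5,6.25,10.0,tuned
PP2C_deact_Cdk5,e_ppm_cdk5,PP2C,Cdk5a,PP2C__Cdk5a,Cdk5,,12.0,60.0,48.0,tuned
PKAc_phos_PP2A,e_pka_pp2a,PKAc,PP2A,PKAc__PP2A,PP2Ap,,4.0,40.0,16.0,literature
PP1_dephos_PP2A,e_pp1_pp2a,PP1,PP2Ap,PP1__PP2Ap,PP2A,,40.0,666.6666666666667,160.0,tuned
PKA_T34_D32,e_pka_t34,PKAc,D32,PKAc__D32,D32_34,,2.0,0.4,8.0,literature
PKA_T34_D32_137,e_pka_t34,PKAc,D32_137,PKAc__D32_137,D32_34_137,,2.0,0.4,8.0,literature
PP2B_T34_D32_34,e_pp2b_t34,PP2B_CaM,D32_34,PP2B_CaM__D32_34,D32,,5.0,2.5,20.0,literature
PP2B_T34_D32_34_75,e_pp2b_t34,PP2B_CaM,D32_34_75,PP2B_CaM__D32_34_75,D32_75,,5.0,2.5,20.0,literature
PP2B_T34s_D32_34_137,e_pp2b_t34s,PP2B_CaM,D32_34_137,PP2B_CaM__D32_34_137,D32_137,,0.5,0.25,2.0,literature
PP2B_T34s_D32_34_75_137,e_pp2b_t34s,PP2B_CaM,D32_34_75_137,PP2B_CaM__D32_34_75_137,D32_75_137,,0.5,0.25,2.0,literature
Cdk5_T75_D32,e_cdk5_t75,Cdk5a,D32,Cdk5a__D32,D32_75,,3.0,3.0,12.0,tuned
Cdk5_T75_D32_34,e_cdk5_t75,Cdk5a,D32_34,Cdk5a__D32_34,D32_34_75,,3.0,3.0,12.0,tuned
Cdk5_T75_D32_137,e_cdk5_t75,Cdk5a,D32_137,Cdk5a__D32_137,D32_75_137,,3.0,3.0,12.0,tuned
Cdk5_T75_D32_34_137,e_cdk5_t75,Cdk5a,D32_34_137,Cdk5a__D32_34_137,D32_34_75_137,,3.0,3.0,12.0,tuned
PP2ACa_T75_D32_75,e_p2ca_t75,PP2A_Ca,D32_75,PP2A_Ca__D32_75,D32,,60.0,5.0,240.0,tuned
PP2ACa_T75_D32_34_75,e_p2ca_t75,PP2A_Ca,D32_34_75,PP2A_Ca__D32_34_75,D32_34,,60.0,5.0,240.0,tuned
PP2ACa_T75_D32_75_137,e_p2ca_t75,PP2A_Ca,D32_75_137,PP2A_Ca__D32_75_137,D32_137,,60.0,5.0,240.0,tuned
PP2ACa_T75_D32_34_75_137,e_p2ca_t75,PP2A_Ca,D32_34_75_137,PP2A_Ca__D32_34_75_137,D32_34_137,,60.0,5.0,240.0,tuned
PP2Ap_T75_D32_75,e_p2ap_t75,PP2Ap,D32_75,PP2Ap__D32_75,D32,,18.0,4.5,72.0,tuned
PP2Ap_T75_D32_34_75,e_p2ap_t75,PP2Ap,D32_34_75,PP2Ap__D32_34_75,D32_34,,18.0,4.5,72.0,tuned
PP2Ap_T75_D32_75_137,e_p2ap_t75,PP2Ap,D32_75_137,PP2Ap__D32_75_137,D32_137,,18.0,4.5,72.0,tuned
PP2Ap_T75_D32_34_75_137,e_p2ap_t75,PP2Ap,D32_34_75_137,PP2Ap__D32_34_75_137,D32_34_137,,18.0,4.5,72.0,tuned
CK1_S137_D32,e_ck1_s137,CK1,D32,CK1__D32,D32_137,,2.0,0.2,8.0,tuned
CK1_S137_D32_34,e_ck1_s137,CK1,D32_34,CK1__D32_34,D32_34_137,,2.0,0.2,8.0,tuned
CK1_S137_D32_75,e_ck1_s137,CK1,D32_75,CK1__D32_75,D32_75_137,,2.0,0.2,8.0,tuned
CK1_S137_D32_34_75,e_ck1_s137,CK1,D32_34_75,CK1__D32_34_75,D32_34_75_137,,2.0,0.2,8.0,tuned
PP2C_S137_D32_137,e_ppm_s137,PP2C,D32_137,PP2C__D32_137,D32,20.0,2.0,,,literature
PP2C_S137_D32_34_137,e_ppm_s137,PP2C,D32_34_137,PP2C__D32_34_137,D32_34,20.0,2.0,,,literature
PP2C_S137_D32_75_137,e_ppm_s137,PP2C,D32_75_137,PP2C__D32_75_137,D32_75,20.0,2.0,,,literature
PP2C_S137_D32_34_75_137,e_ppm_s137,PP2C,D32_34_75_137,PP2C__D32_34_75_137,D32_34_75,20.0,2.0,,,literature
PKAc_phos_I1,e_pka_i1,PKAc,I1,PKAc__I1,I1p,,4.0,2.5,16.0,literature
PP2B_dephos_I1p,e_pp2b_i1,PP2B_CaM,I1p,PP2B_CaM__I1p,I1,2.0,5.0,,,literature
PKAc_phos_845,e_pka_845,PKAc,AMPAR,PKAc__AMPAR,AMPAR_845,,0.5,2.5,2.0,literature
CaMKII_phos_831,e_kii_831,CaMKIIp_CaM,AMPAR_845,CaMKIIp_CaM__AMPAR_845,AMPAR_845_831,,0.6,3.0,2.4,literature
PP1_dephos_845,e_pp1_845,PP1,AMPAR_845,PP1__AMPAR_845,AMPAR,,4.0,20.0,16.0,tuned
PP2A_dephos_845,e_p2a_845,PP2A_Ca,AMPAR_845,PP2A_Ca__AMPAR_845,AMPAR,1.0,0.5,,,tuned
PP1_dephos_845m,e_pp1_845m,PP1,AMPAR_845_A,PP1__AMPAR_845_A,AMPAR_A,,0.06,0.3,0.24,tuned
PP1_dephos_831m,e_pp1_831m,PP1,AMPAR_845_831_A,PP1__AMPAR_845_831_A,AMPAR_845_A,,0.06,0.3,0.24,tuned
sorting_to_bulk,e_sort_in,Sorter,AMPAR,Sorter__AMPAR,BulkAMPAR,,0.1,0.05,0.4,tuned
sorting_from_bulk,e_sort_out,Sorter,BulkAMPAR,Sorter__BulkAMPAR,AMPAR,,0.1,0.05,0.4,tuned
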