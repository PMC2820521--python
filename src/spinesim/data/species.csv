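# Synthetic reconstruction of the D1R-spine model parameter tables
# (topology from the published block/trafficking diagrams; free rate
# constants hand-calibrated to the documented qualitative behaviors).
# Units: concentrations uM, time s, kf uM^-1 s^-1, kb/kcat s^-1.
name,initial_conc,clamped,moieties
Ca,0.06,1,Ca:1
DA,0.01,1,DA:1
ATP,2000.0,1,ATP:1
AMP,0.0,1,AMP:1
D1R,1.0,0,D1R:1
Golf,2.0,0,Golf:1
AC5,2.5,0,AC5:1
PDE,2.0,0,PDE:1
PDEp,0.0,0,PDE:1
cAMP,0.0,0,cAMP:1
PKA,2.5,0,PKAc:1;PKAr:1
PKAc,0.0,0,PKAc:1
CaM,10.0,0,CaM:1
CaMKII,8.0,0,CaMKII:1
CaMKIIp_CaM,0.0,0,CaMKII:1;CaM:1;Ca:4
PP2B,2.0,0,PP2B:1
CK1,0.0,0,CK1:1
CK1p,1.0,0,CK1:1
Cdk5,1.2,0,Cdk5:1
Cdk5a,0.0,0,Cdk5:1
PP2A,2.0,0,PP2A:1
PP2Ap,0.0,0,PP2A:1
PP2C,1.0,0,PP2C:1
PP1,2.0,0,PP1:1
I1,1.5,0,I1:1
I1p,0.0,0,I1:1
D32,50.0,0,D32:1
D32_34,0.0,0,D32:1
D32_75,0.0,0,D32:1
D32_137,0.0,0,D32:1
D32_34_75,0.0,0,D32:1
D32_34_137,0.0,0,D32:1
D32_75_137,0.0,0,D32:1
D32_34_75_137,0.0,0,D32:1
AMPAR,2.0,0,AMPAR:1
AMPAR_845,0.0,0,AMPAR:1
AMPAR_845_831,0.0,0,AMPAR:1
Anchor,2.0,0,Anchor:1
BulkAMPAR,2.0,0,AMPAR:1
Sorter,0.5,0,Sorter:1
PKA_cAMP,0.0,0,PKAc:1;PKAr:1;cAMP:1
PKA_cAMP2,0.0,0,PKAc:1;PKAr:1;cAMP:2
PKAr_cAMP2,0.0,0,PKAr:1;cAMP:2
CaM_Ca2,0.0,0,CaM:1;Ca:2
CaM_Ca4,0.0,0,CaM:1;Ca:4
DA_D1R,0.0,0,DA:1;D1R:1
DA_D1R_Golf,0.0,0,DA:1;D1R:1;Golf:1
AC5_Golf,0.0,0,AC5:1;DA:1;D1R:1;Golf:1
AC5_Ca,0.0,0,Ca:1;AC5:1
AC5_Golf_Ca,0.0,0,Ca:1;AC5:1;DA:1;D1R:1;Golf:1
AC5_Golf__ATP,0.0,0,AC5:1;DA:1;D1R:1;Golf:1;ATP:1
PDE__cAMP,0.0,0,PDE:1;cAMP:1
PKAc__PDE,0.0,0,PKAc:1;PDE:1
PDEp__cAMP,0.0,0,PDE:1;cAMP:1
PP2C__PDEp,0.0,0,PP2C:1;PDE:1
PDE_CaM,0.0,0,CaM:1;Ca:4;PDE:1
PDE_CaM__cAMP,0.0,0,CaM:1;Ca:4;PDE:1;cAMP:1
CaMKII_CaM,0.0,0,CaM:1;Ca:4;CaMKII:1
CaMKII_CaM__CaMKII_CaM,0.0,0,CaM:2;Ca:8;CaMKII:2
PP1__CaMKIIp_CaM,0.0,0,PP1:1;CaMKII:1;CaM:1;Ca:4
PP2B_CaM,0.0,0,PP2B:1;CaM:1;Ca:4
CK1__CK1,0.0,0,CK1:2
PP2B_CaM__CK1p,0.0,0,PP2B:1;CaM:1;Ca:4;CK1:1
CK1__Cdk5,0.0,0,CK1:1;Cdk5:1
PP2C__Cdk5a,0.0,0,PP2C:1;Cdk5:1
PP2A_Ca,0.0,0,PP2A:1;Ca:1
PKAc__PP2A,0.0,0,PKAc:1;PP2A:1
PP1__PP2Ap,0.0,0,PP1:1;PP2A:1
PKAc__D32,0.0,0,PKAc:1;D32:1
PKAc__D32_137,0.0,0,PKAc:1;D32:1
PP2B_CaM__D32_34,0.0,0,PP2B:1;CaM:1;Ca:4;D32:1
PP2B_CaM__D32_34_75,0.0,0,PP2B:1;CaM:1;Ca:4;D32:1
PP2B_CaM__D32_34_137,0.0,0,PP2B:1;CaM:1;Ca:4;D32:1
PP2B_CaM__D32_34_75_137,0.0,0,PP2B:1;CaM:1;Ca:4;D32:1
Cdk5a__D32,0.0,0,Cdk5:1;D32:1
Cdk5a__D32_34,0.0,0,Cdk5:1;D32:1
Cdk5a__D32_137,0.0,0,Cdk5:1;D32:1
Cdk5a__D32_34_137,0.0,0,Cdk5:1;D32:1
PP2A_Ca__D32_75,0.0,0,PP2A:1;Ca:1;D32:1
PP2A_Ca__D32_34_75,0.0,0,PP2A:1;Ca:1;D32:1
PP2A_Ca__D32_75_137,0.0,0,PP2A:1;Ca:1;D32:1
PP2A_Ca__D32_34_75_137,0.0,0,PP2A:1;Ca:1;D32:1
PP2Ap__D32_75,0.0,0,PP2A:1;D32:1
PP2Ap__D32_34_75,0.0,0,PP2A:1;D32:1
PP2Ap__D32_75_137,0.0,0,PP2A:1;D32:1
PP2Ap__D32_34_75_137,0.0,0,PP2A:1;D32:1
CK1__D32,0.0,0,CK1:1;D32:1
CK1__D32_34,0.0,0,CK1:1;D32:1
CK1__D32_75,0.0,0,CK1:1;D32:1
CK1__D32_34_75,0.0,0,CK1:1;D32:1
PP2C__D32_137,0.0,0,PP2C:1;D32:1
PP2C__D32_34_137,0.0,0,PP2C:1;D32:1
PP2C__D32_75_137,0.0,0,PP2C:1;D32:1
PP2C__D32_34_75_137,0.0,0,PP2C:1;D32:1
D32_75_PKAc,0.0,0,D32:1;PKAc:1
D32_75_137_PKAc,0.0,0,D32:1;PKAc:1
D32_34_PP1,0.0,0,D32:1;PP1:1
D32_34_137_PP1,0.0,0,D32:1;PP1:1
PKAc__I1,0.0,0,PKAc:1;I1:1
PP2B_CaM__I1p,0.0,0,PP2B:1;CaM:1;Ca:4;I1:1
I1p_PP1,0.0,0,I1:1;PP1:1
PKAc__AMPAR,0.0,0,PKAc:1;AMPAR:1
CaMKIIp_CaM__AMPAR_845,0.0,0,CaMKII:1;CaM:1;Ca:4;AMPAR:1
PP1__AMPAR_845,0.0,0,PP1:1;AMPAR:1
PP2A_Ca__AMPAR_845,0.0,0,PP2A:1;Ca:1;AMPAR:1
AMPAR_845_A,0.0,0,AMPAR:1;Anchor:1
AMPAR_845_831_A,0.0,0,AMPAR:1;Anchor:1
PP1__AMPAR_845_A,0.0,0,PP1:1;AMPAR:1;Anchor:1
PP1__AMPAR_845_831_A,0.0,0,PP1:1;AMPAR:1;Anchor:1
AMPAR_A,0.0,0,AMPAR:1;Anchor:1
Sorter__AMPAR,0.0,0,Sorter:1;AMPAR:1
Sorter__BulkAMPAR,0.0,0,Sorter:1;AMPAR:1
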