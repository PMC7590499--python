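prefix,group,category
A,any,infections
B,any,infections
G00,any,infections
G03,any,infections
J12,any,infections
J13,any,infections
J14,any,infections
J15,any,infections
J16,any,infections
J17,any,infections
J18,any,infections
P36,any,infections
O85,maternal,infections
C,any,malignant_neoplasms
Q,any,congenital_malformations
P05,any,fetal_growth_restriction
P20,stillbirth,intrauterine_hypoxia
P21,stillbirth,intrapartum_hypoxia
P07,neonate,preterm_complications
P03,neonate,intrapartum_complications
O0,maternal,abortion
O15,maternal,eclampsia
O44,maternal,obstetric_hemorrhage
O45,maternal,obstetric_hemorrhage
O46,maternal,obstetric_hemorrhage
O67,maternal,obstetric_hemorrhage
O72,maternal,obstetric_hemorrhage
O,maternal,other_obstetric_complications
R96,any,non_conclusive
R98,any,non_conclusive
R99,any,non_conclusive
,maternal,non_obstetric_diseases
,neonate,other_diseases
,child,other_diseases
,other_adult,other_diseases
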