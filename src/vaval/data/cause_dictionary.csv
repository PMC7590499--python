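code,label,groups
infections,Infections,stillbirth;neonate;child;maternal;other_adult
fetal_growth_restriction,Fetal growth restriction,stillbirth
intrapartum_hypoxia,Intrapartum hypoxia,stillbirth
intrauterine_hypoxia,Intrauterine hypoxia,stillbirth
congenital_malformations,Congenital malformations,stillbirth;neonate;child
preterm_complications,Preterm complications,neonate
intrapartum_complications,Intrapartum complication,neonate
malignant_neoplasms,Malignant neoplasms,child;other_adult
abortion,Abortion,maternal
eclampsia,Eclampsia,maternal
obstetric_hemorrhage,Obstetric hemorrhage,maternal
other_obstetric_complications,Other obstetric complications,maternal
non_obstetric_diseases,Non-obstetric diseases,maternal
other_diseases,Other diseases,neonate;child;other_adult
non_conclusive,Non-conclusive,stillbirth;neonate;child;maternal;other_adult
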