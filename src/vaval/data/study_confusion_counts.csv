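table,group,cause,tp,tn,fp,fn,sensitivity,specificity,ppv,npv
broad,stillbirth,infections,0,14,0,4,0,100,N/A,78
broad,stillbirth,fetal_growth_restriction,0,10,1,7,0,91,0,59
broad,stillbirth,intrapartum_hypoxia,0,15,0,3,0,100,N/A,83
broad,stillbirth,intrauterine_hypoxia,0,16,0,2,0,100,N/A,89
broad,stillbirth,congenital_malformations,0,11,7,0,N/A,61,0,100
broad,stillbirth,non_conclusive,1,7,9,1,50,44,10,88
broad,neonate,infections,25,2,12,2,93,14,68,50
broad,neonate,congenital_malformations,1,37,0,3,25,100,100,92
broad,neonate,preterm_complications,0,36,0,5,0,100,N/A,88
broad,neonate,intrapartum_complications,1,36,2,2,33,95,33,95
broad,neonate,other_diseases,0,39,0,2,0,100,N/A,95
broad,neonate,non_conclusive,0,41,0,0,N/A,100,N/A,100
broad,child,infections,35,3,9,7,83,25,80,30
broad,child,congenital_malformations,0,52,0,2,0,100,N/A,96
broad,child,malignant_neoplasms,0,47,0,7,0,100,N/A,87
broad,child,other_diseases,0,44,7,3,0,86,0,94
broad,child,non_conclusive,0,51,3,0,N/A,94,0,100
broad,maternal,infections,11,39,13,28,28,75,46,58
broad,maternal,abortion,0,82,0,9,0,100,N/A,90
broad,maternal,eclampsia,3,64,23,1,75,74,12,98
broad,maternal,obstetric_hemorrhage,12,59,16,4,75,79,43,94
broad,maternal,other_obstetric_complications,0,85,0,6,0,100,N/A,93
broad,maternal,non_obstetric_diseases,4,67,8,12,25,89,33,85
broad,maternal,non_conclusive,0,89,1,1,0,99,0,99
broad,other_adult,infections,54,20,12,26,68,62,82,43
broad,other_adult,malignant_neoplasms,3,95,1,13,19,99,75,88
broad,other_adult,other_diseases,10,66,30,6,62,69,25,92
broad,other_adult,non_conclusive,0,110,2,0,N/A,98,0,100
infection,all,disseminated_infections,0,139,2,51,0,99,0,73
infection,all,pneumonia,13,102,54,23,36,65,19,82
infection,all,meningitis,3,173,4,12,20,98,43,94
infection,all,tuberculosis,0,183,2,7,0,99,0,96
infection,all,diarrhoea,0,186,4,2,0,98,0,99
infection,all,hiv_aids_related,18,120,15,39,32,89,55,75
infection,all,malaria,2,181,5,4,33,97,29,98
infection,all,other_infections,0,171,3,18,0,98,0,90
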