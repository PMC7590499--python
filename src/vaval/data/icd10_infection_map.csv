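prefix,group,category
P36,any,disseminated_infections
O85,any,disseminated_infections
A40,any,disseminated_infections
A41,any,disseminated_infections
J12,any,pneumonia
J13,any,pneumonia
J14,any,pneumonia
J15,any,pneumonia
J16,any,pneumonia
J17,any,pneumonia
J18,any,pneumonia
G00,any,meningitis
G03,any,meningitis
A15,any,tuberculosis
A16,any,tuberculosis
A09,any,diarrhoea
A19,any,hiv_aids_related
B20,any,hiv_aids_related
B21,any,hiv_aids_related
B22,any,hiv_aids_related
B23,any,hiv_aids_related
B24,any,hiv_aids_related
B25,any,hiv_aids_related
B37,any,hiv_aids_related
B45,any,hiv_aids_related
B58,any,hiv_aids_related
B59,any,hiv_aids_related
B50,any,malaria
B51,any,malaria
B52,any,malaria
B53,any,malaria
B54,any,malaria
A33,any,other_infections
A35,any,other_infections
A82,any,other_infections
B46,any,other_infections
I30,any,other_infections
K65,any,other_infections
N10,any,other_infections
N11,any,other_infections
N12,any,other_infections
P35,any,other_infections
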