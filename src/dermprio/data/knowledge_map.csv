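code,name,mean_N,mean_P,mean_HP,std_N,std_P,std_HP
SebKer,Seborrheic Keratosis,80,17,3,0,7.7,7.7
ActKer,Actinic Keratosis,57,30,13,19,12,21
Nev,"Nevus, Non-neoplastic",67,30,3,19,23,8
MolCont,Molluscum Contagiosum,60,40,0,57,45,12
Haem,Haemangioma,67,23,10,31,21,12
UncNeop,Neoplasm Unc. Behavior,40,50,10,39,28,12
Drmfib,Dermatofibroma,84,13,3,17,12,8
SLent,Solar Lentigo,84,13,3,17,12,8
PenFib,Pendulum Fibroma,93,7,0,15,15,0
VWart,Viral Warts,87,10,3,12,12,8
OtMalNeop,Other Malignant Neoplasm,9,42,49,17,23,21
BCC,Basal Cell Carcinoma,26,57,17,24,22,8
MM,Malignant Melanoma,0,10,90,0,12,12
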