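code,partition,N,P,HP
SebKer,train,893,54,2
ActKer,train,350,56,10
Nev,train,444,46,5
MolCont,train,54,2,0
Haem,train,41,13,2
UncNeop,train,162,32,2
Drmfib,train,103,9,0
SLent,train,38,1,0
PenFib,train,77,14,0
VWart,train,137,17,0
OtMalNeop,train,47,21,25
BCC,train,8,37,0
MM,train,13,9,22
SebKer,test1,226,8,3
ActKer,test1,89,14,0
Nev,test1,114,8,0
MolCont,test1,7,8,0
Haem,test1,7,6,1
UncNeop,test1,37,4,9
Drmfib,test1,22,5,1
SLent,test1,7,2,0
PenFib,test1,21,1,1
VWart,test1,36,1,1
OtMalNeop,test1,3,6,14
BCC,test1,1,7,3
MM,test1,0,0,8
SebKer,test2,12,8,3
ActKer,test2,10,14,0
Nev,test2,11,8,0
MolCont,test2,2,8,0
Haem,test2,6,6,1
UncNeop,test2,5,4,9
Drmfib,test2,5,5,1
SLent,test2,7,2,0
PenFib,test2,11,1,1
VWart,test2,11,1,1
OtMalNeop,test2,0,6,14
BCC,test2,1,7,3
MM,test2,0,0,8
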