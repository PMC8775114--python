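code,sensitivity,precision,f1
SebKer,43.46,68.67,53.23
ActKer,44.66,63.89,52.57
Nev,36.07,44.44,39.82
MolCont,33.33,17.24,22.73
Haem,14.29,14.29,14.29
UncNeop,16.00,17.78,16.84
Drmfib,64.29,25.00,36.00
SLent,11.11,7.14,8.70
PenFib,26.09,30.00,27.91
VWart,57.89,36.67,44.90
OtMalNeop,13.03,8.57,10.34
BCC,9.09,2.44,3.85
MM,62.50,16.67,26.32
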