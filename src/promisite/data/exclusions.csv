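code,category
HOH,solvent
DOD,solvent
WAT,solvent
EDO,additive
GOL,additive
PEG,additive
PG4,additive
MPD,additive
DMS,additive
ACT,additive
ACY,additive
FMT,additive
EOH,solvent
IPA,solvent
BME,additive
DTT,additive
TRS,buffer
EPE,buffer
MES,buffer
BCT,buffer
CIT,buffer
PO4,ion
SO4,ion
NO3,ion
CL,ion
BR,ion
IOD,ion
F,ion
NA,metal
K,metal
MG,metal
CA,metal
ZN,metal
MN,metal
FE,metal
FE2,metal
CU,metal
CO,metal
NI,metal
CD,metal
HG,metal
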