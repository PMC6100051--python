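functional,basis,environment,state,energy_eV,osc_strength
PBE0,aug-cc-pVDZ,gas,1,3.57,0.28
PBE0,aug-cc-pVDZ,gas,2,3.81,0.000048
PBE0,aug-cc-pVDZ,gas,3,3.85,0.077
PBE0,aug-cc-pVDZ,gas,4,4.47,0.015
PBE0,aug-cc-pVDZ,gas,5,4.54,0.3
PBE0,aug-cc-pVTZ,gas,1,3.57,0.28
PBE0,aug-cc-pVTZ,gas,2,3.83,0.000058
PBE0,aug-cc-pVTZ,gas,3,3.86,0.072
PBE0,aug-cc-pVTZ,gas,4,4.49,0.015
PBE0,aug-cc-pVTZ,gas,5,4.54,0.31
B3LYP,aug-cc-pVDZ,gas,1,3.43,0.28
B3LYP,aug-cc-pVDZ,gas,2,3.71,0.00033
B3LYP,aug-cc-pVDZ,gas,3,3.73,0.00055
B3LYP,aug-cc-pVDZ,gas,4,4.22,0.013
B3LYP,aug-cc-pVDZ,gas,5,4.36,0.25
B3LYP,aug-cc-pVTZ,gas,1,3.44,0.28
B3LYP,aug-cc-pVTZ,gas,2,3.73,0.052
B3LYP,aug-cc-pVTZ,gas,3,3.74,0.00056
B3LYP,aug-cc-pVTZ,gas,4,4.23,0.013
B3LYP,aug-cc-pVTZ,gas,5,4.36,0.26
PBE0,cc-pVDZ,gas,1,3.64,0.26
PBE0,cc-pVDZ,gas,2,3.83,0.000021
PBE0,cc-pVDZ,gas,3,3.95,0.062
PBE0,cc-pVDZ,gas,4,4.65,0.36
PBE0,cc-pVDZ,gas,5,5.13,0.00014
PBE0,cc-pVTZ,gas,1,3.65,0.27
PBE0,cc-pVTZ,gas,2,3.86,0.000041
PBE0,cc-pVTZ,gas,3,3.94,0.073
PBE0,cc-pVTZ,gas,4,4.64,0.34
PBE0,cc-pVTZ,gas,5,5.15,0.00021
B3LYP,cc-pVDZ,gas,1,3.52,0.26
B3LYP,cc-pVDZ,gas,2,3.74,0.000015
B3LYP,cc-pVDZ,gas,3,3.82,0.045
B3LYP,cc-pVDZ,gas,4,4.48,0.31
B3LYP,cc-pVDZ,gas,5,4.88,0.000038
B3LYP,cc-pVTZ,gas,1,3.52,0.27
B3LYP,cc-pVTZ,gas,2,3.78,0.000035
B3LYP,cc-pVTZ,gas,3,3.81,0.052
B3LYP,cc-pVTZ,gas,4,4.46,0.29
B3LYP,cc-pVTZ,gas,5,4.91,0.000026
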