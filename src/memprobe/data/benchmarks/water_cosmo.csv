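functional,basis,environment,state,energy_eV,osc_strength
PBE0,aug-cc-pVDZ,water-cosmo,1,3.33,0.46
PBE0,aug-cc-pVDZ,water-cosmo,2,3.69,0.089
PBE0,aug-cc-pVDZ,water-cosmo,3,3.96,0.000054
PBE0,aug-cc-pVDZ,water-cosmo,4,4.32,0.21
PBE0,aug-cc-pVDZ,water-cosmo,5,4.67,0.016
PBE0,aug-cc-pVTZ,water-cosmo,1,3.34,0.45
PBE0,aug-cc-pVTZ,water-cosmo,2,3.70,0.089
PBE0,aug-cc-pVTZ,water-cosmo,3,3.98,0.000067
PBE0,aug-cc-pVTZ,water-cosmo,4,4.33,0.23
PBE0,aug-cc-pVTZ,water-cosmo,5,4.67,0.015
B3LYP,aug-cc-pVDZ,water-cosmo,1,3.19,0.45
B3LYP,aug-cc-pVDZ,water-cosmo,2,3.57,0.062
B3LYP,aug-cc-pVDZ,water-cosmo,3,3.88,0.000061
B3LYP,aug-cc-pVDZ,water-cosmo,4,4.12,0.18
B3LYP,aug-cc-pVDZ,water-cosmo,5,4.43,0.014
B3LYP,aug-cc-pVTZ,water-cosmo,1,3.21,0.44
B3LYP,aug-cc-pVTZ,water-cosmo,2,3.58,0.065
B3LYP,aug-cc-pVTZ,water-cosmo,3,3.92,0.000074
B3LYP,aug-cc-pVTZ,water-cosmo,4,4.15,0.20
B3LYP,aug-cc-pVTZ,water-cosmo,5,4.44,0.014
PBE0,cc-pVDZ,water-cosmo,1,3.44,0.37
PBE0,cc-pVDZ,water-cosmo,2,3.82,0.10
PBE0,cc-pVDZ,water-cosmo,3,3.98,0.000039
PBE0,cc-pVDZ,water-cosmo,4,4.47,0.29
PBE0,cc-pVDZ,water-cosmo,5,5.11,0.016
PBE0,cc-pVTZ,water-cosmo,1,3.44,0.41
PBE0,cc-pVTZ,water-cosmo,2,3.80,0.10
PBE0,cc-pVTZ,water-cosmo,3,4.04,0.000064
PBE0,cc-pVTZ,water-cosmo,4,4.44,0.27
PBE0,cc-pVTZ,water-cosmo,5,5.09,0.45
B3LYP,cc-pVDZ,water-cosmo,1,3.32,0.37
B3LYP,cc-pVDZ,water-cosmo,2,3.69,0.073
B3LYP,cc-pVDZ,water-cosmo,3,3.90,0.000034
B3LYP,cc-pVDZ,water-cosmo,4,4.28,0.24
B3LYP,cc-pVDZ,water-cosmo,5,4.95,0.27
B3LYP,cc-pVTZ,water-cosmo,1,3.31,0.41
B3LYP,cc-pVTZ,water-cosmo,2,3.68,0.074
B3LYP,cc-pVTZ,water-cosmo,3,3.97,0.000058
B3LYP,cc-pVTZ,water-cosmo,4,4.26,0.22
B3LYP,cc-pVTZ,water-cosmo,5,4.95,0.33
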