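functional,basis,environment,state,energy_eV,osc_strength
PBE0,aug-cc-pVDZ,cyclohexane-cosmo,1,3.46,0.39
PBE0,aug-cc-pVDZ,cyclohexane-cosmo,2,3.79,0.092
PBE0,aug-cc-pVDZ,cyclohexane-cosmo,3,3.86,0.000058
PBE0,aug-cc-pVDZ,cyclohexane-cosmo,4,4.44,0.32
PBE0,aug-cc-pVDZ,cyclohexane-cosmo,5,4.55,0.019
PBE0,aug-cc-pVTZ,cyclohexane-cosmo,1,3.47,0.39
PBE0,aug-cc-pVTZ,cyclohexane-cosmo,2,3.80,0.088
PBE0,aug-cc-pVTZ,cyclohexane-cosmo,3,3.88,0.000063
PBE0,aug-cc-pVTZ,cyclohexane-cosmo,4,4.44,0.34
PBE0,aug-cc-pVTZ,cyclohexane-cosmo,5,4.56,0.018
B3LYP,aug-cc-pVDZ,cyclohexane-cosmo,1,3.33,0.39
B3LYP,aug-cc-pVDZ,cyclohexane-cosmo,2,3.67,0.066
B3LYP,aug-cc-pVDZ,cyclohexane-cosmo,3,3.77,0.000052
B3LYP,aug-cc-pVDZ,cyclohexane-cosmo,4,4.26,0.27
B3LYP,aug-cc-pVDZ,cyclohexane-cosmo,5,4.30,0.016
B3LYP,aug-cc-pVTZ,cyclohexane-cosmo,1,3.34,0.39
B3LYP,aug-cc-pVTZ,cyclohexane-cosmo,2,3.67,0.063
B3LYP,aug-cc-pVTZ,cyclohexane-cosmo,3,3.79,0.000059
B3LYP,aug-cc-pVTZ,cyclohexane-cosmo,4,4.26,0.29
B3LYP,aug-cc-pVTZ,cyclohexane-cosmo,5,4.32,0.016
PBE0,cc-pVDZ,cyclohexane-cosmo,1,3.55,0.34
PBE0,cc-pVDZ,cyclohexane-cosmo,2,3.89,0.000033
PBE0,cc-pVDZ,cyclohexane-cosmo,3,3.90,0.082
PBE0,cc-pVDZ,cyclohexane-cosmo,4,4.56,0.40
PBE0,cc-pVDZ,cyclohexane-cosmo,5,5.15,0.37
PBE0,cc-pVTZ,cyclohexane-cosmo,1,3.55,0.36
PBE0,cc-pVTZ,cyclohexane-cosmo,2,3.89,0.091
PBE0,cc-pVTZ,cyclohexane-cosmo,3,3.902,0.000070
PBE0,cc-pVTZ,cyclohexane-cosmo,4,4.54,0.38
PBE0,cc-pVTZ,cyclohexane-cosmo,5,5.13,0.44
B3LYP,cc-pVDZ,cyclohexane-cosmo,1,3.43,0.34
B3LYP,cc-pVDZ,cyclohexane-cosmo,2,3.77,0.060
B3LYP,cc-pVDZ,cyclohexane-cosmo,3,3.79,0.000052
B3LYP,cc-pVDZ,cyclohexane-cosmo,4,4.38,0.34
B3LYP,cc-pVDZ,cyclohexane-cosmo,5,4.95,0.00029
B3LYP,cc-pVTZ,cyclohexane-cosmo,1,3.43,0.37
B3LYP,cc-pVTZ,cyclohexane-cosmo,2,3.77,0.066
B3LYP,cc-pVTZ,cyclohexane-cosmo,3,3.84,0.000052
B3LYP,cc-pVTZ,cyclohexane-cosmo,4,4.36,0.33
B3LYP,cc-pVTZ,cyclohexane-cosmo,5,4.98,0.33
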