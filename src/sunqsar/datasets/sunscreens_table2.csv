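id,nRot,Flex,Fsp3,logD,caco2,PPB
BMDM,6,0.429,0.300,4.08,-4.70,96.29
BP-3,3,0.231,0.071,3.42,-4.86,97.81
DHHB,12,0.857,0.417,4.26,-4.75,98.13
PABA,1,0.143,0.000,1.00,-5.24,43.55
EHDP,9,1.286,0.588,3.89,-4.90,98.46
Et-PABA,3,0.429,0.222,1.97,-5.12,74.52
PBSA,2,0.111,0.000,1.62,-5.59,98.51
MBC,1,0.063,0.500,3.85,-4.57,95.07
EHMC,10,1.250,0.500,3.86,-4.90,98.60
IMC,7,0.875,0.400,3.59,-4.80,96.20
OCR,10,0.667,0.333,4.52,-4.94,99.28
ET,30,1.111,0.500,5.09,-4.99,100.70
OS,8,1.143,0.533,3.53,-4.89,98.07
HMS,3,0.231,0.562,3.58,-4.87,98.30
DOBT,25,0.926,0.455,4.72,-5.06,99.40
BZ-4,4,0.267,0.071,1.87,-5.49,98.90
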