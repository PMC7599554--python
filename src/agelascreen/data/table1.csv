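name,csm_affinity,docking_score,mmgbsa_conf1,mmgbsa_conf2
CEAA,-11.1,-6.8,-50.81,-32.52
AA,-10.8,-4.59,-48.12,-21.33
CAA,-10.9,-6.65,-32.92,-16.3
DCEAA,-10.5,-6.13,-15.32,-15.42
PAA,-10.4,-5.62,-25.95,77.85
EAA,-10.5,-4.24,1293.69,3472.33
DeBAA,-10.1,-4.16,933.01,49.55
DeBEAA,-9.4,-4.38,1279.36,2815.08
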