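# Monoisotopic atomic masses, Da (7-decimal pinned constants, version 1)
# element	mass
C	12.0000000
H	1.0078250
N	14.0030740
O	15.9949146
S	31.9720707
P	30.9737615
Na	22.9897693
Cl	34.9688527
K	38.9637065
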