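c1ccccc1	M1
Cc1ccccc1	M2
Oc1ccccc1	M3
Clc1ccccc1	M4
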