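c1ccccc1	M1
Cc1ccccc1	M2
Oc1ccccc1	M3
Clc1ccccc1	M4
Nc1ccccc1	M5
CCc1ccccc1	M6
COc1ccccc1	M7
c1ccc2cc3ccccc3cc2c1	M8
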