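# marker coordinates as 0-based offsets within the bundled
# synthetic amplicons; windows are half-open
coib259_start = 20
coib259_end = 279
coib296_start = 10
coib296_end = 306
pos_1164 = 120
pos_1287 = 243
tpie4i4_start = 24
tpie4i4_end = 248
pos_tpi183 = 40
tpi_intron_start = 76
tpi_intron_end = 248
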