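>suppressor_trna_template anticodon_offset=33
TGTCACGACGGATCAGTCAATCGCCATGGGGTGNNNGCATATGAAACATTACATCAATCTCCAGATTGTTCGATAG
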