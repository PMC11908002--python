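name	sequence	role
P1_13_F	AATGGTAAGCTCCCAAACTCA	forward_shared
P2_13_R	ACCAAGGGCAAACTTCCTCGATG	reverse_insertion
P3_13_R	TTCACAAGCACTGACGGAT	reverse_flank
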