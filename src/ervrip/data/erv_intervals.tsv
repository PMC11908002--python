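label	accession	start	end
reference_carrier	GCA_016772045.2	41862971	41870900
east_friesian	GCA_022416915.1	42467070	42475012
white_dorper	GCA_002742125.1	45499852	45507607
reference_internal	GCA_016772045.2	1918	9847
cd36_gene	GCA_016772045.2	41861053	41968317
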