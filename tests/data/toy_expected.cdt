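GID	ORF	NAME	CLUSTER	GWEIGHT	S01	S02
EWEIGHT					1	1
GENE1X	YBR002W	YBR002W	0	1		2
GENE2X	YAL001C	YAL001C	1	1	1.5	-0.25
GENE3X	YCL003A	YCL003A	1	1	0	0.75
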