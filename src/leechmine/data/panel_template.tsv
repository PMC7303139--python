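name	family	accession	species	sequence	known_cys_count	synonyms
destabilase I	destabilase	AAA96144	Hirudo medicinalis		14	destabilase;lysozyme
leech-derived tryptase inhibitor	LDTI	AAB33769	Hirudo medicinalis		6	tryptase inhibitor;LDTI
hirudin	hirudin	APA20833	Hirudo verbana		6	hirudin;HV1;hirudin-like factor
bdellin	bdellin	P09865	Hirudo medicinalis		6	bdellin;bdellin B-3
eglin C	eglin	0905140A	unidentified leech		0	eglin;potato inhibitor
ghilanten	antistasin-family	AAB21233	Haementeria ghilianii		25	ghilanten;antistasin
guamerin	antistasin-family	AAD09442	Hirudo nipponia		9	guamerin;antistasin
cystatin	cystatin	AAN28679	Theromyzon tessulatum		1	cystatin;cystatin B
piguamerin	antistasin-family	P81499	Hirudo nipponia		10	piguamerin;antistasin
antistasin	antistasin-family	P15358	Haementeria officinalis		21	antistasin
bdellastasin	antistasin-family	1C9P	Hirudo medicinalis		10	bdellastasin;antistasin
manillase	manillase		Hirudinaria manillensis		0	manillase;hyaluronoglucuronidase;hyaluronidase
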