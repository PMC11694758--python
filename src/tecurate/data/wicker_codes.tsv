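# Wicker three-letter codes -> (order, superfamily)
# code	order	superfamily
RLC	LTR	Copia
RLG	LTR	Gypsy
RLB	LTR	Bel-Pao
RLR	LTR	Retrovirus
RLE	LTR	ERV
RLX	LTR
RYD	DIRS	DIRS
RYV	DIRS	VIPER
RYN	DIRS	Ngaro
RYX	DIRS
RPP	PLE	Penelope
RPX	PLE
RIR	LINE	R2
RIT	LINE	RTE
RIJ	LINE	Jockey
RIL	LINE	L1
RII	LINE	I
RIX	LINE
RST	SINE	tRNA
RSL	SINE	7SL
RSS	SINE	5S
RSX	SINE
DTT	TIR	Tc1-Mariner
DTA	TIR	hAT
DTM	TIR	Mutator
DTE	TIR	Merlin
DTR	TIR	Transib
DTP	TIR	P
DTB	TIR	PiggyBac
DTH	TIR	PIF-Harbinger
DTC	TIR	CACTA
DTX	TIR
DYC	Crypton	Crypton
DYX	Crypton
DHH	Helitron	Helitron
DHX	Helitron
DMM	Maverick	Maverick
DMX	Maverick
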