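# Expected structural features per TE order. A record passes the check if
# ANY alternative (separated by |) holds; an alternative is a conjunction
# of atoms separated by &. Atoms: ltr, tir, polya, no_ltr, no_tir,
# no_coding, len<=N, domain:<Role>, any_retro_domain, any_dna_domain.
# order	rule
LTR	ltr|domain:RT&domain:INT
LINE	polya&no_ltr|domain:RT&no_ltr|domain:EN&no_ltr
SINE	polya&len<=1000&no_coding
TIR	tir|domain:Transposase
MITE	tir&no_coding&len<=800
Helitron	domain:Helicase
DIRS	any_retro_domain
PLE	any_retro_domain
Maverick	any_dna_domain
Crypton	any_dna_domain
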