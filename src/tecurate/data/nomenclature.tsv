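# Accepted order tokens (case-insensitive) and their canonical form.
# kind: order   -> token maps to a canonical TE order
# kind: alias   -> token is normalized to the canonical order in `maps_to`
# kind: exclude -> sequences with this label are dropped (satellites, RNAs, simple repeats)
# token	kind	maps_to
LTR	order	LTR
LINE	order	LINE
SINE	order	SINE
DIRS	order	DIRS
PLE	order	PLE
Penelope	alias	PLE
TIR	order	TIR
DNA	alias	TIR
Helitron	order	Helitron
RC	alias	Helitron
Maverick	order	Maverick
Polinton	alias	Maverick
Crypton	order	Crypton
MITE	order	MITE
Unclassified	order	Unclassified
Unknown	alias	Unclassified
ClassI	order	ClassI
ClassII	order	ClassII
Satellite	exclude	satellite_or_rna
Simple_repeat	exclude	satellite_or_rna
Low_complexity	exclude	satellite_or_rna
rRNA	exclude	satellite_or_rna
tRNA	exclude	satellite_or_rna
snRNA	exclude	satellite_or_rna
scRNA	exclude	satellite_or_rna
srpRNA	exclude	satellite_or_rna
RNA	exclude	satellite_or_rna
ARTEFACT	exclude	excluded_nomenclature
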