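# Packaged cis-regulatory element catalog (name, IUPAC pattern, functional class).
# Patterns are this package's own editable fixtures in the style of common
# plant promoter catalogs; they are not asserted values from any database.
ABRE	ACGTGKC	ABA
MBS	CAACTG	drought
HSE	AGAANNTTCT	heat
LTR	CCGAAA	low_temperature
TGA-element	AACGAC	auxin
ERE	ATTTCAAA	ethylene
P-box	CCTTTTG	gibberellin
GARE-motif	TCTGTTG	gibberellin
CGTCA-motif	CGTCA	MeJA
TGACG-motif	TGACG	MeJA
TCA-element	CCATCTTTTT	salicylic_acid
ARE	AAACCA	anaerobic
circadian	CAANNNNATC	circadian
WUN-motif	AAATTTCCT	wound
Sp1	GGGCGG	light
G-box	CACGTG	light
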