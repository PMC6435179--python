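# Restriction enzyme panel used for the genomic screens.
# columns: name <tab> cut-site in caret notation (IUPAC) <tab> methylation_blocked
# methylation_blocked = yes means cleavage is blocked when the cytosine of a
# CpG inside the recognition site is methylated (the HpaII behaviour; its
# isoschizomer MspI cleaves regardless).
AluI	AG^CT	no
ApaI	GGGCC^C	no
BamHI	G^GATCC	no
BglI	GCCNNNN^NGGC	no
BglII	A^GATCT	no
EcoRI	G^AATTC	no
EcoRV	GAT^ATC	no
HaeIII	GG^CC	no
HindII	GTY^RAC	no
HindIII	A^AGCTT	no
HinfI	G^ANTC	no
HpaII	C^CGG	yes
MspI	C^CGG	no
NsiI	ATGCA^T	no
PvuII	CAG^CTG	no
RsaI	GT^AC	no
SacI	GAGCT^C	no
Sau3AI	^GATC	no
SmaI	CCC^GGG	no
SphI	GCATG^C	no
TaqI	T^CGA	no
XbaI	T^CTAGA	no
XhoI	C^TCGAG	no
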