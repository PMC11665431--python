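# Common cloning enzymes and their recognition sites (IUPAC patterns).
# NAME  IUPAC_PATTERN
EcoRI   GAATTC
BamHI   GGATCC
HindIII AAGCTT
XhoI    CTCGAG
NdeI    CATATG
NotI    GCGGCCGC
XbaI    TCTAGA
SalI    GTCGAC
NcoI    CCATGG
KpnI    GGTACC
SacI    GAGCTC
SpeI    ACTAGT
PstI    CTGCAG
SmaI    CCCGGG
EcoRV   GATATC
BglII   AGATCT
AvaI    CYCGRG
SphI    GCATGC
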