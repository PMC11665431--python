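# organism: Saccharomyces cerevisiae
# codon  aa  fraction  per_thousand
AAA K 0.58 41.9
AAC N 0.41 24.8
AAG K 0.42 30.8
AAT N 0.59 35.7
ACA T 0.30 17.8
ACC T 0.22 12.7
ACG T 0.14 8.0
ACT T 0.34 20.3
AGA R 0.48 21.3
AGC S 0.11 9.8
AGG R 0.21 9.2
AGT S 0.16 14.2
ATA I 0.27 17.8
ATC I 0.26 17.2
ATG M 1.00 20.9
ATT I 0.47 30.1
CAA Q 0.69 27.3
CAC H 0.36 7.8
CAG Q 0.31 12.1
CAT H 0.64 13.6
CCA P 0.42 18.3
CCC P 0.15 6.8
CCG P 0.12 5.3
CCT P 0.31 13.5
CGA R 0.07 3.0
CGC R 0.06 2.6
CGG R 0.04 1.7
CGT R 0.14 6.4
CTA L 0.14 13.4
CTC L 0.06 5.4
CTG L 0.11 10.5
CTT L 0.13 12.3
GAA E 0.70 45.1
GAC D 0.35 20.2
GAG E 0.30 19.2
GAT D 0.65 37.6
GCA A 0.29 16.2
GCC A 0.22 12.6
GCG A 0.11 6.2
GCT A 0.38 21.2
GGA G 0.22 10.9
GGC G 0.19 9.8
GGG G 0.12 6.0
GGT G 0.47 23.9
GTA V 0.21 11.8
GTC V 0.21 11.8
GTG V 0.19 10.8
GTT V 0.39 22.1
TAA * 0.48 1.1
TAC Y 0.44 14.8
TAG * 0.22 0.5
TAT Y 0.56 18.8
TCA S 0.21 18.7
TCC S 0.16 14.2
TCG S 0.10 8.6
TCT S 0.26 23.5
TGA * 0.30 0.7
TGC C 0.37 4.8
TGG W 1.00 10.4
TGT C 0.63 8.1
TTA L 0.28 26.2
TTC F 0.41 18.4
TTG L 0.28 27.2
TTT F 0.59 26.1
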