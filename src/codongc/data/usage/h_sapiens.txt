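# organism: Homo sapiens
# codon  aa  fraction  per_thousand
AAA K 0.43 24.4
AAC N 0.53 19.1
AAG K 0.57 31.9
AAT N 0.47 17.0
ACA T 0.28 15.1
ACC T 0.36 18.9
ACG T 0.11 6.1
ACT T 0.25 13.1
AGA R 0.22 12.2
AGC S 0.24 19.5
AGG R 0.21 12.0
AGT S 0.15 12.1
ATA I 0.17 7.5
ATC I 0.47 20.8
ATG M 1.00 22.0
ATT I 0.36 16.0
CAA Q 0.26 12.3
CAC H 0.58 15.1
CAG Q 0.74 34.2
CAT H 0.42 10.9
CCA P 0.28 16.9
CCC P 0.32 19.8
CCG P 0.11 6.9
CCT P 0.29 17.5
CGA R 0.11 6.2
CGC R 0.18 10.4
CGG R 0.20 11.4
CGT R 0.08 4.5
CTA L 0.07 7.2
CTC L 0.20 19.6
CTG L 0.39 39.4
CTT L 0.13 13.2
GAA E 0.42 29.0
GAC D 0.54 25.1
GAG E 0.58 39.6
GAT D 0.46 21.8
GCA A 0.23 15.8
GCC A 0.39 27.7
GCG A 0.11 7.4
GCT A 0.27 18.4
GGA G 0.25 16.5
GGC G 0.34 22.2
GGG G 0.25 16.5
GGT G 0.16 10.8
GTA V 0.12 7.1
GTC V 0.24 14.5
GTG V 0.46 28.1
GTT V 0.18 11.0
TAA * 0.29 1.0
TAC Y 0.56 15.3
TAG * 0.24 0.8
TAT Y 0.44 12.2
TCA S 0.15 12.2
TCC S 0.22 17.7
TCG S 0.05 4.4
TCT S 0.19 15.2
TGA * 0.47 1.6
TGC C 0.54 12.6
TGG W 1.00 13.2
TGT C 0.46 10.6
TTA L 0.08 7.7
TTC F 0.54 20.3
TTG L 0.13 12.9
TTT F 0.46 17.6
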