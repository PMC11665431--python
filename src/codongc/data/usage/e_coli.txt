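# organism: Escherichia coli K-12
# codon  aa  fraction  per_thousand
AAA K 0.74 33.6
AAC N 0.55 21.7
AAG K 0.26 12.1
AAT N 0.45 17.7
ACA T 0.13 7.1
ACC T 0.43 23.4
ACG T 0.27 14.4
ACT T 0.17 8.9
AGA R 0.04 2.1
AGC S 0.28 16.1
AGG R 0.02 1.2
AGT S 0.15 8.8
ATA I 0.07 4.4
ATC I 0.42 25.1
ATG M 1.00 27.9
ATT I 0.51 30.3
CAA Q 0.35 15.3
CAC H 0.43 9.7
CAG Q 0.65 28.8
CAT H 0.57 12.9
CCA P 0.19 8.4
CCC P 0.12 5.5
CCG P 0.53 23.2
CCT P 0.16 7.0
CGA R 0.07 3.6
CGC R 0.39 22.0
CGG R 0.10 5.4
CGT R 0.38 20.9
CTA L 0.04 3.9
CTC L 0.10 11.0
CTG L 0.50 51.5
CTT L 0.10 11.0
GAA E 0.69 39.4
GAC D 0.37 19.1
GAG E 0.31 17.8
GAT D 0.63 32.1
GCA A 0.21 20.1
GCC A 0.27 25.5
GCG A 0.36 33.6
GCT A 0.16 15.3
GGA G 0.11 8.0
GGC G 0.40 29.6
GGG G 0.15 11.1
GGT G 0.34 24.7
GTA V 0.15 10.9
GTC V 0.22 15.3
GTG V 0.37 26.4
GTT V 0.26 18.3
TAA * 0.65 2.0
TAC Y 0.43 12.2
TAG * 0.06 0.2
TAT Y 0.57 16.2
TCA S 0.12 7.2
TCC S 0.15 8.6
TCG S 0.15 8.9
TCT S 0.15 8.5
TGA * 0.29 0.9
TGC C 0.55 6.4
TGG W 1.00 15.2
TGT C 0.45 5.2
TTA L 0.13 13.9
TTC F 0.43 16.6
TTG L 0.13 13.7
TTT F 0.57 22.2
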