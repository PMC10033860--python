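# Representative antigen-binding-site codon positions of the class II DRB
# exon 2 peptide-binding region, after the human HLA-DRB1 contact residues
# of Brown et al. (1993), expressed in local exon-2 codon numbering
# (1..90).  Editable: replace with a study-specific list as needed.
9
11
13
26
28
30
32
37
38
47
56
57
60
61
65
67
68
70
71
74
78
81
82
85
86
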