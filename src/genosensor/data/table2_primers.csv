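exon,primer_name,primer_sequence_5to3,amplicon_size_bp
Exon 2,BRCA1_ek2_F_HRM,GAAGTTGTCATTTTATAAACCTTT,258
Exon 2,BRCA1_ek2_R_HRM,TGTCTTTTCTTCCCTAGTATGT,258
Exon 4,BRCA1_ek5_F_HRM,CTCTTAAGGGCAGTTGTGAG,235
Exon 4,BRCA1_ek5_R_HRM,TTCCTACTGTGGTTGCTTCC,235
Exon 10,BRCA1_ek11_F_HRM,CAGGGAGTTGGTCTGAGTGAC,181
Exon 10,BRCA1_ek11_R_HRM,GCTCCCCAAAAGCATAAAC,181
Exon 19,BRCA1_ek20_F_HRM,ATATGACGTGTCTGCTCCAC,401
Exon 19,BRCA1_ek20_R_HRM,GGGAATCCAAATTACACAGC,401
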