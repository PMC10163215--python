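>probe_DNA_1 role=probe orientation=5to3 variant=5370C>T mutation_bearing=false thiol=true
AGGTCCAAAGCGAGCAAGAGAAGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_1 role=target orientation=3to5 variant=5370C>T mutation_bearing=false thiol=false
TCCAGGTTTCGCTCGTTCTCTTCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_2 role=probe orientation=5to3 variant=5370C>T mutation_bearing=true thiol=true
AGGTCCAAAGTGAGCAAGAGAAGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_2 role=target orientation=3to5 variant=5370C>T mutation_bearing=true thiol=false
TCCAGGTTTCACTCGTTCTCTTCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_3 role=probe orientation=5to3 variant=5382insC mutation_bearing=false thiol=true
AAGAGAATCCC-AGGACAGAAAGGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_3 role=target orientation=3to5 variant=5382insC mutation_bearing=false thiol=false
TTCTCTTAGGG-TCCTGTCTTTCCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_4 role=probe orientation=5to3 variant=5382insC mutation_bearing=true thiol=true
AAGAGAATCCCCAGGACAGAAAGGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_4 role=target orientation=3to5 variant=5382insC mutation_bearing=true thiol=false
TTCTCTTAGGGGTCCTGTCTTTCCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_5 role=probe orientation=5to3 variant=c.4035delA mutation_bearing=false thiol=true
TCAGATGATGAAGAAAGAGGAACGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_5 role=target orientation=3to5 variant=c.4035delA mutation_bearing=false thiol=false
AGTCTACTACTTCTTTCTCCTTGCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_6 role=probe orientation=5to3 variant=c.4035delA mutation_bearing=true thiol=true
TCAGATGATGA-GAAAGAGGAACGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_6 role=target orientation=3to5 variant=c.4035delA mutation_bearing=true thiol=false
AGTCTACTACT-CTTTCTCCTTGCCTCACCCAGGGTAGTCAAACTT
>probe_DNA_7 role=probe orientation=5to3 variant=185delAG mutation_bearing=false thiol=true
CAGAAAATCTTAGAGTGTCCCATGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_7 role=target orientation=3to5 variant=185delAG mutation_bearing=false thiol=false
GTCTTTTAGAATCTCACAGGGTACCTCACCCAGGGTAGTCAAACTT
>probe_DNA_8 role=probe orientation=5to3 variant=185delAG mutation_bearing=true thiol=true
CAGAAAATCTTAG--TGTCCCATGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_8 role=target orientation=3to5 variant=185delAG mutation_bearing=true thiol=false
GTCTTTTAGAATC--ACAGGGTACCTCACCCAGGGTAGTCAAACTT
>probe_DNA_9 role=probe orientation=5to3 variant=3819del5GTAAA mutation_bearing=false thiol=true
ATTTGGTAAAGTAAACAATATACCTGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_9 role=target orientation=3to5 variant=3819del5GTAAA mutation_bearing=false thiol=false
TAAACCATTTCATTTGTTATATGGACCTCACCCAGGGTAGTCAAACTT
>probe_DNA_10 role=probe orientation=5to3 variant=3819del5GTAAA mutation_bearing=true thiol=true
ATTTGGTAAA-----CAATATACCTGGAGTGGGTCCCATCAGTTTGAA
>target_DNA_10 role=target orientation=3to5 variant=3819del5GTAAA mutation_bearing=true thiol=false
TAAACCATTT-----GTTATATGGACCTCACCCAGGGTAGTCAAACTT
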