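{
 "table1_oligos.fasta": "6d1c19f0a2a693a144e1b6ce26b73659ece98504f8062b5eb6d62997b7d191c4",
 "table2_primers.csv": "a2654a12cca0778893aff876205ec867bf2852c8198eae354e1a20bdecc6cb70",
 "table3_kinetics.csv": "2b2960b67ffcaa52d903f4b57bb534a167101465848335a93d10bdf3f45e5c4b",
 "table4_calls.csv": "8934a1a9f78ff57ffcb952432fde777b14a426acca9dc16a00064bba7376bd33"
}
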