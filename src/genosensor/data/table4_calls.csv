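panel,sample_id,status,qcmd_call,spr_call,pcr_call
5370C>T,5417/21,mutation,Ambiguous,Positive,Positive
5370C>T,5297/21,without mutation,Negative,Negative,Negative
5370C>T,5623/21,without mutation,Negative,Negative,Negative
5370C>T,5528/21,without mutation,Negative,Negative,Negative
5370C>T,5577/21,without mutation,Negative,Negative,Negative
5370C>T,5615/21,without mutation,Negative,Negative,Negative
5382insC,5675/21,mutation,Positive,Positive,Positive
5382insC,5398/21,mutation,Positive,Positive,Positive
5382insC,2225/21,mutation,Positive,Positive,Positive
5382insC,5714/21,mutation,Positive,Positive,Positive
5382insC,5675/21,mutation,Positive,positive,Positive
5382insC,5252/21,mutation,Positive,Positive,Positive
5382insC,5187/21,mutation,Positive,Positive,Positive
5382insC,4937/21,mutation,Positive,Positive,Positive
5382insC,4930/21,mutation,Positive,Positive,Positive
5382insC,4928/21,mutation,Positive,Positive,Positive
5382insC,5297/21,without mutation,Negative,Negative,Negative
5382insC,5623/21,without mutation,Ambiguous,Negative,Negative
5382insC,5528/21,without mutation,Negative,Negative,Negative
5382insC,5577/21,without mutation,Negative,Negative,Negative
5382insC,5615/21,without mutation,Negative,Negative,Negative
c.4035delA,1848/21,mutation,Positive,Positive,Positive
c.4035delA,2942/21,mutation,Positive,Positive,Positive
c.4035delA,5297/21,without mutation,Negative,Negative,Negative
c.4035delA,5623/21,without mutation,Negative,Negative,Negative
c.4035delA,5528/21,without mutation,Negative,Negative,Negative
c.4035delA,5577/21,without mutation,Negative,Negative,Negative
c.4035delA,5615/21,without mutation,Negative,Negative,Negative
185delAG,2342,mutation,Positive,Positive,Positive
185delAG,5297/21,without mutation,Negative,Negative,Negative
185delAG,5623/21,without mutation,Negative,Negative,Negative
185delAG,5528/21,without mutation,Negative,negative,Negative
185delAG,5577/21,without mutation,Negative,Negative,Negative
185delAG,5615/21,without mutation,Negative,Negative,Negative
3819del5GTAAA,1606/21,mutation,Positive,Positive,Positive
3819del5GTAAA,899/21,mutation,Positive,Positive,Positive
3819del5GTAAA,901/21,mutation,Positive,Positive,Positive
3819del5GTAAA,5297/21,without mutation,Negative,Negative,Negative
3819del5GTAAA,5623/21,without mutation,Negative,Negative,Negative
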