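# Known mouse XCI escapee genes used for the exclusion analysis.
Xist
Shroom4
Mid1
Kdm6a
Kdm5c
Jpx
Ftx
Eif2s3x
Ddx3x
Car5b
Bgn
BC022960
D930009K15Rik
6720401G13Rik
5530601H04Rik
2610029G23Rik
1810030O07Rik
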