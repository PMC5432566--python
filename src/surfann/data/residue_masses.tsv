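# Monoisotopic amino-acid residue masses (Da): residue = free amino acid - H2O.
# Three-letter symbol <TAB> mass. Leu and Ile are isobaric and reported merged
# downstream as "Leu/Ile". Override by passing your own file of the same shape.
Gly	57.02146
Ala	71.03711
Ser	87.03203
Pro	97.05276
Val	99.06841
Thr	101.04768
Cys	103.00919
Leu	113.08406
Ile	113.08406
Asn	114.04293
Asp	115.02694
Gln	128.05858
Lys	128.09496
Glu	129.04259
Met	131.04049
His	137.05891
Phe	147.06841
Arg	156.10111
Tyr	163.06333
Trp	186.07931
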