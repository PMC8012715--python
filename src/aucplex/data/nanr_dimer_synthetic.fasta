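>nanr_monomer_synthetic synthetic stand-in for the E. coli NanR monomer; 263 aa, 2 Trp + 2 Tyr (eps280 composition rule gives 13,980 /M/cm), average mass 29,481.6 Da (homodimer 59.0 kDa)
MIRAHGWRREGNGLSVQMGMIVGQAHLVKVNGQFMGVSNIKDKRLVDLVFATLHDARATA
SDGDPQAGYFAKRARLVLIENELVRSKLDLFSIVRTVVLALTQLQDIEIGALTIAIEKAP
GAQGQHVMLRIHECPPQETADELALLATSDDKEDERELEVYEINQALEAKVRRQRNDFNA
SLTGVTVFIFNPTAEQSPHLVECFRNRLDQLIRSLSSVEAKMKTLPKADSEMRRVCFTGL
WPALDEREIQSKRGEGLRPLEMP
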