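>operator_top_synthetic synthetic stand-in for the 35-bp (GGTATA)3-repeat operator duplex; flanking bases are not published, so AT-rich spacers consistent with the native promoter context are used
TAACGGTATAATAACGGTATAATAACGGTATAATA
>operator_bottom_synthetic reverse complement strand
TATTATACCGTTATTATACCGTTATTATACCGTTA
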