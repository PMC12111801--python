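block	receptor	limit
biocyc	PPARA	-8.13
biocyc	PPARB	-7.05
biocyc	PPARG	-7.52
biocyc	RXRA	-7.14
biocyc	RXRB	-6.85
biocyc	RXRG	-6.84
pubmed	PPARA	-8.12
pubmed	PPARB	-7.13
pubmed	PPARG	-7.17
pubmed	RXRA	-7.28
pubmed	RXRB	-6.94
pubmed	RXRG	-7.00
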