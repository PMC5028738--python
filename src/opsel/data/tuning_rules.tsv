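class	site	from	to	delta_nm	citation
LWS	164	S	A	-7	Asenjo et al. 1994 Neuron 12:1131; Yokoyama 2008 Annu Rev Genomics Hum Genet 9:259
LWS	269	T	A	-15	Asenjo et al. 1994 Neuron 12:1131; Yokoyama 2008 Annu Rev Genomics Hum Genet 9:259
SWS2	292	S	A	8	Takahashi & Ebrey 2003 Biochemistry 42:6025; Yokoyama 2008 Annu Rev Genomics Hum Genet 9:259
RH1	83	D	N	-6	Nathans 1990 Biochemistry 29:9746; Yokoyama 2008 Annu Rev Genomics Hum Genet 9:259
RH1	292	A	S	-10	Janz & Farrens 2001 Biochemistry 40:7219; Yokoyama 2008 Annu Rev Genomics Hum Genet 9:259
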